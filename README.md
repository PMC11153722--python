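# biodiv-relex

Unsupervised relation extraction for biodiversity literature. Given
sentences whose named entities are already annotated — habitats,
geographic locations, reproductive conditions (e.g. *flowering*,
*budburst*), and temporal expressions — the package decides, for every
co-occurring source–target mention pair, whether a binary relation holds:

* **has_time**: reproductive condition → temporal expression
  (*when* did the reproductive event happen?)
* **has_location**: habitat → geographic location
  (*where* does the habitat occur?)

Structured facts of this kind feed databases used for reforestation
planning and seed-collection timing, where the literature — not occurrence
records — holds most of the fine-grained phenology and habitat detail.

## The method

Formally, for a sentence *I* = [t₀…tₙ] with a source entity *E_S* and
target entity *E_T*, the task is binary classification of (*I*, *E_S*,
*E_T*) → y ∈ {0, 1}. All methods here are unsupervised (no task-specific
training):

1. **Token-type regex rules.** Each token maps to one character — `S`
   (source entity), `T` (target entity), `d` (comma/semicolon), `o`
   (other); entity membership beats delimiter status. Two regular
   expressions over this string extract related *consecutive* entities:
   `S+(o)?(To|Td|T)+` and `(?<!S)(To|Td|T)*T(o)?S+`. Every source and
   target mention fully contained in a match is paired. High precision,
   limited recall.
2. **Dependency distance.** A pair is related when the shortest
   undirected path between the mentions' tokens in the dependency parse
   has at most *n* edges (default n = 4, tuned on a development set via
   the provided sweep). As *n* grows this converges to the co-occurrence
   baseline that labels every pair positive.
3. **Zero-shot templates.** Each candidate becomes either a boolean-QA
   passage/question pair (“Is there \<habitat> in \<geographic
   location>?”, “Did \<reproductive condition> event happen on \<temporal
   expression>?”) or an NLI premise/hypothesis pair (“The \<habitat> was
   in \<geographic location>.”, “The \<reproductive condition> event
   happened on \<temporal expression>.”). Yes / entailment ⇒ related.
   Backends are pluggable: adapters for published BoolQ/NLI checkpoints
   (requiring the optional `transformers` extra), plus a deterministic
   `MockBackend` for offline runs and tests.
4. **Hybrid.** Step 1 labels the rule-matched pairs positive; only the
   remainder is sent to the backend. Optionally, runs of ≥ 2 coordinated
   same-type target mentions (matched by `(Et|E){2,}` over an
   entity-granular string) are grouped into one *compound* query whose
   verdict propagates to every member pair — fewer model calls and better
   recall on enumerations.

Evaluation reports precision, recall, F1 and the Matthews correlation
coefficient (MCC), plus inter-annotator agreement as symmetric F1.

Because the corpus the method was originally developed on is available
only on request, the package ships a seeded synthetic-corpus generator
that emulates its sentence structures (adjacent pairs, enumerations,
compound runs, reversed order, distractors) with gold labels assigned by
construction — every component is testable offline.

## Worked example

```python
from biodiv_relex import (RelationType, apply_regex_rules, encode_token_types,
                          generate_candidates, paper_fixture)

doc, gold = paper_fixture()
sentence = doc.sentences[0]
print(sentence.text)
tts = encode_token_types(sentence, RelationType.HAS_LOCATION)
print(tts.chars)
for a, b in sorted(apply_regex_rules(tts), key=lambda p: p[1].start):
    print(f"{a.text!r} -> {b.text!r}")
```

prints

```
The main observation site was conserved forest at Dongmakhai ( 18deg20'03"N , 102deg30'5"E , 190m a.s.l. ) .
oooooSSoToTTTdoooo
'conserved forest' -> 'Dongmakhai'
'conserved forest' -> '18deg20\'03"N , 102deg30\'5"E'
```

The habitat *conserved forest* (`SS`) is followed, one token apart, by a
run of geographic-location tokens, so the forward rule fires and both
location mentions inside the match — including the coordinate string,
whose internal comma encodes as `T`, not as a delimiter — are labelled
related. See `examples/` for the compound-entity walkthrough
(`worked_examples.py`), a full method comparison on synthetic data
(`method_comparison.py`), and the distance-threshold sweep
(`distance_sweep.py`).

The same pipeline runs from the shell:

```bash
biodiv-relex synth --seed 1 --n 200 --out corpus.conllu --gold gold.jsonl
biodiv-relex extract --in corpus.conllu --out preds.jsonl \
    --method hybrid_compound --relation has_time --mock-gold gold.jsonl
biodiv-relex evaluate --pred preds.jsonl --gold gold.jsonl --format markdown
```

Corpora travel as standard 10-column CoNLL-U with entity annotations in a
`biodiv=` FEATS feature (BIO tags, e.g. `biodiv=B-Habitat`); instances and
predictions travel as JSONL.

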