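# Methods

This note records the package's model of the task, the defaults and why
they were chosen, and what the synthetic corpus does and does not show.

## Task model

Relation extraction is cast as binary classification of intra-sentence
mention pairs. A sentence carries tokens (optionally with dependency
heads) and typed, contiguous, non-overlapping entity mentions of four
types: Habitat, GeographicLocation, ReproductiveCondition,
TemporalExpression. Two directed relation types fix the admissible pairs:
has_time (ReproductiveCondition → TemporalExpression) and has_location
(Habitat → GeographicLocation). Candidate generation enumerates the full
cross product of source-typed × target-typed mentions per sentence —
every co-occurring pair is a candidate, and labelling is a separate step.
Nested or discontinuous mentions and cross-sentence relations are out of
scope.

Token indices are 0-based internally; CoNLL-U's 1-based IDs (and HEAD=0
for the root) are converted at the I/O boundary only. Entity annotations
ride in the FEATS column as a `biodiv=<BIO-tag>` feature, keeping files
valid CoNLL-U; multiword-token ranges and empty nodes are skipped for
entity and dependency purposes. When decoding BIO, an `I-X` tag without a
preceding `B-X`/`I-X` of the same type starts a new mention (tolerant
ingestion of noisy annotations); the round-trip property
`decode(encode(s)) == s.mentions` is asserted only on well-formed input.
The JSONL instance reader returns `(instances, sentences)` rather than
instances alone: the sentence text/tokens must survive a read so that
write∘read is byte-identical.

## Regex rules

The per-relation token-type encoding maps each token to `S`, `T`, `d`
(comma or semicolon) or `o`, with entity membership taking precedence
over delimiter status — a comma inside a coordinate-style location
mention is `T`. Tokens of the two non-participating entity types fall
through to the ordinary `d`/`o` logic.

The two rules, `S+(o)?(To|Td|T)+` and `(?<!S)(To|Td|T)*T(o)?S+`, are
applied with ordinary regex-engine semantics: left-to-right,
non-overlapping, greedy scan, independently per rule, union of pair sets
across rules. A mention counts as matched only when its whole character
span lies inside the match — a partially covered mention was not matched
in any defensible sense. This scan dialect is verified equivalent to an
independent leftmost-longest enumeration (hand-written recognizers, no
regex engine) exhaustively in the test suite's oracle checks; the two
agree on all random S/T/d/o strings tried up to length 12.

Compound entities are maximal matches of `(Et|E){2,}` over an
entity-granular string (one `E` per mention of the type, one `t` per
other token): runs of ≥ 2 same-type mentions with at most one token
between neighbours. `joined_text` joins member texts and the single
intervening tokens with single spaces; original inter-token spacing is
not stored, which is irrelevant to the whitespace-insensitive templates.

## Dependency distance

The distance between two mentions is the minimum, over token pairs, of
the undirected shortest-path length in the graph formed by head links
(root excluded). Min-over-pairs is symmetric and tolerant of which token
"anchors" a multi-token mention; undirected traversal is what makes most
pairs reachable at all. Punctuation participates as parsed. Unreachable
pairs (fragmented parses) are labelled negative and counted in a warning.
The decision threshold defaults to n = 4; `sweep_distance_threshold`
reproduces the development-set procedure (n ∈ 1..8, pick the F1
maximizer). The distance matcher is exposed for comparison but excluded
from the hybrid, whose first step is the parameter-free regex rules.

## Zero-shot step

Four fixed templates (question and hypothesis per relation type) are
filled with entity surface text verbatim — no grammatical normalization,
by design; backends are expected to tolerate slightly ungrammatical
queries. Yes/entailment maps to 1; No/neutral/contradiction to 0.
Probabilistic BoolQ backends decide by argmax (threshold 0.5 when a
single probability is exposed). Backends must be deterministic; the
pipeline caches verdicts per (sentence, query text) and calls each unique
query once.

A compound query's verdict propagates uniformly to every covered pair.
When a compound covers pairs with mixed gold truth, uniform propagation
necessarily mislabels some member — a documented trade-off, not an
inference about ground truth. The gold-echoing mock answers positive iff
*any* covered pair is gold-positive; on the synthetic corpus compounds
are label-uniform, so recovery is exact. Compound grouping applies to
target entities by default; `PipelineConfig.compound_sources` extends it
to source runs sharing a target (off by default).

The three published-checkpoint adapters (RoBERTa-BoolQ, T5-BoolQ,
T5-large NLI) load lazily and require the optional `transformers`
dependency plus network access; absent either, they raise an actionable
error pointing at `MockBackend`. All tests and the acceptance script run
offline on the mock.

## Hybrid orchestration

Standalone regex evaluation labels non-matches 0 (so the rules can be
scored alone); in hybrid mode non-matches defer to the backend, and rule
positives are never overridden. Every candidate receives exactly one
label; backend calls never exceed candidates; compound grouping strictly
reduces calls whenever a compound covers ≥ 2 still-open pairs (a compound
with one remaining member is queried as a singleton — the full joined
text could otherwise misdescribe the one open pair).

## Dataset handling

Splitting is instance-level by default with fractions (0.7, 0.1, 0.2),
sizes `round(n·f)` and the remainder assigned to the last split —
deterministic given the seed. A sentence-level option keeps all instances
of a sentence in one split to guard against leakage. The co-occurrence
baseline labels every candidate positive; under the metric conventions
below it scores recall 1.0 and MCC 0.0 whenever both classes occur.

## Metrics

P = tp/(tp+fp), R = tp/(tp+fn), F1 = 2PR/(P+R), MCC =
(tp·tn − fp·fn)/√((tp+fp)(tp+fn)(tn+fp)(tn+fn)). Zero denominators give
0.0 for P/R/F1 and any zero factor gives 0.0 for MCC — the conventions
under which an all-positive classifier reports MCC 0.00. Agreement
between annotators is the F1 of one label vector against the other,
invariant under swapping (P and R exchange), micro-averaged over whatever
instances both labelled. Reports print percentages with two decimals.
The implementations are direct formula evaluations, cross-checked in the
test suite against scikit-learn on 1,000 random confusion matrices.

## Synthetic corpus

The generator emulates the sentence shapes the methods were designed
for, with defaults chosen once as the package's study conditions:
200 sentences; 70% has_time vs 30% has_location (phenology-focused source
material is dominated by reproduction–time pairs at roughly 3:1);
structure weights adjacent 0.30, enumeration 0.20, compound run 0.20,
reversed 0.15, distractor 0.15 (rule-matchable shapes in the majority,
with enough compound and distractor material to exercise the zero-shot
and baseline paths); a 0.25 chance of an appended unrelated source
clause. Gold labels are assigned by construction: rule-matchable shapes
and compound runs are positive for the first source, distractors and
appended sources negative. Consequently the regex rules have precision
1.0 on this corpus *by construction* — that mirrors their qualitative
behaviour on real text but is not evidence about real-corpus precision.

Planted parses use a head-percolation scheme: each mention chains into
its final token, the first source's final token is the root, fillers
default to the root, and a filler chain places every related target at
dependency distance exactly 3 and every unrelated pair strictly above it
(4 or 5). The value 3 sits inside the standard 1..8 sweep range and away
from the default n = 4, so threshold recovery by the sweep is an
informative check rather than a tautology. Only path lengths are
meaningful; the trees are not linguistically realistic, and no deprel
labels or OCR noise are emulated. Passing tests on this corpus therefore
demonstrate the pipeline's contracts (coverage, monotonicity, call
bounds, recovery of planted structure), not performance on real
literature.

Vocabularies are small closed lists shipped as a JSON data file —
habitats, toponyms, temporal expressions and reproductive terms typical
of dipterocarp phenology writing — so corpora reproduce bit-for-bit from
a seed with no downloads.

`paper_fixture()` returns three hand-built worked-example sentences
(coordinate-containing location enumeration; a forest/two-toponym
sentence that defeats both rules; a flowering/fruiting sentence with a
compound temporal run) with gold labels fixed by hand. Its two temporal
span granularities reflect the worked examples it reproduces: the
compound members are the full range expressions, while the template
functions accept any entity text directly.

## Numerical and degenerate-input choices

Fractions must sum to 1 within 1e-9. Empty candidate sets, sentences
without mentions, and empty documents flow through every method and
return empty results. Unreachable dependency pairs are negative, never
errors. UTF-8 everywhere; unicode punctuation in entity text is preserved
verbatim. CLI exit codes: 0 success, 1 usage/config error, 2 data or
backend error.

## Known limitations

No NER: entities must be pre-annotated. Transformer adapters are shipped
but unexercised by the offline test suite beyond their error contract.
The hybrid's reported 100% rows under the gold-echoing mock are upper
bounds measuring orchestration, not model quality. Rule behaviour on
languages or tokenizations other than whitespace-tokenized English
biodiversity prose is untested.
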