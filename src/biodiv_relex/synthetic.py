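"""Seeded synthetic corpora with gold relation labels.

The generator emulates the structure of sentences in phenology/ecology
abstracts about dipterocarp forests: a source mention (reproductive
condition or habitat) and one or more target mentions (temporal expression
or geographic location) arranged in one of five syntactic shapes:

* ``adjacent_pair`` — source immediately before its target (rule-1 matchable);
* ``enumeration`` — source followed by a delimiter-separated target run
  (rule-1 matchable, several positives);
* ``compound_run`` — >= 2 coordinated targets separated from the source by
  several tokens, so the regex rules stay silent and only the zero-shot
  step (ideally with compound grouping) can recover the positives;
* ``reversed_order`` — target before source (rule-2 matchable);
* ``distractor_only`` — co-occurring but unrelated pair (gold 0, not
  matchable by either rule).

Positive structures may also carry a trailing unrelated source clause
("; fruiting was not recorded"), contributing gold-negative pairs that no
rule matches.  Gold labels are assigned by construction, so on this corpus
the regex rules have precision 1.0 by design.

When ``parse_emission`` is on, synthetic head links are planted so that
every related pair sits at dependency distance exactly ``planted_distance``
and every unrelated pair strictly above it — a head-percolation scheme
(mention-final token heads its span, the first source heads the sentence)
in which only path lengths are meaningful, not deprel realism.

The vocabularies are small closed lists shipped with the package, so
corpora are reproducible without any download.  ``paper_fixture`` returns a
three-sentence mini-corpus of worked examples with hand-set gold labels.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .io import Document
from .model import (
    ROOT,
    EntityMention,
    EntityType,
    RelationInstance,
    RelationType,
    Sentence,
    Token,
)

STRUCTURES = (
    "adjacent_pair",
    "enumeration",
    "compound_run",
    "reversed_order",
    "distractor_only",
)

_DEFAULT_WEIGHTS = {
    "adjacent_pair": 0.30,
    "enumeration": 0.20,
    "compound_run": 0.20,
    "reversed_order": 0.15,
    "distractor_only": 0.15,
}


class GeneratorConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_sentences: int = 200
    #: Fraction of sentences carrying a has_time (vs has_location) pair.
    relation_mix: float = 0.7
    structure_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS)
    )
    #: Probability of appending an unrelated second source clause.
    extra_source_prob: float = 0.25
    parse_emission: bool = True
    #: Planted dependency distance of related pairs; unrelated pairs sit
    #: strictly above it.
    planted_distance: int = 3

    def __post_init__(self) -> None:
        unknown = set(self.structure_weights) - set(STRUCTURES)
        if unknown:
            raise GeneratorConfigError(f"unknown structures: {sorted(unknown)}")
        total = sum(self.structure_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise GeneratorConfigError(
                f"structure weights must sum to 1, got {total}"
            )
        if any(w < 0 for w in self.structure_weights.values()):
            raise GeneratorConfigError("structure weights must be non-negative")
        if not (0.0 <= self.relation_mix <= 1.0):
            raise GeneratorConfigError("relation_mix must lie in [0, 1]")
        if self.planted_distance < 1:
            raise GeneratorConfigError("planted_distance must be >= 1")


def _vocab() -> dict[str, list[str]]:
    with resources.files("biodiv_relex.data").joinpath("vocab.json").open(
        "r", encoding="utf-8"
    ) as handle:
        return json.load(handle)


class _SentenceBuilder:
    def __init__(self, sent_id: str):
        self.sent_id = sent_id
        self.tokens: list[str] = []
        self.mentions: list[EntityMention] = []

    def words(self, text: str) -> None:
        self.tokens.extend(text.split())

    def mention(self, entity_type: EntityType, text: str) -> EntityMention:
        words = text.split()
        start = len(self.tokens)
        self.tokens.extend(words)
        m = EntityMention(entity_type, start, start + len(words), " ".join(words))
        self.mentions.append(m)
        return m

    def build(self, heads: Optional[list[int]] = None) -> Sentence:
        toks = [
            Token(index=i, text=t, head=None if heads is None else heads[i])
            for i, t in enumerate(self.tokens)
        ]
        return Sentence(sent_id=self.sent_id, tokens=toks, mentions=list(self.mentions))


def _plant_heads(
    builder: _SentenceBuilder,
    source: EntityMention,
    targets: list[EntityMention],
    distance: int,
) -> list[int]:
    """Head links putting every target at exactly `distance` edges from `source`."""
    n = len(builder.tokens)
    root = source.end - 1
    heads = [root] * n
    heads[root] = ROOT
    in_mention = set()
    for m in builder.mentions:
        in_mention.update(m.span())
        for i in range(m.start, m.end - 1):
            heads[i] = i + 1  # span chains into its final token
    fillers = [i for i in range(n) if i not in in_mention]
    if len(fillers) < distance - 1:
        raise GeneratorConfigError(
            f"sentence {builder.sent_id} too short to plant distance {distance}"
        )
    prev = root
    for f in fillers[: distance - 1]:
        heads[f] = prev
        prev = f
    for tgt in targets:
        heads[tgt.end - 1] = prev
    return heads


def _sample_sentence(
    rng: random.Random,
    vocab: dict[str, list[str]],
    sent_id: str,
    relation_type: RelationType,
    structure: str,
    config: GeneratorConfig,
) -> tuple[Sentence, dict]:
    has_time = relation_type is RelationType.HAS_TIME
    src_list = vocab["reproductive_conditions"] if has_time else vocab["habitats"]
    tgt_list = vocab["temporal_expressions"] if has_time else vocab["locations"]
    src_type = relation_type.source_type
    tgt_type = relation_type.target_type
    b = _SentenceBuilder(sent_id)
    positive = structure != "distractor_only"

    src_text, extra_src_text = rng.sample(src_list, 2)
    if structure == "adjacent_pair":
        source = b.mention(src_type, src_text)
        b.words("at" if not has_time else "in")
        targets = [b.mention(tgt_type, rng.choice(tgt_list))]
        b.words(".")
    elif structure == "enumeration":
        k = rng.randint(2, 3)
        texts = rng.sample(tgt_list, k)
        source = b.mention(src_type, src_text)
        b.words("at" if not has_time else "in")
        targets = [b.mention(tgt_type, texts[0])]
        for t in texts[1:-1]:
            b.words(",")
            targets.append(b.mention(tgt_type, t))
        b.words("and")
        targets.append(b.mention(tgt_type, texts[-1]))
        b.words(".")
    elif structure == "compound_run":
        k = rng.randint(2, 3)
        texts = rng.sample(tgt_list, k)
        source = b.mention(src_type, src_text)
        b.words("was heavy during" if has_time else "types were found in")
        targets = [b.mention(tgt_type, texts[0])]
        for t in texts[1:]:
            b.words("and")
            targets.append(b.mention(tgt_type, t))
        b.words(".")
    elif structure == "reversed_order":
        b.words("In")
        targets = [b.mention(tgt_type, rng.choice(tgt_list))]
        source = b.mention(src_type, src_text)
        b.words("was observed ." if has_time else "predominates .")
    elif structure == "distractor_only":
        source = b.mention(src_type, src_text)
        b.words(
            "was not observed although surveys continued during"
            if has_time
            else "was not sampled although transects continued near"
        )
        targets = [b.mention(tgt_type, rng.choice(tgt_list))]
        b.words(".")
    else:  # pragma: no cover - guarded by config validation
        raise GeneratorConfigError(f"unknown structure {structure!r}")

    extra_source = None
    if positive and structure != "reversed_order" and rng.random() < config.extra_source_prob:
        b.words(";")
        extra_source = b.mention(src_type, extra_src_text)
        b.words(rng.choice(vocab["negative_tails"]))

    heads = None
    if config.parse_emission:
        d = config.planted_distance if positive else config.planted_distance + 1
        heads = _plant_heads(b, source, targets, d)
    sentence = b.build(heads)
    info = {
        "structure": structure,
        "source": source,
        "extra_source": extra_source,
        "targets": targets,
        "positive": positive,
    }
    return sentence, info


def generate_corpus(
    config: Optional[GeneratorConfig] = None, **overrides
) -> tuple[Document, list[RelationInstance]]:
    """Generate a seeded corpus and its gold relation instances.

    Identical configuration (including seed) yields byte-identical output.
    """
    if config is None:
        config = GeneratorConfig(**overrides)
    elif overrides:
        raise GeneratorConfigError("pass either a config object or overrides, not both")
    rng = random.Random(config.seed)
    vocab = _vocab()
    names = sorted(config.structure_weights)
    weights = [config.structure_weights[n] for n in names]
    sentences: list[Sentence] = []
    gold: list[RelationInstance] = []
    for i in range(config.n_sentences):
        relation_type = (
            RelationType.HAS_TIME
            if rng.random() < config.relation_mix
            else RelationType.HAS_LOCATION
        )
        structure = rng.choices(names, weights=weights, k=1)[0]
        sentence, info = _sample_sentence(
            rng, vocab, f"synth-{i:04d}", relation_type, structure, config
        )
        sentences.append(sentence)
        related = (
            {(info["source"], t) for t in info["targets"]} if info["positive"] else set()
        )
        from .dataset import generate_candidates

        for cand in generate_candidates(sentence, relation_type):
            label = 1 if (cand.source, cand.target) in related else 0
            gold.append(cand.with_label(label))
    doc = Document(doc_id=f"synthetic-seed{config.seed}", sentences=sentences)
    return doc, gold


# ---------------------------------------------------------------------------
# Worked-example fixture
# ---------------------------------------------------------------------------

def paper_fixture() -> tuple[Document, list[RelationInstance]]:
    """Three worked-example sentences with hand-set gold labels.

    1. the "conserved forest at Dongmakhai" sentence: one habitat, two
       geographic locations (the second a coordinate string containing a
       comma), both pairs related;
    2. the "Bukit Sai and Lesong ... lowland dipterocarp forest" sentence:
       both location pairs related but neither regex rule applies;
    3. the "It flowered in July - August 1963 and May - June 1968, setting
       fruit only in 1968" sentence: a compound temporal run, with the
       fruit/"August 1963"-style cross pairs unrelated.
    """
    sentences: list[Sentence] = []
    gold: list[RelationInstance] = []

    def add(sent_id, words, mention_specs, labels, relation_type):
        toks = [Token(index=i, text=w) for i, w in enumerate(words)]
        mentions = [
            EntityMention(etype, start, end, " ".join(words[start:end]))
            for etype, start, end in mention_specs
        ]
        sentence = Sentence(sent_id=sent_id, tokens=toks, mentions=mentions)
        sentences.append(sentence)
        from .dataset import generate_candidates

        for cand in generate_candidates(sentence, relation_type):
            y = labels[(cand.source.start, cand.target.start)]
            gold.append(cand.with_label(y))

    add(
        "dongmakhai",
        [
            "The", "main", "observation", "site", "was", "conserved", "forest",
            "at", "Dongmakhai", "(", "18deg20'03\"N", ",", "102deg30'5\"E",
            ",", "190m", "a.s.l.", ")", ".",
        ],
        [
            (EntityType.HABITAT, 5, 7),
            (EntityType.GEO_LOCATION, 8, 9),
            (EntityType.GEO_LOCATION, 10, 13),
        ],
        {(5, 8): 1, (5, 10): 1},
        RelationType.HAS_LOCATION,
    )
    add(
        "bukit-sai",
        [
            "Bukit", "Sai", "and", "Lesong", "belong", "to", "the", "lowland",
            "dipterocarp", "forest", "types", "with", "D.", "aromatica",
            "being", "the", "predominant", "species", ".",
        ],
        [
            (EntityType.GEO_LOCATION, 0, 2),
            (EntityType.GEO_LOCATION, 3, 4),
            (EntityType.HABITAT, 7, 10),
        ],
        {(7, 0): 1, (7, 3): 1},
        RelationType.HAS_LOCATION,
    )
    add(
        "flowered-fruit",
        [
            "It", "flowered", "in", "July", "-", "August", "1963", "and",
            "May", "-", "June", "1968", ",", "setting", "fruit", "only",
            "in", "1968", ".",
        ],
        [
            (EntityType.REPRODUCTIVE_CONDITION, 1, 2),
            (EntityType.TEMPORAL_EXPRESSION, 3, 7),
            (EntityType.TEMPORAL_EXPRESSION, 8, 12),
            (EntityType.REPRODUCTIVE_CONDITION, 14, 15),
            (EntityType.TEMPORAL_EXPRESSION, 17, 18),
        ],
        {
            (1, 3): 1, (1, 8): 1, (1, 17): 0,
            (14, 3): 0, (14, 8): 0, (14, 17): 1,
        },
        RelationType.HAS_TIME,
    )
    return Document(doc_id="worked-examples", sentences=sentences), gold
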