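"""Candidate generation, dataset splitting and the co-occurrence baseline.

Candidate generation enumerates every intra-sentence (source, target)
mention pair of the requested relation type — all pairs co-occurring in a
sentence are candidates, and a separate labelling step decides which hold.
"""

from __future__ import annotations

import random
from typing import Iterable, Sequence

from .io import Document
from .model import RelationInstance, RelationType, Sentence, UNLABELED


class SplitConfigError(ValueError):
    """Split fractions are invalid."""


def generate_candidates(
    sentence: Sentence, relation_type: RelationType
) -> list[RelationInstance]:
    """Enumerate the full cross product of source x target mentions.

    Instances come back unlabelled, ordered by (source.start, target.start).
    """
    sources = sentence.mentions_of_type(relation_type.source_type)
    targets = sentence.mentions_of_type(relation_type.target_type)
    out: list[RelationInstance] = []
    for src in sources:
        for tgt in targets:
            out.append(
                RelationInstance(
                    sent_id=sentence.sent_id,
                    relation_type=relation_type,
                    source=src,
                    target=tgt,
                    label=UNLABELED,
                    sentence=sentence,
                )
            )
    return out


def generate_all_candidates(
    doc: Document, relation_type: RelationType
) -> list[RelationInstance]:
    """Candidates for every sentence of a document, in document order."""
    out: list[RelationInstance] = []
    for sentence in doc.sentences:
        out.extend(generate_candidates(sentence, relation_type))
    return out


def split_dataset(
    instances: Sequence[RelationInstance],
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
    unit: str = "instance",
) -> tuple[list[RelationInstance], list[RelationInstance], list[RelationInstance]]:
    """Randomly partition instances into train/dev/test.

    Split sizes are ``round(n * f)`` for all but the last split, which takes
    the remainder; the same seed always yields the same membership.
    ``unit="sentence"`` keeps all instances of a sentence in one split
    (guards against leakage; off by default).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise SplitConfigError(f"fractions must sum to 1, got {fractions}")
    if unit not in ("instance", "sentence"):
        raise SplitConfigError(f"unit must be 'instance' or 'sentence', got {unit!r}")
    rng = random.Random(seed)

    if unit == "sentence":
        sent_ids = sorted({inst.sent_id for inst in instances})
        rng.shuffle(sent_ids)
        n = len(sent_ids)
        sizes = [round(n * f) for f in fractions[:-1]]
        sizes.append(n - sum(sizes))
        groups: list[set[str]] = []
        pos = 0
        for size in sizes:
            groups.append(set(sent_ids[pos: pos + size]))
            pos += size
        return tuple(  # type: ignore[return-value]
            [inst for inst in instances if inst.sent_id in group] for group in groups
        )

    order = list(range(len(instances)))
    rng.shuffle(order)
    n = len(order)
    sizes = [round(n * f) for f in fractions[:-1]]
    sizes.append(n - sum(sizes))
    if sizes[-1] < 0:
        raise SplitConfigError(f"fractions {fractions} over-allocate {n} instances")
    splits: list[list[RelationInstance]] = []
    pos = 0
    for size in sizes:
        splits.append([instances[i] for i in order[pos: pos + size]])
        pos += size
    return splits[0], splits[1], splits[2]


def cooccurrence_baseline(
    instances: Iterable[RelationInstance],
) -> list[RelationInstance]:
    """Label every co-occurring pair positive (the trivial all-yes baseline)."""
    return [inst.with_label(1, predicted_by="baseline") for inst in instances]
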