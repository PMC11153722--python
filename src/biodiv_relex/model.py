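"""Core domain types for biodiversity relation extraction.

The unit of work is a :class:`Sentence`: an ordered list of tokens
(optionally carrying dependency links) plus a list of typed, contiguous,
non-overlapping entity mentions.  Relation extraction asks, for a pair of
mentions in one sentence, whether a binary relation holds from a source
entity to a target entity:

* ``has_time``: reproductive condition -> temporal expression
* ``has_location``: habitat -> geographic location

Entity spans travel through files in the BIO (Beginning/Inside/Outside)
sequence-labelling format; the codec lives here so every module shares one
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

#: Sentinel head index marking the root of the dependency tree.
ROOT = -1

#: Sentinel label for relation instances that have not been labelled yet.
UNLABELED = None


class InvalidAnnotationError(ValueError):
    """Raised when entity annotations violate the span invariants."""


class BioTagError(ValueError):
    """Raised for a malformed BIO tag string."""


class EntityType(Enum):
    """The four biodiversity entity types this package knows about."""

    HABITAT = "Habitat"
    GEO_LOCATION = "GeographicLocation"
    REPRODUCTIVE_CONDITION = "ReproductiveCondition"
    TEMPORAL_EXPRESSION = "TemporalExpression"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def from_label(cls, label: str) -> "EntityType":
        for member in cls:
            if member.value == label:
                return member
        raise BioTagError(f"unknown entity type label: {label!r}")


class RelationType(Enum):
    """Directed binary relation types, each fixing a source and target entity type."""

    HAS_TIME = "has_time"
    HAS_LOCATION = "has_location"

    @property
    def source_type(self) -> EntityType:
        if self is RelationType.HAS_TIME:
            return EntityType.REPRODUCTIVE_CONDITION
        return EntityType.HABITAT

    @property
    def target_type(self) -> EntityType:
        if self is RelationType.HAS_TIME:
            return EntityType.TEMPORAL_EXPRESSION
        return EntityType.GEO_LOCATION

    @classmethod
    def from_name(cls, name: str) -> "RelationType":
        key = name.strip().lower()
        for member in cls:
            if member.value == key:
                return member
        raise ValueError(f"unknown relation type: {name!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class Token:
    """A single token.

    ``head`` is the 0-based index of the governing token, :data:`ROOT` for
    the tree root, or ``None`` when the sentence has no dependency parse.
    ``feats`` keeps any CoNLL-U morphological features other than the
    ``biodiv`` entity feature, verbatim, so files round-trip.
    """

    index: int
    text: str
    upos: Optional[str] = None
    head: Optional[int] = None
    deprel: Optional[str] = None
    feats: Optional[str] = None


@dataclass(frozen=True)
class EntityMention:
    """A typed, contiguous token span: ``start`` inclusive, ``end`` exclusive."""

    entity_type: EntityType
    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InvalidAnnotationError(
                f"invalid mention span [{self.start}, {self.end})"
            )

    def span(self) -> range:
        return range(self.start, self.end)

    def overlaps(self, other: "EntityMention") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Sentence:
    """A tokenized sentence with its entity mentions."""

    sent_id: str
    tokens: list[Token]
    mentions: list[EntityMention] = field(default_factory=list)
    doc_id: Optional[str] = None

    def __post_init__(self) -> None:
        for i, tok in enumerate(self.tokens):
            if tok.index != i:
                raise InvalidAnnotationError(
                    f"sentence {self.sent_id}: token indices must be contiguous "
                    f"from 0 (token {i} has index {tok.index})"
                )
            if tok.head is not None and tok.head != ROOT:
                if not (0 <= tok.head < len(self.tokens)) or tok.head == i:
                    raise InvalidAnnotationError(
                        f"sentence {self.sent_id}: token {i} has invalid head "
                        f"{tok.head}"
                    )
        self.mentions = sorted(self.mentions, key=lambda m: (m.start, m.end))
        prev: Optional[EntityMention] = None
        for m in self.mentions:
            if m.end > len(self.tokens):
                raise InvalidAnnotationError(
                    f"sentence {self.sent_id}: mention [{m.start}, {m.end}) "
                    f"exceeds sentence length {len(self.tokens)}"
                )
            if prev is not None and prev.overlaps(m):
                raise InvalidAnnotationError(
                    f"sentence {self.sent_id}: overlapping mentions "
                    f"{prev.text!r} and {m.text!r}"
                )
            prev = m

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def text(self) -> str:
        return " ".join(t.text for t in self.tokens)

    def mentions_of_type(self, entity_type: EntityType) -> list[EntityMention]:
        return [m for m in self.mentions if m.entity_type is entity_type]

    def has_parse(self) -> bool:
        return bool(self.tokens) and all(t.head is not None for t in self.tokens)


@dataclass
class RelationInstance:
    """A candidate or labelled relation: (sentence, source, target, label).

    ``label`` is 1 (related), 0 (unrelated) or :data:`UNLABELED` (``None``).
    ``predicted_by`` records provenance ("rule", "backend", "baseline", ...).
    ``sentence`` is an optional in-memory back-reference; it is never
    serialized and is ignored by equality.
    """

    sent_id: str
    relation_type: RelationType
    source: EntityMention
    target: EntityMention
    label: Optional[int] = UNLABELED
    predicted_by: Optional[str] = None
    sentence: Optional[Sentence] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.source.entity_type is not self.relation_type.source_type:
            raise InvalidAnnotationError(
                f"source mention type {self.source.entity_type} does not match "
                f"relation {self.relation_type}"
            )
        if self.target.entity_type is not self.relation_type.target_type:
            raise InvalidAnnotationError(
                f"target mention type {self.target.entity_type} does not match "
                f"relation {self.relation_type}"
            )
        if self.label not in (0, 1, UNLABELED):
            raise InvalidAnnotationError(f"label must be 0, 1 or None, got {self.label!r}")

    @property
    def key(self) -> tuple:
        """Identity of the instance: sentence, relation type and both spans."""
        return (
            self.sent_id,
            self.relation_type.value,
            self.source.start,
            self.source.end,
            self.target.start,
            self.target.end,
        )

    def with_label(self, label: int, predicted_by: Optional[str] = None) -> "RelationInstance":
        return replace(self, label=label, predicted_by=predicted_by)


# ---------------------------------------------------------------------------
# BIO codec
# ---------------------------------------------------------------------------

def encode_bio_tags(sentence: Sentence) -> list[str]:
    """Encode a sentence's mentions as one BIO tag per token.

    Tokens outside every mention get ``"O"``; the first token of a mention of
    type X gets ``"B-X"`` and subsequent tokens ``"I-X"``.
    """
    tags = ["O"] * len(sentence.tokens)
    for m in sentence.mentions:
        tags[m.start] = f"B-{m.entity_type.value}"
        for i in range(m.start + 1, m.end):
            tags[i] = f"I-{m.entity_type.value}"
    return tags


def parse_bio_tag(tag: str) -> tuple[str, Optional[EntityType]]:
    """Split a BIO tag into its prefix ('B', 'I' or 'O') and entity type."""
    if tag == "O":
        return "O", None
    if len(tag) > 2 and tag[0] in "BI" and tag[1] == "-":
        return tag[0], EntityType.from_label(tag[2:])
    raise BioTagError(f"malformed BIO tag: {tag!r}")


def decode_bio_tags(tags: Sequence[str], tokens: Sequence[Token]) -> list[EntityMention]:
    """Decode BIO tags back into mentions.

    An ``I-X`` tag that does not continue a mention of type X (an "orphan I")
    is tolerated and starts a new mention, as if it were ``B-X``.
    """
    if len(tags) != len(tokens):
        raise BioTagError(
            f"tag count {len(tags)} does not match token count {len(tokens)}"
        )
    mentions: list[EntityMention] = []
    start: Optional[int] = None
    current: Optional[EntityType] = None

    def flush(end: int) -> None:
        nonlocal start, current
        if start is not None and current is not None:
            text = " ".join(tokens[i].text for i in range(start, end))
            mentions.append(EntityMention(current, start, end, text))
        start, current = None, None

    for i, tag in enumerate(tags):
        prefix, etype = parse_bio_tag(tag)
        if prefix == "O":
            flush(i)
        elif prefix == "B":
            flush(i)
            start, current = i, etype
        else:  # "I"
            if current is etype and start is not None:
                continue
            flush(i)  # orphan I: promote to B
            start, current = i, etype
    flush(len(tags))
    return mentions


def attach_sentence(
    instances: Iterable[RelationInstance], sentence: Sentence
) -> list[RelationInstance]:
    """Attach the in-memory sentence back-reference to each instance."""
    out = []
    for inst in instances:
        inst.sentence = sentence
        out.append(inst)
    return out
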