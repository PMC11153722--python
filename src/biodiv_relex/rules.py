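"""Token-type encoding, the two relation regex rules, and compound entities.

A sentence is encoded, per relation type, as one character per token over
the alphabet ``{S, T, d, o}``:

* ``S`` — token inside a source-typed mention,
* ``T`` — token inside a target-typed mention,
* ``d`` — a comma or semicolon (an enumeration delimiter),
* ``o`` — anything else.

Entity membership beats delimiter status: a comma inside a geographic
coordinate mention encodes as ``T``, not ``d``.

Two rules then match directly on this string:

1. ``S+(o)?(To|Td|T)+`` — source immediately (or one token) before a run of
   targets, possibly delimiter-separated;
2. ``(?<!S)(To|Td|T)*T(o)?S+`` — a target run followed by the source, the
   run not continuing an earlier source.

Every source and target mention whose character span falls entirely inside
a match is paired; the pair set is the union over both rules, scanned
left-to-right, non-overlapping, greedy (ordinary regex-engine semantics —
the match dialect of this package).

Separately, the compound-entity detector groups runs of >= 2 same-type
mentions separated by at most one token, via ``(Et|E){2,}`` over an
entity-granular string (one ``E`` per mention, one ``t`` per other token).
Compound targets let the zero-shot step ask one question for the whole run.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .model import EntityMention, EntityType, RelationType, Sentence

#: Tokens that act as enumeration delimiters.
DELIMITERS = frozenset({",", ";"})

RULE_FORWARD = re.compile(r"S+o?(?:To|Td|T)+")
RULE_REVERSED = re.compile(r"(?<!S)(?:To|Td|T)*To?S+")


@dataclass(frozen=True)
class TokenTypeString:
    """Per-relation-type character encoding of a sentence.

    Character i corresponds to token i, so a mention's character span equals
    its token span.
    """

    chars: str
    relation_type: RelationType
    source_spans: tuple[tuple[EntityMention, tuple[int, int]], ...]
    target_spans: tuple[tuple[EntityMention, tuple[int, int]], ...]


@dataclass(frozen=True)
class CompoundEntity:
    """A run of >=2 same-type mentions with <=1 token between neighbours."""

    entity_type: EntityType
    members: tuple[EntityMention, ...]
    joined_text: str

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a compound entity needs at least two members")


def encode_token_types(
    sentence: Sentence, relation_type: RelationType
) -> TokenTypeString:
    """Map each token to S/T/d/o for the given relation type."""
    chars = []
    for tok in sentence.tokens:
        chars.append("d" if tok.text in DELIMITERS else "o")
    source_spans = []
    target_spans = []
    for m in sentence.mentions:
        if m.entity_type is relation_type.source_type:
            symbol = "S"
            source_spans.append((m, (m.start, m.end)))
        elif m.entity_type is relation_type.target_type:
            symbol = "T"
            target_spans.append((m, (m.start, m.end)))
        else:
            continue  # non-participating entity types stay d/o
        for i in range(m.start, m.end):
            chars[i] = symbol
    return TokenTypeString(
        chars="".join(chars),
        relation_type=relation_type,
        source_spans=tuple(source_spans),
        target_spans=tuple(target_spans),
    )


def apply_regex_rules(
    tts: TokenTypeString,
) -> set[tuple[EntityMention, EntityMention]]:
    """Pairs of (source, target) mentions related according to the two rules.

    For each rule independently, matches are found by a left-to-right,
    non-overlapping, greedy scan; a mention counts as matched only when its
    whole span lies inside the match. The union over both rules is returned.
    """
    pairs: set[tuple[EntityMention, EntityMention]] = set()
    for rule in (RULE_FORWARD, RULE_REVERSED):
        for m in rule.finditer(tts.chars):
            lo, hi = m.start(), m.end()
            sources = [
                sm for sm, (a, b) in tts.source_spans if lo <= a and b <= hi
            ]
            targets = [
                tm for tm, (a, b) in tts.target_spans if lo <= a and b <= hi
            ]
            for sm in sources:
                for tm in targets:
                    pairs.add((sm, tm))
    return pairs


_COMPOUND = re.compile(r"(?:Et|E){2,}")


def detect_compound_entities(
    sentence: Sentence, entity_type: EntityType
) -> list[CompoundEntity]:
    """Find maximal compounds of the given entity type in a sentence.

    The sentence is collapsed to an entity-granular symbol string ('E' per
    mention of the type, 't' per other token); each maximal ``(Et|E){2,}``
    match yields one compound. ``joined_text`` concatenates member texts and
    the single intervening tokens with single spaces.
    """
    mentions = sentence.mentions_of_type(entity_type)
    symbols: list[str] = []
    payloads: list[object] = []  # EntityMention for 'E', Token for 't'
    i = 0
    by_start = {m.start: m for m in mentions}
    while i < len(sentence.tokens):
        if i in by_start:
            m = by_start[i]
            symbols.append("E")
            payloads.append(m)
            i = m.end
        else:
            symbols.append("t")
            payloads.append(sentence.tokens[i])
            i += 1
    string = "".join(symbols)
    compounds: list[CompoundEntity] = []
    for match in _COMPOUND.finditer(string):
        e_positions = [
            j for j in range(match.start(), match.end()) if string[j] == "E"
        ]
        if len(e_positions) < 2:
            continue
        first, last = e_positions[0], e_positions[-1]
        members = tuple(payloads[j] for j in e_positions)  # type: ignore[misc]
        joined = " ".join(
            payloads[j].text for j in range(first, last + 1)  # type: ignore[union-attr]
        )
        compounds.append(
            CompoundEntity(entity_type=entity_type, members=members, joined_text=joined)
        )
    return compounds


def format_aligned_encoding(sentence: Sentence, relation_type: RelationType) -> str:
    """Debug rendering: the token-type character printed under each token."""
    tts = encode_token_types(sentence, relation_type)
    tok_line = []
    chr_line = []
    for tok, ch in zip(sentence.tokens, tts.chars):
        width = max(len(tok.text), 1)
        tok_line.append(tok.text.ljust(width))
        chr_line.append(ch.ljust(width))
    return " ".join(tok_line).rstrip() + "\n" + " ".join(chr_line).rstrip()
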