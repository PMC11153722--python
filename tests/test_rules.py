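"""Token-type encoding, the two relation rules, and compound detection."""

import random

import pytest

from biodiv_relex import (
    EntityType,
    RelationType,
    apply_regex_rules,
    detect_compound_entities,
    encode_token_types,
)
from biodiv_relex.model import EntityMention
from biodiv_relex.rules import TokenTypeString

import _oracles
from conftest import make_sentence


class TestEncoding:
    def test_enumeration_sentence_has_time(self, enumeration_sentence):
        tts = encode_token_types(enumeration_sentence, RelationType.HAS_TIME)
        assert tts.chars == "SoToTdSoT"

    def test_enumeration_sentence_other_relation_all_other(self, enumeration_sentence):
        tts = encode_token_types(enumeration_sentence, RelationType.HAS_LOCATION)
        assert tts.chars == "ooooodooo"  # comma still a delimiter

    def test_comma_inside_participating_mention_is_target(self, fixture_corpus):
        doc, _ = fixture_corpus
        tts = encode_token_types(doc.sentences[0], RelationType.HAS_LOCATION)
        # coordinate mention spans tokens 10-12 including the comma at 11
        assert tts.chars[10:13] == "TTT"
        # the comma outside the mention (token 13) stays a delimiter
        assert tts.chars[13] == "d"

    def test_comma_inside_nonparticipating_mention_stays_delimiter(self):
        s = make_sentence(
            "s",
            ["flowering", "in", "March", "10deg", ",", "20deg"],
            [
                (EntityType.REPRODUCTIVE_CONDITION, 0, 1),
                (EntityType.TEMPORAL_EXPRESSION, 2, 3),
                (EntityType.GEO_LOCATION, 3, 6),
            ],
        )
        tts = encode_token_types(s, RelationType.HAS_TIME)
        assert tts.chars == "SoTodo"


class TestRules:
    def test_enumeration_pairs(self, enumeration_sentence):
        tts = encode_token_types(enumeration_sentence, RelationType.HAS_TIME)
        pairs = {(a.text, b.text) for a, b in apply_regex_rules(tts)}
        assert pairs == {
            ("flowering", "March"),
            ("flowering", "April"),
            ("fruiting", "May"),
        }

    def test_no_source_no_pairs(self):
        tts = TokenTypeString(
            chars="oToTd",
            relation_type=RelationType.HAS_TIME,
            source_spans=(),
            target_spans=(
                (EntityMention(EntityType.TEMPORAL_EXPRESSION, 1, 2, "March"), (1, 2)),
                (EntityMention(EntityType.TEMPORAL_EXPRESSION, 3, 4, "May"), (3, 4)),
            ),
        )
        assert apply_regex_rules(tts) == set()

    def test_flowered_sentence_leaves_fruit_pair_for_backend(self, fixture_corpus):
        doc, _ = fixture_corpus
        sentence = doc.sentences[2]
        tts = encode_token_types(sentence, RelationType.HAS_TIME)
        pairs = {(a.text, b.text) for a, b in apply_regex_rules(tts)}
        assert pairs == {
            ("flowered", "July - August 1963"),
            ("flowered", "May - June 1968"),
        }
        # "setting fruit only in 1968" encodes SooT: matched by neither rule
        assert ("fruit", "1968") not in pairs

    def test_reversed_order_matched_by_second_rule(self):
        s = make_sentence(
            "s",
            ["In", "March", "flowering", "was", "observed", "."],
            [
                (EntityType.TEMPORAL_EXPRESSION, 1, 2),
                (EntityType.REPRODUCTIVE_CONDITION, 2, 3),
            ],
        )
        tts = encode_token_types(s, RelationType.HAS_TIME)
        pairs = {(a.text, b.text) for a, b in apply_regex_rules(tts)}
        assert pairs == {("flowering", "March")}


def _tts_from_string(chars: str) -> TokenTypeString:
    """Build a TokenTypeString whose mentions are the maximal S/T runs."""
    sources = tuple(
        (
            EntityMention(EntityType.REPRODUCTIVE_CONDITION, a, b, f"S{a}"),
            (a, b),
        )
        for a, b in _oracles.maximal_runs(chars, "S")
    )
    targets = tuple(
        (
            EntityMention(EntityType.TEMPORAL_EXPRESSION, a, b, f"T{a}"),
            (a, b),
        )
        for a, b in _oracles.maximal_runs(chars, "T")
    )
    return TokenTypeString(
        chars=chars,
        relation_type=RelationType.HAS_TIME,
        source_spans=sources,
        target_spans=targets,
    )


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_random_strings_match_brute_force(self, seed):
        """The scanning matcher equals exhaustive leftmost-longest enumeration."""
        rng = random.Random(seed)
        for _ in range(500):
            chars = "".join(
                rng.choice("STdo") for _ in range(rng.randint(1, 12))
            )
            got = {
                ((a.start, a.end), (b.start, b.end))
                for a, b in apply_regex_rules(_tts_from_string(chars))
            }
            assert got == _oracles.brute_force_rule_pairs(chars), chars


class TestCompounds:
    def test_coordinated_temporal_runs_form_one_compound(self, fixture_corpus):
        doc, _ = fixture_corpus
        comps = detect_compound_entities(
            doc.sentences[2], EntityType.TEMPORAL_EXPRESSION
        )
        assert len(comps) == 1
        assert len(comps[0].members) == 2
        assert comps[0].joined_text == "July - August 1963 and May - June 1968"

    def test_single_mention_is_not_a_compound(self):
        s = make_sentence(
            "s", ["in", "March", "."], [(EntityType.TEMPORAL_EXPRESSION, 1, 2)]
        )
        assert detect_compound_entities(s, EntityType.TEMPORAL_EXPRESSION) == []

    def test_two_intervening_tokens_break_the_run(self):
        s = make_sentence(
            "s",
            ["March", "and", "also", "May"],
            [
                (EntityType.TEMPORAL_EXPRESSION, 0, 1),
                (EntityType.TEMPORAL_EXPRESSION, 3, 4),
            ],
        )
        assert detect_compound_entities(s, EntityType.TEMPORAL_EXPRESSION) == []

    def test_members_never_overlap_and_cover_at_least_two(self, small_corpus):
        doc, _ = small_corpus
        for sentence in doc:
            for etype in EntityType:
                for comp in detect_compound_entities(sentence, etype):
                    assert len(comp.members) >= 2
                    for a, b in zip(comp.members, comp.members[1:]):
                        assert a.end <= b.start
                        assert b.start - a.end <= 1
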