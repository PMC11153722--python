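import pytest

from biodiv_relex import (
    EntityMention,
    EntityType,
    RelationType,
    Sentence,
    Token,
    generate_corpus,
    paper_fixture,
)


def make_sentence(sent_id, words, mention_specs, heads=None):
    """Build a sentence from word strings and (type, start, end) mention specs."""
    tokens = [
        Token(index=i, text=w, head=None if heads is None else heads[i])
        for i, w in enumerate(words)
    ]
    mentions = [
        EntityMention(etype, start, end, " ".join(words[start:end]))
        for etype, start, end in mention_specs
    ]
    return Sentence(sent_id=sent_id, tokens=tokens, mentions=mentions)


@pytest.fixture(scope="session")
def fixture_corpus():
    """The three worked-example sentences with their gold labels."""
    return paper_fixture()


@pytest.fixture(scope="session")
def small_corpus():
    """A small seeded synthetic corpus shared by read-only tests."""
    return generate_corpus(seed=3, n_sentences=60)


@pytest.fixture
def enumeration_sentence():
    """'flowering in March and April , fruiting in May' -> token types SoToTdSoT."""
    return make_sentence(
        "enum",
        ["flowering", "in", "March", "and", "April", ",", "fruiting", "in", "May"],
        [
            (EntityType.REPRODUCTIVE_CONDITION, 0, 1),
            (EntityType.TEMPORAL_EXPRESSION, 2, 3),
            (EntityType.TEMPORAL_EXPRESSION, 4, 5),
            (EntityType.REPRODUCTIVE_CONDITION, 6, 7),
            (EntityType.TEMPORAL_EXPRESSION, 8, 9),
        ],
    )


def gold_for(gold, relation_type):
    return [g for g in gold if g.relation_type is relation_type]


@pytest.fixture(scope="session")
def relation_types():
    return (RelationType.HAS_TIME, RelationType.HAS_LOCATION)
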