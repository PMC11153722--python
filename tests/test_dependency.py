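"""Dependency distance: BFS equivalence, metric properties, thresholding."""

import math
import random

import pytest

from biodiv_relex import (
    RelationType,
    UNREACHABLE,
    cooccurrence_baseline,
    dependency_distance,
    generate_all_candidates,
    generate_corpus,
    predict_by_distance,
    sweep_distance_threshold,
)
from biodiv_relex.dependency import MissingHeadsError
from biodiv_relex.model import ROOT, EntityMention, EntityType

import _oracles
from conftest import make_sentence


def _parsed_sentence(words, heads, mention_specs):
    return make_sentence("dep", words, mention_specs, heads=heads)


class TestDistance:
    def test_small_tree_distance(self):
        # flowering -> occurred (root) <- March, with "in" under March
        s = _parsed_sentence(
            ["flowering", "occurred", "in", "March"],
            [1, ROOT, 3, 1],
            [
                (EntityType.REPRODUCTIVE_CONDITION, 0, 1),
                (EntityType.TEMPORAL_EXPRESSION, 3, 4),
            ],
        )
        assert dependency_distance(s, s.mentions[0], s.mentions[1]) == 2

    def test_adjacent_governor_is_one_edge(self):
        s = _parsed_sentence(
            ["flowering", "March"],
            [ROOT, 0],
            [
                (EntityType.REPRODUCTIVE_CONDITION, 0, 1),
                (EntityType.TEMPORAL_EXPRESSION, 1, 2),
            ],
        )
        assert dependency_distance(s, s.mentions[0], s.mentions[1]) == 1

    def test_identical_spans_distance_zero(self):
        s = _parsed_sentence(
            ["flowering", "March"],
            [ROOT, 0],
            [(EntityType.REPRODUCTIVE_CONDITION, 0, 1)],
        )
        m = s.mentions[0]
        assert dependency_distance(s, m, m) == 0

    def test_fragmented_parse_is_unreachable(self):
        # token 2 has no path to the rest (its own isolated root)
        s = _parsed_sentence(
            ["flowering", "occurred", "March"],
            [1, ROOT, ROOT],
            [
                (EntityType.REPRODUCTIVE_CONDITION, 0, 1),
                (EntityType.TEMPORAL_EXPRESSION, 2, 3),
            ],
        )
        assert dependency_distance(s, s.mentions[0], s.mentions[1]) == UNREACHABLE

    def test_missing_heads_raise_actionable_error(self):
        s = make_sentence(
            "noparse",
            ["flowering", "March"],
            [
                (EntityType.REPRODUCTIVE_CONDITION, 0, 1),
                (EntityType.TEMPORAL_EXPRESSION, 1, 2),
            ],
        )
        with pytest.raises(MissingHeadsError, match="pars"):
            dependency_distance(s, s.mentions[0], s.mentions[1])


class TestOracleAndProperties:
    def _random_parsed_sentences(self, seed, count):
        rng = random.Random(seed)
        out = []
        for k in range(count):
            n = rng.randint(2, 10)
            order = list(range(n))
            rng.shuffle(order)
            heads = [None] * n
            heads[order[0]] = ROOT
            for pos in range(1, n):
                heads[order[pos]] = order[rng.randrange(pos)]
            # two random disjoint single/double-token spans
            starts = rng.sample(range(n), 2)
            starts.sort()
            a_end = min(starts[0] + rng.randint(1, 2), starts[1])
            spans = [
                (EntityType.REPRODUCTIVE_CONDITION, starts[0], max(a_end, starts[0] + 1)),
                (EntityType.TEMPORAL_EXPRESSION, starts[1], starts[1] + 1),
            ]
            words = [f"w{i}" for i in range(n)]
            out.append(make_sentence(f"r{k}", words, spans, heads=heads))
        return out

    def test_equals_brute_force_bfs_on_small_trees(self):
        for s in self._random_parsed_sentences(seed=13, count=300):
            edges = [
                (t.index, t.head)
                for t in s.tokens
                if t.head is not None and t.head != ROOT
            ]
            dist = _oracles.bfs_all_pairs(len(s.tokens), edges)
            a, b = s.mentions
            expected = min(dist[i][j] for i in a.span() for j in b.span())
            got = dependency_distance(s, a, b)
            assert got == expected

    def test_symmetry_and_triangle_inequality(self):
        for s in self._random_parsed_sentences(seed=7, count=60):
            a, b = s.mentions
            assert dependency_distance(s, a, b) == dependency_distance(s, b, a)
        # triangle inequality over three mentions on one tree
        s = _parsed_sentence(
            ["a", "b", "c", "d", "e"],
            [ROOT, 0, 1, 2, 3],
            [
                (EntityType.REPRODUCTIVE_CONDITION, 0, 1),
                (EntityType.TEMPORAL_EXPRESSION, 2, 3),
                (EntityType.HABITAT, 4, 5),
            ],
        )
        x, y, z = s.mentions
        dxy = dependency_distance(s, x, y)
        dyz = dependency_distance(s, y, z)
        dxz = dependency_distance(s, x, z)
        assert dxz <= dxy + dyz


class TestThresholding:
    def test_default_threshold_accepts_distance_two(self):
        s = _parsed_sentence(
            ["flowering", "occurred", "in", "March"],
            [1, ROOT, 3, 1],
            [
                (EntityType.REPRODUCTIVE_CONDITION, 0, 1),
                (EntityType.TEMPORAL_EXPRESSION, 3, 4),
            ],
        )
        from biodiv_relex import generate_candidates

        cands = generate_candidates(s, RelationType.HAS_TIME)
        assert [p.label for p in predict_by_distance(cands, n=4)] == [1]
        assert [p.label for p in predict_by_distance(cands, n=1)] == [0]

    def test_large_threshold_converges_to_cooccurrence(self):
        doc, _ = generate_corpus(seed=21, n_sentences=40)
        cands = generate_all_candidates(doc, RelationType.HAS_TIME)
        wide = predict_by_distance(cands, n=max(len(s.tokens) for s in doc))
        base = cooccurrence_baseline(cands)
        assert [p.label for p in wide] == [b.label for b in base]

    def test_sweep_recall_and_positive_count_monotone(self, small_corpus):
        doc, gold = small_corpus
        cands = generate_all_candidates(doc, RelationType.HAS_TIME)
        gold_t = [g for g in gold if g.relation_type is RelationType.HAS_TIME]
        table = sweep_distance_threshold(cands, gold_t)
        recalls = table["recall"].tolist()
        assert recalls == sorted(recalls)
        counts = [
            sum(p.label for p in predict_by_distance(cands, n=n))
            for n in range(1, 9)
        ]
        assert counts == sorted(counts)

    def test_sweep_recovers_planted_threshold(self):
        doc, gold = generate_corpus(seed=17, n_sentences=80, planted_distance=3)
        cands = generate_all_candidates(doc, RelationType.HAS_TIME)
        gold_t = [g for g in gold if g.relation_type is RelationType.HAS_TIME]
        table = sweep_distance_threshold(cands, gold_t)
        best_n = int(table.loc[table["f1"].idxmax(), "n"])
        assert best_n == 3
        assert math.isclose(table.loc[table["n"] == 3, "f1"].item(), 1.0)
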