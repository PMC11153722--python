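"""Dependency-distance relation matching.

The dependency distance between two entity mentions is the number of edges
on the shortest path between any token of one and any token of the other in
the sentence's dependency graph, edges traversed without regard to
direction.  A pair is predicted related when that distance is at most a
threshold ``n`` (default 4); as ``n`` grows toward the sentence size the
predictions converge to the all-positive co-occurrence baseline.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .model import EntityMention, RelationInstance, ROOT, Sentence
from . import metrics as _metrics

logger = logging.getLogger(__name__)

#: Distance reported for mention pairs in disconnected parse fragments.
UNREACHABLE = math.inf

#: The development-set threshold used by default.
DEFAULT_N = 4


class MissingHeadsError(ValueError):
    """The sentence has no (complete) dependency annotation."""


def dependency_graph(sentence: Sentence) -> nx.Graph:
    """Undirected graph over token indices; head links become edges, ROOT excluded."""
    g = nx.Graph()
    g.add_nodes_from(range(len(sentence.tokens)))
    for tok in sentence.tokens:
        if tok.head is not None and tok.head != ROOT:
            g.add_edge(tok.index, tok.head)
    return g


def dependency_distance(
    sentence: Sentence, a: EntityMention, b: EntityMention
) -> float:
    """Minimum shortest-path length between the two mentions' token spans.

    Returns 0 for identical spans and :data:`UNREACHABLE` when no path
    exists (fragmented parse).
    """
    if not sentence.has_parse():
        raise MissingHeadsError(
            f"sentence {sentence.sent_id} lacks dependency heads; run a "
            "dependency parser (or use CoNLL-U input with HEAD columns) first"
        )
    g = dependency_graph(sentence)
    best = UNREACHABLE
    b_span = set(b.span())
    for ta in a.span():
        lengths = nx.single_source_shortest_path_length(g, ta)
        for tb in b_span:
            d = lengths.get(tb)
            if d is not None and d < best:
                best = d
    return best


def predict_by_distance(
    instances: Iterable[RelationInstance], n: int = DEFAULT_N
) -> list[RelationInstance]:
    """Label each instance 1 iff its dependency distance is <= n.

    Unreachable pairs are labelled 0; their count is logged as a warning.
    Instances must carry their sentence back-reference (as produced by
    candidate generation).
    """
    if n < 1:
        raise ValueError(f"distance threshold n must be >= 1, got {n}")
    out: list[RelationInstance] = []
    unreachable = 0
    for inst in instances:
        if inst.sentence is None:
            raise MissingHeadsError(
                f"instance {inst.key} has no attached sentence; generate "
                "candidates from parsed sentences first"
            )
        d = dependency_distance(inst.sentence, inst.source, inst.target)
        if d == UNREACHABLE:
            unreachable += 1
        label = 1 if d <= n else 0
        out.append(inst.with_label(label, predicted_by="rule"))
    if unreachable:
        logger.warning(
            "%d instance(s) had unreachable dependency paths and were labelled 0",
            unreachable,
        )
    return out


def sweep_distance_threshold(
    instances: Sequence[RelationInstance],
    gold: Sequence[RelationInstance],
    n_values: Iterable[int] = range(1, 9),
) -> pd.DataFrame:
    """Evaluate the distance matcher at each threshold n.

    Returns a table with columns ``n, precision, recall, f1, mcc`` (one row
    per threshold), suitable for picking n on a development set.
    """
    rows = []
    for n in n_values:
        pred = predict_by_distance(instances, n=n)
        counts = _metrics.confusion(pred, gold)
        p, r, f1 = _metrics.prf1(counts)
        rows.append(
            {"n": n, "precision": p, "recall": r, "f1": f1, "mcc": _metrics.mcc(counts)}
        )
    return pd.DataFrame(rows)
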