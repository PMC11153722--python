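"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the rule grammars are
recognized by hand-written recursive matchers (no `re`), matches are found
by explicit leftmost-longest scanning, and shortest paths come from a
from-scratch BFS (no networkx).
"""

from __future__ import annotations

from collections import deque


# --- token-type rule grammars, recognized without the re module -----------

def fullmatch_rule_forward(s: str) -> bool:
    """Recognize S+o?(To|Td|T)+ consuming the whole string."""
    n = len(s)
    i = 0
    if i >= n or s[i] != "S":
        return False
    while i < n and s[i] == "S":
        i += 1

    def units(k: int) -> bool:
        if k == n:
            return True
        if s[k] != "T":
            return False
        if k + 1 < n and s[k + 1] in "od" and units(k + 2):
            return True
        return units(k + 1)

    if i < n and units(i):
        return True
    return i < n and s[i] == "o" and i + 1 < n and units(i + 1)


def fullmatch_rule_reversed(s: str) -> bool:
    """Recognize (To|Td|T)*To?S+ consuming the whole string."""
    n = len(s)

    def all_s(j: int) -> bool:
        return j < n and all(c == "S" for c in s[j:])

    def tail(k: int) -> bool:  # T o? S+
        if k >= n or s[k] != "T":
            return False
        if all_s(k + 1):
            return True
        return k + 1 < n and s[k + 1] == "o" and all_s(k + 2)

    def f(k: int) -> bool:
        if tail(k):
            return True
        if k < n and s[k] == "T":
            if k + 1 < n and s[k + 1] in "od" and f(k + 2):
                return True
            return f(k + 1)
        return False

    return f(0)


def leftmost_longest_spans(s, recognize, exclude_after_s=False):
    """Maximal non-overlapping left-to-right matches of a full-string grammar."""
    spans = []
    pos, n = 0, len(s)
    while pos < n:
        if exclude_after_s and pos > 0 and s[pos - 1] == "S":
            pos += 1
            continue
        hit = None
        for length in range(n - pos, 0, -1):
            if recognize(s[pos: pos + length]):
                hit = length
                break
        if hit is None:
            pos += 1
        else:
            spans.append((pos, pos + hit))
            pos += hit
    return spans


def maximal_runs(s: str, char: str):
    """[start, end) spans of maximal runs of `char` in `s`."""
    runs = []
    i = 0
    while i < len(s):
        if s[i] == char:
            j = i
            while j < len(s) and s[j] == char:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def brute_force_rule_pairs(s: str) -> set[tuple[tuple[int, int], tuple[int, int]]]:
    """All (source-run, target-run) span pairs related per the two rules.

    Treats each maximal S run as one source mention and each maximal T run
    as one target mention; a pair is related when both runs fall entirely
    inside one maximal match of either rule.
    """
    sources = maximal_runs(s, "S")
    targets = maximal_runs(s, "T")
    pairs = set()
    for spans in (
        leftmost_longest_spans(s, fullmatch_rule_forward),
        leftmost_longest_spans(s, fullmatch_rule_reversed, exclude_after_s=True),
    ):
        for lo, hi in spans:
            inside_s = [r for r in sources if lo <= r[0] and r[1] <= hi]
            inside_t = [r for r in targets if lo <= r[0] and r[1] <= hi]
            for sr in inside_s:
                for tr in inside_t:
                    pairs.add((sr, tr))
    return pairs


# --- shortest paths by plain BFS -------------------------------------------

def bfs_all_pairs(n_nodes: int, edges) -> list[list[float]]:
    """All-pairs shortest-path lengths over an undirected graph; inf if disconnected."""
    adj = [[] for _ in range(n_nodes)]
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    dist = [[float("inf")] * n_nodes for _ in range(n_nodes)]
    for start in range(n_nodes):
        dist[start][start] = 0
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if dist[start][v] == float("inf"):
                    dist[start][v] = dist[start][u] + 1
                    queue.append(v)
    return dist
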