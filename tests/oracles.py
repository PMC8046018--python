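"""Independent brute-force oracles used by the test suite.

These deliberately use different algorithms/formulations from the package
implementations they check.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np


def levenshtein_full_dp(a: str, b: str) -> int:
    """Full-matrix edit distance (vs the package's rolling-row version)."""
    n, m = len(a), len(b)
    d = np.zeros((n + 1, m + 1), dtype=int)
    d[:, 0] = np.arange(n + 1)
    d[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d[i, j] = min(
                d[i - 1, j] + 1,
                d[i, j - 1] + 1,
                d[i - 1, j - 1] + (a[i - 1] != b[j - 1]),
            )
    return int(d[n, m])


def gotoh_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> float:
    """Optimal global affine-gap alignment score (Gotoh three-matrix DP).

    ``gap_open`` is the score of the first gap position and ``gap_extend`` of
    each subsequent one (a run of length L scores gap_open + (L-1)*gap_extend).
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (vertical)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (horizontal)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def alignment_columns_score(
    top: str,
    bottom: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> float:
    """Score a gapped alignment (two equal-length strings with '-') column by
    column, charging affine penalties per gap run."""
    score = 0.0
    in_gap_top = in_gap_bottom = False
    for x, y in zip(top, bottom):
        if x == "-":
            score += gap_extend if in_gap_top else gap_open
            in_gap_top, in_gap_bottom = True, False
        elif y == "-":
            score += gap_extend if in_gap_bottom else gap_open
            in_gap_bottom, in_gap_top = True, False
        else:
            score += match if x == y else mismatch
            in_gap_top = in_gap_bottom = False
    return score


def union_find_components(nodes: list, edges: list[tuple]) -> list[frozenset]:
    """Connected components by naive union-find over an edge list."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return [frozenset(g) for g in groups.values()]


def hypergeom_tail_enumeration(total: int, successes: int, draws: int, k: int) -> float:
    """P(X >= k) by enumerating all C(total, draws) subsets (total <= 12)."""
    population = list(range(total))
    success_set = set(range(successes))
    hits = 0
    count = 0
    for subset in itertools.combinations(population, draws):
        count += 1
        if len(success_set.intersection(subset)) >= k:
            hits += 1
    return hits / count


def rank_sum_u(a: list[float], b: list[float]) -> float:
    """Mann-Whitney U for group a by direct pair counting with tie halving."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u
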