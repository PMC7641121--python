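"""Naive reference implementations used as independent oracles in tests.

Everything here is written for clarity, not speed: explicit loops, explicit
sorting, exhaustive enumeration.  These functions deliberately share no code
with the package under test.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def naive_pcc(x, y) -> float:
    """Pearson correlation from the summation formula, one pair at a time."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    den = math.sqrt(sum((v - mx) ** 2 for v in x)) * math.sqrt(sum((v - my) ** 2 for v in y))
    if den == 0:
        return float("nan")
    return num / den


def naive_pcc_matrix(values: np.ndarray) -> np.ndarray:
    """All-pairs correlation by looping naive_pcc; diagonal 1 where defined."""
    n = values.shape[0]
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            out[i, j] = 1.0 if i == j else naive_pcc(values[i], values[j])
        if np.std(values[i]) == 0:
            out[i, i] = np.nan
    return out


def naive_ranks(pcc: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    """1-based partner ranks by descending |pcc|, ties by ascending gene id."""
    n = len(gene_ids)
    rank = np.zeros((n, n), dtype=int)
    for a in range(n):
        if np.isnan(pcc[a, a]):
            continue
        partners = [b for b in range(n) if b != a and not np.isnan(pcc[a, b])]
        partners.sort(key=lambda b: (-abs(pcc[a, b]), gene_ids[b]))
        for pos, b in enumerate(partners, start=1):
            rank[a, b] = pos
    return rank


def naive_mr(rank: np.ndarray) -> np.ndarray:
    n = rank.shape[0]
    mr = np.full((n, n), np.nan)
    for a in range(n):
        for b in range(n):
            if rank[a, b] > 0 and rank[b, a] > 0:
                mr[a, b] = math.sqrt(rank[a, b] * rank[b, a])
    return mr


def naive_edges(
    pcc: np.ndarray,
    rank: np.ndarray,
    mr: np.ndarray,
    gene_ids: list[str],
    pcc_cutoff: float = 0.7,
    top_k: int = 3,
    mr_cutoff: float = 30.0,
) -> set[tuple[str, str]]:
    """Brute-force scan of the selection rule over every unordered pair."""
    n = len(gene_ids)
    topk: list[set[int]] = []
    for a in range(n):
        partners = [b for b in range(n) if b != a and not np.isnan(mr[a, b])]
        partners.sort(key=lambda b: (mr[a, b], gene_ids[b]))
        topk.append(set(partners[:top_k]))
    edges = set()
    for a in range(n):
        for b in range(a + 1, n):
            if np.isnan(pcc[a, b]) or abs(pcc[a, b]) < pcc_cutoff:
                continue
            if mr[a, b] <= mr_cutoff or b in topk[a] or a in topk[b]:
                key = tuple(sorted((gene_ids[a], gene_ids[b])))
                edges.add(key)
    return edges


def enumerate_upper_tail(N: int, n: int, K: int, k: int) -> float:
    """P(overlap >= k) by enumerating every possible n-subset of N items."""
    success = set(range(K))
    total = 0
    hits = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(success.intersection(draw)) >= k:
            hits += 1
    return hits / total


def exact_pmf(N: int, n: int, K: int, k: int):
    """Hypergeometric point probability with exact integer binomials."""
    from fractions import Fraction

    return Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))


def naive_bh(p_values) -> list[float]:
    """BH step-up from its textbook definition."""
    m = len(p_values)
    indexed = sorted(enumerate(p_values), key=lambda t: t[1])
    adjusted = [0.0] * m
    for pos, (orig, p) in enumerate(indexed, start=1):
        q = min(
            min(indexed[j][1] * m / (j + 1) for j in range(pos - 1, m)),
            1.0,
        )
        adjusted[orig] = q
    return adjusted
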