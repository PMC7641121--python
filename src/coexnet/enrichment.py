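"""Overlap-based gene-set enrichment: Fisher's exact upper tail with BH FDR.

For a query list of n genes drawn from a universe of N genes and a gene set
of K members, the probability of observing exactly k overlapping genes under
random sampling is hypergeometric::

    P(X = k) = C(K, k) * C(N - K, n - k) / C(N, n)

Enrichment significance is the one-sided upper tail P(X >= k) (Fisher's
exact test for over-representation); the point probability alone is not a
significance level.  Multiple testing across sets is controlled with the
Benjamini-Hochberg step-up adjustment, within annotation category when
categories are present (e.g. separate GO and pathway FDR tracks).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "hypergeom_pmf",
    "fisher_enrichment_p",
    "bh_fdr",
    "gsea",
]


@dataclass
class GeneSetCollection:
    """Named gene sets over an explicit gene universe.

    Every set member must belong to the universe.  ``categories`` optionally
    labels each set (e.g. 'GO:BP', 'pathway'); when present, FDR in
    :func:`gsea` is computed per category.
    """

    universe: tuple[str, ...]
    sets: dict[str, frozenset[str]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise ValueError("duplicate gene ids in universe")
        for name, members in self.sets.items():
            if not name:
                raise ValueError("empty gene-set name")
            stray = members - uni
            if stray:
                raise ValueError(f"set {name!r} has members outside the universe: {sorted(stray)[:5]}")

    @property
    def n_universe(self) -> int:
        return len(self.universe)

    @classmethod
    def from_gmt(cls, path, universe=None, categories=None) -> "GeneSetCollection":
        """Read GMT (name TAB description TAB member ids).

        Without an explicit universe, the union of all set members is used.
        A non-placeholder description field is taken as the set's category,
        which makes the GMT writer/reader a category-preserving round trip.
        """
        sets: dict[str, frozenset[str]] = {}
        parsed_cats: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
                name, desc, *members = parts
                sets[name] = frozenset(m for m in members if m)
                if desc and desc != "na":
                    parsed_cats[name] = desc
        if universe is None:
            universe = tuple(sorted(set().union(*sets.values()))) if sets else ()
        return cls(
            universe=tuple(universe),
            sets=sets,
            categories=dict(categories) if categories is not None else parsed_cats,
        )

    def to_gmt(self, path, descriptions: dict[str, str] | None = None) -> None:
        descriptions = descriptions or {}
        with open(path, "w", encoding="utf-8") as fh:
            for name in sorted(self.sets):
                desc = descriptions.get(name, self.categories.get(name, "na"))
                members = "\t".join(sorted(self.sets[name]))
                fh.write(f"{name}\t{desc}\t{members}\n")


@dataclass
class EnrichmentResult:
    name: str
    category: str
    k: int  # overlap
    K: int  # set size
    n: int  # query size
    N: int  # universe size
    p_value: float
    fdr: float


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _check_counts(N: int, n: int, K: int, k: int) -> None:
    for name, v in (("N", N), ("n", n), ("K", K), ("k", k)):
        if not isinstance(v, (int,)) or isinstance(v, bool):
            raise ValueError(f"{name} must be an integer, got {v!r}")
    if not (0 <= k <= min(n, K) and K <= N and n <= N and n - k <= N - K):
        raise ValueError(f"invalid hypergeometric counts N={N}, n={n}, K={K}, k={k}")


def hypergeom_pmf(N: int, n: int, K: int, k: int) -> float:
    """P(X = k) for a hypergeometric draw of n from N with K successes.

    Evaluated as a sum of log-gamma binomial coefficients, so large counts
    never overflow.
    """
    _check_counts(N, n, K, k)
    return math.exp(_log_binom(K, k) + _log_binom(N - K, n - k) - _log_binom(N, n))


def fisher_enrichment_p(N: int, n: int, K: int, k: int) -> float:
    """One-sided upper tail P(X >= k): Fisher's exact over-representation p.

    ``k = 0`` returns exactly 1.  The tail is accumulated in log space.
    """
    _check_counts(N, n, K, k)
    if k == 0:
        return 1.0
    log_norm = _log_binom(N, n)
    log_terms = [
        _log_binom(K, j) + _log_binom(N - K, n - j) - log_norm
        for j in range(k, min(n, K) + 1)
    ]
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def bh_fdr(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    Sort ascending, take ``q_i = min_{j >= i} p_(j) * m / j`` capped at 1,
    then map back to the original positions.
    """
    p = [float(v) for v in p_values]
    if any(v < 0 or v > 1 or math.isnan(v) for v in p):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, p[i] * m / (pos + 1))
        adjusted[i] = running
    return adjusted


def gsea(
    query,
    collection: GeneSetCollection,
    min_overlap: int = 1,
) -> list[EnrichmentResult]:
    """Test a query gene list against every set in the collection.

    Query genes outside the universe are dropped (their count is logged);
    duplicates are collapsed.  One result per set with overlap >= ``min_overlap``,
    p-values from :func:`fisher_enrichment_p`, FDR from :func:`bh_fdr`
    across all tested sets (per category when categories are present),
    sorted by ascending p then set name.
    """
    uni = set(collection.universe)
    query_set = set(query)
    effective = query_set & uni
    n_outside = len(query_set) - len(effective)
    if n_outside:
        logger.info("dropped %d query genes outside the universe", n_outside)
    if not effective:
        raise ValueError("no query genes remain within the universe")
    N = collection.n_universe
    n = len(effective)
    tested: list[EnrichmentResult] = []
    for name, members in collection.sets.items():
        k = len(effective & members)
        if k < min_overlap:
            continue
        p = fisher_enrichment_p(N, n, len(members), k)
        tested.append(
            EnrichmentResult(
                name=name,
                category=collection.categories.get(name, ""),
                k=k,
                K=len(members),
                n=n,
                N=N,
                p_value=p,
                fdr=float("nan"),
            )
        )
    by_cat: dict[str, list[EnrichmentResult]] = {}
    for res in tested:
        by_cat.setdefault(res.category, []).append(res)
    for group in by_cat.values():
        for res, q in zip(group, bh_fdr([r.p_value for r in group])):
            res.fdr = q
    tested.sort(key=lambda r: (r.p_value, r.name))
    return tested


def results_table(results: list[EnrichmentResult]):
    """Results as a DataFrame in the TSV export column order."""
    import pandas as pd

    return pd.DataFrame(
        [
            (r.name, r.category, r.k, r.K, r.n, r.N, r.p_value, r.fdr)
            for r in results
        ],
        columns=["set", "category", "k", "K", "n", "N", "p_value", "fdr"],
    )
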