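"""Mutual-rank co-expression network construction.

Pipeline: all-pairs Pearson correlation (PCC) over samples -> per-gene
neighbor ranking by descending \\|PCC\\| -> mutual rank
``MR(a,b) = sqrt(rank(a->b) * rank(b->a))`` -> edge selection.  A gene pair
becomes an edge when \\|PCC\\| >= ``pcc_cutoff`` and it is admitted by either
MR route: ``MR <= mr_cutoff``, or one endpoint is among the other's ``top_k``
partners by MR.  Edges are signed by the sign of the PCC, giving a positive
(PCC > 0) and a negative (PCC < 0) subnetwork within one graph.

Ranking uses the absolute correlation so that strongly anti-correlated pairs
can attain small mutual ranks; without this the negative subnetwork would be
unreachable.  Ties in \\|PCC\\| (and in MR for the top-k route) are broken by
ascending gene id, which makes the whole construction deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .expression import (
    DEFAULT_FPKM_THRESHOLD,
    ExpressionMatrix,
    TissueProfile,
    summarize_replicates,
    tissue_breadth,
)

__all__ = [
    "NetworkParams",
    "CorrelationStore",
    "RankStore",
    "CoexpressionNetwork",
    "DegreeStats",
    "pcc",
    "pcc_matrix",
    "rank_neighbors",
    "select_edges",
    "degree_distribution",
    "build_network",
]


@dataclass(frozen=True)
class NetworkParams:
    """Edge-selection thresholds.

    pcc_cutoff
        Minimum absolute Pearson correlation for an edge (default 0.7).
    top_k
        Number of lowest-MR partners per gene retained regardless of
        ``mr_cutoff`` (default 3).
    mr_cutoff
        Maximum mutual rank for the threshold route (default 30).
    min_expressed_tissues
        Genes expressed in fewer tissues are dropped before correlation
        (default 1, i.e. genes never expressed are excluded).
    """

    pcc_cutoff: float = 0.7
    top_k: int = 3
    mr_cutoff: float = 30.0
    min_expressed_tissues: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.pcc_cutoff <= 1.0:
            raise ValueError("pcc_cutoff must be in [0, 1]")
        if self.top_k < 0:
            raise ValueError("top_k must be >= 0")
        if self.mr_cutoff < 1:
            raise ValueError("mr_cutoff must be >= 1 (MR is never below 1)")


@dataclass
class CorrelationStore:
    """Symmetric all-pairs PCC matrix over a gene universe.

    ``undefined`` flags genes whose expression is constant across samples;
    their correlations are NaN and they take no part in ranking.
    """

    gene_ids: list[str]
    pcc: np.ndarray  # gene x gene, NaN where undefined
    undefined: np.ndarray  # bool per gene

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def defined_genes(self) -> list[str]:
        return [g for g, u in zip(self.gene_ids, self.undefined) if not u]


@dataclass
class RankStore:
    """Asymmetric neighbor ranks and the symmetric mutual ranks derived from them.

    ``rank[a, b]`` is the 1-based position of gene ``b`` in gene ``a``'s
    partner list ordered by descending \\|PCC\\| (ties by ascending gene id);
    0 marks self/undefined entries.  ``mr`` is the geometric mean of the two
    opposing ranks, NaN where undefined.
    """

    gene_ids: list[str]
    rank: np.ndarray  # int, 0 where undefined/self
    mr: np.ndarray  # float, NaN where undefined/self


def pcc(x, y) -> float:
    """Pearson correlation of two equal-length expression vectors.

    Returns NaN (the undefined-correlation signal) when either vector has
    zero variance, rather than guessing a numeric value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))


def pcc_matrix(data: pd.DataFrame | ExpressionMatrix | TissueProfile) -> CorrelationStore:
    """All-pairs gene correlation over sample (or tissue) columns.

    Accepts a raw gene x sample DataFrame, an :class:`ExpressionMatrix`
    (correlates over all replicate samples) or a :class:`TissueProfile`
    (correlates over tissue medians).  Zero-variance genes are flagged
    undefined, not dropped, so the caller controls the gene universe.
    """
    if isinstance(data, (ExpressionMatrix, TissueProfile)):
        df = data.values
    else:
        df = data
    arr = df.to_numpy(dtype=float)
    n_genes = arr.shape[0]
    if n_genes < 2:
        raise ValueError("need at least 2 genes to correlate")
    centered = arr - arr.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered * centered).sum(axis=1))
    undefined = norms == 0.0
    safe = np.where(undefined, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr = np.clip(corr, -1.0, 1.0)
    corr[undefined, :] = np.nan
    corr[:, undefined] = np.nan
    if int((~undefined).sum()) < 2:
        raise ValueError("fewer than 2 genes with non-constant expression")
    return CorrelationStore(gene_ids=list(df.index), pcc=corr, undefined=undefined)


def rank_neighbors(c: CorrelationStore) -> RankStore:
    """Rank every gene's partners by descending \\|PCC\\| and form mutual ranks.

    For gene ``a`` the defined partners are sorted by decreasing absolute
    correlation, ties broken by ascending gene id; ``rank[a, b]`` is the
    1-based position of ``b``.  ``mr[a, b] = sqrt(rank[a, b] * rank[b, a])``.
    """
    n = c.n_genes
    abs_pcc = np.abs(c.pcc)
    # lexicographic position of each gene id, used as the deterministic tie-break
    id_order = np.argsort(np.argsort(np.asarray(c.gene_ids, dtype=object)))
    rank = np.zeros((n, n), dtype=np.int64)
    defined = ~c.undefined
    partner_idx = np.flatnonzero(defined)
    for a in range(n):
        if c.undefined[a]:
            continue
        others = partner_idx[partner_idx != a]
        scores = abs_pcc[a, others]
        order = np.lexsort((id_order[others], -scores))
        rank[a, others[order]] = np.arange(1, others.size + 1)
    with np.errstate(invalid="ignore"):
        mr = np.sqrt(rank.astype(float) * rank.T.astype(float))
    mr[rank == 0] = np.nan
    mr[rank.T == 0] = np.nan
    return RankStore(gene_ids=list(c.gene_ids), rank=rank, mr=mr)


@dataclass
class CoexpressionNetwork:
    """Signed undirected co-expression graph.

    Edges carry ``pcc``, ``mr`` and ``sign`` ('positive' iff pcc > 0)
    attributes.  Nodes are the genes that entered correlation, whether or
    not they gained edges; genes dropped before correlation (unexpressed or
    constant) are listed in ``dropped_genes``.
    """

    graph: nx.Graph
    params: NetworkParams
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def subgraph_by_sign(self, sign: str) -> nx.Graph:
        if sign not in ("positive", "negative"):
            raise ValueError("sign must be 'positive' or 'negative'")
        keep = [(u, v) for u, v, s in self.graph.edges(data="sign") if s == sign]
        sub = self.graph.edge_subgraph(keep).copy()
        sub.add_nodes_from(self.graph.nodes)  # keep full node set, matching the parent
        return sub

    def positive(self) -> nx.Graph:
        return self.subgraph_by_sign("positive")

    def negative(self) -> nx.Graph:
        return self.subgraph_by_sign("negative")

    def edge_count_by_sign(self) -> dict[str, int]:
        counts = {"positive": 0, "negative": 0}
        for _, _, s in self.graph.edges(data="sign"):
            counts[s] += 1
        return counts

    def edge_table(self) -> pd.DataFrame:
        """Canonical edge list: gene_a < gene_b lexicographically, sorted."""
        rows = []
        for u, v, d in self.graph.edges(data=True):
            a, b = (u, v) if u < v else (v, u)
            rows.append((a, b, d["pcc"], d["mr"], d["sign"]))
        rows.sort()
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcc", "mr", "sign"])

    def node_table(self, profile: TissueProfile | None = None) -> pd.DataFrame:
        """Per-node degree, optionally with per-tissue expressed flags."""
        degree = dict(self.graph.degree)
        df = pd.DataFrame({"gene_id": self.nodes})
        df["degree"] = df["gene_id"].map(degree)
        if profile is not None:
            flags = profile.expressed.reindex(df["gene_id"])
            for t in profile.tissue_ids:
                df[f"expressed_{t}"] = flags[t].to_numpy()
        return df.sort_values("gene_id", ignore_index=True)


def select_edges(
    c: CorrelationStore, r: RankStore, params: NetworkParams | None = None
) -> CoexpressionNetwork:
    """Apply the correlation/mutual-rank thresholds and assemble the graph.

    Pair (a, b) is kept iff ``|pcc| >= pcc_cutoff`` and (``mr <= mr_cutoff``
    or b is among a's ``top_k`` partners by MR or vice versa).  The two MR
    routes are a union; the PCC cutoff is a conjunct over both.
    """
    if params is None:
        params = NetworkParams()
    if c.gene_ids != r.gene_ids:
        raise ValueError("correlation and rank stores cover different genes")
    n = c.n_genes
    abs_pcc = np.abs(c.pcc)
    with np.errstate(invalid="ignore"):
        pcc_ok = abs_pcc >= params.pcc_cutoff
        mr_ok = r.mr <= params.mr_cutoff
    topk = np.zeros((n, n), dtype=bool)
    if params.top_k > 0:
        id_order = np.argsort(np.argsort(np.asarray(c.gene_ids, dtype=object)))
        defined_idx = np.flatnonzero(~c.undefined)
        for a in defined_idx:
            others = defined_idx[defined_idx != a]
            order = np.lexsort((id_order[others], r.mr[a, others]))
            topk[a, others[order[: params.top_k]]] = True
    keep = pcc_ok & (mr_ok | topk | topk.T)
    np.fill_diagonal(keep, False)

    g = nx.Graph()
    g.add_nodes_from(c.defined_genes())
    ii, jj = np.nonzero(np.triu(keep, k=1))
    for a, b in zip(ii.tolist(), jj.tolist()):
        val = float(c.pcc[a, b])
        g.add_edge(
            c.gene_ids[a],
            c.gene_ids[b],
            pcc=val,
            mr=float(r.mr[a, b]),
            sign="positive" if val > 0 else "negative",
        )
    return CoexpressionNetwork(graph=g, params=params, dropped_genes=[g_ for g_, u in zip(c.gene_ids, c.undefined) if u])


@dataclass
class DegreeStats:
    histogram: pd.Series  # degree -> node count, degrees >= 1
    n_isolated: int
    slope: float
    r_squared: float


def degree_distribution(net: CoexpressionNetwork) -> DegreeStats:
    """Degree histogram and a log-log power-law fit.

    Fits least squares to log10(count) vs log10(degree) over degrees with at
    least one node; a negative slope with high R^2 indicates the scale-free
    shape (many weakly connected genes, few hubs).  Isolated nodes cannot
    enter the log-log fit and are reported separately.
    """
    degrees = [d for _, d in net.graph.degree]
    if not degrees or max(degrees) == 0:
        raise ValueError("network has no edges")
    pos = [d for d in degrees if d >= 1]
    hist = pd.Series(pos).value_counts().sort_index()
    hist.index.name = "degree"
    n_isolated = len(degrees) - len(pos)
    logd = np.log10(hist.index.to_numpy(dtype=float))
    logc = np.log10(hist.to_numpy(dtype=float))
    if len(hist) < 2:
        return DegreeStats(hist, n_isolated, float("nan"), float("nan"))
    slope, intercept = np.polyfit(logd, logc, 1)
    fitted = slope * logd + intercept
    ss_res = float(((logc - fitted) ** 2).sum())
    ss_tot = float(((logc - logc.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return DegreeStats(hist, n_isolated, float(slope), r2)


def build_network(
    m: ExpressionMatrix,
    params: NetworkParams | None = None,
    *,
    fpkm_threshold: float = DEFAULT_FPKM_THRESHOLD,
    use_tissue_medians: bool = False,
    log_transform: bool = False,
) -> tuple[CoexpressionNetwork, TissueProfile]:
    """End-to-end construction from an expression matrix.

    Genes expressed (median FPKM > ``fpkm_threshold``) in fewer than
    ``params.min_expressed_tissues`` tissues are removed before correlation.
    Correlation runs over all replicate samples by default; set
    ``use_tissue_medians`` to correlate tissue medians instead.  FPKM values
    are used untransformed unless ``log_transform`` applies log2(FPKM + 1).
    """
    if params is None:
        params = NetworkParams()
    profile = summarize_replicates(m, threshold=fpkm_threshold)
    breadth, _ = tissue_breadth(profile)
    keep = breadth[breadth >= params.min_expressed_tissues].index
    if len(keep) < 2:
        raise ValueError("fewer than 2 genes pass the expression filter")
    data = profile.values.loc[keep] if use_tissue_medians else m.values.loc[keep]
    if log_transform:
        data = np.log2(data + 1.0)
    store = pcc_matrix(data)
    ranks = rank_neighbors(store)
    net = select_edges(store, ranks, params)
    filtered_out = [g for g in m.gene_ids if g not in set(keep)]
    net.dropped_genes = filtered_out + net.dropped_genes
    return net, profile
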