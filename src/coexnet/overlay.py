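"""Neighborhood queries and tissue-expression / differential-expression overlays.

The case-study workflow: pull the mutual-rank-bounded neighborhood of one or
more query genes out of a built network, then annotate its nodes with the
expressed/not-expressed state in a chosen tissue and with up/down/ns classes
from a differential-expression table.  Overlays only attach node attributes;
they never change the subnetwork topology.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .expression import TissueProfile
from .network import CoexpressionNetwork

__all__ = [
    "DegTable",
    "OverlaidSubnetwork",
    "classify_deg",
    "neighborhood",
    "overlay_tissue",
    "overlay_deg",
    "to_cytoscape_json",
]

DEG_CLASSES = ("up", "down", "ns")


def classify_deg(log2fc: float, padj: float, fc_threshold: float = 1.0, alpha: float = 0.05) -> str:
    """Classify one gene as up / down / ns from its fold change and adjusted p.

    Strict inequalities throughout: ``up`` iff padj < alpha and
    log2fc > fc_threshold; ``down`` iff padj < alpha and log2fc < -fc_threshold;
    boundary values (padj == alpha, |log2fc| == fc_threshold) are ``ns``.
    """
    if math.isnan(padj) or not 0.0 <= padj <= 1.0:
        raise ValueError(f"padj must be in [0, 1], got {padj}")
    if padj < alpha and log2fc > fc_threshold:
        return "up"
    if padj < alpha and log2fc < -fc_threshold:
        return "down"
    return "ns"


@dataclass
class DegTable:
    """Per-gene log2 fold change, BH-adjusted p, and up/down/ns class.

    Classes are derived once at construction from ``fc_threshold`` and
    ``alpha``; reclassify by building a new table.
    """

    table: pd.DataFrame  # index gene_id; columns log2fc, padj, class
    fc_threshold: float = 1.0
    alpha: float = 0.05

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fc_threshold: float = 1.0, alpha: float = 0.05) -> "DegTable":
        """Build from a frame with gene_id, log2FoldChange, padj columns."""
        df = df.rename(columns={"log2FoldChange": "log2fc"})
        if "gene_id" in df.columns:
            df = df.set_index("gene_id")
        if df.index.has_duplicates:
            raise ValueError("duplicate gene ids in DEG table")
        out = df[["log2fc", "padj"]].astype(float).copy()
        out["class"] = [
            classify_deg(fc, p, fc_threshold, alpha)
            for fc, p in zip(out["log2fc"], out["padj"])
        ]
        return cls(table=out, fc_threshold=fc_threshold, alpha=alpha)

    @classmethod
    def from_tsv(cls, path, fc_threshold: float = 1.0, alpha: float = 0.05) -> "DegTable":
        """Read TSV with columns gene_id, log2FoldChange, padj."""
        return cls.from_frame(pd.read_csv(path, sep="\t"), fc_threshold, alpha)

    def class_of(self, gene: str) -> str:
        """Class for a gene; genes absent from the table are 'ns'."""
        if gene in self.table.index:
            return str(self.table.at[gene, "class"])
        return "ns"


@dataclass
class OverlaidSubnetwork:
    """A neighborhood extracted from a parent network, plus node annotations.

    Node attributes: ``role`` ('query' or 'neighbor'), and after overlays
    ``tissue``/``expressed`` and ``deg_class``.  Edge attributes (pcc, mr,
    sign) are copied unchanged from the parent network.
    """

    graph: nx.Graph
    queries: tuple[str, ...]
    mr_max: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v, d in self.graph.edges(data=True):
            a, b = (u, v) if u < v else (v, u)
            rows.append((a, b, d["pcc"], d["mr"], d["sign"]))
        rows.sort()
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcc", "mr", "sign"])


def neighborhood(net: CoexpressionNetwork, queries, mr_max: float) -> OverlaidSubnetwork:
    """Extract the MR-bounded neighborhood of one or more query genes.

    Neighbors are genes sharing an edge of ``mr <= mr_max`` with any query.
    The subnetwork keeps every edge among the selected nodes (queries plus
    neighbors) whose mr is within the same bound, so links between neighbors
    are displayed too, not just query spokes.
    """
    queries = tuple(queries)
    unknown = [q for q in queries if q not in net.graph]
    if unknown:
        raise KeyError(f"query genes not in network: {unknown}")
    members = set(queries)
    for q in queries:
        for _, nb, mr in net.graph.edges(q, data="mr"):
            if mr <= mr_max:
                members.add(nb)
    sub = nx.Graph()
    for node in sorted(members):
        sub.add_node(node, role="query" if node in queries else "neighbor")
    for u, v, d in net.graph.subgraph(members).edges(data=True):
        if d["mr"] <= mr_max:
            sub.add_edge(u, v, **d)
    return OverlaidSubnetwork(graph=sub, queries=queries, mr_max=float(mr_max))


def overlay_tissue(sub: OverlaidSubnetwork, p: TissueProfile, tissue: str) -> OverlaidSubnetwork:
    """Annotate each node with its expressed state in one tissue.

    Nodes not expressed in the tissue are the ones a viewer would gray out.
    Topology is untouched; re-applying the same overlay is a no-op.
    """
    if tissue not in p.tissue_ids:
        raise KeyError(f"unknown tissue {tissue!r}")
    missing = [g for g in sub.graph.nodes if g not in p.values.index]
    if missing:
        raise KeyError(f"genes missing from tissue profile: {missing[:5]}")
    out = OverlaidSubnetwork(graph=sub.graph.copy(), queries=sub.queries, mr_max=sub.mr_max)
    for node in out.graph.nodes:
        out.graph.nodes[node]["tissue"] = tissue
        out.graph.nodes[node]["expressed"] = p.is_expressed(node, tissue)
    return out


def overlay_deg(sub: OverlaidSubnetwork, table: DegTable) -> OverlaidSubnetwork:
    """Annotate each node with its up/down/ns class; absent genes are 'ns'."""
    out = OverlaidSubnetwork(graph=sub.graph.copy(), queries=sub.queries, mr_max=sub.mr_max)
    for node in out.graph.nodes:
        out.graph.nodes[node]["deg_class"] = table.class_of(node)
    return out


def to_cytoscape_json(sub: OverlaidSubnetwork) -> dict:
    """Cytoscape-compatible elements dict (nodes[] and edges[] with data)."""
    nodes = [
        {"data": {"id": node, **attrs}}
        for node, attrs in sorted(sub.graph.nodes(data=True))
    ]
    edges = []
    for u, v, d in sub.graph.edges(data=True):
        a, b = (u, v) if u < v else (v, u)
        edges.append({"data": {"id": f"{a}|{b}", "source": a, "target": b, **d}})
    edges.sort(key=lambda e: e["data"]["id"])
    return {"elements": {"nodes": nodes, "edges": edges}}


def write_cytoscape_json(sub: OverlaidSubnetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(to_cytoscape_json(sub), fh, indent=1, sort_keys=True)
        fh.write("\n")
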