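"""FPKM expression matrices: loading, validation, replicate summaries, expression calls.

The central objects are :class:`ExpressionMatrix` (gene x sample FPKM values
plus per-sample metadata) and :class:`TissueProfile` (per-gene, per-tissue
median expression with boolean expressed/not-expressed calls).  A gene is
called *expressed* in a tissue when its median FPKM across that tissue's
replicates is strictly greater than the FPKM threshold (default 0.3); the
value 0.3 itself is therefore not expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Minimum FPKM for a gene to be called expressed (strict greater-than).
DEFAULT_FPKM_THRESHOLD = 0.3

META_COLUMNS = ("tissue", "replicate", "cultivar")


class FormatError(ValueError):
    """Malformed expression matrix: duplicate ids, negative or non-numeric values."""


class MetadataError(ValueError):
    """Sample metadata does not cover the expression matrix."""


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of FPKM values with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.  All
        entries must be finite and non-negative.
    sample_meta
        DataFrame indexed by sample id with columns ``tissue``, ``replicate``
        and ``cultivar``.  Every sample column of ``values`` must appear.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dupes}")
        if v.columns.has_duplicates:
            dupes = v.columns[v.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric values in expression matrix")
        if not np.all(np.isfinite(arr)):
            raise FormatError("non-finite values in expression matrix")
        if (arr < 0).any():
            raise FormatError("negative FPKM values in expression matrix")
        missing_cols = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing_cols:
            raise MetadataError(f"metadata lacks columns: {missing_cols}")
        missing = [s for s in v.columns if s not in self.sample_meta.index]
        if missing:
            raise MetadataError(f"samples missing from metadata: {missing}")
        # replicate indices must be distinct within a tissue
        meta = self.sample_meta.loc[list(v.columns)]
        if meta.duplicated(subset=["tissue", "replicate", "cultivar"]).any():
            raise MetadataError("duplicate (tissue, replicate, cultivar) in metadata")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissues(self) -> list[str]:
        """Tissue labels in order of first appearance among the samples."""
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_meta.at[s, "tissue"], None)
        return list(seen)

    def tissue_samples(self, tissue: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_meta.at[s, "tissue"] == tissue]

    def to_tsv(self, path, meta_path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")
        meta = self.sample_meta.loc[list(self.values.columns), list(META_COLUMNS)]
        meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def load_expression(path, meta_path) -> ExpressionMatrix:
    """Read an expression matrix and its sample metadata from TSV files.

    The matrix file has a header row of sample ids and one row per gene, the
    first column holding the gene id.  The metadata file has columns
    ``sample_id``, ``tissue``, ``replicate``, ``cultivar``.  Row and column
    order is preserved.
    """
    try:
        values = pd.read_csv(path, sep="\t", index_col=0)
        values = values.astype(float)
    except ValueError as exc:
        raise FormatError(f"cannot parse expression matrix {path}: {exc}") from exc
    try:
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id", dtype=str)
    except ValueError as exc:
        raise MetadataError(f"cannot parse sample metadata {meta_path}: {exc}") from exc
    return ExpressionMatrix(values=values, sample_meta=meta)


@dataclass
class TissueProfile:
    """Per-gene, per-tissue summarized expression with expressed calls.

    ``values`` holds the median FPKM across a tissue's replicates;
    ``expressed`` is derived: median strictly greater than ``threshold``.
    """

    values: pd.DataFrame  # genes x tissues, medians
    threshold: float = DEFAULT_FPKM_THRESHOLD

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative summarized FPKM")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def expressed(self) -> pd.DataFrame:
        return self.values > self.threshold

    def is_expressed(self, gene: str, tissue: str) -> bool:
        return bool(self.values.at[gene, tissue] > self.threshold)


def summarize_replicates(
    m: ExpressionMatrix, threshold: float = DEFAULT_FPKM_THRESHOLD
) -> TissueProfile:
    """Collapse replicate samples to per-tissue medians.

    The median is taken across all samples sharing a tissue label (the
    midpoint of the two central values for even replicate counts).  Tissue
    column order follows first appearance in the sample metadata.
    """
    if m.values.empty:
        raise ValueError("empty expression matrix")
    cols = {t: m.values[m.tissue_samples(t)].median(axis=1) for t in m.tissues}
    summary = pd.DataFrame(cols, index=m.values.index)
    return TissueProfile(values=summary, threshold=threshold)


def per_sample_expressed(
    m: ExpressionMatrix, threshold: float = DEFAULT_FPKM_THRESHOLD
) -> pd.DataFrame:
    """Per-sample expressed calls (FPKM > threshold), the un-summarized variant."""
    return m.values > threshold


def tissue_breadth(p: TissueProfile) -> tuple[pd.Series, pd.Series]:
    """Count, per gene, the tissues in which it is expressed.

    Returns ``(breadth, histogram)`` where ``breadth`` maps gene id to the
    number of tissues with an expressed call and ``histogram`` maps each
    breadth value 0..n_tissues to the number of genes attaining it.
    """
    breadth = p.expressed.sum(axis=1).astype(int)
    n_tissues = len(p.tissue_ids)
    hist = breadth.value_counts().reindex(range(n_tissues + 1), fill_value=0)
    hist.index.name = "n_tissues_expressed"
    return breadth, hist


def replicate_correlation(m: ExpressionMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson correlation between sample columns.

    Used as a replicate-quality check: biological replicates of the same
    tissue should correlate highly.  Samples that are constant across all
    genes have undefined correlation; their rows/columns are NaN and their
    ids are returned in the second element rather than silently zeroed.
    """
    arr = m.values.to_numpy(dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 genes for sample correlations")
    sd = arr.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, np.where(constant, np.nan, 1.0))
    df = pd.DataFrame(corr, index=m.sample_ids, columns=m.sample_ids)
    flagged = [s for s, c in zip(m.sample_ids, constant) if c]
    return df, flagged
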