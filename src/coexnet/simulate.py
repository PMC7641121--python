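"""Seeded synthetic FPKM data with planted co-expression structure.

The generator emulates a multi-tissue RNA-seq design (10 tissues x 3
biological replicates by default) with four gene populations:

* **module genes** — each of ``n_modules`` modules has a latent per-tissue
  activity archetype; a member gene's tissue mean is ``expression_scale *
  latent`` (sign +1) or ``expression_scale * (max(latent) - latent)``
  (sign -1, reflecting the profile about its maximum so that opposite-sign
  pairs are exactly anti-correlated at zero noise);
* **background genes** — each gets its own independent latent profile;
* **silent genes** — uniform values in [0, 0.3], never called expressed at
  the default FPKM threshold;
* replicate values are the tissue mean times ``2**eps`` with
  ``eps ~ Normal(0, noise_sd)`` — multiplicative log-normal noise, keeping
  FPKM non-negative without clipping.

Module archetypes are rejection-sampled so that no two have \\|corr\\| above
``max_archetype_corr``; planted module identity is then unambiguous ground
truth for recovery experiments.  Every operation draws from its own RNG
stream keyed by (seed, operation), so adding operations never perturbs
existing outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .enrichment import GeneSetCollection
from .overlay import DegTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_expression",
    "simulate_gene_sets",
    "simulate_deg_table",
]

# offsets separating the per-operation RNG streams
_STREAMS = {"expression": 0, "gene_sets": 1, "deg": 2, "deg_table": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters for the synthetic generator.

    Defaults mirror a 10-tissue, 3-replicate design with 20 planted modules
    of 25 genes, a background of 300 independently varying genes and 50
    silent genes; 10% of each module's genes are anti-correlated with its
    archetype, and replicate noise has sd 0.2 on the log2 scale.
    """

    n_tissues: int = 10
    n_replicates: int = 3
    n_modules: int = 20
    module_size: int = 25
    n_background_genes: int = 300
    n_silent_genes: int = 50
    frac_negative: float = 0.1
    noise_sd: float = 0.2
    expression_scale: float = 50.0
    seed: int = 0
    # Archetypes are resampled until every pair satisfies this |corr| cap.
    # 0.45 keeps realized between-module gene correlations (cap plus a few
    # standard errors of a PCC estimate at ~30 samples, se ~ 0.12) clearly
    # below the within-module range, so planted membership is unambiguous;
    # much tighter caps approach the packing limit of 20 profiles in the
    # 9-dimensional centered tissue space and stall rejection sampling.
    max_archetype_corr: float = 0.45
    #: fraction of non-silent genes planted as true DEGs between two cultivars
    frac_deg: float = 0.1
    cultivar: str = "cultivarA"

    def __post_init__(self) -> None:
        counts = (
            self.n_tissues,
            self.n_replicates,
            self.n_modules,
            self.module_size,
            self.n_background_genes,
            self.n_silent_genes,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not 0.0 <= self.frac_negative <= 1.0:
            raise ValueError("frac_negative must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.expression_scale <= 0:
            raise ValueError("expression_scale must be > 0")

    @property
    def n_module_genes(self) -> int:
        return self.n_modules * self.module_size

    @property
    def n_genes(self) -> int:
        return self.n_module_genes + self.n_background_genes + self.n_silent_genes


@dataclass
class SimTruth:
    """Ground truth accompanying one simulated matrix."""

    gene_ids: tuple[str, ...]
    module_of_gene: dict[str, str]  # gene -> module name, 'background' or 'silent'
    sign_of_gene: dict[str, int]  # +1/-1 for module genes, +1 otherwise
    tissue_archetype: dict[str, np.ndarray]  # module name -> latent activity per tissue
    planted_gene_sets: dict[str, tuple[str, ...]]  # module name -> member genes
    planted_deg: dict[str, float]  # gene -> true log2 fold change
    config: SimConfig = field(repr=False, default=None)

    def module_labels(self, genes=None) -> pd.Series:
        genes = list(genes) if genes is not None else list(self.gene_ids)
        return pd.Series({g: self.module_of_gene[g] for g in genes})

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "gene_id": list(self.gene_ids),
                "module": [self.module_of_gene[g] for g in self.gene_ids],
                "sign": [self.sign_of_gene[g] for g in self.gene_ids],
                "true_log2fc": [self.planted_deg.get(g, 0.0) for g in self.gene_ids],
            }
        )
        df.to_csv(path, sep="\t", index=False)


def _sample_archetypes(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Uniform(0,1) tissue profiles, resampled until pairwise |corr| is capped.

    Greedy rejection in batches with full restarts: a candidate profile is
    kept when its correlation with every already-kept profile stays within
    ``max_archetype_corr``.  Deterministic given the generator state.
    """
    if cfg.n_tissues < 3 or cfg.n_modules < 2:
        return rng.uniform(0.0, 1.0, size=(cfg.n_modules, cfg.n_tissues))
    batch_size, slot_budget, max_restarts = 512, 60000, 20
    for _restart in range(max_restarts):
        raw: list[np.ndarray] = []
        units: list[np.ndarray] = []
        while len(raw) < cfg.n_modules:
            placed = False
            for _ in range(0, slot_budget, batch_size):
                batch = rng.uniform(0.0, 1.0, size=(batch_size, cfg.n_tissues))
                centered = batch - batch.mean(axis=1, keepdims=True)
                norms = np.linalg.norm(centered, axis=1)
                valid = norms > 0
                unit = np.zeros_like(centered)
                unit[valid] = centered[valid] / norms[valid, None]
                if units:
                    ok = valid & (
                        np.max(np.abs(np.asarray(units) @ unit.T), axis=0)
                        <= cfg.max_archetype_corr
                    )
                else:
                    ok = valid
                hits = np.flatnonzero(ok)
                if hits.size:
                    i = int(hits[0])
                    raw.append(batch[i])
                    units.append(unit[i])
                    placed = True
                    break
            if not placed:
                break
        if len(raw) == cfg.n_modules:
            return np.asarray(raw)
    raise RuntimeError("cannot sample archetypes under the correlation cap")


def simulate_expression(cfg: SimConfig | None = None) -> tuple[ExpressionMatrix, SimTruth]:
    """Draw one expression matrix plus its ground truth; deterministic given seed."""
    if cfg is None:
        cfg = SimConfig()
    if cfg.n_tissues == 0 or cfg.n_genes == 0:
        raise ValueError("need at least one tissue and one gene")
    rng = _rng(cfg.seed, "expression")

    tissues = [f"T{t + 1:02d}" for t in range(cfg.n_tissues)]
    sample_ids = [f"{t}_R{r + 1}" for t in tissues for r in range(cfg.n_replicates)]
    meta = pd.DataFrame(
        {
            "tissue": [s.split("_R")[0] for s in sample_ids],
            "replicate": [int(s.split("_R")[1]) for s in sample_ids],
            "cultivar": cfg.cultivar,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    archetypes = _sample_archetypes(rng, cfg)
    gene_ids: list[str] = []
    module_of: dict[str, str] = {}
    sign_of: dict[str, int] = {}
    planted_sets: dict[str, tuple[str, ...]] = {}
    tissue_means: list[np.ndarray] = []
    n_neg = int(round(cfg.frac_negative * cfg.module_size))

    for m in range(cfg.n_modules):
        mod = f"module_{m + 1:02d}"
        latent = archetypes[m]
        reflected = latent.max() - latent
        members = []
        for j in range(cfg.module_size):
            g = f"M{m + 1:02d}_{j + 1:03d}"
            sign = -1 if j >= cfg.module_size - n_neg else 1
            profile = latent if sign == 1 else reflected
            gene_ids.append(g)
            members.append(g)
            module_of[g] = mod
            sign_of[g] = sign
            tissue_means.append(cfg.expression_scale * profile)
        planted_sets[mod] = tuple(members)
    for i in range(cfg.n_background_genes):
        g = f"BG_{i + 1:04d}"
        gene_ids.append(g)
        module_of[g] = "background"
        sign_of[g] = 1
        tissue_means.append(cfg.expression_scale * rng.uniform(0.0, 1.0, cfg.n_tissues))
    silent_ids = [f"SI_{i + 1:04d}" for i in range(cfg.n_silent_genes)]

    n_samples = cfg.n_tissues * cfg.n_replicates
    structured = np.asarray(tissue_means) if tissue_means else np.empty((0, cfg.n_tissues))
    # expand tissue means to the replicate layout, then apply log-normal noise
    expanded = np.repeat(structured, cfg.n_replicates, axis=1)
    if cfg.noise_sd > 0 and expanded.size:
        eps = rng.normal(0.0, cfg.noise_sd, size=expanded.shape)
        expanded = expanded * np.exp2(eps)
    silent_vals = rng.uniform(0.0, 0.3, size=(cfg.n_silent_genes, n_samples))

    all_ids = gene_ids + silent_ids
    for g in silent_ids:
        module_of[g] = "silent"
        sign_of[g] = 1
    values = pd.DataFrame(
        np.vstack([expanded, silent_vals]) if all_ids else np.empty((0, n_samples)),
        index=pd.Index(all_ids, name="gene_id"),
        columns=sample_ids,
    )

    deg_rng = _rng(cfg.seed, "deg")
    non_silent = gene_ids
    n_deg = int(round(cfg.frac_deg * len(non_silent)))
    deg_genes = sorted(deg_rng.choice(non_silent, size=n_deg, replace=False).tolist()) if n_deg else []
    magnitudes = deg_rng.uniform(1.5, 4.0, size=len(deg_genes))
    signs = deg_rng.choice([-1.0, 1.0], size=len(deg_genes))
    planted_deg = {g: float(s * m) for g, s, m in zip(deg_genes, signs, magnitudes)}

    truth = SimTruth(
        gene_ids=tuple(all_ids),
        module_of_gene=module_of,
        sign_of_gene=sign_of,
        tissue_archetype={f"module_{m + 1:02d}": archetypes[m] for m in range(cfg.n_modules)},
        planted_gene_sets=planted_sets,
        planted_deg=planted_deg,
        config=cfg,
    )
    return ExpressionMatrix(values=values, sample_meta=meta), truth


def simulate_gene_sets(
    truth: SimTruth,
    n_random_sets: int = 50,
    random_set_size: int = 25,
    seed: int = 0,
) -> GeneSetCollection:
    """One gene set per planted module plus random decoy sets from the universe."""
    universe = tuple(truth.gene_ids)
    if n_random_sets > 0 and random_set_size > len(universe):
        raise ValueError("random_set_size exceeds the gene universe")
    rng = _rng(seed, "gene_sets")
    sets: dict[str, frozenset[str]] = {
        name: frozenset(members) for name, members in truth.planted_gene_sets.items()
    }
    categories = {name: "planted" for name in sets}
    for i in range(n_random_sets):
        name = f"random_{i + 1:03d}"
        members = rng.choice(universe, size=random_set_size, replace=False)
        sets[name] = frozenset(members.tolist())
        categories[name] = "random"
    return GeneSetCollection(universe=universe, sets=sets, categories=categories)


def simulate_deg_table(truth: SimTruth, seed: int = 0) -> DegTable:
    """A differential-expression table consistent with the planted truth.

    Planted DEGs keep their true log2 fold change (|lfc| >= 1.5) and draw
    an adjusted p below 0.01; all other genes draw |lfc| < 0.5 with adjusted
    p uniform on (0.05, 1), so the default up/down thresholds recover
    exactly the planted genes.
    """
    rng = _rng(seed, "deg_table")
    rows = []
    for g in truth.gene_ids:
        if g in truth.planted_deg:
            lfc = truth.planted_deg[g]
            padj = float(rng.uniform(1e-10, 0.01))
        else:
            lfc = float(rng.uniform(-0.5, 0.5))
            padj = float(rng.uniform(0.05, 1.0))
        rows.append((g, lfc, padj))
    df = pd.DataFrame(rows, columns=["gene_id", "log2FoldChange", "padj"])
    return DegTable.from_frame(df)


def deg_table_to_tsv(table: DegTable, path) -> None:
    out = table.table.rename(columns={"log2fc": "log2FoldChange"})
    out[["log2FoldChange", "padj"]].to_csv(path, sep="\t", index_label="gene_id")
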