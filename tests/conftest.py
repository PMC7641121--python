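import numpy as np
import pandas as pd
import pytest

from coexnet import ExpressionMatrix, SimConfig, simulate_expression


def make_matrix(values, gene_ids=None, tissues=None, replicates=None) -> ExpressionMatrix:
    """Hand-build a small ExpressionMatrix with one-tissue-per-column defaults."""
    arr = np.asarray(values, dtype=float)
    n_genes, n_samples = arr.shape
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(n_genes)]
    tissues = tissues or [f"t{j + 1}" for j in range(n_samples)]
    replicates = replicates or [1] * n_samples
    sample_ids = [f"{t}_r{r}" for t, r in zip(tissues, replicates)]
    meta = pd.DataFrame(
        {"tissue": tissues, "replicate": replicates, "cultivar": "cv"},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    values_df = pd.DataFrame(arr, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(values=values_df, sample_meta=meta)


@pytest.fixture(scope="session")
def small_sim():
    """A small noisy simulation shared across read-only tests."""
    cfg = SimConfig(
        n_modules=4,
        module_size=10,
        n_background_genes=40,
        n_silent_genes=10,
        seed=7,
    )
    return simulate_expression(cfg)


@pytest.fixture(scope="session")
def zero_noise_sim():
    cfg = SimConfig(
        n_modules=3,
        module_size=8,
        n_background_genes=20,
        n_silent_genes=5,
        noise_sd=0.0,
        seed=11,
    )
    return simulate_expression(cfg)
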