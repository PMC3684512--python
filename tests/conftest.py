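import numpy as np
import pandas as pd
import pytest

from chipxpress.compendium import ExpressionCompendium, GeneMatrix, standardize


def make_compendium_raw(gene_ids, values, sample_ids=None):
    """Build a compendium directly from given rows, without standardizing.

    Used by worked examples that specify the matrix values exactly; metadata
    is computed from the rows as given.
    """
    values = np.asarray(values, dtype=float)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(values.shape[1])]
    mu = values.mean(axis=1)
    var = values.var(axis=1, ddof=1)
    meta = pd.DataFrame(
        {
            "mu": mu,
            "var": var,
            "cv": np.where(mu == 0, np.inf, np.sqrt(var) / np.where(mu == 0, 1, mu)),
            "zero_variance": var == 0,
        },
        index=pd.Index(list(gene_ids), name="gene_id"),
    )
    return ExpressionCompendium(list(gene_ids), list(sample_ids), values, meta)


def random_compendium(rng, n_genes, n_samples, prefix="g"):
    ids = [f"{prefix}{i:03d}" for i in range(n_genes)]
    values = rng.standard_normal((n_genes, n_samples))
    return standardize(
        GeneMatrix(ids, [f"s{i:03d}" for i in range(n_samples)], values)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_cp(rng):
    """20 genes x 12 samples, standardized, deterministic."""
    return random_compendium(rng, 20, 12)
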