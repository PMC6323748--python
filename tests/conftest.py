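import numpy as np
import pandas as pd
import pytest

from trimodal.preprocess import ExpressionMatrix
from trimodal.synthetic import SimConfig, simulate_mixture_gene


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def fig1a_gene():
    """Reference validation simulation: tumor 100/250/150 from
    N(-4,1)/N(0,1)/N(3,1), 50 normals from N(0,1)."""
    gene, labels = simulate_mixture_gene(SimConfig(seed=11))
    return gene, labels


def make_matrix(values, gene_ids=None, sample_ids=None, classes=None):
    """Small ExpressionMatrix from a 2-D array; all samples tumor by default."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    classes = classes or ["tumor"] * n_samples
    data = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    return ExpressionMatrix(data=data, sample_class=pd.Series(classes, index=sample_ids))
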