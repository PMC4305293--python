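import numpy as np
import pytest

from aberrex.formats_io import ExpressionMatrix


@pytest.fixture
def tiny_expr():
    """3 genes × 4 samples with two populations."""
    return ExpressionMatrix(
        gene_ids=["gA", "gB", "gC"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.arange(12, dtype=float).reshape(3, 4),
        population={"s1": "EUR", "s2": "EUR", "s3": "AFR", "s4": "AFR"},
    )


@pytest.fixture
def mvn_expr():
    """200 multivariate-normal background genes over 120 samples."""
    rng = np.random.default_rng(42)
    n_genes, n_samples = 200, 120
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        sample_ids=[f"s{i}" for i in range(n_samples)],
        values=rng.standard_normal((n_genes, n_samples)),
    )
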