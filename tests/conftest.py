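"""Shared fixtures: small expression matrices and a synthetic dataset."""

import numpy as np
import pandas as pd
import pytest

from cetriplet.preprocess import ExpressionMatrix
from cetriplet.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def tiny_matrix():
    """A 5-RNA x 8-sample matrix with one of each class plus spares."""
    rng = np.random.default_rng(11)
    ids = ["mir-a", "mir-b", "LNC-A", "GENE-A", "GENE-B"]
    classes = ["miRNA", "miRNA", "lncRNA", "mRNA", "mRNA"]
    values = pd.DataFrame(
        rng.lognormal(2.0, 1.0, (5, 8)),
        index=ids,
        columns=[f"S{i}" for i in range(8)],
    )
    return ExpressionMatrix(values, pd.Series(classes, index=ids))


@pytest.fixture(scope="session")
def small_dataset():
    """A quick planted dataset shared across tests (n=120, 5 planted)."""
    cfg = SyntheticConfig(
        n_samples=120, n_planted=5, n_null_genes=20, n_null_mirnas=6, seed=3
    )
    return generate_dataset(cfg)
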