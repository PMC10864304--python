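"""Shared fixtures: small synthetic datasets and fast training configs."""

import numpy as np
import pytest

from markersel.data_io import ExpressionDataset
from markersel.synthetic import gaussian_clusters
from markersel.training import TrainingConfig


@pytest.fixture(scope="session")
def easy_dataset():
    """One strongly informative gene among ten; two classes."""
    rng = np.random.default_rng(7)
    n, d = 600, 10
    X = rng.standard_normal((n, d))
    y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
    X[: n // 2, 0] += 3.0
    X[n // 2:, 0] -= 3.0
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    return ExpressionDataset(
        matrix=X,
        gene_names=[f"g{j}" for j in range(d)],
        cell_ids=[f"c{i}" for i in range(n)],
        labels=y,
        stage="normalized_standard",
    )


@pytest.fixture(scope="session")
def small_clusters():
    """Separable Gaussian clusters at desk-test scale."""
    ds, truth = gaussian_clusters(n=450, d=30, C=3, n_informative=6,
                                  separation=6.0, seed=3)
    return ds, truth


@pytest.fixture
def fast_config():
    """A training config sized for unit tests (fixed lr, few epochs)."""
    return TrainingConfig(mode="supervised", seed=0, learning_rate=5e-4,
                          max_epochs=5, min_epochs=2)
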