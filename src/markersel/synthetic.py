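"""Synthetic fixtures with known ground truth.

Three generators cover the behaviours the rest of the package has to
demonstrate.  ``parity_toy`` builds the three-gene parity problem: every
gene is an independent +-1 signal, and the cell state depends on whether
the first three genes agree in sign — so no single gene is marginally
informative, only the joint panel is.  ``gaussian_clusters`` builds
well-separated Gaussian classes whose signal lives in a known subset of
genes, for recovery and classification benchmarks.  ``count_matrix``
produces non-negative integer counts whose per-cell-type presence
fractions are controlled exactly, to exercise the preprocessing filters.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data_io import ExpressionDataset

__all__ = ["GroundTruth", "parity_toy", "gaussian_clusters", "count_matrix"]


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Which genes carry signal, and how the data were generated."""

    informative_genes: tuple[int, ...]
    generative_params: dict
    seed: int


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    return (X - X.mean(axis=0)) / sd


def parity_toy(n: int = 4000, d: int = 500, seed: int = 0,
               jitter: float = 0.1) -> tuple[ExpressionDataset, GroundTruth]:
    """Two cell states determined by the parity of three +-1 genes.

    A cell is in state A when genes 0, 1 and 2 are all overexpressed
    (+1, +1, +1) or all underexpressed (-1, -1, -1); otherwise it is in
    state B.  Every gene has per-state mean 0, so marginal statistics are
    useless and only a joint three-gene panel predicts the state.  A small
    Gaussian jitter (sd ``jitter``) keeps the data continuous for
    gradient-based training; ``jitter=0`` gives the literal +-1 signals.
    The returned matrix is per-gene standardized.
    """
    if d < 3:
        raise ValueError("parity toy needs d >= 3")
    if n < 8:
        raise ValueError("parity toy needs n >= 8")
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n, d))
    state_a = (signs[:, 0] == signs[:, 1]) & (signs[:, 1] == signs[:, 2])
    labels = np.where(state_a, "A", "B")
    X = signs + (jitter * rng.standard_normal((n, d)) if jitter > 0 else 0.0)
    X = _standardize_columns(X)
    ds = ExpressionDataset(
        matrix=X,
        gene_names=[f"g{j}" for j in range(d)],
        cell_ids=[f"cell{i}" for i in range(n)],
        labels=labels,
        stage="normalized_standard",
    )
    truth = GroundTruth(informative_genes=(0, 1, 2),
                        generative_params={"jitter": jitter, "n": n, "d": d},
                        seed=seed)
    return ds, truth


def _simplex_means(C: int, n_informative: int, separation: float,
                   rng: np.random.Generator) -> np.ndarray:
    """C class-mean vectors in R^n_informative, pairwise distance = separation."""
    # regular simplex in C-1 dimensions: vertices of identity minus centroid
    eye = np.eye(C)
    centered = eye - eye.mean(axis=0)
    dist = np.linalg.norm(centered[0] - centered[1])
    simplex = centered * (separation / dist)  # (C, C) but rank C-1
    # random orthonormal embedding into gene space
    if n_informative < C:
        raise ValueError("need n_informative >= C to embed the simplex")
    raw = rng.standard_normal((n_informative, C))
    q, _ = np.linalg.qr(raw)
    return simplex @ q[:, :C].T  # (C, n_informative)


def gaussian_clusters(n: int = 1000, d: int = 300, C: int = 5,
                      n_informative: int = 20, separation: float = 2.0,
                      seed: int = 0) -> tuple[ExpressionDataset, GroundTruth]:
    """Balanced Gaussian classes with signal confined to known genes.

    The C class means, restricted to the informative coordinates, form a
    regular simplex with pairwise distance ``separation`` in within-class
    standard-deviation units (a random rotation spreads the signal across
    the informative genes).  Non-informative genes are standard normal
    noise.  Within-class noise has unit standard deviation and columns are
    mean-centered, so ``separation`` is exactly the pairwise class-mean
    distance in noise units; columns carrying signal retain the extra
    between-class variance.
    """
    if n_informative > d:
        raise ValueError("n_informative must not exceed d")
    if C < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(seed)
    base, extra = divmod(n, C)
    counts = [base + (1 if c < extra else 0) for c in range(C)]
    labels = np.concatenate([np.full(cnt, c) for c, cnt in enumerate(counts)])
    perm = rng.permutation(n)
    labels = labels[perm]
    means = _simplex_means(C, n_informative, separation, rng)
    X = rng.standard_normal((n, d))
    X[:, :n_informative] += means[labels]
    X = X - X.mean(axis=0)
    ds = ExpressionDataset(
        matrix=X,
        gene_names=[f"g{j}" for j in range(d)],
        cell_ids=[f"cell{i}" for i in range(n)],
        labels=np.array([f"type{c}" for c in labels]),
        stage="normalized_standard",
    )
    truth = GroundTruth(informative_genes=tuple(range(n_informative)),
                        generative_params={"C": C, "separation": separation,
                                           "n": n, "d": d},
                        seed=seed)
    return ds, truth


def count_matrix(n: int, presence_profile: np.ndarray, labels: np.ndarray,
                 seed: int = 0, rate: float = 2.0) -> ExpressionDataset:
    """Integer counts with controlled per-cell-type presence fractions.

    ``presence_profile`` is (n_types, d): entry (t, j) is the probability a
    cell of type t expresses gene j at all.  Expressed entries get a
    Poisson(rate) + 1 count, so "present" (count > 0) matches the Bernoulli
    draw exactly and realized presence concentrates on the profile.
    """
    presence_profile = np.asarray(presence_profile, dtype=float)
    labels = np.asarray(labels)
    if labels.shape != (n,):
        raise ValueError("labels must have length n")
    if ((presence_profile < 0) | (presence_profile > 1)).any():
        raise ValueError("presence fractions must lie in [0, 1]")
    types = np.unique(labels)
    if len(types) != presence_profile.shape[0]:
        raise ValueError("one profile row per cell type required")
    d = presence_profile.shape[1]
    rng = np.random.default_rng(seed)
    type_index = {t: i for i, t in enumerate(types)}
    rows = np.array([type_index[t] for t in labels])
    expressed = rng.random((n, d)) < presence_profile[rows]
    counts = np.where(expressed, rng.poisson(rate, size=(n, d)) + 1, 0)
    return ExpressionDataset(
        matrix=counts.astype(float),
        gene_names=[f"g{j}" for j in range(d)],
        cell_ids=[f"cell{i}" for i in range(n)],
        labels=labels,
        stage="raw",
    )
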