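"""Expression-data containers, readers/writers, filtering and normalization.

The central object is :class:`ExpressionDataset`, an n_cells x d_genes dense
matrix with gene names, cell identifiers and optional categorical labels.
Preprocessing follows the pipeline used for marker selection on annotated
scRNA-seq data: presence-based gene filtering computed per cell type, either
per-gene standardization after per-cell count scaling and a log2(1+x)
transform ("standard") or a whole-matrix standardization after log2(1+x)
alone ("generative"), and seeded random train/validation/test splits.

"Presence" of a gene in a cell means a strictly positive raw count.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "SplitAssignment",
    "ValidationError",
    "load_expression",
    "save_expression",
    "filter_genes",
    "coarse_filter",
    "normalize",
    "split_dataset",
    "write_markers",
    "read_markers",
]

STAGES = ("raw", "normalized_standard", "normalized_generative")


class ValidationError(ValueError):
    """Raised when data violate a documented contract."""


def _check_unique(names, what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for n in names:
        seen[n] = seen.get(n, 0) + 1
    dups = sorted(n for n, c in seen.items() if c > 1)
    if dups:
        raise ValidationError(f"duplicated {what}: {', '.join(map(str, dups))}")


@dataclasses.dataclass
class ExpressionDataset:
    """A cells x genes expression matrix with names and optional labels.

    Parameters
    ----------
    matrix
        Dense ``(n_cells, d_genes)`` float array.
    gene_names, cell_ids
        Unique identifiers matching the matrix dimensions.
    labels
        Optional length-``n_cells`` categorical vector (cell types).
    stage
        One of ``raw``, ``normalized_standard``, ``normalized_generative``.
    """

    matrix: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    labels: np.ndarray | None = None
    stage: str = "raw"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValidationError("matrix must be 2-dimensional (cells x genes)")
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n, d = self.matrix.shape
        if len(self.gene_names) != d:
            raise ValidationError(f"{len(self.gene_names)} gene names for {d} columns")
        if len(self.cell_ids) != n:
            raise ValidationError(f"{len(self.cell_ids)} cell ids for {n} rows")
        _check_unique(self.gene_names, "gene names")
        _check_unique(self.cell_ids, "cell ids")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValidationError("labels length must equal number of cells")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> np.ndarray:
        if self.labels is None:
            raise ValidationError("dataset has no labels")
        return np.unique(self.labels)

    def validate_stage(self) -> None:
        """Check the numeric invariant attached to the current stage."""
        X = self.matrix
        if self.stage == "raw":
            if (X < 0).any():
                raise ValidationError("raw data must be non-negative")
        elif self.stage == "normalized_standard":
            sd = X.std(axis=0)
            nonconst = sd > 1e-8
            if np.abs(X.mean(axis=0)).max() > 1e-6:
                raise ValidationError("per-gene means are not 0")
            if nonconst.any() and np.abs(X.var(axis=0)[nonconst] - 1).max() > 1e-4:
                raise ValidationError("per-gene variances are not 1")
        elif self.stage == "normalized_generative":
            if abs(X.mean()) > 1e-6 or abs(X.var() - 1) > 1e-4:
                raise ValidationError("global mean/variance are not 0/1")

    def subset_cells(self, idx) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return ExpressionDataset(
            matrix=self.matrix[idx],
            gene_names=list(self.gene_names),
            cell_ids=[self.cell_ids[i] for i in idx],
            labels=None if self.labels is None else self.labels[idx],
            stage=self.stage,
        )

    def subset_genes(self, idx) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return ExpressionDataset(
            matrix=self.matrix[:, idx],
            gene_names=[self.gene_names[i] for i in idx],
            cell_ids=list(self.cell_ids),
            labels=self.labels,
            stage=self.stage,
        )

    def drop_labels(self) -> "ExpressionDataset":
        return dataclasses.replace(self, labels=None)


@dataclasses.dataclass(frozen=True)
class SplitAssignment:
    """Disjoint train/validation/test cell indices for one seed."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    fractions: tuple[float, float, float]
    seed: int

    def __post_init__(self):
        n = len(self.train_idx) + len(self.val_idx) + len(self.test_idx)
        union = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        if len(np.unique(union)) != n or union.min() != 0 or union.max() != n - 1:
            raise ValidationError("splits must partition {0..n-1}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_expression(path, format: str, label_field: str | None = None) -> ExpressionDataset:
    """Read an expression matrix into a raw-stage :class:`ExpressionDataset`.

    Parameters
    ----------
    path
        File (h5ad, csv) or directory (mtx triplet) to read.
    format
        ``"h5ad"``, ``"csv"`` or ``"mtx_triplet"``.  CSV files are cells x
        genes with a header of gene names and the cell id in the first
        column; MTX triplets are genes x cells on disk (with ``genes.tsv``
        and ``barcodes.tsv`` alongside) and are transposed on read.
    label_field
        Name of the obs column (h5ad) or CSV column holding cell labels.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    if format == "h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        X = adata.X
        if not isinstance(X, np.ndarray):
            X = np.asarray(X.todense())
        labels = None
        if label_field is not None:
            if label_field not in adata.obs.columns:
                raise ValidationError(f"label field {label_field!r} not in obs")
            labels = np.asarray(adata.obs[label_field].astype(str))
        stage = str(adata.uns.get("stage", "raw"))
        return ExpressionDataset(X, list(adata.var_names), list(adata.obs_names),
                                 labels=labels, stage=stage)
    if format == "csv":
        # pandas silently mangles duplicate column names; check the raw header
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(",")[1:]
        _check_unique(header, "gene names")
        df = pd.read_csv(path, index_col=0)
        labels = None
        if label_field is not None:
            if label_field not in df.columns:
                raise ValidationError(f"label column {label_field!r} not in CSV")
            labels = df[label_field].astype(str).to_numpy()
            df = df.drop(columns=[label_field])
        return ExpressionDataset(df.to_numpy(dtype=np.float64), list(df.columns),
                                 [str(i) for i in df.index], labels=labels)
    if format == "mtx_triplet":
        from scipy.io import mmread

        folder = path if path.is_dir() else path.parent
        mtx = folder / "matrix.mtx"
        if not mtx.exists():
            mtx = path
        X = np.asarray(mmread(mtx).todense(), dtype=np.float64).T  # genes x cells on disk
        genes = pd.read_csv(folder / "genes.tsv", sep="\t", header=None)[0].tolist()
        cells = pd.read_csv(folder / "barcodes.tsv", sep="\t", header=None)[0].tolist()
        return ExpressionDataset(X, genes, cells)
    raise ValidationError(f"unknown format {format!r}")


def save_expression(ds: ExpressionDataset, path, format: str = "csv",
                    label_field: str = "label") -> None:
    """Write a dataset back to disk (csv or h5ad); round-trips with the reader."""
    path = Path(path)
    if format == "csv":
        df = pd.DataFrame(ds.matrix, index=ds.cell_ids, columns=ds.gene_names)
        if ds.labels is not None:
            df[label_field] = ds.labels
        df.to_csv(path)
    elif format == "h5ad":
        import anndata

        adata = anndata.AnnData(X=ds.matrix.copy())
        adata.obs_names = ds.cell_ids
        adata.var_names = ds.gene_names
        if ds.labels is not None:
            adata.obs[label_field] = pd.Categorical([str(y) for y in ds.labels])
        adata.uns["stage"] = ds.stage
        adata.write_h5ad(path)
    else:
        raise ValidationError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _presence_by_type(ds: ExpressionDataset) -> np.ndarray:
    """(n_types, d) fraction of cells of each type with a positive count."""
    classes = ds.classes
    out = np.empty((len(classes), ds.n_genes))
    for i, c in enumerate(classes):
        sub = ds.matrix[ds.labels == c]
        out[i] = (sub > 0).mean(axis=0)
    return out


def filter_genes(ds: ExpressionDataset, min_presence: float = 0.30,
                 max_presence: float = 0.75, type_fraction: float = 0.50,
                 exclusion_list: set[str] | None = None) -> ExpressionDataset:
    """Presence-based gene filtering computed per cell type.

    A gene is kept iff it is not excluded by name, it is present (count > 0)
    in at least ``min_presence`` of the cells of at least one cell type, and
    it is present in more than ``max_presence`` of the cells in fewer than
    ``type_fraction`` of the cell types.  Near-ubiquitous genes are dropped
    because they carry little cell-type information; near-absent genes
    because they carry mostly noise.
    """
    if ds.stage != "raw":
        raise ValidationError("filter_genes operates on raw counts")
    if ds.labels is None:
        raise ValidationError(
            "filter_genes needs cell-type labels; supply labels or skip this filter")
    exclusion_list = exclusion_list or set()
    presence = _presence_by_type(ds)
    not_excluded = np.array([g not in exclusion_list for g in ds.gene_names])
    detectable = (presence >= min_presence).any(axis=0)
    frac_types_high = (presence > max_presence).mean(axis=0)
    keep = not_excluded & detectable & (frac_types_high < type_fraction)
    if not keep.any():
        raise ValidationError("all genes removed by filter_genes")
    return ds.subset_genes(np.flatnonzero(keep))


def coarse_filter(ds: ExpressionDataset, min_presence: float = 0.0005,
                  presence_or: float = 0.03,
                  mean_when_present: float = 1.12) -> ExpressionDataset:
    """Optional coarse pre-filter for very large sparse datasets.

    Keeps genes present in at least ``min_presence`` of all cells and, in
    addition, either present in ``presence_or`` of cells or with mean
    expression above ``mean_when_present`` in the cells where they appear.
    Off by default in every pipeline; label-free.
    """
    if ds.stage != "raw":
        raise ValidationError("coarse_filter operates on raw counts")
    pos = ds.matrix > 0
    presence = pos.mean(axis=0)
    with np.errstate(invalid="ignore"):
        mean_present = np.where(pos.any(axis=0),
                                ds.matrix.sum(axis=0) / np.maximum(pos.sum(axis=0), 1),
                                0.0)
    keep = (presence >= min_presence) & ((presence >= presence_or)
                                         | (mean_present > mean_when_present))
    if not keep.any():
        raise ValidationError("all genes removed by coarse_filter")
    return ds.subset_genes(np.flatnonzero(keep))


def normalize(ds: ExpressionDataset, mode: str = "standard",
              log_base: float = 2.0, target_total: float | None = None) -> ExpressionDataset:
    """Normalize raw counts for model input.

    ``standard``: scale each cell to a common total count (the median
    per-cell total unless ``target_total`` is given), apply ``log2(1+x)``,
    then center and scale every gene to mean 0 / variance 1 (constant genes
    are left at 0 after centering).  ``generative``: apply ``log2(1+x)``
    only, then center and scale the whole matrix globally — preserving
    between-gene variance differences for reconstruction evaluation.
    """
    if ds.stage != "raw":
        raise ValidationError("normalize expects a raw-stage dataset")
    X = ds.matrix
    if (X < 0).any():
        raise ValidationError("negative entries in raw data")
    if mode == "standard":
        totals = X.sum(axis=1)
        zero = np.flatnonzero(totals == 0)
        if zero.size:
            ids = ", ".join(ds.cell_ids[i] for i in zero[:10])
            raise ValidationError(f"cells with zero total count: {ids}")
        target = float(np.median(totals)) if target_total is None else float(target_total)
        X = X * (target / totals)[:, None]
        X = np.log1p(X) / np.log(log_base)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd_safe = np.where(sd > 1e-12, sd, 1.0)
        X = (X - mu) / sd_safe
        stage = "normalized_standard"
    elif mode == "generative":
        X = np.log1p(X) / np.log(log_base)
        X = (X - X.mean()) / X.std()
        stage = "normalized_generative"
    else:
        raise ValidationError(f"unknown normalization mode {mode!r}")
    return dataclasses.replace(ds, matrix=X, stage=stage)


def split_dataset(ds: ExpressionDataset | int,
                  fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
                  seed: int = 0) -> SplitAssignment:
    """Seeded uniform random train/validation/test split of cells.

    Sizes are the largest-remainder apportionment of ``n * fractions``, so
    each observed fraction is within 1/n of the request.
    """
    n = ds if isinstance(ds, int) else ds.n_cells
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValidationError("three positive fractions required")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError("fractions must sum to 1")
    raw = np.array([n * f for f in fractions])
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    if (counts == 0).any():
        raise ValidationError(f"n={n} too small for fractions {fractions}")
    perm = np.random.default_rng(seed).permutation(n)
    a, b = counts[0], counts[0] + counts[1]
    return SplitAssignment(train_idx=np.sort(perm[:a]), val_idx=np.sort(perm[a:b]),
                           test_idx=np.sort(perm[b:]), fractions=fractions, seed=seed)


# ---------------------------------------------------------------------------
# marker lists
# ---------------------------------------------------------------------------

def write_markers(markers, gene_names: list[str], path) -> None:
    """Write a marker set as a rank/gene_index/gene_name/score TSV."""
    d = len(gene_names)
    for idx in markers.indices:
        if not 0 <= idx < d:
            raise ValidationError(f"marker index {idx} out of range for d={d}")
    df = pd.DataFrame({
        "rank": np.arange(1, len(markers.indices) + 1),
        "gene_index": list(markers.indices),
        "gene_name": [gene_names[i] for i in markers.indices],
        "score": list(markers.scores),
    })
    df.to_csv(path, sep="\t", index=False)


def read_markers(path):
    """Read a marker TSV back into a :class:`~markersel.selector.MarkerSet`."""
    from .selector import MarkerSet

    df = pd.read_csv(path, sep="\t")
    indices = df["gene_index"].astype(int).tolist()
    scores = df["score"].astype(float).tolist()
    return MarkerSet(indices=indices, scores=scores, budget=len(indices))
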