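"""Evaluation harness: classification metrics, reconstruction metrics,
label-noise robustness protocols and reference baselines.

Classification quality of a marker panel is measured by restricting train
and test data to the panel, fitting a standard downstream classifier
(1-nearest-neighbor or a 100-tree random forest) and summarizing the test
confusion matrix.  Per-class misclassification is the precision complement
M_c = 1 - TP_c / (TP_c + FP_c); F1 is reported both macro-averaged and
support-weighted.  Reconstruction quality compares per-gene variance
structure (Jaccard overlap of top-variance gene sets, Spearman correlation
of variance ranks) and per-cell l2/l1 distances.

Any callable ``method(dataset, k, seed) -> MarkerSet`` can enter the
harness, so external selection methods plug in without being bundled.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier

from .data_io import ExpressionDataset, split_dataset
from .selector import MarkerSet

__all__ = [
    "ConfusionMatrix",
    "ClassificationReport",
    "ReconstructionReport",
    "confusion",
    "misclassification",
    "f1_report",
    "evaluate_markers",
    "jaccard_top_variance",
    "spearman_variance",
    "mean_l2",
    "mean_l1",
    "reconstruction_report",
    "corrupt_labels",
    "noise_robustness",
    "random_marker_baseline",
    "local_logit_baseline",
    "markersel_method",
    "random_method",
]


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    """Counts[i, j] = cells of true class i predicted as class j."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_names),
                            columns=list(self.class_names))


@dataclasses.dataclass(frozen=True)
class ClassificationReport:
    confusion: ConfusionMatrix
    misclassification: np.ndarray       # per-class M_c (precision complement)
    average_misclassification: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_f1: float
    weighted_f1: float
    accuracy: float

    @property
    def error_rate(self) -> float:
        """Plain 1 - accuracy, reported alongside the precision-complement average."""
        return 1.0 - self.accuracy

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.confusion.class_names),
            "misclassification": self.misclassification.tolist(),
            "average_misclassification": self.average_misclassification,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "accuracy": self.accuracy,
            "error_rate": self.error_rate,
        }


@dataclasses.dataclass(frozen=True)
class ReconstructionReport:
    jaccard: float
    spearman: float
    mean_l2: float
    mean_l1: float
    per_label: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {"jaccard": self.jaccard, "spearman": self.spearman,
               "mean_l2": self.mean_l2, "mean_l1": self.mean_l1}
        if self.per_label is not None:
            out["per_label"] = json.loads(self.per_label.to_json(orient="index"))
        return out


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------

def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must have equal length")
    classes = np.unique(true_labels)
    unseen = set(np.unique(predicted_labels)) - set(classes)
    if unseen:
        raise ValueError(f"predicted labels not in the true alphabet: {sorted(unseen)}")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_names=tuple(str(c) for c in classes))


def misclassification(cm: ConfusionMatrix) -> tuple[np.ndarray, float]:
    """Per-class precision complement M_c and its unweighted average.

    A class that is never predicted (TP + FP = 0) gets M_c = 1 with a
    warning, keeping the average defined.
    """
    counts = cm.counts
    predicted = counts.sum(axis=0)
    tp = np.diag(counts)
    m = np.ones(len(predicted))
    never = predicted == 0
    if never.any():
        names = [cm.class_names[i] for i in np.flatnonzero(never)]
        warnings.warn(f"classes never predicted, M_c set to 1: {names}")
    nz = ~never
    m[nz] = 1.0 - tp[nz] / predicted[nz]
    return m, float(m.mean())


def f1_report(cm: ConfusionMatrix) -> tuple[np.ndarray, float, float]:
    """Per-class F1 plus macro (unweighted) and support-weighted averages."""
    counts = cm.counts
    tp = np.diag(counts).astype(float)
    predicted = counts.sum(axis=0)
    support = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted > 0, tp / predicted, 0.0)
        recall = np.where(support > 0, tp / support, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    macro = float(f1.mean())
    weighted = float((f1 * support).sum() / support.sum())
    return f1, macro, weighted


def _classifier(name: str, seed: int, n_neighbors: int = 1):
    if name == "nearest_neighbor":
        return KNeighborsClassifier(n_neighbors=n_neighbors)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def evaluate_markers(train: ExpressionDataset, test: ExpressionDataset,
                     markers: MarkerSet, classifier: str = "nearest_neighbor",
                     seed: int = 0, n_neighbors: int = 1) -> ClassificationReport:
    """Fit a downstream classifier on the marker columns; report on test."""
    if not markers.indices:
        raise ValueError("empty marker set")
    if train.labels is None or test.labels is None:
        raise ValueError("both splits need labels")
    cols = np.asarray(markers.indices)
    clf = _classifier(classifier, seed, n_neighbors)
    clf.fit(train.matrix[:, cols], np.asarray(train.labels, dtype=str))
    pred = clf.predict(test.matrix[:, cols])
    cm = confusion(np.asarray(test.labels, dtype=str), pred)
    m, m_avg = misclassification(cm)
    f1, macro, weighted = f1_report(cm)
    counts = cm.counts
    tp = np.diag(counts).astype(float)
    predicted = counts.sum(axis=0)
    support = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted > 0, tp / predicted, 0.0)
        recall = np.where(support > 0, tp / support, 0.0)
    return ClassificationReport(
        confusion=cm, misclassification=m, average_misclassification=m_avg,
        precision=precision, recall=recall, f1=f1, macro_f1=macro,
        weighted_f1=weighted, accuracy=float(tp.sum() / counts.sum()))


# ---------------------------------------------------------------------------
# reconstruction metrics
# ---------------------------------------------------------------------------

def _top_variance_set(X: np.ndarray, top_frac: float) -> set[int]:
    variances = X.var(axis=0)
    ranks = rankdata(-variances, method="average")  # 1 = largest variance
    cutoff = int(np.floor(X.shape[1] * top_frac))
    return set(np.flatnonzero(ranks <= cutoff))


def jaccard_top_variance(X: np.ndarray, X_hat: np.ndarray,
                         top_frac: float = 0.20) -> float:
    """Jaccard overlap of the top-variance gene sets of X and X_hat."""
    X, X_hat = np.asarray(X), np.asarray(X_hat)
    if X.shape != X_hat.shape:
        raise ValueError("matrices must share a shape")
    if X.shape[1] < 5:
        raise ValueError("need at least 5 genes")
    if X.var(axis=0).max() == 0 and X_hat.var(axis=0).max() == 0:
        raise ValueError("all genes have zero variance")
    a = _top_variance_set(X, top_frac)
    b = _top_variance_set(X_hat, top_frac)
    return len(a & b) / len(a | b)


def spearman_variance(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Spearman correlation of per-gene variance ranks (average ranks on ties)."""
    X, X_hat = np.asarray(X), np.asarray(X_hat)
    if X.shape != X_hat.shape:
        raise ValueError("matrices must share a shape")
    if X.shape[1] < 3:
        raise ValueError("need at least 3 genes")
    va, vb = X.var(axis=0), X_hat.var(axis=0)
    if np.unique(va).size == 1 or np.unique(vb).size == 1:
        raise ValueError("constant variance vector: correlation undefined")
    rho, _ = spearmanr(va, vb)
    return float(rho)


def mean_l2(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Average over cells of the euclidean distance between profiles."""
    diff = np.asarray(X) - np.asarray(X_hat)
    return float(np.linalg.norm(diff, axis=1).mean())


def mean_l1(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Average over cells of the l1 distance between profiles."""
    diff = np.asarray(X) - np.asarray(X_hat)
    return float(np.abs(diff).sum(axis=1).mean())


def reconstruction_report(X: np.ndarray, X_hat: np.ndarray,
                          labels: np.ndarray | None = None,
                          top_frac: float = 0.20) -> ReconstructionReport:
    """All four reconstruction metrics, optionally broken down by label."""
    per_label = None
    if labels is not None:
        rows = {}
        for c in np.unique(labels):
            mask = labels == c
            rows[str(c)] = {
                "jaccard": jaccard_top_variance(X[mask], X_hat[mask], top_frac),
                "spearman": spearman_variance(X[mask], X_hat[mask]),
                "mean_l2": mean_l2(X[mask], X_hat[mask]),
                "mean_l1": mean_l1(X[mask], X_hat[mask]),
            }
        rows["All"] = {
            "jaccard": jaccard_top_variance(X, X_hat, top_frac),
            "spearman": spearman_variance(X, X_hat),
            "mean_l2": mean_l2(X, X_hat),
            "mean_l1": mean_l1(X, X_hat),
        }
        per_label = pd.DataFrame(rows).T
    return ReconstructionReport(
        jaccard=jaccard_top_variance(X, X_hat, top_frac),
        spearman=spearman_variance(X, X_hat),
        mean_l2=mean_l2(X, X_hat), mean_l1=mean_l1(X, X_hat),
        per_label=per_label)


# ---------------------------------------------------------------------------
# label-noise protocols
# ---------------------------------------------------------------------------

def corrupt_labels(y: np.ndarray, fraction: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Resample the labels of a uniformly chosen fraction of cells.

    Replacement labels are drawn uniformly over all observed labels, so a
    corrupted cell keeps its original label with probability 1/C; the
    expected fraction of labels actually changed is fraction * (1 - 1/C).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    y = np.asarray(y)
    out = y.copy()
    n = y.size
    n_corrupt = int(np.floor(fraction * n))
    if n_corrupt == 0:
        return out
    targets = rng.choice(n, size=n_corrupt, replace=False)
    classes = np.unique(y)
    out[targets] = rng.choice(classes, size=n_corrupt, replace=True)
    return out


def noise_robustness(ds: ExpressionDataset, method, fractions, k: int = 50,
                     protocol: str = "noisy_both",
                     classifier: str = "nearest_neighbor",
                     seeds=(0, 1, 2)) -> pd.DataFrame:
    """Test accuracy of a selection method under training-label corruption.

    ``noisy_both``: markers are selected and the downstream classifier is
    fitted on corrupted labels; accuracy is measured on clean test labels.
    ``noisy_selection_only``: only the selection step sees corrupted
    labels; the classifier trains on clean labels restricted to the
    selected markers.  Returns one row per fraction with the mean and
    standard deviation of accuracy across seeds.
    """
    if protocol not in ("noisy_both", "noisy_selection_only"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if ds.labels is None:
        raise ValueError("noise protocols need labeled data")
    records = []
    for fraction in fractions:
        accs = []
        for seed in seeds:
            rng = np.random.default_rng(np.random.SeedSequence((seed, 977, int(fraction * 1000))))
            split = split_dataset(ds, (0.70, 0.10, 0.20), seed=seed)
            fit_idx = np.concatenate([split.train_idx, split.val_idx])
            train_clean = ds.subset_cells(fit_idx)
            test = ds.subset_cells(split.test_idx)
            noisy = dataclasses.replace(
                train_clean, labels=corrupt_labels(train_clean.labels, fraction, rng))
            markers = method(noisy, k, seed)
            clf_train = noisy if protocol == "noisy_both" else train_clean
            report = evaluate_markers(clf_train, test, markers,
                                      classifier=classifier, seed=seed)
            accs.append(report.accuracy)
        records.append({"fraction": float(fraction),
                        "mean_accuracy": float(np.mean(accs)),
                        "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                        "n_seeds": len(accs)})
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# baselines and method adapters
# ---------------------------------------------------------------------------

def random_marker_baseline(d: int, k: int, seed: int) -> MarkerSet:
    """k genes sampled uniformly without replacement; equal scores."""
    if k > d:
        raise ValueError(f"k={k} exceeds d={d}")
    rng = np.random.default_rng(seed)
    indices = rng.choice(d, size=k, replace=False)
    return MarkerSet(indices=[int(i) for i in indices],
                     scores=[1.0 / d] * k, budget=k)


def local_logit_baseline(ds: ExpressionDataset, k: int, config=None) -> MarkerSet:
    """Ablation: free logit parameters updated only by gradient (no batch
    aggregation through the logit network and no moving average), with the
    same sampler, architecture, loss and extraction rule.  Isolates the
    effect of the EMA aggregation mechanism."""
    import dataclasses as _dc

    from .training import TrainingConfig, select

    if config is None:
        config = TrainingConfig()
    config = _dc.replace(config, logit_mode="free")
    return select(ds, k, config=config)


def markersel_method(mode: str, config=None):
    """Adapter: a ``(dataset, k, seed) -> MarkerSet`` callable for the harness."""
    import dataclasses as _dc

    from .training import TrainingConfig, select

    base = config if config is not None else TrainingConfig(mode=mode)

    def _run(ds: ExpressionDataset, k: int, seed: int) -> MarkerSet:
        cfg = _dc.replace(base, mode=mode, seed=seed)
        return select(ds, k, config=cfg)
    return _run


def random_method(ds: ExpressionDataset, k: int, seed: int) -> MarkerSet:
    return random_marker_baseline(ds.n_genes, k, seed)
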