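"""Soft-margin kernel SVM training, grid search, CV and baseline models.

Training minimizes the usual soft-margin objective (1/2 ||w||^2 + C sum xi)
under the selected kernel; for the RBF kernel K(x, y) = exp(-gamma ||x-y||^2).
Scores in [0, 1] come from Platt-style sigmoid calibration of the decision
values; a row is classified positive iff its score is strictly greater
than 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from scipy import sparse
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .dataset import FoldSplit, VectorizedDataset, kfold_split
from .metrics import MetricsReport, compute_metrics, confusion

__all__ = [
    "KernelConfig",
    "TrainedModel",
    "GridSearchResult",
    "PROFILES",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "train",
    "fit_svm",
    "grid_search",
    "cross_validate",
    "train_baseline",
    "save_model",
    "load_model",
]

KERNELS = ("rbf", "linear", "polynomial", "sigmoid")
_SKLEARN_KERNEL = {"rbf": "rbf", "linear": "linear", "polynomial": "poly", "sigmoid": "sigmoid"}

#: default grids bracketing all published optima for this method family
DEFAULT_C_GRID = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)
DEFAULT_GAMMA_GRID = (0.005, 0.01, 0.05, 0.055, 0.1, 0.5)


@dataclass(frozen=True)
class KernelConfig:
    """Kernel kind plus hyperparameters; coef0 defaults to 0.0, degree to 3."""

    kind: str = "rbf"
    C: float = 1.0
    gamma: float = 0.05
    degree: int = 3
    coef0: float = 0.0

    def __post_init__(self):
        if self.kind not in KERNELS:
            raise ValueError(f"unknown kernel {self.kind!r}; expected one of {KERNELS}")
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.kind != "linear" and self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")


#: published per-organism optima, retrievable by profile name
PROFILES: dict[str, KernelConfig] = {
    "bmori": KernelConfig(kind="rbf", C=8.0, gamma=0.05),
    "human": KernelConfig(kind="rbf", C=36.0, gamma=0.01),
    "crustacea": KernelConfig(kind="rbf", C=8.0, gamma=0.055),
}


@dataclass
class TrainedModel:
    """Fitted SVM with calibration, bound to a feature-space fingerprint."""

    config: KernelConfig
    pair_dim: int
    space_fingerprint: str
    estimator: SVC

    def predict_scores(self, rows) -> np.ndarray:
        """Calibrated probability of the positive class, one per row."""
        rows = _as_matrix(rows)
        if rows.shape[1] != self.pair_dim:
            raise ValueError(
                f"row width {rows.shape[1]} does not match model pair_dim {self.pair_dim}"
            )
        proba = self.estimator.predict_proba(rows)
        pos_col = int(np.flatnonzero(self.estimator.classes_ == 1)[0])
        return proba[:, pos_col]

    def predict_labels(self, rows) -> np.ndarray:
        """1 iff score strictly greater than 0.5 (a score of exactly 0.5 is negative)."""
        return (self.predict_scores(rows) > 0.5).astype(np.int8)


@dataclass
class GridSearchResult:
    cells: list[tuple[float, float, float]]  # (C, gamma, mean CV accuracy)
    best: tuple[float, float]
    kernel: str

    def best_config(self, degree: int = 3, coef0: float = 0.0) -> KernelConfig:
        C, gamma = self.best
        return KernelConfig(
            kind=self.kernel,
            C=C,
            gamma=gamma if self.kernel != "linear" else 1.0,
            degree=degree,
            coef0=coef0,
        )


def _as_matrix(rows):
    if sparse.issparse(rows):
        return rows.tocsr()
    arr = np.asarray(rows)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    return arr


def _fit_quietly(estimator, X, y):
    # sklearn >= 1.9 deprecation chatter for SVC(probability=True); the
    # calibrated-probability contract here is deliberate
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning)
        estimator.fit(X, y)
    return estimator


def _make_svc(cfg: KernelConfig, probability: bool, seed: int) -> SVC:
    return SVC(
        kernel=_SKLEARN_KERNEL[cfg.kind],
        C=cfg.C,
        gamma=cfg.gamma if cfg.kind != "linear" else "scale",
        degree=cfg.degree,
        coef0=cfg.coef0,
        probability=probability,
        random_state=seed,
        cache_size=256,
    )


def fit_svm(X, y, cfg: KernelConfig, seed: int = 0, probability: bool = True,
            fingerprint: str = "", ) -> TrainedModel:
    """Fit an SVM on a raw matrix; the dataset-level entry point is :func:`train`."""
    X = _as_matrix(X)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    svc = _make_svc(cfg, probability, seed)
    _fit_quietly(svc, X, y)
    return TrainedModel(
        config=cfg,
        pair_dim=X.shape[1],
        space_fingerprint=fingerprint,
        estimator=svc,
    )


def train(ds: VectorizedDataset, cfg: KernelConfig, seed: int = 0) -> TrainedModel:
    """Fit the soft-margin kernel SVM with Platt calibration on a dataset."""
    return fit_svm(
        ds.rows, ds.labels, cfg, seed=seed, probability=True,
        fingerprint=ds.space.fingerprint(),
    )


def _fold_accuracy(X, y, cfg: KernelConfig, split: FoldSplit, seed: int) -> float:
    """Mean held-out accuracy over folds using raw decision values (no calibration)."""
    accs = []
    for fold in range(split.k):
        tr, te = split.train_rows(fold), split.test_rows(fold)
        svc = _make_svc(cfg, probability=False, seed=seed)
        _fit_quietly(svc, X[tr], y[tr])
        pred = svc.predict(X[te])
        accs.append(float(np.mean(pred == y[te])))
    return float(np.mean(accs))


def grid_search(
    ds: VectorizedDataset,
    kernel_kind: str = "rbf",
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    k: int = 5,
    seed: int = 0,
    degree: int = 3,
    coef0: float = 0.0,
    split_mode: str = "row_level",
) -> GridSearchResult:
    """Exhaustive (C, gamma) search by mean k-fold CV accuracy.

    Ties break toward smaller C, then smaller gamma.  The fold split is
    fixed once per search so all cells see identical partitions.
    """
    if not C_grid or not gamma_grid:
        raise ValueError("grids must be non-empty")
    if kernel_kind == "linear":
        gamma_grid = (1.0,)  # gamma unused
    split = kfold_split(ds, k=k, seed=seed, mode=split_mode)
    X, y = ds.rows, ds.labels
    cells: list[tuple[float, float, float]] = []
    for C in C_grid:
        for gamma in gamma_grid:
            cfg = KernelConfig(kind=kernel_kind, C=C, gamma=gamma, degree=degree, coef0=coef0)
            acc = _fold_accuracy(X, y, cfg, split, seed)
            cells.append((C, gamma, acc))
    best = min(cells, key=lambda c: (-c[2], c[0], c[1]))
    return GridSearchResult(cells=cells, best=(best[0], best[1]), kernel=kernel_kind)


def cross_validate(
    ds: VectorizedDataset,
    cfg: KernelConfig,
    split: FoldSplit,
    seed: int = 0,
    train_on_single_fold: bool = False,
) -> list[MetricsReport]:
    """Per-fold seven-metric reports; rows tested are never seen in training.

    By default each fold is held out for testing and the remaining k-1 folds
    train the model; ``train_on_single_fold=True`` inverts this (train on one
    fold, test on the rest).
    """
    if split.assignment.shape[0] != ds.n_rows:
        raise ValueError("fold split does not cover the dataset")
    reports: list[MetricsReport] = []
    for fold in range(split.k):
        if train_on_single_fold:
            tr, te = split.test_rows(fold), split.train_rows(fold)
        else:
            tr, te = split.train_rows(fold), split.test_rows(fold)
        if len(tr) == 0 or len(te) == 0:
            raise ValueError(f"fold {fold} is empty")
        model = fit_svm(ds.rows[tr], ds.labels[tr], cfg, seed=seed)
        scores = model.predict_scores(ds.rows[te])
        preds = (scores > 0.5).astype(np.int8)
        counts = confusion(ds.labels[te], preds)
        reports.append(compute_metrics(counts, scores=scores, labels=ds.labels[te]))
    return reports


def train_baseline(
    ds: VectorizedDataset,
    method: str,
    split: FoldSplit,
    seed: int = 0,
) -> list[MetricsReport]:
    """Cross-validate a baseline: L2 logistic regression or 200-tree forest.

    LR uses penalty='l2', C=1.0, liblinear solver; RF uses n_estimators=200
    with sklearn defaults otherwise.  Same CV harness as the SVM.
    """
    if method == "logistic_regression":
        def make():
            return LogisticRegression(penalty="l2", C=1.0, solver="liblinear")
    elif method == "random_forest":
        def make():
            return RandomForestClassifier(n_estimators=200, random_state=seed)
    else:
        raise ValueError(
            f"unknown baseline {method!r}; expected 'logistic_regression' or 'random_forest'"
        )
    reports: list[MetricsReport] = []
    for fold in range(split.k):
        tr, te = split.train_rows(fold), split.test_rows(fold)
        est = make()
        _fit_quietly(est, ds.rows[tr], ds.labels[tr])
        proba = est.predict_proba(ds.rows[te])
        pos_col = int(np.flatnonzero(est.classes_ == 1)[0])
        scores = proba[:, pos_col]
        preds = (scores > 0.5).astype(np.int8)
        counts = confusion(ds.labels[te], preds)
        reports.append(compute_metrics(counts, scores=scores, labels=ds.labels[te]))
    return reports


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, path: str | Path, space=None) -> None:
    """Persist config, fitted machinery, fingerprint and (optionally) the space."""
    payload = {
        "config": asdict(model.config),
        "pair_dim": model.pair_dim,
        "space_fingerprint": model.space_fingerprint,
        "estimator": model.estimator,
    }
    if space is not None:
        payload["domain_features"] = list(space.domain_features)
        payload["go_features"] = list(space.go_features)
    joblib.dump(payload, path)


def load_model(path: str | Path, expected_fingerprint: str | None = None):
    """Load a model archive; refuses a fingerprint mismatch.

    Returns ``(model, space_or_None)``.
    """
    from .dataset import FeatureSpace

    payload = joblib.load(path)
    model = TrainedModel(
        config=KernelConfig(**payload["config"]),
        pair_dim=payload["pair_dim"],
        space_fingerprint=payload["space_fingerprint"],
        estimator=payload["estimator"],
    )
    if expected_fingerprint is not None and expected_fingerprint != model.space_fingerprint:
        raise ValueError("feature-space fingerprint mismatch between model and data")
    space = None
    if "domain_features" in payload:
        space = FeatureSpace(
            tuple(payload["domain_features"]), tuple(payload["go_features"])
        )
    return model, space
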