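"""Class-weighted classification of breathing / hold / swallow windows.

The dataset is heavily imbalanced (quiet breathing dominates), so training
uses balanced class weights (w_c = N / (k * n_c)) and evaluation uses the
macro-averaged F1 score, which weighs every class equally.  Cross-validation
is grouped by subject (leave-one-subject-out by default) so that windows
from one person never appear on both sides of a split.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import (
    GridSearchCV,
    GroupKFold,
    LeaveOneGroupOut,
    StratifiedKFold,
)
from sklearn.svm import SVC

from .features import feature_matrix
from .segmentation import WindowDataset, build_dataset

__all__ = [
    "ClassReport",
    "TrainConfig",
    "TrainResult",
    "make_class_weights",
    "per_class_metrics",
    "macro_f1",
    "evaluate",
    "tune_and_train",
    "cross_validated_report",
    "window_size_sweep",
]

MODEL_KINDS = ("margin-linear", "margin-rbf", "tree-ensemble")

#: Hyperparameter grids; the classifiers' usual knobs (SVM cost/width, forest
#: size/depth/features-per-split) with modest spans.
DEFAULT_GRIDS: dict[str, dict] = {
    "margin-linear": {"C": [0.1, 1.0, 10.0, 100.0]},
    "margin-rbf": {"C": [0.1, 1.0, 10.0, 100.0], "gamma_factor": [0.1, 1.0, 10.0]},
    "tree-ensemble": {
        "n_estimators": [100, 300],
        "max_depth": [None, 5, 10],
        "max_features": ["sqrt", "log2"],
    },
}


@dataclass
class ClassReport:
    """Confusion matrix (rows = truth, columns = prediction) plus metrics."""

    classes: tuple[str, ...]
    confusion: np.ndarray
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_f1: float

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "macro_f1": self.macro_f1,
        }

    def __str__(self) -> str:
        width = max(6, *(len(c) for c in self.classes))
        head = " " * (width + 6) + "Pred.\n"
        head += " " * (width + 6) + "  ".join(f"{c:>{width}}" for c in self.classes)
        rows = []
        for i, c in enumerate(self.classes):
            tag = "Ans. " if i == len(self.classes) // 2 else "     "
            cells = "  ".join(f"{int(v):>{width}}" for v in self.confusion[i])
            rows.append(f"{tag}{c:>{width}} {cells}")
        metrics = "\n".join(
            f"{c}: precision={self.precision[c]:.3f} recall={self.recall[c]:.3f} "
            f"F1={self.f1[c]:.3f}" for c in self.classes
        )
        return (head + "\n" + "\n".join(rows) + "\n" + metrics
                + f"\nmacro-F1={self.macro_f1:.3f}")


@dataclass
class TrainConfig:
    """Model family, grid, weighting and cross-validation choices."""

    model_kind: str = "tree-ensemble"
    grid: dict | None = None
    class_weighting: bool = True
    cv: str = "loso"  # "loso", "group-kfold" or "stratified"
    n_splits: int = 5
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        if self.grid is not None and not self.grid:
            raise ValueError("hyperparameter grid must be nonempty")
        if self.cv not in ("loso", "group-kfold", "stratified"):
            raise ValueError("cv must be 'loso', 'group-kfold' or 'stratified'")


@dataclass
class TrainResult:
    model: object
    cv_macro_f1: float
    best_params: dict
    config: TrainConfig


def make_class_weights(labels: Sequence[str]) -> dict[str, float]:
    """Balanced weights w_c = N / (k * n_c): minority classes weigh most."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts == 0):
        raise ValueError("every class must have at least one sample")
    n, k = labels.size, classes.size
    return {str(c): float(n / (k * m)) for c, m in zip(classes, counts)}


def per_class_metrics(confusion: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precision, recall and F1 per class from a confusion matrix.

    Undefined ratios (a class never predicted, or with zero support) are set
    to 0 by convention.
    """
    confusion = np.asarray(confusion, dtype=float)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(confusion < 0):
        raise ValueError("confusion counts must be nonnegative")
    tp = np.diag(confusion)
    pred = confusion.sum(axis=0)
    true = confusion.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred > 0, tp / pred, 0.0)
        recall = np.where(true > 0, tp / true, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    return precision, recall, f1


def macro_f1(confusion: np.ndarray) -> float:
    """Unweighted mean of the per-class F1 scores."""
    confusion = np.asarray(confusion, dtype=float)
    if confusion.sum() == 0:
        raise ValueError("confusion matrix is empty")
    return float(per_class_metrics(confusion)[2].mean())


def evaluate(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    classes: Sequence[str] | None = None,
) -> ClassReport:
    """Confusion matrix and per-class / macro metrics for predictions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal lengths")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred])).tolist()
    classes = tuple(str(c) for c in classes)
    conf = confusion_matrix(y_true, y_pred, labels=list(classes))
    precision, recall, f1 = per_class_metrics(conf)
    return ClassReport(
        classes=classes,
        confusion=conf,
        precision={c: float(p) for c, p in zip(classes, precision)},
        recall={c: float(r) for c, r in zip(classes, recall)},
        f1={c: float(v) for c, v in zip(classes, f1)},
        macro_f1=float(f1.mean()),
    )


def _make_estimator(config: TrainConfig, class_weight: dict | None):
    if config.model_kind == "margin-linear":
        return SVC(kernel="linear", class_weight=class_weight)
    if config.model_kind == "margin-rbf":
        return SVC(kernel="rbf", class_weight=class_weight)
    return RandomForestClassifier(
        class_weight=class_weight, random_state=config.seed, n_jobs=config.n_jobs
    )


def _expand_grid(config: TrainConfig, X: np.ndarray) -> dict:
    grid = dict(config.grid if config.grid is not None
                else DEFAULT_GRIDS[config.model_kind])
    if "gamma_factor" in grid:
        base = 1.0 / (X.shape[1] * X.var()) if X.var() > 0 else 1.0
        grid["gamma"] = [f * base for f in grid.pop("gamma_factor")]
    return grid


def _make_cv(config: TrainConfig):
    if config.cv == "loso":
        return LeaveOneGroupOut()
    if config.cv == "group-kfold":
        return GroupKFold(n_splits=config.n_splits)
    return StratifiedKFold(n_splits=config.n_splits, shuffle=True,
                           random_state=config.seed)


def _check_feasible(y: np.ndarray, groups: np.ndarray, config: TrainConfig
                    ) -> None:
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if config.cv in ("loso", "group-kfold"):
        if np.unique(groups).size < 2:
            raise ValueError("grouped cross-validation needs at least two groups")
        for c in classes:
            if np.unique(groups[y == c]).size < 2:
                raise ValueError(
                    f"class {c!r} occurs in a single group; every training "
                    "fold would lack it"
                )


def tune_and_train(
    X: np.ndarray,
    y: Sequence[str],
    groups: Sequence[str] | None,
    config: TrainConfig | None = None,
) -> TrainResult:
    """Grid search maximising macro-F1 under grouped CV; refit on all data."""
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = None if groups is None else np.asarray(groups)
    if config.cv != "stratified" and groups is None:
        raise ValueError("grouped cross-validation requires group labels")
    _check_feasible(y, groups if groups is not None else np.zeros(y.size), config)
    weights = make_class_weights(y) if config.class_weighting else None
    search = GridSearchCV(
        _make_estimator(config, weights),
        _expand_grid(config, X),
        scoring="f1_macro",
        cv=_make_cv(config),
        n_jobs=config.n_jobs,
        refit=True,
    )
    search.fit(X, y, groups=groups)
    return TrainResult(
        model=search.best_estimator_,
        cv_macro_f1=float(search.best_score_),
        best_params=dict(search.best_params_),
        config=config,
    )


def cross_validated_report(
    X: np.ndarray,
    y: Sequence[str],
    groups: Sequence[str] | None,
    config: TrainConfig | None = None,
    params: dict | None = None,
) -> ClassReport:
    """Pooled out-of-fold predictions -> one confusion matrix and metrics.

    ``params`` fixes the estimator's hyperparameters (no inner tuning); when
    omitted, the estimator's defaults are used.
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = None if groups is None else np.asarray(groups)
    _check_feasible(y, groups if groups is not None else np.zeros(y.size), config)
    weights = make_class_weights(y) if config.class_weighting else None
    y_pred = np.empty_like(y)
    for train_idx, test_idx in _make_cv(config).split(X, y, groups):
        est = _make_estimator(config, weights)
        if params:
            est.set_params(**params)
        est.fit(X[train_idx], y[train_idx])
        y_pred[test_idx] = est.predict(X[test_idx])
    return evaluate(y, y_pred, classes=np.unique(y).tolist())


def window_size_sweep(
    recordings: list,
    sizes_s: Sequence[float] = (2.0, 3.0, 4.0, 5.0, 6.0),
    config: TrainConfig | None = None,
    params: dict | None = None,
    stride_s: float = 1.0,
) -> pd.DataFrame:
    """Macro-F1 as a function of window size (labelling rules held fixed)."""
    config = config or TrainConfig()
    rows = []
    for size in sizes_s:
        dataset = build_dataset(recordings, window_s=size, stride_s=stride_s)
        table = feature_matrix(dataset)
        X = table[[c for c in table.columns
                   if c not in ("subject", "start_s", "label")]].to_numpy()
        report = cross_validated_report(X, dataset.labels, dataset.groups,
                                        config, params)
        rows.append({"window_s": size, "macro_f1": report.macro_f1,
                     "n_windows": len(dataset)})
    return pd.DataFrame(rows)
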