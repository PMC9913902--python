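"""Evaluation protocol: repeated stratified holdout, k-fold CV, ROC.

Every split refits the SVD feature model on its training rows only (no
leakage) and retrains the ensemble. The positive class is tumor (1).
Confusion counts are pooled over all repetitions/folds; per-repetition
accuracies feed the summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from . import ensemble, features
from .errors import DataError, ValidationError

BASE_MODELS = ("svm", "nb", "knn")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with tumor as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        )

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fn + other.fn,
                               self.tn + other.tn, self.fp + other.fp)

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def sensitivity(cm: ConfusionMatrix) -> float:
    """Percentage of tumor samples correctly identified: 100*TP/(TP+FN)."""
    if cm.tp + cm.fn == 0:
        raise DataError("sensitivity undefined: no positive (tumor) samples")
    return 100.0 * cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """Percentage of normal samples correctly classified: 100*TN/(TN+FP)."""
    if cm.tn + cm.fp == 0:
        raise DataError("specificity undefined: no negative (normal) samples")
    return 100.0 * cm.tn / (cm.tn + cm.fp)


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall correct percentage: 100*(TP+TN)/total."""
    if cm.total == 0:
        raise DataError("accuracy undefined on an empty confusion matrix")
    return 100.0 * (cm.tp + cm.tn) / cm.total


@dataclass
class EvalReport:
    accuracies: list[float]  # ensemble accuracy per repetition/fold, %
    mean_accuracy: float
    min_accuracy: float
    max_accuracy: float
    std_accuracy: float
    pooled: ConfusionMatrix
    sensitivity: float
    specificity: float
    roc_points: list[tuple[float, float]]
    auc: float
    base_accuracies: dict[str, list[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracies": self.accuracies,
            "mean_accuracy": self.mean_accuracy,
            "min_accuracy": self.min_accuracy,
            "max_accuracy": self.max_accuracy,
            "std_accuracy": self.std_accuracy,
            "confusion_matrix": {"tp": self.pooled.tp, "fn": self.pooled.fn,
                                 "tn": self.pooled.tn, "fp": self.pooled.fp},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "roc_points": [list(p) for p in self.roc_points],
            "auc": self.auc,
            "base_accuracies": self.base_accuracies,
        }


def roc_curve(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """(FPR, TPR) sweep over unique score thresholds plus trapezoidal AUC."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise DataError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return [(float(f), float(t)) for f, t in zip(fpr, tpr)], auc


def _fit_and_score(X, y, splits, energy_fraction: float, standardize: bool) -> EvalReport:
    accs: list[float] = []
    base_accs: dict[str, list[float]] = {m: [] for m in BASE_MODELS}
    pooled = ConfusionMatrix(0, 0, 0, 0)
    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    for train_idx, test_idx in splits:
        model = features.build_feature_model(X[train_idx], energy_fraction)
        f_train = features.project(model, X[train_idx])
        f_test = features.project(model, X[test_idx])
        ens = ensemble.train(f_train, y[train_idx], standardize=standardize)
        votes = ensemble.predict_votes(ens, f_test)
        pred = ensemble.majority(votes)
        cm = ConfusionMatrix.from_predictions(y[test_idx], pred)
        pooled = pooled + cm
        accs.append(accuracy(cm))
        for col, name in enumerate(BASE_MODELS):
            base_cm = ConfusionMatrix.from_predictions(y[test_idx], votes[:, col])
            base_accs[name].append(accuracy(base_cm))
        all_scores.append(votes.sum(axis=1) / 3.0)
        all_labels.append(y[test_idx])
    points, auc = roc_curve(np.concatenate(all_scores), np.concatenate(all_labels))
    accs_arr = np.array(accs)
    return EvalReport(
        accuracies=accs,
        mean_accuracy=float(accs_arr.mean()),
        min_accuracy=float(accs_arr.min()),
        max_accuracy=float(accs_arr.max()),
        std_accuracy=float(accs_arr.std()),
        pooled=pooled,
        sensitivity=sensitivity(pooled),
        specificity=specificity(pooled),
        roc_points=points,
        auc=auc,
        base_accuracies=base_accs,
    )


def _check_data(X, y, min_per_class: int):
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("data and labels disagree in length")
    counts = np.bincount(y, minlength=2)
    if counts.min() < min_per_class:
        raise DataError(
            f"need at least {min_per_class} samples per class, got {counts.tolist()}")
    return X, y


def repeated_holdout(X, y, reps: int = 20, train_frac: float = 0.7,
                     energy_fraction: float = 0.99, seed: int = 0,
                     standardize: bool = False) -> EvalReport:
    """Stratified random 70/30 splits, refit per repetition, pooled counts."""
    X, y = _check_data(X, y, 2)
    splitter = StratifiedShuffleSplit(n_splits=reps, train_size=train_frac,
                                      random_state=seed)
    return _fit_and_score(X, y, splitter.split(X, y), energy_fraction, standardize)


def kfold_cv(X, y, k: int = 10, energy_fraction: float = 0.99, seed: int = 0,
             standardize: bool = False) -> EvalReport:
    """Stratified k-fold cross validation with per-fold refits."""
    X, y = _check_data(X, y, 1)
    if k > min(np.bincount(y)):
        raise DataError(f"k={k} exceeds the size of the smallest class")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return _fit_and_score(X, y, splitter.split(X, y), energy_fraction, standardize)
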