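"""Majority-vote ensemble of linear SVM, Gaussian naive Bayes and 3-NN.

All three base classifiers are trained on the same feature matrix; the
ensemble label is the class predicted by at least two of them. The naive
Bayes and KNN implementations are local so tie-breaking is fully
deterministic: posterior and distance ties resolve toward class 0
(normal). Class labels are {0 = normal, 1 = tumor}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

from .errors import DataError, ValidationError

NB_VAR_FLOOR = 1e-9
KNN_K = 3


@dataclass(frozen=True)
class GaussianNB:
    """Per-class Gaussian parameters and log priors."""

    classes: np.ndarray
    log_priors: np.ndarray
    means: np.ndarray  # (n_classes, n_features)
    variances: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        # V_MAP: maximum posterior; np.argmax takes the first (lower) class on ties.
        log_post = self.log_priors[None, :] - 0.5 * (
            np.log(2 * np.pi * self.variances)[None, :, :]
            + (X[:, None, :] - self.means[None, :, :]) ** 2 / self.variances[None, :, :]
        ).sum(axis=2)
        return self.classes[np.argmax(log_post, axis=1)]


@dataclass(frozen=True)
class KNN:
    """Stored training set; k nearest by Euclidean distance, ties to class 0."""

    X: np.ndarray
    y: np.ndarray
    k: int = KNN_K

    def predict(self, X: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - self.X[None, :, :]) ** 2).sum(axis=2)
        out = np.empty(len(X), dtype=int)
        for i, row in enumerate(d2):
            # Sort by (distance, class) so equidistant neighbors of the
            # lower class are admitted first.
            order = np.lexsort((self.y, row))[: self.k]
            out[i] = int(self.y[order].sum() * 2 > self.k)
        return out


@dataclass(frozen=True)
class EnsembleModel:
    svm: SVC
    nb: GaussianNB
    knn: KNN
    scaler_mean: np.ndarray | None = None
    scaler_sd: np.ndarray | None = None


def _check_xy(X, y):
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("features and labels disagree in length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValidationError("labels must be 0 (normal) or 1 (tumor)")
    return X, y


def train(X, y, standardize: bool = False) -> EnsembleModel:
    """Fit all three base classifiers on identical data."""
    X, y = _check_xy(X, y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise DataError("training data must contain both classes")
    if min((y == c).sum() for c in classes) < 2:
        raise DataError("need at least 2 samples per class")

    mean = sd = None
    if standardize:
        mean = X.mean(axis=0)
        sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        X = (X - mean) / sd

    # max_iter caps libsvm on ill-conditioned (e.g. 1-D overlapping) inputs
    # where the default -1 can spin for hours; benign fits never hit it.
    svm = SVC(kernel="linear", C=1.0, tol=1e-4, max_iter=1_000_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svm.fit(X, y)

    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    variances = np.maximum(np.stack([X[y == c].var(axis=0) for c in classes]), NB_VAR_FLOOR)
    priors = np.array([(y == c).mean() for c in classes])
    nb = GaussianNB(classes=classes, log_priors=np.log(priors), means=means,
                    variances=variances)
    return EnsembleModel(svm=svm, nb=nb, knn=KNN(X=X, y=y),
                         scaler_mean=mean, scaler_sd=sd)


def _prepare(model: EnsembleModel, X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.knn.X.shape[1]:
        raise DataError(
            f"feature width {X.shape[1]} does not match training width "
            f"{model.knn.X.shape[1]}")
    if model.scaler_mean is not None:
        X = (X - model.scaler_mean) / model.scaler_sd
    return X

def predict_votes(model: EnsembleModel, X) -> np.ndarray:
    """Per-sample (svm, nb, knn) label triples."""
    X = _prepare(model, X)
    return np.column_stack([
        model.svm.predict(X).astype(int),
        model.nb.predict(X).astype(int),
        model.knn.predict(X),
    ])


def predict(model: EnsembleModel, X) -> np.ndarray:
    """Majority label over the three base votes (strict majority of 3)."""
    return majority(predict_votes(model, X))


def majority(votes: np.ndarray) -> np.ndarray:
    """Majority class of each row of a (n, 3) vote matrix."""
    votes = np.atleast_2d(np.asarray(votes, dtype=int))
    return (votes.sum(axis=1) * 2 > votes.shape[1]).astype(int)


def vote_score(model: EnsembleModel, X) -> np.ndarray:
    """Tumor-vote fraction in {0, 1/3, 2/3, 1}; thresholding at 0.5 = predict."""
    return predict_votes(model, X).sum(axis=1) / 3.0
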