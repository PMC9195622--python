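"""Linear soft-margin SVM, LOOCV evaluation, confusion metrics, ROC/AUC and
the label-permutation significance test.

The positive class (+1) is the post-training condition throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

__all__ = [
    "SvmModel",
    "ClassificationMetrics",
    "PermutationResult",
    "train_linear_svm",
    "prepare_folds",
    "predict_prepared",
    "loocv_predictions",
    "loocv_accuracy",
    "loocv_evaluate",
    "compute_metrics",
    "roc_auc",
    "permutation_test",
]


@dataclass
class SvmModel:
    """Trained linear SVM: decision value = <w, x> + b."""

    weights: np.ndarray
    bias: float
    C: float

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_values(X)
        return np.where(d >= 0, 1, -1)


@dataclass
class ClassificationMetrics:
    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc_points: list = field(default_factory=list)
    predictions: np.ndarray | None = None
    decision_values: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "auc": self.auc,
        }


@dataclass
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    p_raw: float
    p_add_one: float
    B: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed_accuracy": self.observed_accuracy,
            "p_raw": self.p_raw,
            "p_add_one": self.p_add_one,
            "B": self.B,
            "seed": self.seed,
            "null_mean": float(np.mean(self.null_accuracies)),
        }


def train_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> SvmModel:
    """Fit the soft-margin hinge-loss linear SVM."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if C <= 0:
        raise ValueError("C must be positive")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    clf = SVC(kernel="linear", C=C, tol=1e-8)
    clf.fit(X, y)
    w = clf.coef_.ravel().copy()
    b = float(clf.intercept_[0])
    return SvmModel(weights=w, bias=b, C=C)


def _fold_indices(subject_ids: np.ndarray, scheme: str) -> list[np.ndarray]:
    subject_ids = np.asarray(subject_ids)
    if scheme == "subject":
        return [np.flatnonzero(subject_ids == sid)
                for sid in np.unique(subject_ids)]
    if scheme == "scan":
        return [np.array([i]) for i in range(subject_ids.size)]
    raise ValueError(f"unknown CV scheme {scheme!r}")


def _scale_fit(train: np.ndarray, mode: str | None):
    if mode is None:
        return None
    if mode == "minmax":
        lo = train.min(axis=0)
        rng = train.max(axis=0) - lo
        return ("minmax", lo, np.where(rng == 0, 1.0, rng), rng == 0)
    if mode == "zscore":
        mu = train.mean(axis=0)
        sd = train.std(axis=0, ddof=1)
        return ("zscore", mu, np.where(sd == 0, 1.0, sd), sd == 0)
    raise ValueError(f"unknown scaling mode {mode!r}")


def _scale_apply(X: np.ndarray, params) -> np.ndarray:
    if params is None:
        return X
    kind, a, b, const = params
    out = (X - a) / b
    if const.any():
        out[:, const] = 0.5 if kind == "minmax" else 0.0
    return out


def prepare_folds(
    X: np.ndarray,
    subject_ids: np.ndarray,
    scheme: str = "subject",
    scale: str | None = None,
) -> list[tuple]:
    """Precompute per-fold (train_idx, test_idx, scaled Xtr, scaled Xte).

    Scaling parameters are learned on the training rows of each fold and are
    per-column and label-independent, so the cache stays valid across label
    permutations and across column subsets.
    """
    X = np.asarray(X, dtype=float)
    folds = _fold_indices(subject_ids, scheme)
    if len(folds) < 2:
        raise ValueError("need at least 2 cross-validation units")
    prepared = []
    all_idx = np.arange(X.shape[0])
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx, assume_unique=True)
        sc = _scale_fit(X[train_idx], scale)
        prepared.append((train_idx, test_idx,
                         _scale_apply(X[train_idx], sc),
                         _scale_apply(X[test_idx], sc)))
    return prepared


def predict_prepared(prepared, fit_y, n_samples, C=1.0, cols=None):
    """Held-out predictions/decision values from a prepared fold cache."""
    fit_y = np.asarray(fit_y, dtype=int)
    pred = np.empty(n_samples, dtype=int)
    dec = np.empty(n_samples, dtype=float)
    for train_idx, test_idx, Xtr, Xte in prepared:
        if cols is not None:
            Xtr, Xte = Xtr[:, cols], Xte[:, cols]
        ytr = fit_y[train_idx]
        if np.unique(ytr).size < 2:
            # degenerate permuted training set: constant classifier
            pred[test_idx] = ytr[0]
            dec[test_idx] = float(ytr[0])
            continue
        clf = SVC(kernel="linear", C=C)
        clf.fit(Xtr, ytr)
        d = clf.decision_function(Xte)
        pred[test_idx] = np.where(d >= 0, 1, -1)
        dec[test_idx] = d
    return pred, dec


def loocv_predictions(
    X: np.ndarray,
    y: np.ndarray,
    subject_ids: np.ndarray,
    scheme: str = "subject",
    C: float = 1.0,
    train_labels: np.ndarray | None = None,
    scale: str | None = None,
):
    """One held-out prediction per sample under leave-one-unit-out CV.

    ``train_labels``, when given, replaces the labels used for *fitting*
    (the permutation test trains on shuffled labels but scores against the
    true ones).  Returns (predictions, decision_values).
    """
    y = np.asarray(y, dtype=int)
    fit_y = y if train_labels is None else np.asarray(train_labels, dtype=int)
    prepared = prepare_folds(X, subject_ids, scheme=scheme, scale=scale)
    return predict_prepared(prepared, fit_y, y.size, C=C)


def loocv_accuracy(X, y, subject_ids, scheme: str = "subject", C: float = 1.0,
                   scale: str | None = None) -> float:
    pred, _ = loocv_predictions(X, y, subject_ids, scheme=scheme, C=C, scale=scale)
    return float((pred == np.asarray(y)).mean())


def compute_metrics(tp: int, fn: int, tn: int, fp: int):
    """(accuracy, sensitivity, specificity) from the confusion counts."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("a class is empty; sensitivity/specificity undefined")
    accuracy = (tp + tn) / (tp + fn + tn + fp)
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    return accuracy, sensitivity, specificity


def roc_auc(decision_values: np.ndarray, y: np.ndarray):
    """AUC as P(score+ > score-) + 0.5 P(tie), plus ROC curve points."""
    d = np.asarray(decision_values, dtype=float)
    y = np.asarray(y, dtype=int)
    pos, neg = d[y == 1], d[y == -1]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present for ROC/AUC")
    if np.ptp(d) == 0:
        warnings.warn("constant decision values; AUC = 0.5", stacklevel=2)
        return 0.5, [(0.0, 0.0), (1.0, 1.0)]
    ranks = rankdata(d)
    auc = (ranks[y == 1].sum() - pos.size * (pos.size + 1) / 2.0) \
        / (pos.size * neg.size)
    fpr, tpr, _ = roc_curve(y, d)
    return float(auc), list(zip(fpr.tolist(), tpr.tolist()))


def loocv_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    subject_ids: np.ndarray,
    scheme: str = "subject",
    C: float = 1.0,
    scale: str | None = None,
) -> ClassificationMetrics:
    """LOOCV with pooled per-fold decision values; +1 (post) is positive."""
    y = np.asarray(y, dtype=int)
    pred, dec = loocv_predictions(X, y, subject_ids, scheme=scheme, C=C,
                                  scale=scale)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == -1) & (y == 1)).sum())
    tn = int(((pred == -1) & (y == -1)).sum())
    fp = int(((pred == 1) & (y == -1)).sum())
    accuracy, sensitivity, specificity = compute_metrics(tp, fn, tn, fp)
    auc, roc_points = roc_auc(dec, y)
    return ClassificationMetrics(tp, fn, tn, fp, accuracy, sensitivity,
                                 specificity, auc, roc_points, pred, dec)


def _permute_labels(y, subject_ids, pairing, rng):
    y = np.asarray(y, dtype=int)
    if pairing == "subject":
        # flip both scans of a subject coherently: preserves balance
        out = y.copy()
        for sid in np.unique(subject_ids):
            if rng.random() < 0.5:
                out[subject_ids == sid] *= -1
        return out
    if pairing == "scan":
        # independent random +-1 per scan (may be unbalanced)
        return rng.choice([-1, 1], size=y.size)
    raise ValueError(f"unknown permutation pairing {pairing!r}")


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    subject_ids: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    scheme: str = "subject",
    pairing: str = "subject",
    C: float = 1.0,
    scale: str | None = None,
) -> PermutationResult:
    """Null distribution of LOOCV accuracy under randomly reassigned labels.

    Training labels are shuffled in each of the B iterations; each held-out
    scan keeps its true label for scoring.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(y, dtype=int)
    prepared = prepare_folds(X, subject_ids, scheme=scheme, scale=scale)
    pred, _ = predict_prepared(prepared, y, y.size, C=C)
    observed = float((pred == y).mean())
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        yb = _permute_labels(y, np.asarray(subject_ids), pairing, rng)
        pred, _ = predict_prepared(prepared, yb, y.size, C=C)
        null[b] = (pred == y).mean()
    n_ge = int((null >= observed - 1e-12).sum())
    return PermutationResult(
        observed_accuracy=observed,
        null_accuracies=null,
        p_raw=n_ge / B,
        p_add_one=(n_ge + 1) / (B + 1),
        B=B,
        seed=seed,
    )
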