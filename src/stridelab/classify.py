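"""t-test feature preselection, classifiers, and leave-one-pair-out CV.

The classifiers and their default hyperparameters follow the tabular
gait-parameter setup this package implements: a random forest (50 trees,
depth 30, sqrt feature subsampling), XGBoost (gbtree, binary:logistic,
eta 0.018, depth 15, gamma 0.009, subsample 0.98, colsample_bytree 0.86)
and SVMs with linear and RBF kernels (gamma 1.0, C 5.0).  SVM inputs are
z-scored on the training fold because an RBF kernel at gamma 1.0 is scale
sensitive; tree models see raw features.

Cross-validation is leave-one-pair-out (LOPO): with n subjects per class
there are n folds, each holding out exactly one subject of each class, and
feature selection is re-run inside every training fold to avoid selection
leakage.  The positive class (label 1) is the patient group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .core import GaitError

__all__ = ["ModelSpec", "CVResult", "ttest_select", "fit", "lopo_cv", "metrics"]

MODEL_FAMILIES = ("rf", "xgboost", "svm-linear", "svm-rbf")


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family plus hyperparameters (defaults as documented)."""

    family: str = "rf"
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise GaitError(f"unknown model family {self.family!r}; "
                            f"choose from {MODEL_FAMILIES}")


_DEFAULTS = {
    "rf": dict(n_estimators=50, max_depth=30, max_features="sqrt"),
    "xgboost": dict(booster="gbtree", objective="binary:logistic",
                    learning_rate=0.018, max_depth=15, gamma=0.009,
                    subsample=0.98, colsample_bytree=0.86, n_estimators=100),
    "svm": dict(gamma=1.0, C=5.0),
}


def build_estimator(spec: ModelSpec):
    """Instantiate an (unfitted) scikit-learn estimator for a spec."""
    if spec.family == "rf":
        kw = {**_DEFAULTS["rf"], **spec.params}
        return RandomForestClassifier(random_state=spec.seed, **kw)
    if spec.family == "xgboost":
        kw = {**_DEFAULTS["xgboost"], **spec.params}
        return XGBClassifier(random_state=spec.seed, n_jobs=1,
                             verbosity=0, **kw)
    kernel = "linear" if spec.family == "svm-linear" else "rbf"
    kw = {**_DEFAULTS["svm"], **spec.params}
    return Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(kernel=kernel, random_state=spec.seed, **kw)),
    ])


def fit(spec: ModelSpec, X: np.ndarray, y: np.ndarray):
    """Fit a classifier; deterministic under the spec's seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise GaitError("training data must contain both classes")
    est = build_estimator(spec)
    est.fit(X, y)
    return est


def ttest_select(X: np.ndarray, y: np.ndarray, k: int = 100,
                 equal_var: bool = False) -> np.ndarray:
    """Indices of the k features with the smallest two-sample t-test p-values.

    Welch's (unequal-variance) t-test by default; features with zero variance
    in both classes get p = 1.  Ties are broken by ascending feature index,
    and the returned indices are ordered by ascending p.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k > X.shape[1]:
        raise GaitError(f"k={k} exceeds the {X.shape[1]} available features")
    a, b = X[y == 1], X[y == 0]
    if min(len(a), len(b)) < 2:
        raise GaitError("each class needs >= 2 subjects for the t-test")
    import warnings
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant features trip scipy's catastrophic-cancellation
        # warning; they legitimately get p ~ 1 and are never selected
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = sps.ttest_ind(a, b, equal_var=equal_var)
    p = np.where(np.isfinite(p), p, 1.0)
    order = np.lexsort((np.arange(p.size), p))
    return order[:k]


def metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Binary accuracy/precision/recall/F1 with the patient class positive."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise GaitError("y_true and y_pred must be equal-length and non-empty")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    acc = float(np.mean(y_true == y_pred))
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


@dataclass
class CVResult:
    """Leave-one-pair-out cross-validation output."""

    fold_predictions: list          # per fold: (test_idx, y_true, y_pred)
    fold_features: list             # per fold: selected feature indices
    fold_models: list               # per fold: the fitted estimator
    accuracy: float
    precision: float
    recall: float
    f1: float

    @property
    def n_folds(self) -> int:
        return len(self.fold_predictions)

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        yt = np.concatenate([f[1] for f in self.fold_predictions])
        yp = np.concatenate([f[2] for f in self.fold_predictions])
        return yt, yp


def _predict_label(model, X: np.ndarray) -> np.ndarray:
    """Predict labels, breaking a probability tie at 0.5 toward class 0."""
    if hasattr(model, "predict_proba"):
        p = model.predict_proba(X)[:, 1]
        return (p > 0.5).astype(int)
    return np.asarray(model.predict(X), dtype=int)


def lopo_cv(X: np.ndarray, y: np.ndarray, spec: ModelSpec,
            select_k: int | None = 100) -> CVResult:
    """Leave-one-pair-out cross-validation.

    Subjects are paired by their within-class order: fold i holds out the
    i-th patient and the i-th control.  When ``select_k`` is given, t-test
    feature selection is re-run on each training fold.  Per-fold accuracies
    are averaged; precision/recall/F1 are computed on the pooled
    out-of-fold predictions (a two-sample test set makes per-fold
    precision/recall degenerate).

    Raises :class:`~stridelab.core.GaitError` on unbalanced classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size != neg.size:
        raise GaitError(f"LOPO-CV needs balanced classes, got {pos.size} "
                        f"patients vs {neg.size} controls")
    if pos.size < 2:
        raise GaitError("need at least 2 subjects per class")

    folds_pred, folds_feat, folds_model, fold_acc = [], [], [], []
    for i in range(pos.size):
        test_idx = np.array([pos[i], neg[i]])
        train_idx = np.setdiff1d(np.arange(y.size), test_idx)
        X_tr, y_tr = X[train_idx], y[train_idx]
        if select_k is not None:
            feat = ttest_select(X_tr, y_tr, select_k)
        else:
            feat = np.arange(X.shape[1])
        model = fit(spec, X_tr[:, feat], y_tr)
        y_pred = _predict_label(model, X[test_idx][:, feat])
        folds_pred.append((test_idx, y[test_idx], y_pred))
        folds_feat.append(feat)
        folds_model.append(model)
        fold_acc.append(np.mean(y_pred == y[test_idx]))

    yt = np.concatenate([f[1] for f in folds_pred])
    yp = np.concatenate([f[2] for f in folds_pred])
    pooled = metrics(yt, yp)
    return CVResult(folds_pred, folds_feat, folds_model,
                    accuracy=float(np.mean(fold_acc)),
                    precision=pooled["precision"], recall=pooled["recall"],
                    f1=pooled["f1"])
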