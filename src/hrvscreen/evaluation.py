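"""Confusion-matrix performance measures and a cross-validation harness.

CHF is the positive class.  AUC here is the single-operating-point
balanced-accuracy convention, ``(SEN + SPE) / 2`` — the form computable from
one confusion matrix (a ROC-integral AUC is not).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .classifiers import (
    CHF,
    KNNConfig,
    SVMConfig,
    knn_predict,
    svm_predict,
    train_svm,
)

__all__ = [
    "ConfusionMatrix",
    "PerformanceReport",
    "metrics",
    "auc_from_rates",
    "confusion_from_predictions",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with CHF positive: tp = CHF detected, tn = healthy detected,
    fp = healthy called CHF, fn = CHF called healthy."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class PerformanceReport:
    """Accuracy, precision, sensitivity, specificity and balanced AUC, all in
    percent; undefined measures (zero denominator) are NaN."""

    acc: float
    pre: float
    sen: float
    spe: float
    auc: float
    cm: ConfusionMatrix | None = None


def auc_from_rates(sen: float, spe: float) -> float:
    """Balanced-accuracy AUC, ``(SEN + SPE) / 2``, in percent."""
    return (sen + spe) / 2.0


def _ratio(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else math.nan


def metrics(cm: ConfusionMatrix) -> PerformanceReport:
    """The five performance measures of a single confusion matrix."""
    acc = _ratio(cm.tp + cm.tn, cm.total)
    pre = _ratio(cm.tp, cm.tp + cm.fp)
    sen = _ratio(cm.tp, cm.tp + cm.fn)
    spe = _ratio(cm.tn, cm.tn + cm.fp)
    auc = auc_from_rates(sen, spe)
    return PerformanceReport(acc=acc, pre=pre, sen=sen, spe=spe, auc=auc, cm=cm)


def confusion_from_predictions(y_true, y_pred) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionMatrix(
        tp=int(np.sum((y_true == CHF) & (y_pred == CHF))),
        tn=int(np.sum((y_true != CHF) & (y_pred != CHF))),
        fp=int(np.sum((y_true != CHF) & (y_pred == CHF))),
        fn=int(np.sum((y_true == CHF) & (y_pred != CHF))),
    )


def _fit_predict(X_tr, y_tr, X_te, model_cfg, seed: int) -> np.ndarray:
    if isinstance(model_cfg, SVMConfig):
        cfg = SVMConfig(
            degree=model_cfg.degree, coef0=model_cfg.coef0, C=model_cfg.C,
            cv_folds=model_cfg.cv_folds, c_grid=model_cfg.c_grid, seed=seed,
        )
        model = train_svm(X_tr, y_tr, cfg)
        return np.array([svm_predict(model, x)[1] for x in X_te])
    if isinstance(model_cfg, KNNConfig):
        return np.array([knn_predict(X_tr, y_tr, x, model_cfg) for x in X_te])
    raise TypeError("model_cfg must be an SVMConfig or a KNNConfig")


def _splits(X, y, protocol, seed: int):
    if protocol == "loocv":
        return list(LeaveOneOut().split(X))
    if protocol == "resubstitution":
        idx = np.arange(len(y))
        return [(idx, idx)]
    if isinstance(protocol, str) and protocol.startswith("kfold"):
        n = int(protocol.split(":")[1]) if ":" in protocol else 5
    elif isinstance(protocol, tuple) and protocol[0] == "kfold":
        n = int(protocol[1])
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    for attempt_seed in (seed, seed + 1):
        skf = StratifiedKFold(n_splits=n, shuffle=True, random_state=attempt_seed)
        folds = list(skf.split(X, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            if attempt_seed != seed:
                warnings.warn("reshuffled folds once to keep both classes in every "
                              "training split", stacklevel=3)
            return folds
    raise ValueError("could not build folds with both classes in every training split")


def cross_validate(X, y, model_cfg, protocol="loocv", seed: int = 0) -> PerformanceReport:
    """Evaluate a classifier configuration under a validation protocol.

    ``protocol`` is ``'loocv'``, ``'resubstitution'`` or ``'kfold:n'``.  Held
    -out predictions are pooled into a single confusion matrix (resubstitution
    pools training-set predictions); deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts[:2].min() < 2 or len(np.unique(y)) != 2:
        raise ValueError("cross-validation needs at least 2 samples per class")
    y_pred = np.empty_like(y)
    for tr, te in _splits(X, y, protocol, seed):
        y_pred[te] = _fit_predict(X[tr], y[tr], X[te], model_cfg, seed)
    return metrics(confusion_from_predictions(y, y_pred))
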