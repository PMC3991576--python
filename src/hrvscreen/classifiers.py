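"""Classifiers: polynomial-kernel soft-margin SVM, the published fixed
quadratic decision boundary on (SUM_TD, SUM_FD), and a KNN comparator.

Label convention throughout: CHF = 1 (positive class), healthy = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "CHF",
    "HEALTHY",
    "SVMConfig",
    "SVMModel",
    "FixedBoundaryModel",
    "PUBLISHED_BOUNDARY",
    "KNNConfig",
    "fixed_model_z",
    "train_svm",
    "svm_predict",
    "knn_predict",
    "save_model",
    "load_model",
]

CHF = 1
HEALTHY = 0

DEFAULT_C_GRID = (1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)


@dataclass(frozen=True)
class SVMConfig:
    """Polynomial-kernel SVM settings.

    The kernel is ``K(u, v) = (gamma * u.v + coef0)^degree`` with ``gamma=1``.
    When ``C`` is None it is chosen from ``c_grid`` by ``cv_folds``-fold
    cross-validated accuracy, ties broken toward the smallest C.
    """

    degree: int = 2
    coef0: float = 1.0
    C: float | None = None
    cv_folds: int = 5
    c_grid: tuple = DEFAULT_C_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("kernel degree must be >= 1")
        if self.C is not None and self.C <= 0:
            raise ValueError("C must be positive")


@dataclass(frozen=True)
class SVMModel:
    """A trained polynomial-kernel SVM in explicit dual form.

    ``dual_coef[i]`` is ``alpha_i * y_i`` (y in {-1, +1}, CHF positive); the
    decision score of a query x is ``sum_i dual_coef[i] * K(sv_i, x) + bias``
    and a positive score labels CHF.
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    bias: float
    degree: int
    coef0: float
    gamma: float
    C: float
    feature_names: tuple = ()

    def kernel(self, U: np.ndarray, v: np.ndarray) -> np.ndarray:
        return (self.gamma * U @ v + self.coef0) ** self.degree


@dataclass(frozen=True)
class FixedBoundaryModel:
    """The published fixed quadratic boundary in the (SUM_TD, SUM_FD) plane.

    ``Z = SUM_FD - (p2 * SUM_TD^2 + p1 * SUM_TD + p0)``; ``Z < 0`` labels
    CHF.  The orientation (the polynomial predicts SUM_FD from SUM_TD) is
    fixed by requiring the two published group-mean points to land on the
    correct sides of the curve.
    """

    poly_coeffs: tuple = (0.0001, 0.0208, 9.3036)


#: name accepted by the CLI / model loader for the built-in fixed boundary
PUBLISHED_BOUNDARY = "published-boundary"


def fixed_model_z(sum_td, sum_fd, model: FixedBoundaryModel = FixedBoundaryModel()):
    """Signed distance-like score and label of the fixed boundary.

    Returns ``(z, label)``; label is CHF (1) iff ``z < 0`` (strict).
    """
    p2, p1, p0 = model.poly_coeffs
    z = float(sum_fd) - (p2 * float(sum_td) ** 2 + p1 * float(sum_td) + p0)
    return z, (CHF if z < 0 else HEALTHY)


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    return X, y


def _select_c(X: np.ndarray, y: np.ndarray, cfg: SVMConfig) -> float:
    """Pick C from the grid by cross-validated accuracy (ties -> smallest C)."""
    n_per_class = np.bincount(y).min()
    folds = int(min(cfg.cv_folds, n_per_class))
    if folds < 2:
        return 1.0
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    best_c, best_acc = None, -1.0
    for c in sorted(cfg.c_grid):
        correct = 0
        for tr, te in skf.split(X, y):
            clf = SVC(C=c, kernel="poly", degree=cfg.degree, coef0=cfg.coef0, gamma=1.0)
            clf.fit(X[tr], y[tr])
            correct += int(np.sum(clf.predict(X[te]) == y[te]))
        acc = correct / len(y)
        if acc > best_acc:
            best_c, best_acc = c, acc
    return float(best_c)


def train_svm(X, y, cfg: SVMConfig = SVMConfig(), feature_names: tuple = ()) -> SVMModel:
    """Fit the soft-margin polynomial-kernel SVM.

    Deterministic given ``cfg.seed`` (the seed only shuffles the folds of the
    cross-validated C search).
    """
    X, y = _validate_xy(X, y)
    C = cfg.C if cfg.C is not None else _select_c(X, y, cfg)
    clf = SVC(C=C, kernel="poly", degree=cfg.degree, coef0=cfg.coef0, gamma=1.0)
    clf.fit(X, y)
    return SVMModel(
        support_vectors=np.array(clf.support_vectors_),
        dual_coef=np.array(clf.dual_coef_[0]),
        bias=float(clf.intercept_[0]),
        degree=cfg.degree,
        coef0=cfg.coef0,
        gamma=1.0,
        C=float(C),
        feature_names=tuple(feature_names),
    )


def svm_predict(model: SVMModel, x):
    """Decision score and label for one feature vector.

    ``score = sum_i dual_i * K(sv_i, x) + bias``; positive scores label CHF.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size != model.support_vectors.shape[1]:
        raise ValueError(
            f"query has {x.size} features, model was trained with "
            f"{model.support_vectors.shape[1]}"
        )
    score = float(model.dual_coef @ model.kernel(model.support_vectors, x) + model.bias)
    return score, (CHF if score > 0 else HEALTHY)


@dataclass(frozen=True)
class KNNConfig:
    """K-nearest-neighbour settings: odd ``k`` (default 3), Euclidean
    distance on features min-max normalized with the training set's ranges."""

    k: int = 3

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _minmax_train(X: np.ndarray):
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0  # constant column -> maps to 0
    return lo, span


def knn_predict(train_X, train_y, query, cfg: KNNConfig = KNNConfig()) -> int:
    """Majority vote among the k nearest training points.

    Distances are Euclidean on features normalized with the training min/max.
    Distance ties break toward the lower sample index; vote ties break toward
    CHF (sensitivity-conservative).
    """
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_y, dtype=int)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if cfg.k > X.shape[0]:
        raise ValueError(f"k={cfg.k} exceeds the training-set size {X.shape[0]}")
    q = np.asarray(query, dtype=float).ravel()
    lo, span = _minmax_train(X)
    Xn = (X - lo) / span
    qn = (q - lo) / span
    d = np.sqrt(np.sum((Xn - qn) ** 2, axis=1))
    order = np.lexsort((np.arange(len(d)), d))  # stable: ties by lower index
    votes = y[order[: cfg.k]]
    n_chf = int(np.sum(votes == CHF))
    return CHF if n_chf >= (cfg.k - n_chf) else HEALTHY


def save_model(model, path) -> None:
    """Serialize a trained SVM or fixed-boundary model as JSON."""
    if isinstance(model, FixedBoundaryModel):
        doc = {"kind": "fixed_boundary", "poly_coeffs": list(model.poly_coeffs)}
    elif isinstance(model, SVMModel):
        doc = {
            "kind": "svm_poly",
            "support_vectors": model.support_vectors.tolist(),
            "dual_coef": model.dual_coef.tolist(),
            "bias": model.bias,
            "degree": model.degree,
            "coef0": model.coef0,
            "gamma": model.gamma,
            "C": model.C,
            "feature_names": list(model.feature_names),
        }
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path_or_name):
    """Load a model from JSON, or return the built-in fixed boundary for the
    name ``'published-boundary'``."""
    if path_or_name == PUBLISHED_BOUNDARY:
        return FixedBoundaryModel()
    with open(path_or_name) as fh:
        doc = json.load(fh)
    kind = doc.get("kind")
    if kind == "fixed_boundary":
        return FixedBoundaryModel(poly_coeffs=tuple(doc["poly_coeffs"]))
    if kind == "svm_poly":
        return SVMModel(
            support_vectors=np.asarray(doc["support_vectors"], dtype=float),
            dual_coef=np.asarray(doc["dual_coef"], dtype=float),
            bias=float(doc["bias"]),
            degree=int(doc["degree"]),
            coef0=float(doc["coef0"]),
            gamma=float(doc["gamma"]),
            C=float(doc["C"]),
            feature_names=tuple(doc.get("feature_names", ())),
        )
    raise ValueError(f"unknown model kind {kind!r} in {path_or_name}")
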