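"""The three movement classifiers behind one train/predict contract.

* ``knn`` — K-nearest neighbours with Euclidean distance and majority
  vote, implemented here directly so the vote and its tie-breaking are
  fully specified: vote ties are broken by the smallest summed distance
  of the tied class's neighbours, then by the lowest class index.
  Default K = 5 (a common odd default; the choice is configurable).
* ``svm`` — support vector machine with a Gaussian (RBF) kernel,
  one-vs-one multiclass voting; C = 1 and gamma = 1/(n_features * var)
  by default.
* ``bagging`` — bootstrap aggregation of unpruned decision trees,
  100 estimators by default, fully seeded.

Distance-based classifiers need commensurate feature scales, so for
``knn`` and ``svm`` the input columns are z-scored with statistics
fitted on the training data (disable with ``params={"scale": False}``
when the caller has already standardised, e.g. via PCA with
standardisation on).  Tree ensembles are scale-invariant and skip it.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import BaggingClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = ["TrainedClassifier", "train", "predict", "DEFAULT_PARAMS"]

DEFAULT_PARAMS: dict[str, dict[str, Any]] = {
    "knn": {"k": 5, "scale": True},
    "svm": {"C": 1.0, "gamma": "scale", "scale": True},
    "bagging": {"n_estimators": 100, "scale": False},
}


@dataclass
class TrainedClassifier:
    kind: str
    params: dict[str, Any]
    classes: np.ndarray  # sorted class labels
    scaler: tuple[np.ndarray, np.ndarray] | None  # (mean, std) or None
    state: Any  # (X, y_idx) for knn; fitted sklearn model otherwise
    seed: int = 0

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not contain a TrainedClassifier")
        return obj


def _apply_scaler(scaler, X):
    if scaler is None:
        return X
    mean, std = scaler
    return (X - mean) / std


def train(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    params: dict[str, Any] | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit one of the three classifiers on feature rows ``X`` with labels ``y``."""
    if kind not in DEFAULT_PARAMS:
        raise ValueError(f"unknown classifier kind {kind!r}; one of {sorted(DEFAULT_PARAMS)}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    p = dict(DEFAULT_PARAMS[kind])
    p.update(params or {})

    scaler = None
    if p.get("scale", False):
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std == 0, 1.0, std)
        scaler = (mean, std)
        X = _apply_scaler(scaler, X)

    y_idx = np.searchsorted(classes, y)
    if kind == "knn":
        k = int(p["k"])
        if not 1 <= k <= X.shape[0]:
            raise ValueError(f"knn k={k} out of range [1, {X.shape[0]}]")
        state = (X.copy(), y_idx)
    elif kind == "svm":
        state = SVC(C=p["C"], gamma=p["gamma"], kernel="rbf", random_state=seed)
        state.fit(X, y_idx)
    else:  # bagging
        state = BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=int(p["n_estimators"]),
            random_state=seed,
        )
        state.fit(X, y_idx)
    return TrainedClassifier(
        kind=kind, params=p, classes=classes, scaler=scaler, state=state, seed=seed
    )


def _knn_predict(model: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    Xtr, y_idx = model.state
    k = int(model.params["k"])
    n_classes = model.classes.size
    out = np.empty(X.shape[0], dtype=int)
    # squared Euclidean distances; monotone in the true distance
    d2 = (
        np.sum(X * X, axis=1)[:, None]
        - 2.0 * X @ Xtr.T
        + np.sum(Xtr * Xtr, axis=1)[None, :]
    )
    for i in range(X.shape[0]):
        nn = np.argpartition(d2[i], k - 1)[:k] if k < Xtr.shape[0] else np.arange(Xtr.shape[0])
        votes = np.bincount(y_idx[nn], minlength=n_classes)
        best = votes.max()
        tied = np.flatnonzero(votes == best)
        if tied.size == 1:
            out[i] = tied[0]
        else:
            # smallest summed Euclidean distance among tied classes,
            # then lowest class index
            d = np.sqrt(np.maximum(d2[i], 0.0))
            sums = np.array([d[nn[y_idx[nn] == c]].sum() for c in tied])
            out[i] = tied[np.argmin(sums)]  # argmin takes the first (lowest class) on ties
    return out


def predict(model: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Predict class labels for the rows of ``X``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n_features = (
        model.state[0].shape[1] if model.kind == "knn" else model.state.n_features_in_
    )
    if X.shape[1] != n_features:
        raise ValueError(f"X has {X.shape[1]} columns, model expects {n_features}")
    if X.shape[0] == 0:
        return model.classes[:0].copy()
    X = _apply_scaler(model.scaler, X)
    if model.kind == "knn":
        idx = _knn_predict(model, X)
    else:
        idx = model.state.predict(X)
    return model.classes[idx]
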