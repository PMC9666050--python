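"""PCA by eigendecomposition of the covariance of centred features.

The covariance is normalised by ``1/n`` (not ``1/(n-1)``), matching the
decentralised-data formulation ``C = (1/n) X^T X`` with ``X`` column-
centred.  The top-``k`` eigenvectors form the projection matrix; each
eigenvector's sign is fixed so its largest-magnitude loading is
positive, making serialized models reproducible across platforms.

Standardisation (dividing each centred column by its standard deviation)
is off by default — plain mean-centring mirrors the method being
implemented — but is exposed because amplitude features (signal units)
and spectral features (Hz) live on incommensurate scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["PCAModel", "pca_fit", "pca_transform", "pca_inverse_transform"]

_TIE_TOL = 1e-12


@dataclass
class PCAModel:
    mean: np.ndarray          # (n_features,)
    components: np.ndarray    # (k, n_features), rows orthonormal
    eigenvalues: np.ndarray   # (k,), nonincreasing
    scale: np.ndarray | None = None  # per-feature std if standardised

    @property
    def k(self) -> int:
        return self.components.shape[0]

    @property
    def n_features(self) -> int:
        return self.components.shape[1]

    def to_json(self, path) -> None:
        obj = {
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "scale": None if self.scale is None else self.scale.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "PCAModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            mean=np.array(obj["mean"]),
            components=np.array(obj["components"]),
            eigenvalues=np.array(obj["eigenvalues"]),
            scale=None if obj["scale"] is None else np.array(obj["scale"]),
        )


def pca_fit(X: np.ndarray, k: int, standardize: bool = False) -> PCAModel:
    """Fit a rank-``k`` PCA model on the rows of ``X``.

    ``k`` must satisfy ``1 <= k <= min(n_rows - 1, n_features)`` (the
    ``1/n``-normalised covariance of ``n`` centred rows has at most
    ``n - 1`` nonzero eigenvalues).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 rows")
    n, p = X.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k={k} out of range [1, {min(n - 1, p)}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    scale = None
    if standardize:
        scale = Xc.std(axis=0)
        zero = np.flatnonzero(scale == 0)
        if zero.size:
            raise ValueError(f"zero-variance column(s) with standardize on: {zero.tolist()}")
        Xc = Xc / scale
    C = (Xc.T @ Xc) / n
    eigvals, eigvecs = np.linalg.eigh(C)  # ascending
    # sort descending; eigh order breaks ties within _TIE_TOL
    order = np.argsort(-eigvals, kind="stable")
    eigvals = eigvals[order][:k]
    comps = eigvecs[:, order][:, :k].T
    # deterministic sign: largest-|loading| entry positive
    for i in range(k):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    eigvals = np.where(np.abs(eigvals) < _TIE_TOL, np.maximum(eigvals, 0.0), eigvals)
    return PCAModel(mean=mean, components=comps, eigenvalues=eigvals, scale=scale)


def pca_transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project rows of ``X`` into the retained component space."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1]} columns, model expects {model.n_features}"
        )
    Xc = X - model.mean
    if model.scale is not None:
        Xc = Xc / model.scale
    return Xc @ model.components.T


def pca_inverse_transform(model: PCAModel, Y: np.ndarray) -> np.ndarray:
    """Map component scores back to the feature space (lossless at full k)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[1] != model.k:
        raise ValueError(f"Y has {Y.shape[1]} columns, model has k={model.k}")
    Xc = Y @ model.components
    if model.scale is not None:
        Xc = Xc * model.scale
    return Xc + model.mean
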