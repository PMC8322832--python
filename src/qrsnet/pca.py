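"""PCA with dimension selection by cumulative contribution rate.

The reduced dimension k is the smallest number of leading principal
components whose cumulative share of total variance exceeds a threshold
``a`` (85% or 99% in the reference protocol).  Inputs are assumed already
normalized to [-1, 1], so only mean-centering is applied by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .types import InvalidArgumentError


class InsufficientDataError(ValueError):
    pass


@dataclass
class PcaModel:
    """Fitted principal axes.

    ``components`` rows are principal directions sorted by decreasing
    eigenvalue; ``cum_contrib[i]`` is the variance fraction carried by the
    first i+1 components.
    """

    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    cum_contrib: np.ndarray

    @property
    def n_features(self) -> int:
        return self.mean.size

    def to_json(self) -> str:
        return json.dumps({
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "PcaModel":
        d = json.loads(text)
        eig = np.asarray(d["eigenvalues"], dtype=float)
        total = eig.sum()
        cum = np.cumsum(eig) / total if total > 0 else np.ones_like(eig)
        return cls(np.asarray(d["mean"], dtype=float),
                   np.asarray(d["components"], dtype=float), eig, cum)


def fit_pca(X) -> PcaModel:
    """Eigendecomposition of the mean-centered covariance.

    Sign convention: each component's largest-magnitude loading is positive,
    so the fit is deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InsufficientDataError("PCA needs at least 2 rows")
    mean = X.mean(axis=0)
    C = np.cov(X - mean, rowvar=False, ddof=1)
    C = np.atleast_2d(C)
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    components = eigvec[:, order].T
    # deterministic sign: largest |loading| positive
    for i, row in enumerate(components):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            components[i] = -row
    total = eigval.sum()
    cum = np.cumsum(eigval) / total if total > 0 else np.ones_like(eigval)
    return PcaModel(mean=mean, components=components, eigenvalues=eigval, cum_contrib=cum)


def select_dim(model: PcaModel, a: float) -> int:
    """Smallest k whose cumulative contribution strictly exceeds ``a``."""
    if not 0 < a < 1:
        raise InvalidArgumentError(f"a must be in (0, 1), got {a}")
    above = np.nonzero(model.cum_contrib > a)[0]
    return int(above[0]) + 1 if above.size else model.eigenvalues.size


def transform(model: PcaModel, X, k: int) -> np.ndarray:
    """Project rows of ``X`` onto the first ``k`` principal directions."""
    X = np.asarray(X, dtype=float)
    d = model.n_features
    if not 1 <= k <= d:
        raise InvalidArgumentError(f"k must be in 1..{d}, got {k}")
    if X.ndim != 2 or X.shape[1] != d:
        raise InvalidArgumentError(f"X must have {d} columns")
    return (X - model.mean) @ model.components[:k].T


def inverse_transform(model: PcaModel, Z) -> np.ndarray:
    """Map k-dimensional scores back to the original feature space."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    k = Z.shape[1]
    return Z @ model.components[:k] + model.mean
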