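"""Classical NMF by Lee–Seung multiplicative updates (linear baseline).

min ||X - WH||_F^2  s.t.  W >= 0, H >= 0, via the multiplicative rules

    H <- H * (W^T X) / (W^T W H + eps)
    W <- W * (X H^T) / (W H H^T + eps)

which never increase the Frobenius residual and preserve non-negativity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigurationError, DegenerateInputError

__all__ = ["MultiplicativeNMF", "NMFResult", "nmf_multiplicative"]

_EPS = 1e-10


@dataclass
class NMFResult:
    W: np.ndarray
    H: np.ndarray
    residual_trace: list[float] = field(default_factory=list)

    @property
    def residual(self) -> float:
        return self.residual_trace[-1]


def _nndsvd_init(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """NNDSVD-style non-negative projection of the truncated SVD."""
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    W = np.zeros((X.shape[0], k))
    H = np.zeros((k, X.shape[1]))
    W[:, 0] = np.sqrt(s[0]) * np.abs(u[:, 0])
    H[0] = np.sqrt(s[0]) * np.abs(vt[0])
    for j in range(1, k):
        x, y = u[:, j], vt[j]
        xp, xn = np.maximum(x, 0), np.maximum(-x, 0)
        yp, yn = np.maximum(y, 0), np.maximum(-y, 0)
        mp, mn = np.linalg.norm(xp) * np.linalg.norm(yp), np.linalg.norm(xn) * np.linalg.norm(yn)
        if mp >= mn and mp > 0:
            W[:, j] = np.sqrt(s[j] * mp) * xp / np.linalg.norm(xp)
            H[j] = np.sqrt(s[j] * mp) * yp / np.linalg.norm(yp)
        elif mn > 0:
            W[:, j] = np.sqrt(s[j] * mn) * xn / np.linalg.norm(xn)
            H[j] = np.sqrt(s[j] * mn) * yn / np.linalg.norm(yn)
    # zero columns stall multiplicative updates; seed them with the mean
    scale = X.mean() or 1.0
    W[:, W.sum(axis=0) == 0] = scale
    H[H.sum(axis=1) == 0] = scale
    return W, H


def nmf_multiplicative(
    X: np.ndarray,
    k: int,
    max_iter: int = 500,
    seed: int = 0,
    init: str = "svd",
    tol: float = 0.0,
) -> NMFResult:
    """Factor a non-negative matrix at rank ``k``.

    ``init="svd"`` uses the deterministic NNDSVD-style start, ``"random"``
    draws |N(0,1)| entries from ``seed``.  The residual trace is recorded
    after every update pair and is non-increasing (classical guarantee).
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise DegenerateInputError("NMF requires a non-negative input matrix")
    if not 1 <= k < min(X.shape):
        raise ConfigurationError(f"rank k={k} must satisfy 1 <= k < min{X.shape}")
    if init == "svd":
        W, H = _nndsvd_init(X, k)
    elif init == "random":
        rng = np.random.default_rng(seed)
        W = np.abs(rng.normal(size=(X.shape[0], k)))
        H = np.abs(rng.normal(size=(k, X.shape[1])))
    else:
        raise ConfigurationError(f"unknown init {init!r}")
    trace = [float(np.linalg.norm(X - W @ H) ** 2)]
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ H @ H.T + _EPS)
        trace.append(float(np.linalg.norm(X - W @ H) ** 2))
        if tol > 0 and trace[-2] - trace[-1] <= tol * max(trace[0], 1e-300):
            break
    return NMFResult(W=W, H=H, residual_trace=trace)


class MultiplicativeNMF(TransformerMixin, BaseEstimator):
    """Lee–Seung NMF with the scikit-learn estimator interface.

    Attributes after :meth:`fit`: ``components_`` (k x n non-negative H),
    ``W_`` (m x k non-negative loadings of the training data) and
    ``residual_trace_``.
    """

    def __init__(self, n_components: int = 5, max_iter: int = 500, init: str = "svd",
                 random_state: int = 0):
        self.n_components = n_components
        self.max_iter = max_iter
        self.init = init
        self.random_state = random_state

    def fit(self, X, y=None):
        res = nmf_multiplicative(
            X, self.n_components, max_iter=self.max_iter, seed=self.random_state, init=self.init
        )
        self.W_ = res.W
        self.components_ = res.H
        self.residual_trace_ = res.residual_trace
        self.reconstruction_err_ = float(np.sqrt(res.residual))
        return self

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.W_

    def transform(self, X):
        """Project new non-negative rows onto the fitted components by
        multiplicative updates on W with H fixed."""
        X = np.asarray(X, dtype=float)
        if np.any(X < 0):
            raise DegenerateInputError("NMF requires a non-negative input matrix")
        H = self.components_
        rng = np.random.default_rng(self.random_state)
        W = np.abs(rng.normal(size=(X.shape[0], H.shape[0])))
        for _ in range(self.max_iter):
            W *= (X @ H.T) / (W @ H @ H.T + _EPS)
        return W
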