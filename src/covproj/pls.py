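"""PLS1 regression (single outcome) via NIPALS with X-deflation.

For one response all mainstream PLS algorithms yield the same regression
vector; NIPALS is used for its transparency. Scores are kept orthogonal by
deflating X after each component (``X_{a+1} = X_a - t_a p_a^T``); y is not
deflated, which is unnecessary for a univariate response.

The regression vector is assembled as ``b = W (P^T W)^{-1} q`` where
``P^T W`` is unit upper triangular for NIPALS, so a triangular solve is used.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from .errors import DegenerateError, RankError


@dataclass
class PLSModel:
    """Fitted PLS1 model with ``A`` latent components.

    Attributes
    ----------
    W : (m, A) weight matrix, orthonormal columns.
    T : (n, A) score matrix, mutually orthogonal columns.
    P : (m, A) x-loading matrix.
    q : (A,) y-loadings.
    b : (m,) regression vector; fitted values are ``X @ b == T @ q``.
    """

    n_components: int
    W: np.ndarray
    T: np.ndarray
    P: np.ndarray
    q: np.ndarray
    b: np.ndarray
    x_train_ref: str = ""

    def fitted(self) -> np.ndarray:
        return self.T @ self.q

    def to_json(self) -> str:
        doc = {
            "n_components": self.n_components,
            "W": self.W.tolist(),
            "T": self.T.tolist(),
            "P": self.P.tolist(),
            "q": self.q.tolist(),
            "b": self.b.tolist(),
            "x_train_ref": self.x_train_ref,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, doc: str) -> "PLSModel":
        d = json.loads(doc)
        return cls(
            n_components=int(d["n_components"]),
            W=np.asarray(d["W"], dtype=float),
            T=np.asarray(d["T"], dtype=float),
            P=np.asarray(d["P"], dtype=float),
            q=np.asarray(d["q"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            x_train_ref=d.get("x_train_ref", ""),
        )


def _matrix_ref(X: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(X).tobytes()).hexdigest()[:16]


def fit_pls1(X: np.ndarray, y: np.ndarray, A: int) -> PLSModel:
    """Fit a PLS1 model with ``A`` components on column-centered data.

    Parameters
    ----------
    X : (n, m) column-centered predictor matrix.
    y : (n,) centered response.
    A : number of latent components, ``1 <= A <= rank(X)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    if y.shape[0] != n:
        raise ValueError(f"X has {n} rows but y has {y.shape[0]}")
    if A < 1:
        raise RankError(f"need at least one component, got A={A}")
    if float(y @ y) <= 0:
        raise DegenerateError("response has zero variance")

    Xa = X.copy()
    W = np.empty((m, A))
    T = np.empty((n, A))
    P = np.empty((m, A))
    q = np.empty(A)
    for a in range(A):
        w = Xa.T @ y
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * max(1.0, np.linalg.norm(y)):
            raise RankError(
                f"component {a + 1}: residual X carries no covariance with y "
                f"(A={A} exceeds the predictive rank)"
            )
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        if tt <= 0 or not np.isfinite(tt):
            raise RankError(f"component {a + 1}: degenerate score (A exceeds rank)")
        p = Xa.T @ t / tt
        q[a] = float(y @ t) / tt
        W[:, a] = w
        T[:, a] = t
        P[:, a] = p
        Xa -= np.outer(t, p)

    # P^T W is unit upper triangular for NIPALS PLS1
    R = P.T @ W
    b = W @ solve_triangular(R, q, lower=False)
    return PLSModel(
        n_components=A, W=W, T=T, P=P, q=q, b=b, x_train_ref=_matrix_ref(X)
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Fitted/predicted values ``X_new @ b`` (X_new centered with training means)."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.b.shape[0]:
        raise ValueError(
            f"X_new has shape {X_new.shape}, expected (*, {model.b.shape[0]})"
        )
    return X_new @ model.b
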