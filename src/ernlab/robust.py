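"""Batched bisquare (Tukey biweight) IRLS regression.

This is the workhorse behind both regression levels: the same model is fitted
independently at thousands of electrode x timepoint cells, so the solver is
vectorized over "columns" (cells).  The design matrix may be shared by all
columns (first level: one design, many signals) or vary per column (coupling
model: the EEG-amplitude regressor changes at every cell).

Estimator choices
-----------------
* weight function: bisquare with tuning constant c = 4.685 (95% Gaussian
  efficiency), working scale = normalized MAD of the current residuals;
* at most 50 iterations, convergence when the largest coefficient change is
  below 1e-6 relative to the largest coefficient;
* standard errors: biweight-midvariance scale of the final residuals times
  sqrt(diag((X'X)^-1)).  This robust scale is unbiased for sigma under
  Gaussian noise, so the scaled weights (b/SE) coincide with OLS t-statistics
  on clean data while remaining resistant to outlier trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BISQUARE_C = 4.685
MAD_NORM = 1.4826022185056018  # 1 / Phi^-1(0.75)


@dataclass
class IRLSResult:
    coef: np.ndarray       # (m, p)
    se: np.ndarray         # (m, p)
    scale: np.ndarray      # (m,) biweight-midvariance residual scale
    n_iter: np.ndarray     # (m,)
    converged: np.ndarray  # (m,) bool

    @property
    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.coef / self.se


def mad(r: np.ndarray, axis: int = -1) -> np.ndarray:
    """Normalized median absolute deviation about the median."""
    med = np.median(r, axis=axis, keepdims=True)
    return MAD_NORM * np.median(np.abs(r - med), axis=axis)


def biweight_midvariance_scale(r: np.ndarray, c: float = 9.0) -> np.ndarray:
    """Biweight midvariance scale estimate, batched over rows of (m, n)."""
    r = np.atleast_2d(r)
    n = r.shape[-1]
    med = np.median(r, axis=-1, keepdims=True)
    d = r - med
    mad0 = np.median(np.abs(d), axis=-1, keepdims=True)
    safe = np.where(mad0 > 0, mad0, 1.0)
    u = d / (c * safe)
    w = np.abs(u) < 1
    one_u2 = np.where(w, 1.0 - u**2, 0.0)
    num = np.sum(d**2 * one_u2**4, axis=-1)
    den = np.sum(one_u2 * (1.0 - 5.0 * u**2) * w, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.sqrt(n * num) / np.abs(den)
    return np.where(mad0[..., 0] > 0, s, 0.0)


def _bisquare_weights(resid: np.ndarray, cs: np.ndarray) -> np.ndarray:
    """Tukey biweight w = (1 - (r/cs)^2)^2 for |r| < cs else 0, in place."""
    w = resid / cs
    np.square(w, out=w)
    np.subtract(1.0, w, out=w)
    np.clip(w, 0.0, None, out=w)
    np.square(w, out=w)
    return w


def irls_bisquare(X: np.ndarray, Y: np.ndarray, *, c: float = BISQUARE_C,
                  max_iter: int = 50, rtol: float = 1e-6) -> IRLSResult:
    """Fit Y[:, j] ~ X (or X[j]) by bisquare IRLS for every column j.

    Parameters
    ----------
    X : (n, p) shared design, or (m, n, p) per-column designs.
    Y : (n, m) responses (a single (n,) vector is treated as m = 1).
    """
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = Y.shape
    X = np.asarray(X, dtype=np.float64)
    shared = X.ndim == 2
    if shared:
        if X.shape[0] != n:
            raise ValueError("X and Y row counts differ")
        p = X.shape[1]
        Xb = np.broadcast_to(X, (m, n, p))
    else:
        if X.shape[:2] != (m, n):
            raise ValueError("per-column X must be (m, n, p)")
        p = X.shape[2]
        Xb = X
    if n <= p:
        raise ValueError("need more observations than parameters")

    Yt = np.ascontiguousarray(Y.T)  # (m, n)
    if shared:
        # X'WX assembled via one GEMM: W @ (X_p * X_q) for all (p, q) pairs
        XX = np.ascontiguousarray(
            (X[:, :, None] * X[:, None, :]).reshape(n, p * p))

    # OLS start
    if shared:
        B = np.linalg.lstsq(X, Y, rcond=None)[0].T  # (m, p)
    else:
        XtX = np.einsum("mnp,mnq->mpq", Xb, Xb)
        Xty = np.einsum("mnp,mn->mp", Xb, Yt)
        B = np.linalg.solve(XtX, Xty[..., None])[..., 0]

    coef = B.copy()
    n_iter = np.zeros(m, dtype=int)
    converged = np.zeros(m, dtype=bool)
    active = np.arange(m)

    for it in range(max_iter):
        if active.size == 0:
            break
        Ba = coef[active]
        if shared:
            resid = Yt[active] - Ba @ X.T
        else:
            Xa = Xb[active]
            resid = Yt[active] - np.einsum("mnp,mp->mn", Xa, Ba)
        s = mad(resid, axis=-1)
        exact = s <= 1e-12 * np.maximum(1.0, np.abs(Yt[active]).max(axis=-1))
        s_safe = np.where(exact, 1.0, s)
        W = _bisquare_weights(resid, (c * s_safe)[:, None])
        W[exact] = 1.0
        if shared:
            A = (W @ XX).reshape(-1, p, p)
            b = (W * Yt[active]) @ X
        else:
            A = np.einsum("mnp,mn,mnq->mpq", Xa, W, Xa)
            b = np.einsum("mnp,mn->mp", Xa, W * Yt[active])
        # guard: if too many weights hit zero the system may be singular
        try:
            Bnew = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            A = A + 1e-10 * np.eye(p)
            Bnew = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.abs(Bnew - Ba).max(axis=-1)
        ref = np.abs(Bnew).max(axis=-1) + 1e-30
        done = (delta / ref < rtol) | exact
        coef[active] = Bnew
        n_iter[active] = it + 1
        converged[active[done]] = True
        active = active[~done]

    # final residuals and standard errors
    if shared:
        resid = Yt - coef @ X.T
        XtX_inv = np.linalg.inv(X.T @ X)
        dvec = np.sqrt(np.diag(XtX_inv))[None, :]  # (1, p)
    else:
        resid = Yt - np.einsum("mnp,mp->mn", Xb, coef)
        XtX_inv = np.linalg.inv(np.einsum("mnp,mnq->mpq", Xb, Xb))
        dvec = np.sqrt(np.diagonal(XtX_inv, axis1=1, axis2=2))  # (m, p)
    scale = biweight_midvariance_scale(resid)
    se = scale[:, None] * dvec
    return IRLSResult(coef=coef, se=se, scale=scale,
                      n_iter=n_iter, converged=converged)
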