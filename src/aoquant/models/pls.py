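"""Partial least squares regression (single response) via NIPALS.

The bilinear model is X = D P' + E, y = U q' + f with the inner relation
linking the score matrices; prediction reduces to the regression vector
B = W (P' W)^-1 q on mean-centered data.  The NIPALS deflation loop yields
the coefficient vector for *every* number of latent variables in one pass
(``pls_coefficient_path``), which the CARS wavelength selector relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

__all__ = [
    "PLSRModel",
    "plsr_fit",
    "plsr_predict",
    "pls_coefficient_path",
    "choose_lv_by_cv",
    "pls_rmsecv",
]

_EPS = np.finfo(float).eps


def _nipals_path(X: np.ndarray, y: np.ndarray, max_lv: int):
    """Centered NIPALS; returns per-LV coefficient vectors and the factors.

    ``coefs[a-1]`` is the regression vector using ``a`` latent variables,
    applicable to centered X / producing centered y.
    """
    n, p = X.shape
    max_lv = min(max_lv, p, n - 1)
    Xc = X.copy()
    yc = y.copy()
    W = np.zeros((max_lv, p))
    P = np.zeros((max_lv, p))
    Q = np.zeros(max_lv)
    T = np.zeros((max_lv, n))
    R = np.zeros((max_lv, p))
    coefs = np.zeros((max_lv, p))
    B = np.zeros(p)
    a_used = 0
    for a in range(max_lv):
        w = Xc.T @ yc
        wn = np.linalg.norm(w)
        if wn < 1e-12:
            break
        w /= wn
        t = Xc @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        pvec = Xc.T @ t / tt
        q = float(yc @ t) / tt
        Xc -= np.outer(t, pvec)
        yc = yc - q * t
        r = w.copy()
        for j in range(a):
            r -= float(P[j] @ w) * R[j]
        W[a], P[a], Q[a], T[a], R[a] = w, pvec, q, t, r
        B = B + q * r
        coefs[a] = B
        a_used = a + 1
    if a_used < max_lv:
        # rank exhausted: later LVs add nothing
        for a in range(a_used, max_lv):
            coefs[a] = coefs[a_used - 1] if a_used else 0.0
    return coefs, W[:a_used], P[:a_used], Q[:a_used], T[:a_used], a_used


@dataclass
class PLSRModel:
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray
    x_weights: np.ndarray = field(repr=False, default=None)
    x_loadings: np.ndarray = field(repr=False, default=None)
    y_loadings: np.ndarray = field(repr=False, default=None)
    x_scores: np.ndarray = field(repr=False, default=None)

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coef + self.y_mean


def plsr_fit(X, y, n_lv: int) -> PLSRModel:
    """Fit PLSR with ``n_lv`` latent variables (NIPALS, mean-centered)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    bound = min(p, n - 1)
    if not 1 <= n_lv <= bound:
        raise ValueError(f"n_lv must be in [1, {bound}], got {n_lv}")
    xm = X.mean(axis=0)
    ym = float(y.mean())
    coefs, W, P, Q, T, a_used = _nipals_path(X - xm, y - ym, n_lv)
    return PLSRModel(
        n_components=n_lv,
        x_mean=xm,
        y_mean=ym,
        coef=coefs[n_lv - 1],
        x_weights=W,
        x_loadings=P,
        y_loadings=Q,
        x_scores=T,
    )


def plsr_predict(model: PLSRModel, X) -> np.ndarray:
    return model.predict(X)


def pls_coefficient_path(X, y, max_lv: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-LV regression vectors from one NIPALS pass.

    Returns ``(coefs, x_mean, y_mean)`` where ``coefs[a-1]`` predicts via
    ``(X - x_mean) @ coefs[a-1] + y_mean``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = X.mean(axis=0)
    ym = float(y.mean())
    coefs, *_ = _nipals_path(X - xm, y - ym, max_lv)
    return coefs, xm, ym


def pls_rmsecv(
    X, y, max_lv: int, folds: int = 5, seed: int = 0, return_folds: bool = False
):
    """k-fold RMSECV for every LV count 1..max_lv (one NIPALS pass per fold).

    Returns ``(rmsecv_per_lv, best_lv)``; ties resolve to the smaller LV.
    With ``return_folds`` also returns the per-fold RMSE matrix
    (folds x max_lv), e.g. for paired model comparisons.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if folds > n:
        raise ValueError("more folds than samples")
    max_lv = min(max_lv, p, n - 1 - (n // folds))
    max_lv = max(max_lv, 1)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sse = np.zeros(max_lv)
    fold_rmse = np.zeros((folds, max_lv))
    for f, (train, test) in enumerate(kf.split(X)):
        coefs, xm, ym = pls_coefficient_path(X[train], y[train], max_lv)
        pred = (X[test] - xm) @ coefs.T + ym  # (n_test, max_lv)
        err2 = (pred - y[test, None]) ** 2
        sse += err2.sum(axis=0)
        fold_rmse[f] = np.sqrt(err2.mean(axis=0))
    rmsecv = np.sqrt(sse / n)
    best = int(np.argmin(rmsecv)) + 1  # first minimum = smallest LV on ties
    if not return_folds:
        return rmsecv, best
    return rmsecv, best, fold_rmse


def choose_lv_by_cv(X, y, max_lv: int, folds: int = 5, seed: int = 0) -> int:
    """Cross-validated choice of the latent-variable count (argmin RMSECV)."""
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    _, best = pls_rmsecv(X, y, max_lv, folds=folds, seed=seed)
    return best
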