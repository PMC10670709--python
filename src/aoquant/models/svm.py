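"""Epsilon-insensitive support-vector regression with an RBF kernel.

Thin wrapper over scikit-learn's SVR that autoscales inputs and targets by
training-set statistics; the penalty ``c`` and kernel width ``g`` are tuned
by exhaustive grid search with k-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold
from sklearn.svm import SVR

__all__ = ["SVRModel", "svr_fit", "svr_predict", "svr_grid_cv", "default_grid"]


def default_grid() -> np.ndarray:
    """Powers of two 2^-8 .. 2^8."""
    return 2.0 ** np.arange(-8, 9)


@dataclass
class SVRModel:
    c: float
    g: float
    epsilon: float
    x_mean: np.ndarray = field(repr=False)
    x_scale: np.ndarray = field(repr=False)
    y_mean: float
    y_scale: float
    estimator: SVR = field(repr=False, default=None)

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = (X - self.x_mean) / self.x_scale
        return self.estimator.predict(Xs) * self.y_scale + self.y_mean


def _scales(X: np.ndarray, y: np.ndarray):
    xm = X.mean(axis=0)
    xs = X.std(axis=0)
    xs[xs == 0] = 1.0
    ym = float(y.mean())
    ys = float(y.std()) or 1.0
    return xm, xs, ym, ys


def svr_fit(X, y, c: float, g: float, epsilon: float = 0.01) -> SVRModel:
    """Fit RBF SVR; ``epsilon`` is the tube width on the normalized target."""
    if c <= 0 or g <= 0:
        raise ValueError("penalty c and kernel width g must be positive")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, xs, ym, ys = _scales(X, y)
    est = SVR(kernel="rbf", C=c, gamma=g, epsilon=epsilon)
    est.fit((X - xm) / xs, (y - ym) / ys)
    return SVRModel(c=c, g=g, epsilon=epsilon, x_mean=xm, x_scale=xs,
                    y_mean=ym, y_scale=ys, estimator=est)


def svr_predict(model: SVRModel, X) -> np.ndarray:
    return model.predict(X)


def svr_grid_cv(
    X,
    y,
    c_grid=None,
    g_grid=None,
    folds: int = 5,
    seed: int = 0,
    epsilon: float = 0.01,
) -> tuple[float, float]:
    """Exhaustive (c, g) grid search by k-fold RMSECV.

    Ties resolve to the smaller ``c``, then the smaller ``g``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if folds > len(y):
        raise ValueError("more folds than samples")
    c_grid = default_grid() if c_grid is None else np.asarray(c_grid, dtype=float)
    g_grid = default_grid() if g_grid is None else np.asarray(g_grid, dtype=float)
    if c_grid.size == 0 or g_grid.size == 0:
        raise ValueError("grids must be non-empty")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    best = None
    # ascending grids make the first strict improvement the tie-rule winner
    for c in np.sort(c_grid):
        for g in np.sort(g_grid):
            sse = 0.0
            for train, test in splits:
                model = svr_fit(X[train], y[train], c=c, g=g, epsilon=epsilon)
                resid = model.predict(X[test]) - y[test]
                sse += float(resid @ resid)
            if best is None or sse < best[0] - 1e-15:
                best = (sse, float(c), float(g))
    return best[1], best[2]
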