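"""Single-hidden-layer backpropagation network and its SSA-seeded variant.

Architecture: tanh hidden layer, linear output, trained by full-batch
gradient descent on mean-squared error.  Inputs and targets are min-max
normalized to [-1, 1] using training-set statistics only (the layer-wise
normalization that smooths the loss landscape).  ``ssa_bp_fit`` first lets
the sparrow search algorithm pick the initial weights and thresholds
(biases) by minimizing training MSE over the flattened parameter vector,
then fine-tunes with backpropagation — the standard remedy for plain BP's
tendency to stall in poor local minima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .ssa import SSAConfig, SSARun, ssa_optimize

__all__ = [
    "BPNet",
    "default_hidden_size",
    "init_bp",
    "bp_train",
    "bp_predict",
    "ssa_bp_fit",
]


def default_hidden_size(n_in: int, n_out: int = 1) -> int:
    """Classic sqrt(n_in + n_out) + 4 heuristic."""
    return int(round(math.sqrt(n_in + n_out))) + 4


@dataclass
class BPNet:
    W1: np.ndarray  # (hidden, n_in)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden,)
    b2: float
    x_min: np.ndarray = field(repr=False, default=None)
    x_max: np.ndarray = field(repr=False, default=None)
    y_min: float = 0.0
    y_max: float = 1.0

    @property
    def n_in(self) -> int:
        return self.W1.shape[1]

    @property
    def hidden(self) -> int:
        return self.W1.shape[0]

    @property
    def n_params(self) -> int:
        return self.hidden * self.n_in + self.hidden + self.hidden + 1

    # --- parameter vector (for the SSA search space) -------------------
    def flatten(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1, self.W2, [self.b2]])

    def with_params(self, vec: np.ndarray) -> "BPNet":
        h, d = self.hidden, self.n_in
        vec = np.asarray(vec, dtype=float)
        if vec.size != self.n_params:
            raise ValueError("parameter vector has wrong length")
        W1 = vec[: h * d].reshape(h, d)
        b1 = vec[h * d : h * d + h]
        W2 = vec[h * d + h : h * d + 2 * h]
        b2 = float(vec[-1])
        return replace(self, W1=W1.copy(), b1=b1.copy(), W2=W2.copy(), b2=b2)

    # --- normalization -------------------------------------------------
    def _norm_x(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.x_max > self.x_min, self.x_max - self.x_min, 1.0)
        return 2.0 * (X - self.x_min) / span - 1.0

    def _norm_y(self, y: np.ndarray) -> np.ndarray:
        span = (self.y_max - self.y_min) or 1.0
        return 2.0 * (y - self.y_min) / span - 1.0

    def _denorm_y(self, yn: np.ndarray) -> np.ndarray:
        span = (self.y_max - self.y_min) or 1.0
        return (yn + 1.0) * span / 2.0 + self.y_min

    def _forward_normed(self, Xn: np.ndarray) -> np.ndarray:
        H = np.tanh(Xn @ self.W1.T + self.b1)
        return H @ self.W2 + self.b2

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._denorm_y(self._forward_normed(self._norm_x(X)))

    def training_mse(self, X, y) -> float:
        """MSE on the normalized target scale."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        yn = self._norm_y(np.asarray(y, dtype=float))
        resid = self._forward_normed(self._norm_x(X)) - yn
        return float(np.mean(resid**2))


def init_bp(X, y, hidden: int | None = None, seed: int = 0, init_scale: float = 3.0) -> BPNet:
    """Seeded random init; normalization statistics from the training data.

    Weights and thresholds are drawn uniformly from ``[-init_scale,
    init_scale]`` — the same box the sparrow search explores, so plain BP and
    SSA-BP start from one common prior and differ only in how the starting
    point is chosen.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n_in = X.shape[1]
    if hidden is None:
        hidden = default_hidden_size(n_in)
    rng = np.random.default_rng(seed)
    scale = init_scale
    return BPNet(
        W1=rng.uniform(-scale, scale, (hidden, n_in)),
        b1=rng.uniform(-scale, scale, hidden),
        W2=rng.uniform(-scale, scale, hidden),
        b2=float(rng.uniform(-scale, scale)),
        x_min=X.min(axis=0),
        x_max=X.max(axis=0),
        y_min=float(y.min()),
        y_max=float(y.max()),
    )


def bp_train(
    net: BPNet,
    X,
    y,
    epochs: int = 2000,
    learning_rate: float = 0.05,
    momentum: float = 0.9,
) -> BPNet:
    """Full-batch gradient descent with momentum on MSE; returns a trained
    copy.

    Deterministic given the initial network (sample order is irrelevant for
    full-batch updates).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    Xn = net._norm_x(X)
    yn = net._norm_y(y)
    W1 = net.W1.copy()
    b1 = net.b1.copy()
    W2 = net.W2.copy()
    b2 = net.b2
    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2)
    vb2 = 0.0
    n = Xn.shape[0]
    for _ in range(epochs):
        H = np.tanh(Xn @ W1.T + b1)  # (n, h)
        out = H @ W2 + b2
        err = out - yn  # (n,)
        loss = float(np.mean(err**2))
        if not np.isfinite(loss):
            raise FloatingPointError("BP training diverged (non-finite loss)")
        g_out = 2.0 * err / n
        gW2 = H.T @ g_out
        gb2 = g_out.sum()
        g_hidden = np.outer(g_out, W2) * (1.0 - H**2)  # (n, h)
        gW1 = g_hidden.T @ Xn
        gb1 = g_hidden.sum(axis=0)
        vW1 = momentum * vW1 - learning_rate * gW1
        vb1 = momentum * vb1 - learning_rate * gb1
        vW2 = momentum * vW2 - learning_rate * gW2
        vb2 = momentum * vb2 - learning_rate * gb2
        W1 += vW1
        b1 += vb1
        W2 += vW2
        b2 += vb2
    return replace(net, W1=W1, b1=b1, W2=W2, b2=b2)


def bp_predict(net: BPNet, X) -> np.ndarray:
    return net.predict(X)


def ssa_bp_fit(
    X,
    y,
    hidden: int | None = None,
    ssa_config: SSAConfig | None = None,
    bp_epochs: int = 2000,
    learning_rate: float = 0.05,
    seed: int = 0,
) -> tuple[BPNet, SSARun | None]:
    """SSA-optimized BP: sparrow search over the flattened weight/threshold
    vector (objective = training MSE), then backpropagation fine-tuning from
    the global best.  With ``n_iterations=0`` this degenerates to plain BP
    from the seeded random init.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    net = init_bp(X, y, hidden=hidden, seed=seed)
    if ssa_config is None:
        ssa_config = SSAConfig(seed=seed)
    run = None
    if ssa_config.n_iterations > 0:
        def objective(vec: np.ndarray) -> float:
            return net.with_params(vec).training_mse(X, y)

        # warm-seed the population with the random init so the SSA start
        # never fares worse than plain BP's starting point
        run = ssa_optimize(objective, dim=net.n_params, config=ssa_config,
                           initial=net.flatten())
        net = net.with_params(run.best_position)
    net = bp_train(net, X, y, epochs=bp_epochs, learning_rate=learning_rate)
    return net, run
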