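"""Sparrow search algorithm (SSA), a population metaheuristic.

The population splits into discoverers (the current best fraction PD, which
lead the search), joiners (which follow the best discoverer or, when ranked
in the worse half, make a starvation jump) and scouts (a random SD fraction
that reacts to danger by moving toward the global best or away from the
worst).  An alarm value drawn each generation against the safety threshold ST
switches the discoverer update between a multiplicative exponential-decay
contraction and a Gaussian jump.  The global best is tracked elitistically,
so the fitness curve is non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SSAConfig", "SSARun", "ssa_optimize"]


@dataclass(frozen=True)
class SSAConfig:
    pop_size: int = 30
    n_iterations: int = 100
    discoverer_fraction: float = 0.2  # PD
    scout_fraction: float = 0.1  # SD
    alarm_threshold: float = 0.8  # ST
    lower: np.ndarray | float = -3.0
    upper: np.ndarray | float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("population size must be >= 2")
        if not 0 < self.discoverer_fraction < 1:
            raise ValueError("discoverer fraction PD must be in (0, 1)")
        if not 0 < self.scout_fraction < 1:
            raise ValueError("scout fraction SD must be in (0, 1)")
        if not 0 < self.alarm_threshold <= 1:
            raise ValueError("alarm threshold ST must be in (0, 1]")


@dataclass
class SSARun:
    best_position: np.ndarray
    best_fitness: float
    fitness_curve: np.ndarray = field(repr=False)


def ssa_optimize(objective, dim: int, config: SSAConfig, initial: np.ndarray | None = None) -> SSARun:
    """Minimize ``objective`` over a box-bounded ``dim``-dimensional space.

    ``initial`` optionally warm-seeds one population member (clipped to the
    bounds); with elitist best-tracking the result can then never be worse
    than that starting point.
    """
    lower = np.broadcast_to(np.asarray(config.lower, dtype=float), (dim,)).copy()
    upper = np.broadcast_to(np.asarray(config.upper, dtype=float), (dim,)).copy()
    if not (np.all(np.isfinite(lower)) and np.all(np.isfinite(upper))):
        raise ValueError("search space must be bounded")
    if np.any(lower > upper):
        raise ValueError("lower bounds exceed upper bounds")
    rng = np.random.default_rng(config.seed)
    pop = config.pop_size
    T = config.n_iterations
    n_disc = max(1, int(round(config.discoverer_fraction * pop)))
    n_scout = max(1, int(round(config.scout_fraction * pop)))

    X = lower + (upper - lower) * rng.random((pop, dim))
    if initial is not None:
        X[0] = np.clip(np.asarray(initial, dtype=float), lower, upper)
    fit = np.array([float(objective(x)) for x in X])
    gbest_idx = int(np.argmin(fit))
    gbest = X[gbest_idx].copy()
    gbest_fit = float(fit[gbest_idx])
    curve = np.empty(T)

    eps = np.finfo(float).tiny
    for t in range(1, T + 1):
        order = np.argsort(fit)
        X = X[order]
        fit = fit[order]
        worst = X[-1].copy()
        f_worst = float(fit[-1])

        # discoverers: best n_disc sparrows
        R2 = rng.random()
        for i in range(n_disc):
            if R2 < config.alarm_threshold:
                alpha = rng.random() or 1.0
                X[i] = X[i] * np.exp(-(i + 1) / (alpha * T))
            else:
                X[i] = X[i] + rng.normal() * np.ones(dim)
        best_disc = X[0].copy()

        # joiners: the rest; worse half makes a starvation jump
        for i in range(n_disc, pop):
            if i > pop / 2:
                X[i] = rng.normal() * np.exp((worst - X[i]) / ((i + 1) ** 2))
            else:
                A = rng.choice((-1.0, 1.0), size=dim)
                X[i] = best_disc + np.abs(X[i] - best_disc) * A / dim

        # scouts: random SD fraction become danger-aware
        for i in rng.choice(pop, size=n_scout, replace=False):
            if fit[i] > gbest_fit:
                X[i] = gbest + rng.normal() * np.abs(X[i] - gbest)
            else:
                K = rng.uniform(-1.0, 1.0)
                X[i] = X[i] + K * np.abs(X[i] - worst) / (fit[i] - f_worst + eps)

        np.clip(X, lower, upper, out=X)
        fit = np.array([float(objective(x)) for x in X])
        it_best = int(np.argmin(fit))
        if fit[it_best] < gbest_fit:
            gbest_fit = float(fit[it_best])
            gbest = X[it_best].copy()
        curve[t - 1] = gbest_fit

    return SSARun(best_position=gbest, best_fitness=gbest_fit, fitness_curve=curve)
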