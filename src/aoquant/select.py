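"""CARS characteristic-wavelength selection.

Competitive adaptive reweighted sampling runs N Monte-Carlo iterations.  Each
iteration fits PLSR on a random row subsample, ranks the surviving variables
by the magnitude of their autoscaled regression coefficients, enforces the
exponentially decaying retention count (EDF), and then performs adaptive
reweighted sampling — a weighted draw with replacement whose unique survivors
form the next variable set.  The subset with the smallest cross-validated
RMSE over the run is returned.  ``secondary_screen`` re-runs the selection on
an augmented multi-matrix training set, the step used after target-matrix
samples are added to the calibration set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .models.pls import pls_coefficient_path, pls_rmsecv

__all__ = ["CARSResult", "CARSEnsemble", "edf_ratio", "cars_run", "ensemble_cars", "secondary_screen"]


@dataclass
class CARSResult:
    selected_indices: np.ndarray
    selected_wavenumbers: np.ndarray | None
    rmsecv_trajectory: np.ndarray
    retained_counts: np.ndarray
    best_iteration: int
    seed: int
    retained_sets: list = field(default_factory=list, repr=False)


def edf_ratio(iteration: int, total: int, p0: float = 1.0, pN: float = 0.1) -> float:
    """Exponentially decreasing retention ratio r(i) = a * exp(-k i) with
    r(1) = p0 and r(total) = pN."""
    if not 0 < pN < p0 <= 1:
        raise ValueError("need 0 < pN < p0 <= 1")
    if not 1 <= iteration <= total or total < 2:
        raise ValueError("iteration out of range")
    k = math.log(p0 / pN) / (total - 1)
    a = p0 * math.exp(k)
    return a * math.exp(-k * iteration)


def cars_run(
    X,
    y,
    n_iterations: int = 50,
    folds: int = 5,
    max_lv: int = 10,
    seed: int = 0,
    mc_rate: float = 0.8,
    p0: float = 1.0,
    pN: float | None = None,
    wavenumbers=None,
    selection_rule: str = "parsimonious",
) -> CARSResult:
    """One CARS run; reproducible from ``seed``.

    The EDF keep-count is capped at the current retained count, so the
    per-iteration retained counts are non-increasing; if fewer than two
    variables survive mid-run the loop terminates at the last valid
    iteration.  Coefficients are ranked at the latent-variable count that
    minimized the previous iteration's RMSECV, which keeps null variables
    from gaining large overfitted coefficients.

    ``selection_rule="parsimonious"`` (default) returns the smallest retained
    set whose RMSECV lies within one standard error of the trajectory
    minimum (the 1-SE rule); ``"argmin"`` returns the strict minimizer.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n_iterations < 2:
        raise ValueError("need at least two iterations")
    if pN is None:
        pN = 2.0 / p
    rng = np.random.default_rng(seed)
    # autoscale for scale-free coefficient ranking
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    current = np.arange(p)
    n_mc = max(2, int(round(mc_rate * n)))
    # LV count for coefficient ranking: CV-optimal on the full spectrum,
    # then refreshed from each iteration's retained-set CV
    _, rank_lv = pls_rmsecv(X, y, max_lv=min(max_lv, p, n - 2), folds=folds, seed=seed)
    retained_sets: list[np.ndarray] = []
    rmsecv_traj: list[float] = []
    fold_traj: list[np.ndarray] = []
    counts: list[int] = []
    for i in range(1, n_iterations + 1):
        if current.size < 2:
            break
        rows = rng.choice(n, size=n_mc, replace=False)
        lv = min(rank_lv, current.size, n_mc - 1)
        coefs, _, _ = pls_coefficient_path(Xs[rows][:, current], y[rows], lv)
        w = np.abs(coefs[lv - 1])
        # EDF: the retention count decays from p toward 2 over the run; the
        # top-|b| variables survive, never more than currently retained
        n_draw = max(2, int(round(edf_ratio(i, n_iterations, p0, pN) * p)))
        n_keep = min(current.size, n_draw)
        top = np.argsort(-w, kind="stable")[:n_keep]
        kept = current[np.sort(top)]
        w_kept = w[np.sort(top)]
        # ARS: n_draw weighted draws with replacement; unique survivors go
        # forward (when n_draw >> |kept| almost all of them survive, so the
        # retained counts track the EDF curve)
        if w_kept.sum() <= 0:
            probs = np.full(kept.size, 1.0 / kept.size)
        else:
            probs = w_kept / w_kept.sum()
        drawn = rng.choice(kept.size, size=n_draw, replace=True, p=probs)
        survivors = kept[np.unique(drawn)]
        if survivors.size < 2:
            survivors = kept[np.argsort(-w_kept, kind="stable")[:2]]
        current = np.sort(survivors)
        rmse, best_lv, fold_rmse = pls_rmsecv(
            X[:, current], y, max_lv=min(max_lv, current.size),
            folds=folds, seed=seed, return_folds=True,
        )
        rank_lv = best_lv
        retained_sets.append(current.copy())
        rmsecv_traj.append(float(rmse.min()))
        fold_traj.append(fold_rmse[:, best_lv - 1])
        counts.append(current.size)

    if not retained_sets:
        raise RuntimeError("CARS terminated before any valid iteration")
    argmin_it = int(np.argmin(rmsecv_traj))
    if selection_rule == "argmin":
        best_it = argmin_it
    elif selection_rule == "parsimonious":
        # classic 1-SE rule: smallest retained set whose RMSECV is within one
        # standard error (between-fold spread at the minimizer) of the minimum
        ref = fold_traj[argmin_it]
        thr = rmsecv_traj[argmin_it] + float(ref.std(ddof=1) / np.sqrt(ref.size))
        best_it = argmin_it
        for i in range(len(retained_sets)):
            if rmsecv_traj[i] <= thr and counts[i] <= counts[best_it]:
                best_it = i
    else:
        raise ValueError(f"unknown selection rule {selection_rule!r}")
    selected = retained_sets[best_it]
    wn = None if wavenumbers is None else np.asarray(wavenumbers, dtype=float)[selected]
    return CARSResult(
        selected_indices=selected,
        selected_wavenumbers=wn,
        rmsecv_trajectory=np.asarray(rmsecv_traj),
        retained_counts=np.asarray(counts),
        best_iteration=best_it + 1,
        seed=seed,
        retained_sets=retained_sets,
    )


@dataclass
class CARSEnsemble:
    """Stability-selected wavelengths from repeated CARS runs."""

    selected_indices: np.ndarray
    selected_wavenumbers: np.ndarray | None
    votes: np.ndarray
    runs: list


def ensemble_cars(
    X,
    y,
    n_runs: int = 8,
    min_votes: int = 3,
    window: int = 3,
    seed: int = 0,
    wavenumbers=None,
    **cars_kwargs,
) -> CARSEnsemble:
    """Repeat CARS with different Monte-Carlo seeds and report one channel
    per stably selected band region.

    A single CARS run is a stochastic draw from a broad RMSECV plateau: runs
    agree on band *regions* but land on different channels within a band.
    Each run therefore votes for a ``window``-channel neighborhood around its
    selections; contiguous regions with at least ``min_votes`` votes survive,
    and each region is represented by the apex of the mean spectrum inside it
    (the band position an analyst reports).  The result is the consolidated
    characteristic-wavelength list.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    votes = np.zeros(p, dtype=int)
    exact = np.zeros(p, dtype=int)
    runs = []
    for k in range(n_runs):
        res = cars_run(X, y, seed=seed + k, wavenumbers=wavenumbers, **cars_kwargs)
        support = np.zeros(p, dtype=bool)
        for j in res.selected_indices:
            support[max(0, j - window): j + window + 1] = True
        votes += support
        exact[res.selected_indices] += 1
        runs.append(res)

    mask = votes >= min_votes
    mean_spectrum = X.mean(axis=0)
    selected: list[int] = []
    j = 0
    while j < p:
        if not mask[j]:
            j += 1
            continue
        j0 = j
        while j < p and mask[j]:
            j += 1
        region = np.arange(j0, j)
        selected.append(int(region[np.argmax(mean_spectrum[region])]))
    if len(selected) < 2:
        # degenerate consensus: fall back to the best single run
        best = min(runs, key=lambda r: float(r.rmsecv_trajectory.min()))
        selected = list(best.selected_indices)
    sel = np.asarray(sorted(selected), dtype=int)
    wn = None if wavenumbers is None else np.asarray(wavenumbers, dtype=float)[sel]
    return CARSEnsemble(
        selected_indices=sel,
        selected_wavenumbers=wn,
        votes=votes,
        runs=runs,
    )


def secondary_screen(X_aug, y_aug, seed: int = 0, **cars_kwargs) -> CARSResult:
    """Re-run CARS on an augmented (multi-matrix) training set.

    With zero added samples this is exactly ``cars_run`` on the base set.
    """
    return cars_run(X_aug, y_aug, seed=seed, **cars_kwargs)
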