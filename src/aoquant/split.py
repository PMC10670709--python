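"""Sample-set partitioning: SPXY split, stratified random test selection and
the groups-of-five training-set augmentation schedule.

SPXY (sample-set partitioning based on joint X-Y distances) deterministically
picks a calibration set by max-min selection on the joint distance
``d(i,j) = d_X(i,j)/max(d_X) + d_y(i,j)/max(d_y)`` with Euclidean distance in
spectral space and absolute difference in concentration.  Setting the y part
to zero recovers Kennard-Stone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SplitResult",
    "AugmentationStep",
    "spxy_split",
    "random_test_select",
    "augmentation_schedule",
]


@dataclass(frozen=True)
class SplitResult:
    calibration_ids: tuple
    test_ids: tuple


@dataclass(frozen=True)
class AugmentationStep:
    step_index: int
    added_saffron: int
    added_curcuma: int
    training_ids: tuple


def _joint_distance(X: np.ndarray, y: np.ndarray | None, y_weight: float) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    dX = np.sqrt((diff**2).sum(axis=2))
    mx = dX.max()
    if mx == 0 and (y is None or y_weight == 0):
        raise ValueError("all samples identical: SPXY distances degenerate")
    d = dX / mx if mx > 0 else np.zeros_like(dX)
    if y is not None and y_weight != 0:
        dy = np.abs(y[:, None] - y[None, :])
        my = dy.max()
        if my > 0:
            d = d + y_weight * dy / my
        elif mx == 0:
            raise ValueError("all samples identical: SPXY distances degenerate")
    return d


def spxy_split(
    X,
    y=None,
    calib_fraction: float = 0.7,
    y_weight: float = 1.0,
) -> SplitResult:
    """SPXY max-min calibration/test split; deterministic.

    Seeds the calibration set with the pair at maximum joint distance, then
    repeatedly adds the sample whose minimum distance to the selected set is
    largest, until the calibration set holds ``round(calib_fraction * n)``
    samples.  Ties break to the lowest sample index.  Ids returned are row
    indices into ``X``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two samples")
    if not 0.0 < calib_fraction < 1.0:
        raise ValueError("calibration fraction must lie strictly in (0, 1)")
    n = X.shape[0]
    yv = None if y is None else np.asarray(y, dtype=float)
    d = _joint_distance(X, yv, y_weight)
    n_cal = int(round(calib_fraction * n))
    n_cal = min(max(n_cal, 2), n - 1)

    flat = np.argmax(d)  # first occurrence = lowest (i, j) in row-major order
    i, j = divmod(int(flat), n)
    selected = [min(i, j), max(i, j)]
    if n_cal == 1:
        # forced two-sample case: calibration keeps the first of the pair
        return SplitResult(
            calibration_ids=(selected[0],),
            test_ids=tuple(k for k in range(n) if k != selected[0]),
        )
    in_sel = np.zeros(n, dtype=bool)
    in_sel[selected] = True
    min_d = np.minimum(d[selected[0]], d[selected[1]])
    while len(selected) < n_cal:
        masked = np.where(in_sel, -np.inf, min_d)
        nxt = int(np.argmax(masked))  # argmax takes the lowest index on ties
        selected.append(nxt)
        in_sel[nxt] = True
        min_d = np.minimum(min_d, d[nxt])
    test = [k for k in range(n) if not in_sel[k]]
    return SplitResult(calibration_ids=tuple(selected), test_ids=tuple(test))


def random_test_select(y, n_test: int, seed: int = 0, sample_ids=None) -> SplitResult:
    """Random test-set draw stratified over concentration levels.

    Every level contributes at least one test sample; allocation is
    proportional to level frequency with the remainder going to the lowest
    concentrations first.  Reproducible from ``seed``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n_test > n:
        raise ValueError("n_test exceeds pool size")
    ids = np.arange(n) if sample_ids is None else np.asarray(sample_ids, dtype=object)
    levels = np.unique(y)  # ascending
    if n_test < len(levels):
        raise ValueError(
            f"n_test={n_test} cannot cover all {len(levels)} concentration levels"
        )
    counts = {lv: int((y == lv).sum()) for lv in levels}
    alloc = {lv: max(1, math.floor(n_test * counts[lv] / n)) for lv in levels}
    # trim overshoot from the largest allocations, then hand the remainder to
    # the lowest concentrations first
    while sum(alloc.values()) > n_test:
        biggest = max(levels, key=lambda lv: (alloc[lv], lv))
        alloc[biggest] -= 1
    k = 0
    while sum(alloc.values()) < n_test:
        lv = levels[k % len(levels)]
        if alloc[lv] < counts[lv]:
            alloc[lv] += 1
        k += 1
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for lv in levels:
        pool = np.flatnonzero(y == lv)
        take = rng.choice(pool, size=alloc[lv], replace=False)
        test_idx.extend(int(t) for t in np.sort(take))
    test_set = set(test_idx)
    rest = [k for k in range(n) if k not in test_set]
    return SplitResult(
        calibration_ids=tuple(ids[k] for k in rest),
        test_ids=tuple(ids[k] for k in test_idx),
    )


def augmentation_schedule(
    saffron_pool,
    curcuma_pool,
    base_ids,
    group_size: int = 5,
) -> list[AugmentationStep]:
    """Groups-of-five augmentation: step k adds the first ``group_size * k``
    samples of each target-matrix pool (ordered low-to-high concentration) to
    the base calibration ids; the final step absorbs any unequal remainder so
    all pool members are used.
    """
    base = tuple(base_ids)
    if not base:
        raise ValueError("base calibration set must not be empty")
    s = list(saffron_pool)
    c = list(curcuma_pool)
    n_steps = max(
        math.ceil(len(s) / group_size),
        math.ceil(len(c) / group_size),
    )
    steps = []
    for k in range(1, n_steps + 1):
        ns = min(group_size * k, len(s))
        nc = min(group_size * k, len(c))
        steps.append(
            AugmentationStep(
                step_index=k,
                added_saffron=ns,
                added_curcuma=nc,
                training_ids=base + tuple(s[:ns]) + tuple(c[:nc]),
            )
        )
    return steps
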