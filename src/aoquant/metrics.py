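"""Model evaluation metrics and detection/quantification limits.

R^2 = 1 - SS_res / SS_tot.  The root-mean-square errors (RMSEC on the
calibration set, RMSEP on the test set) use an (n-1) denominator by default —
the convention of the source tables — with the plain 1/n variant available
via ``denominator="n"``; the two differ by the factor sqrt(n/(n-1)).

LOD and LOQ follow the three-times-noise principle: LOD = 3*sigma/S with
sigma the intensity noise in a signal-free spectral window and S the
low-concentration sensitivity (slope of the 778 cm^-1 band height vs
concentration).  The default LOQ factor of 9 makes LOQ = 3*LOD; the
conventional 10-sigma LOQ is available by passing ``loq_factor=10``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import SpectrumGrid

__all__ = [
    "EvalReport",
    "r_squared",
    "rmsep",
    "rmsec",
    "lod_loq",
    "estimate_noise_sd",
    "peak_height",
    "estimate_sensitivity",
]


@dataclass
class EvalReport:
    model: str
    preprocessing: str
    r2_c: float
    rmsec: float
    r2_p: float
    rmsep: float
    n_cal: int
    n_test: int

    def as_row(self) -> dict:
        return {
            "model": self.model,
            "preprocessing": self.preprocessing,
            "n_cal": self.n_cal,
            "n_test": self.n_test,
            "R2_c": self.r2_c,
            "RMSEC": self.rmsec,
            "R2_p": self.r2_p,
            "RMSEP": self.rmsep,
        }


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (may be negative)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant y_true")
    ss_res = float(((y_true - y_pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def rmsep(y_true, y_pred, denominator: str = "n-1") -> float:
    """Root-mean-square error of prediction, (n-1) denominator by default."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    n = y_true.size
    if n < 2:
        raise ValueError("need at least two observations")
    sse = float(((y_true - y_pred) ** 2).sum())
    if denominator == "n-1":
        return np.sqrt(sse / (n - 1))
    if denominator == "n":
        return np.sqrt(sse / n)
    raise ValueError(f"unknown denominator {denominator!r}")


def rmsec(y_true, y_pred, denominator: str = "n-1") -> float:
    """Root-mean-square error of calibration (same formula as rmsep)."""
    return rmsep(y_true, y_pred, denominator=denominator)


def lod_loq(noise_sd: float, sensitivity: float, loq_factor: float = 9.0) -> tuple[float, float]:
    """(LOD, LOQ) in mg/mL from noise and sensitivity.

    LOD = 3*noise_sd/sensitivity; LOQ = loq_factor*noise_sd/sensitivity.
    """
    if sensitivity <= 0:
        raise ValueError("sensitivity must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    return 3.0 * noise_sd / sensitivity, loq_factor * noise_sd / sensitivity


def estimate_noise_sd(X, grid: SpectrumGrid, window: tuple[float, float] = (1700.0, 1800.0)) -> float:
    """Noise level from a signal-free window: per-spectrum sd of the
    linearly detrended intensities, averaged over spectra."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    w = grid.wavenumbers
    mask = (w >= window[0]) & (w <= window[1])
    if mask.sum() < 3:
        raise ValueError("noise window holds fewer than three grid points")
    u = w[mask]
    sds = []
    for row in X:
        seg = row[mask]
        coef = np.polyfit(u, seg, 1)
        sds.append(np.std(seg - np.polyval(coef, u), ddof=1))
    return float(np.mean(sds))


def peak_height(spectrum, grid: SpectrumGrid, center: float = 778.0, halfwidth: float = 10.0) -> float:
    """Maximum intensity within ``center +/- halfwidth``."""
    spectrum = np.asarray(spectrum, dtype=float)
    w = grid.wavenumbers
    mask = (w >= center - halfwidth) & (w <= center + halfwidth)
    if not mask.any():
        raise ValueError("band window falls outside the grid")
    return float(spectrum[mask].max())


def estimate_sensitivity(
    X,
    concentrations,
    grid: SpectrumGrid,
    center: float = 778.0,
    max_conc: float = 0.01,
) -> float:
    """Low-concentration slope (intensity per mg/mL) of the diagnostic band.

    Fits a line to band height vs concentration over samples with
    concentration <= ``max_conc`` (the linear regime of the Langmuir
    response), including any blanks.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    c = np.asarray(concentrations, dtype=float)
    mask = c <= max_conc
    if mask.sum() < 2 or np.unique(c[mask]).size < 2:
        raise ValueError("need at least two distinct low concentrations")
    heights = np.array([peak_height(row, grid, center=center) for row in X[mask]])
    slope = np.polyfit(c[mask], heights, 1)[0]
    return float(slope)
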