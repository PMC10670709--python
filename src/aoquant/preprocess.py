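"""Spectral preprocessing: SG smoothing, airPLS baseline removal, SNV, MSC.

The transforms operate on 1-D spectra or sample x wavenumber matrices and can
be composed into chains such as ``airPLS+SG+MSC``.  MSC is the only transform
with set-level state (the reference spectrum); a fitted chain therefore
carries the calibration-set reference so test spectra are corrected without
leaking test statistics into the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

__all__ = [
    "DegenerateSpectrumError",
    "sg_smooth",
    "airpls",
    "airpls_baseline",
    "snv",
    "msc",
    "ChainSpec",
    "PreprocessingChain",
    "parse_chain",
    "apply_chain",
]

KNOWN_TRANSFORMS = ("airPLS", "SG", "SNV", "MSC")


class DegenerateSpectrumError(ValueError):
    """Raised for inputs a transform cannot meaningfully process."""


def _as_matrix(x) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        return arr[None, :], True
    if arr.ndim == 2:
        return arr, False
    raise ValueError("expected a 1-D spectrum or 2-D sample x wavenumber matrix")


def sg_smooth(x, window: int = 7, order: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing.

    Interior points take the value of the local least-squares polynomial;
    edges are evaluated from the polynomial fitted to the terminal window, so
    polynomials of degree <= ``order`` are reproduced exactly everywhere.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if order >= window:
        raise ValueError(f"order ({order}) must be smaller than window ({window})")
    X, was_1d = _as_matrix(x)
    if X.shape[1] < window:
        raise ValueError("spectrum shorter than the smoothing window")
    out = savgol_filter(X, window_length=window, polyorder=order, axis=1, mode="interp")
    return out[0] if was_1d else out


def _whittaker_smooth(x: np.ndarray, w: np.ndarray, lam: float, D: sparse.csc_matrix) -> np.ndarray:
    W = sparse.diags(w)
    A = sparse.csc_matrix(W + lam * (D.T @ D))
    return spsolve(A, w * x)


def _diff_matrix(n: int, order: int) -> sparse.csc_matrix:
    D = sparse.eye(n, format="csc")
    for _ in range(order):
        D = D[1:] - D[:-1]
    return sparse.csc_matrix(D)


def airpls(
    x,
    lam: float = 1e5,
    max_iter: int = 30,
    tol: float = 1e-3,
    diff_order: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive iteratively reweighted penalized least-squares baseline.

    Each iteration solves the weighted Whittaker problem
    ``min_z sum_i w_i (x_i - z_i)^2 + lam * sum_j (Delta^d z_j)^2`` and then
    re-weights: points at or above the baseline get weight 0, points below get
    ``exp(t * |x_i - z_i| / |d|)`` where ``d`` collects the negative residuals
    of iteration ``t``.  Stops when ``|d| < tol * |x|``.

    Returns ``(baseline, corrected)`` with ``corrected = x - baseline``.
    ``diff_order=2`` (default) reproduces straight-line baselines exactly;
    ``diff_order=1`` penalizes first differences instead.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if diff_order not in (1, 2):
        raise ValueError("diff_order must be 1 or 2")
    X, was_1d = _as_matrix(x)
    n = X.shape[1]
    D = _diff_matrix(n, diff_order)
    baselines = np.empty_like(X)
    for row in range(X.shape[0]):
        xi = X[row]
        w = np.ones(n)
        abs_x = np.abs(xi).sum()
        z = np.zeros(n)
        for t in range(1, max_iter + 1):
            z = _whittaker_smooth(xi, w, lam, D)
            d = xi - z
            neg = d < 0
            dssn = np.abs(d[neg]).sum()
            if dssn < tol * abs_x or abs_x == 0.0:
                break
            w = np.zeros(n)
            # exponential up-weighting of points below the current baseline
            w[neg] = np.exp(t * np.abs(d[neg]) / dssn)
        baselines[row] = z
    corrected = X - baselines
    if was_1d:
        return baselines[0], corrected[0]
    return baselines, corrected


def airpls_baseline(x, **kwargs) -> np.ndarray:
    """Convenience: the airPLS-corrected spectrum only."""
    return airpls(x, **kwargs)[1]


def snv(x) -> np.ndarray:
    """Standard normal variate: per-spectrum centering and unit-sd scaling.

    Uses the (m-1)-denominator standard deviation.  Constant spectra are
    degenerate (zero variance) and rejected.
    """
    X, was_1d = _as_matrix(x)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd <= 0):
        raise DegenerateSpectrumError("SNV undefined for a constant spectrum")
    out = (X - mean) / sd
    return out[0] if was_1d else out


def msc(X, reference: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative scatter correction against a reference spectrum.

    Each sample is regressed on the reference by ordinary least squares
    (``x_i = k_i * ref + b_i``) and corrected as ``(x_i - b_i) / k_i``.  With
    ``reference=None`` the set mean is used (requires >= 2 samples).  Returns
    ``(corrected, reference)``; keep the reference to correct later test sets.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("MSC expects a sample x wavenumber matrix")
    if reference is None:
        if X.shape[0] < 2:
            raise ValueError("mean-reference MSC needs at least two samples")
        reference = X.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    ref_centered = reference - reference.mean()
    denom = float(ref_centered @ ref_centered)
    if denom <= 0:
        raise DegenerateSpectrumError("MSC reference must not be constant")
    k = (X - X.mean(axis=1, keepdims=True)) @ ref_centered / denom
    if np.any(np.abs(k) < 1e-12):
        raise DegenerateSpectrumError("sample uncorrelated with MSC reference")
    b = X.mean(axis=1) - k * reference.mean()
    corrected = (X - b[:, None]) / k[:, None]
    return corrected, reference


@dataclass(frozen=True)
class ChainSpec:
    """Ordered list of transform names from {airPLS, SG, SNV, MSC}."""

    steps: tuple[str, ...]

    def __post_init__(self) -> None:
        for s in self.steps:
            if s not in KNOWN_TRANSFORMS:
                raise ValueError(f"unknown transform {s!r}")
        if len(set(self.steps)) != len(self.steps):
            raise ValueError("each transform may appear at most once in a chain")

    @property
    def label(self) -> str:
        return " + ".join(self.steps) if self.steps else "none"


def parse_chain(text: str) -> ChainSpec:
    """Parse ``"airPLS+SG+MSC"`` (also accepts ``" + "`` separators)."""
    steps = tuple(s.strip() for s in text.replace(" ", "").split("+") if s.strip())
    return ChainSpec(steps)


@dataclass
class PreprocessingChain:
    """A fittable transform chain.

    ``fit_transform`` learns any set-level statistics (the MSC reference) on
    the calibration matrix; ``transform`` reuses them on new spectra.
    """

    spec: ChainSpec
    lam: float = 1e5
    window: int = 7
    order: int = 2
    diff_order: int = 2
    msc_reference: np.ndarray | None = field(default=None, repr=False)

    def _run(self, X: np.ndarray, fit: bool) -> np.ndarray:
        out = np.asarray(X, dtype=float)
        for step in self.spec.steps:
            if step == "airPLS":
                out = airpls(out, lam=self.lam, diff_order=self.diff_order)[1]
            elif step == "SG":
                out = sg_smooth(out, window=self.window, order=self.order)
            elif step == "SNV":
                out = snv(out)
            elif step == "MSC":
                if fit:
                    out, self.msc_reference = msc(out)
                else:
                    if self.msc_reference is None:
                        raise RuntimeError("chain with MSC must be fitted first")
                    out, _ = msc(out, reference=self.msc_reference)
        return out

    def fit_transform(self, X) -> np.ndarray:
        return self._run(np.atleast_2d(np.asarray(X, dtype=float)), fit=True)

    def transform(self, X) -> np.ndarray:
        return self._run(np.atleast_2d(np.asarray(X, dtype=float)), fit=False)


def apply_chain(
    X,
    chain: ChainSpec | str,
    fitted_context: PreprocessingChain | None = None,
    **params,
) -> tuple[np.ndarray, PreprocessingChain]:
    """Apply a transform chain to a spectra matrix.

    Without a ``fitted_context`` the chain is fitted on ``X`` (calibration
    use); with one, the stored calibration statistics are reused (test use).
    Returns ``(transformed, fitted_context)``.
    """
    if fitted_context is not None:
        return fitted_context.transform(X), fitted_context
    spec = parse_chain(chain) if isinstance(chain, str) else chain
    ctx = PreprocessingChain(spec=spec, **params)
    return ctx.fit_transform(X), ctx
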