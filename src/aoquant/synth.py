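"""Synthetic SERS spectrum generation for Auramine O (AO) adulteration studies.

The experimental spectra this pipeline was designed around are not publicly
deposited, so this module generates surface-enhanced Raman spectra with the
same statistical structure: a shared 400-1800 cm^-1 wavenumber grid, AO
characteristic bands whose height follows a Langmuir-type adsorption response
in dye concentration, a herb-specific background (matrix bands plus a smooth
fluorescence baseline), small matrix-dependent shifts of the AO bands, and
additive Gaussian noise.

Three default matrix profiles emulate *Dendrobium officinale*, *Saffron* and
*Curcuma* analogs.  The *Saffron* profile shifts the diagnostic C-N-C
deformation band 778 -> 781 cm^-1 (plus 1353 -> 1363 and 1635 -> 1657); the
*Curcuma* profile shifts 778 -> 811 cm^-1.  These shifts, not enhancement
differences, carry the cross-matrix calibration-transfer difficulty studied
by the experiments module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumGrid",
    "PeakSpec",
    "MatrixProfile",
    "SpectralDataset",
    "StudyDesign",
    "build_grid",
    "ao_response",
    "ao_component",
    "simulate_spectrum",
    "simulate_study",
    "default_profiles",
    "default_design",
    "AURAMINE_O_SOLUTION_BANDS",
    "AO_HERB_BANDS",
    "CONCENTRATIONS_MG_PER_ML",
]

#: Six spiking concentrations of the AO dye solutions (mg/mL).
CONCENTRATIONS_MG_PER_ML = (0.500, 0.100, 0.050, 0.010, 0.005, 0.001)

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class SpectrumGrid:
    """Uniform wavenumber grid, inclusive of ``start``, last point <= ``stop``."""

    start: float = 400.0
    stop: float = 1800.0
    step: float = 2.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"grid step must be positive, got {self.step}")
        if self.start >= self.stop:
            raise ValueError(
                f"grid start must be below stop, got [{self.start}, {self.stop}]"
            )

    @property
    def n_points(self) -> int:
        return int(math.floor((self.stop - self.start) / self.step)) + 1

    @property
    def wavenumbers(self) -> np.ndarray:
        return float(self.start) + float(self.step) * np.arange(self.n_points)

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point closest to ``wavenumber``."""
        idx = int(round((wavenumber - self.start) / self.step))
        return min(max(idx, 0), self.n_points - 1)


def build_grid(start: float, stop: float, step: float) -> SpectrumGrid:
    """Build a uniform wavenumber grid (default spectral range 400-1800 cm^-1)."""
    return SpectrumGrid(start=start, stop=stop, step=step)


@dataclass(frozen=True)
class PeakSpec:
    """A Gaussian band: center (cm^-1), FWHM (cm^-1), relative amplitude."""

    center: float
    fwhm: float
    rel_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("peak FWHM must be positive")
        if self.rel_amplitude < 0:
            raise ValueError("peak amplitude must be non-negative")

    def profile(self, wavenumbers: np.ndarray, center: float | None = None) -> np.ndarray:
        c = self.center if center is None else center
        sigma = self.fwhm * FWHM_TO_SIGMA
        return self.rel_amplitude * np.exp(-0.5 * ((wavenumbers - c) / sigma) ** 2)


#: Raman bands of the AO standard solution (band assignment table): C-H
#: stretches at 551/649, H-C-H deformation at 735, the diagnostic C-N-C
#: deformation at 778, C-C stretch at 1189, ring stretches at 1438/1481 and
#: the C-N twist at 1598 cm^-1.
AURAMINE_O_SOLUTION_BANDS: tuple[PeakSpec, ...] = (
    PeakSpec(551.0, 10.0, 0.55),
    PeakSpec(649.0, 10.0, 0.50),
    PeakSpec(735.0, 10.0, 0.30),
    PeakSpec(778.0, 8.0, 1.00),
    PeakSpec(1189.0, 12.0, 0.45),
    PeakSpec(1438.0, 12.0, 0.40),
    PeakSpec(1481.0, 12.0, 0.30),
    PeakSpec(1598.0, 12.0, 0.60),
)

#: Shared in-herb AO band positions (slightly shifted from the solution bands
#: by adsorption on the herb surface); 778 cm^-1 remains the strongest
#: diagnostic band.  Matrix profiles move individual centers via ao_shift_map.
AO_HERB_BANDS: tuple[PeakSpec, ...] = (
    PeakSpec(452.0, 12.0, 0.35),
    PeakSpec(551.0, 12.0, 0.50),
    PeakSpec(649.0, 12.0, 0.45),
    PeakSpec(778.0, 12.0, 1.00),
    PeakSpec(1195.0, 12.0, 0.40),
    PeakSpec(1353.0, 12.0, 0.30),
    PeakSpec(1444.0, 12.0, 0.40),
    PeakSpec(1553.0, 12.0, 0.30),
    PeakSpec(1635.0, 12.0, 0.45),
)

_MAX_SHIFT = 40.0  # cm^-1; adsorption shifts larger than this are unphysical here


@dataclass(frozen=True)
class MatrixProfile:
    """Generative parameters of one herb matrix.

    ``response_a`` and ``response_b`` parameterize the Langmuir-type
    concentration response a*c/(1 + b*c) of the AO band amplitude (physisorbed
    cationic dye on citrate AgNPs saturates the available hot spots).
    ``baseline_poly`` are coefficients (c0, c1, c2) in the reduced coordinate
    u = (w - start)/(stop - start); the broad hump emulates residual matrix
    fluorescence.  ``scatter_sd`` is the sd of the per-sample multiplicative
    intensity factor (droplet geometry / hot-spot density variation — the
    effect MSC and SNV exist to correct), ``baseline_jitter_sd`` the relative
    per-sample variation of the baseline amplitude, and ``background_jitter_sd``
    the relative per-sample variation of each matrix band (herb composition
    differs sample to sample).  ``ao_band_jitter_sd`` adds independent
    per-sample relative variation to each AO band's height: the SERS
    enhancement of different vibrational modes fluctuates with adsorption
    geometry, so band heights are strongly but not perfectly correlated.
    """

    name: str
    background_peaks: tuple[PeakSpec, ...] = ()
    ao_shift_map: tuple[tuple[float, float], ...] = ()
    ao_peaks: tuple[PeakSpec, ...] = AO_HERB_BANDS
    baseline_poly: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hump_amplitude: float = 0.0
    hump_center: float = 1100.0
    hump_fwhm: float = 600.0
    noise_sd: float = 1.0
    response_a: float = 100.0
    response_b: float = 0.5
    scatter_sd: float = 0.08
    baseline_jitter_sd: float = 0.2
    background_jitter_sd: float = 0.3
    ao_band_jitter_sd: float = 0.12

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.response_a <= 0:
            raise ValueError("response_a must be positive")
        if self.response_b < 0:
            raise ValueError("response_b must be non-negative")
        for center, shifted in self.ao_shift_map:
            if abs(shifted - center) > _MAX_SHIFT:
                raise ValueError(
                    f"shift {center}->{shifted} exceeds {_MAX_SHIFT} cm^-1"
                )

    def shifted_center(self, center: float) -> float:
        for c, s in self.ao_shift_map:
            if c == center:
                return s
        return center

    def without_shifts(self) -> "MatrixProfile":
        return replace(self, ao_shift_map=())


def default_profiles() -> dict[str, MatrixProfile]:
    """The three default herb-matrix analogs.

    Background bands are mutually disjoint across matrices and kept clear of
    every AO band and of the signal-free 1700-1800 cm^-1 noise window.
    """
    return {
        "dendrobium": MatrixProfile(
            name="dendrobium",
            background_peaks=(
                PeakSpec(612.0, 30.0, 10.0),
                PeakSpec(938.0, 36.0, 14.0),
                PeakSpec(1262.0, 30.0, 8.0),
            ),
            ao_shift_map=(),
            baseline_poly=(5.0, 8.0, -4.0),
            hump_amplitude=12.0,
        ),
        "saffron": MatrixProfile(
            name="saffron",
            background_peaks=(
                PeakSpec(508.0, 28.0, 9.0),
                PeakSpec(872.0, 34.0, 12.0),
                PeakSpec(1090.0, 30.0, 8.0),
            ),
            ao_shift_map=((778.0, 781.0), (1353.0, 1363.0), (1635.0, 1657.0)),
            baseline_poly=(8.0, -3.0, 6.0),
            hump_amplitude=18.0,
            response_a=80.0,
        ),
        "curcuma": MatrixProfile(
            name="curcuma",
            background_peaks=(
                PeakSpec(690.0, 30.0, 11.0),
                PeakSpec(1020.0, 34.0, 9.0),
                PeakSpec(1318.0, 28.0, 7.0),
            ),
            ao_shift_map=((778.0, 811.0),),
            baseline_poly=(6.0, 5.0, 2.0),
            hump_amplitude=9.0,
            response_a=80.0,
        ),
    }


def ao_response(conc: float, profile: MatrixProfile) -> float:
    """Langmuir-type AO band amplitude a*c/(1 + b*c); linear limit at b=0."""
    if conc < 0:
        raise ValueError(f"concentration must be non-negative, got {conc}")
    return profile.response_a * conc / (1.0 + profile.response_b * conc)


def ao_component(
    conc: float,
    profile: MatrixProfile,
    grid: SpectrumGrid,
    band_factors: np.ndarray | None = None,
) -> np.ndarray:
    """Noise-free AO-only signal: shifted Gaussian bands scaled by ao_response."""
    w = grid.wavenumbers
    amp = ao_response(conc, profile)
    signal = np.zeros_like(w)
    for k, peak in enumerate(profile.ao_peaks):
        f = 1.0 if band_factors is None else band_factors[k]
        signal += f * amp * peak.profile(w, center=profile.shifted_center(peak.center))
    return signal


def _background(
    profile: MatrixProfile,
    grid: SpectrumGrid,
    amp_factors: np.ndarray | None = None,
) -> np.ndarray:
    w = grid.wavenumbers
    out = np.zeros_like(w)
    for k, peak in enumerate(profile.background_peaks):
        f = 1.0 if amp_factors is None else amp_factors[k]
        out += f * peak.profile(w)
    return out


def _baseline(profile: MatrixProfile, grid: SpectrumGrid) -> np.ndarray:
    w = grid.wavenumbers
    u = (w - grid.start) / (grid.stop - grid.start)
    c0, c1, c2 = profile.baseline_poly
    base = c0 + c1 * u + c2 * u**2
    if profile.hump_amplitude:
        sigma = profile.hump_fwhm * FWHM_TO_SIGMA
        base = base + profile.hump_amplitude * np.exp(
            -0.5 * ((w - profile.hump_center) / sigma) ** 2
        )
    return base


def simulate_spectrum(
    conc: float,
    profile: MatrixProfile,
    rng_seed: int | np.random.Generator,
    grid: SpectrumGrid | None = None,
) -> np.ndarray:
    """One SERS trace: AO bands + matrix background + baseline + noise.

    Deterministic given the seed (or the state of a passed Generator).
    """
    if grid is None:
        grid = SpectrumGrid()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    # per-sample multiplicative scatter, baseline and matrix-band jitter
    scatter = max(1.0 + rng.normal(0.0, profile.scatter_sd), 0.1) if profile.scatter_sd > 0 else 1.0
    bjit = max(1.0 + rng.normal(0.0, profile.baseline_jitter_sd), 0.0) if profile.baseline_jitter_sd > 0 else 1.0
    n_bg = len(profile.background_peaks)
    if profile.background_jitter_sd > 0 and n_bg:
        amp_factors = np.clip(1.0 + rng.normal(0.0, profile.background_jitter_sd, n_bg), 0.0, None)
    else:
        amp_factors = np.ones(n_bg)
    n_ao = len(profile.ao_peaks)
    if profile.ao_band_jitter_sd > 0 and n_ao:
        # weaker modes have less reproducible enhancement: jitter scales
        # inversely with the square root of the relative band strength
        rel = np.array([pk.rel_amplitude for pk in profile.ao_peaks])
        sds = profile.ao_band_jitter_sd / np.sqrt(np.clip(rel, 1e-3, None))
        band_factors = np.clip(1.0 + rng.normal(0.0, 1.0, n_ao) * sds, 0.0, None)
    else:
        band_factors = np.ones(n_ao)
    intensity = scatter * (
        ao_component(conc, profile, grid, band_factors)
        + _background(profile, grid, amp_factors)
        + bjit * _baseline(profile, grid)
    )
    if profile.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, profile.noise_sd, grid.n_points)
    return intensity


@dataclass
class SpectralDataset:
    """Spectra on a shared grid plus a per-sample manifest.

    manifest columns: ``sample_id``, ``matrix``, ``concentration_mg_per_ml``.
    """

    grid: SpectrumGrid
    intensities: np.ndarray
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D sample x wavenumber matrix")
        if self.intensities.shape[0] != len(self.manifest):
            raise ValueError("row count must equal manifest length")
        if self.intensities.shape[1] != self.grid.n_points:
            raise ValueError("column count must equal grid size")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.manifest["sample_id"])

    @property
    def concentrations(self) -> np.ndarray:
        return self.manifest["concentration_mg_per_ml"].to_numpy(dtype=float)

    def subset(self, sample_ids) -> "SpectralDataset":
        """Row subset by sample id, preserving the requested order."""
        pos = {sid: i for i, sid in enumerate(self.manifest["sample_id"])}
        idx = [pos[s] for s in sample_ids]
        return SpectralDataset(
            grid=self.grid,
            intensities=self.intensities[idx],
            manifest=self.manifest.iloc[idx].reset_index(drop=True),
        )

    def for_matrix(self, name: str) -> "SpectralDataset":
        mask = (self.manifest["matrix"] == name).to_numpy()
        return SpectralDataset(
            grid=self.grid,
            intensities=self.intensities[mask],
            manifest=self.manifest[mask].reset_index(drop=True),
        )


@dataclass(frozen=True)
class StudyDesign:
    """Per-matrix sample counts and the concentration replicate plan.

    The default reproduces the published set sizes: 100 D. officinale-like,
    85 Saffron-like and 90 Curcuma-like samples, with the six spiking levels
    cycled evenly over the samples of each matrix.
    """

    counts: tuple[tuple[str, int], ...] = (
        ("dendrobium", 100),
        ("saffron", 85),
        ("curcuma", 90),
    )
    concentrations: tuple[float, ...] = CONCENTRATIONS_MG_PER_ML
    grid: SpectrumGrid = field(default_factory=SpectrumGrid)

    def __post_init__(self) -> None:
        for name, n in self.counts:
            if n <= 0:
                raise ValueError(f"sample count for {name!r} must be positive")


def default_design() -> StudyDesign:
    return StudyDesign()


def simulate_study(
    design: StudyDesign | None = None,
    seed: int = 0,
    profiles: dict[str, MatrixProfile] | None = None,
) -> SpectralDataset:
    """Generate the full multi-matrix study dataset, reproducible from seed."""
    if design is None:
        design = default_design()
    if profiles is None:
        profiles = default_profiles()
    rng = np.random.default_rng(seed)
    rows = []
    spectra = []
    levels = design.concentrations
    for name, n in design.counts:
        if name not in profiles:
            raise KeyError(f"unknown matrix name {name!r}")
        profile = profiles[name]
        for j in range(n):
            conc = levels[j % len(levels)]
            spectra.append(simulate_spectrum(conc, profile, rng, design.grid))
            rows.append(
                {
                    "sample_id": f"{name}-{j:03d}",
                    "matrix": name,
                    "concentration_mg_per_ml": conc,
                }
            )
    return SpectralDataset(
        grid=design.grid,
        intensities=np.vstack(spectra),
        manifest=pd.DataFrame(rows),
    )
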