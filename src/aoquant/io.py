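"""On-disk formats: wide spectra CSV + sample manifest CSV + YAML configs.

Wide CSV dialect: first column ``wavenumber``, one column per sample id.
Manifest CSV columns: ``sample_id``, ``matrix``, ``concentration_mg_per_ml``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import MatrixProfile, PeakSpec, SpectralDataset, SpectrumGrid, StudyDesign

__all__ = [
    "write_wide_csv",
    "read_wide_csv",
    "write_split_csv",
    "read_split_csv",
    "load_study_config",
    "dump_study_config",
]


def write_wide_csv(dataset: SpectralDataset, spectra_path, manifest_path) -> None:
    wide = pd.DataFrame(
        dataset.intensities.T,
        columns=dataset.sample_ids,
    )
    wide.insert(0, "wavenumber", dataset.grid.wavenumbers)
    wide.to_csv(spectra_path, index=False)
    dataset.manifest.to_csv(manifest_path, index=False)


def read_wide_csv(spectra_path, manifest_path) -> SpectralDataset:
    wide = pd.read_csv(spectra_path)
    manifest = pd.read_csv(manifest_path)
    w = wide["wavenumber"].to_numpy(dtype=float)
    if len(w) < 2:
        raise ValueError("need at least two wavenumber rows")
    step = float(w[1] - w[0])
    if not np.allclose(np.diff(w), step):
        raise ValueError("wavenumber grid must be uniform")
    grid = SpectrumGrid(start=float(w[0]), stop=float(w[-1]), step=step)
    ids = list(manifest["sample_id"])
    intensities = wide[ids].to_numpy(dtype=float).T
    return SpectralDataset(grid=grid, intensities=intensities, manifest=manifest)


def write_split_csv(path, calibration_ids, test_ids) -> None:
    rows = [{"sample_id": s, "set": "calibration"} for s in calibration_ids]
    rows += [{"sample_id": s, "set": "test"} for s in test_ids]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_split_csv(path) -> tuple[list, list]:
    df = pd.read_csv(path)
    cal = list(df.loc[df["set"] == "calibration", "sample_id"])
    test = list(df.loc[df["set"] == "test", "sample_id"])
    return cal, test


def _peaks_from_cfg(items) -> tuple[PeakSpec, ...]:
    return tuple(
        PeakSpec(float(p["center"]), float(p["fwhm"]), float(p.get("rel_amplitude", 1.0)))
        for p in items
    )


def _profile_from_cfg(name: str, cfg: dict) -> MatrixProfile:
    kwargs = dict(name=name)
    if "background_peaks" in cfg:
        kwargs["background_peaks"] = _peaks_from_cfg(cfg["background_peaks"])
    if "ao_peaks" in cfg:
        kwargs["ao_peaks"] = _peaks_from_cfg(cfg["ao_peaks"])
    if "ao_shift_map" in cfg:
        kwargs["ao_shift_map"] = tuple(
            (float(c), float(s)) for c, s in dict(cfg["ao_shift_map"]).items()
        )
    for key in (
        "baseline_poly",
        "hump_amplitude",
        "hump_center",
        "hump_fwhm",
        "noise_sd",
        "response_a",
        "response_b",
    ):
        if key in cfg:
            val = cfg[key]
            kwargs[key] = tuple(float(v) for v in val) if key == "baseline_poly" else float(val)
    return MatrixProfile(**kwargs)


def load_study_config(path) -> tuple[StudyDesign, dict[str, MatrixProfile], int]:
    """Read a YAML study config: grid, design, matrix profiles, seed."""
    cfg = yaml.safe_load(Path(path).read_text())
    grid_cfg = cfg.get("grid", {})
    grid = SpectrumGrid(
        start=float(grid_cfg.get("start", 400.0)),
        stop=float(grid_cfg.get("stop", 1800.0)),
        step=float(grid_cfg.get("step", 2.0)),
    )
    profiles = {
        name: _profile_from_cfg(name, pcfg)
        for name, pcfg in cfg.get("profiles", {}).items()
    }
    counts = tuple((name, int(n)) for name, n in cfg.get("counts", {}).items())
    concs = tuple(float(c) for c in cfg.get("concentrations", []))
    design_kwargs = {"grid": grid}
    if counts:
        design_kwargs["counts"] = counts
    if concs:
        design_kwargs["concentrations"] = concs
    design = StudyDesign(**design_kwargs)
    return design, profiles, int(cfg.get("seed", 0))


def dump_study_config(path, design: StudyDesign, profiles: dict[str, MatrixProfile], seed: int) -> None:
    cfg = {
        "seed": seed,
        "grid": {
            "start": design.grid.start,
            "stop": design.grid.stop,
            "step": design.grid.step,
        },
        "counts": {name: n for name, n in design.counts},
        "concentrations": list(design.concentrations),
        "profiles": {
            p.name: {
                "background_peaks": [
                    {"center": pk.center, "fwhm": pk.fwhm, "rel_amplitude": pk.rel_amplitude}
                    for pk in p.background_peaks
                ],
                "ao_peaks": [
                    {"center": pk.center, "fwhm": pk.fwhm, "rel_amplitude": pk.rel_amplitude}
                    for pk in p.ao_peaks
                ],
                "ao_shift_map": {c: s for c, s in p.ao_shift_map},
                "baseline_poly": list(p.baseline_poly),
                "hump_amplitude": p.hump_amplitude,
                "hump_center": p.hump_center,
                "hump_fwhm": p.hump_fwhm,
                "noise_sd": p.noise_sd,
                "response_a": p.response_a,
                "response_b": p.response_b,
            }
            for p in profiles.values()
        },
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
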