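import numpy as np
import pytest
from dataclasses import replace

from aoquant import preprocess, select, synth


def noise_free(profile: synth.MatrixProfile) -> synth.MatrixProfile:
    """Strip every stochastic component from a matrix profile."""
    return replace(
        profile,
        noise_sd=0.0,
        scatter_sd=0.0,
        baseline_jitter_sd=0.0,
        background_jitter_sd=0.0,
        ao_band_jitter_sd=0.0,
    )


@pytest.fixture(scope="session")
def doff_dataset():
    """Default D. officinale-like study matrix (100 samples, 6 levels)."""
    ds = synth.simulate_study(seed=1)
    return ds.for_matrix("dendrobium")


@pytest.fixture(scope="session")
def doff_screened(doff_dataset):
    """Baseline-corrected, smoothed spectra used for wavelength screening."""
    Z, _ = preprocess.apply_chain(doff_dataset.intensities, "airPLS+SG")
    return Z


@pytest.fixture(scope="session")
def doff_bands(doff_dataset, doff_screened):
    """Stability-selected characteristic wavelengths of the source matrix."""
    return select.ensemble_cars(
        doff_screened,
        doff_dataset.concentrations,
        seed=1,
        wavenumbers=doff_dataset.grid.wavenumbers,
    )


@pytest.fixture(scope="session")
def ao_training_matrix(doff_screened, doff_bands, doff_dataset):
    """Selected-wavelength design matrix + concentrations for model tests."""
    X = doff_screened[:, doff_bands.selected_indices]
    return X, doff_dataset.concentrations
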