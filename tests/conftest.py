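import numpy as np
import pytest

from ivrtools import (
    DEFAULT_GRID_NM,
    ProbeCalibration,
    RunConfig,
    SimulationParams,
    Spectrum,
    WavelengthGrid,
    drug_reference_spectrum,
)


@pytest.fixture
def grid():
    return WavelengthGrid(DEFAULT_GRID_NM)


@pytest.fixture
def params():
    return SimulationParams(seed=12345)


@pytest.fixture
def gaussian_standard(grid, params):
    """Noise-free drug reference band: Gaussian, center 241 nm, sd 11 nm,
    peak 0.8 AU, i.e. the 100 %-release standard spectrum."""
    return drug_reference_spectrum(grid, params)


@pytest.fixture
def calibration(gaussian_standard):
    return ProbeCalibration("P1", gaussian_standard, standard_concentration=0.004)


@pytest.fixture
def run_config():
    return RunConfig(medium_volume=500.0, dose_mass=2.0)


def gaussian_band(grid_values, center=241.0, sd=11.0, peak=0.8):
    """Analytic Gaussian band for oracle comparisons."""
    lam = np.asarray(grid_values, dtype=float)
    return peak * np.exp(-((lam - center) ** 2) / (2.0 * sd**2))


def gaussian_band_derivative(grid_values, center=241.0, sd=11.0, peak=0.8):
    """Analytic first derivative of the Gaussian band, AU/nm."""
    lam = np.asarray(grid_values, dtype=float)
    return gaussian_band(lam, center, sd, peak) * (-(lam - center) / sd**2)
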