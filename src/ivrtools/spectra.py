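"""Spectral data model, CSV I/O, resampling and baseline correction.

The unit of all spectral arithmetic is the :class:`Spectrum`: absorbance
(AU) sampled on a fixed, strictly increasing wavelength grid (nm).  A
dissolution run produces one :class:`SpectralSeries` per vessel — a
time-indexed stack of spectra sharing one grid.  Files are plain
long-format CSV so that any instrument export can be massaged into the
canonical layout with a one-liner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import GridRangeError, SpectraDataError, SpectraFormatError

#: Default analysis grid: 200-300 nm inclusive at 1 nm spacing.  This
#: matches typical fiber-optic diode-array output and puts the usual
#: analysis wavelengths (241 nm, 252 nm) exactly on grid points.
DEFAULT_GRID_NM = np.arange(200.0, 301.0, 1.0)

SERIES_COLUMNS = ["vessel", "time_min", "wavelength_nm", "absorbance"]
SPECTRUM_COLUMNS = ["wavelength_nm", "absorbance"]


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelengths in nm."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("grid must be a 1-D array with at least 2 points")
        if not np.all(np.diff(values) > 0):
            raise ValueError("grid wavelengths must be strictly increasing")
        if not np.all(values > 0):
            raise ValueError("grid wavelengths must be positive")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    def is_uniform(self, rtol: float = 1e-9) -> bool:
        steps = np.diff(self.values)
        return bool(np.allclose(steps, steps[0], rtol=rtol, atol=0.0))

    @property
    def step(self) -> float:
        """Grid spacing in nm; only meaningful for uniform grids."""
        if not self.is_uniform():
            raise ValueError("grid is not uniform; it has no single step")
        return float(self.values[1] - self.values[0])

    def require_window(self, lo: float, hi: float) -> None:
        """Raise unless [lo, hi] lies within the grid span."""
        g_lo, g_hi = self.span
        if lo < g_lo or hi > g_hi:
            raise GridRangeError(
                f"requested window [{lo}, {hi}] nm exceeds grid span "
                f"[{g_lo}, {g_hi}] nm"
            )

    def index_of(self, wavelength: float) -> int:
        """Index of an exact grid wavelength; error if absent."""
        idx = np.searchsorted(self.values, wavelength)
        if idx < len(self.values) and np.isclose(self.values[idx], wavelength):
            return int(idx)
        raise GridRangeError(f"{wavelength} nm is not a grid point")


@dataclass(frozen=True)
class Spectrum:
    """Absorbance (AU) on a wavelength grid; all values finite."""

    grid: WavelengthGrid
    absorbance: np.ndarray

    def __post_init__(self):
        absorbance = np.asarray(self.absorbance, dtype=float)
        if absorbance.shape != (len(self.grid),):
            raise ValueError(
                f"absorbance length {absorbance.size} != grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(absorbance)):
            raise ValueError("absorbance values must be finite")
        object.__setattr__(self, "absorbance", absorbance)

    def value_at(self, wavelength: float) -> float:
        """Absorbance at a wavelength inside the span (linear interpolation)."""
        self.grid.require_window(wavelength, wavelength)
        return float(np.interp(wavelength, self.grid.values, self.absorbance))

    def __add__(self, other: "Spectrum") -> "Spectrum":
        _require_same_grid(self.grid, other.grid)
        return Spectrum(self.grid, self.absorbance + other.absorbance)

    def __sub__(self, other: "Spectrum") -> "Spectrum":
        _require_same_grid(self.grid, other.grid)
        return Spectrum(self.grid, self.absorbance - other.absorbance)

    def __mul__(self, scalar: float) -> "Spectrum":
        return Spectrum(self.grid, self.absorbance * float(scalar))

    __rmul__ = __mul__


@dataclass(frozen=True)
class SpectralSeries:
    """Per-vessel time-indexed spectra on one shared grid.

    ``times`` are minutes, non-negative and strictly increasing — the
    raw output of an in-situ fiber-optic acquisition for one vessel.
    """

    vessel_id: str
    times: np.ndarray
    spectra: tuple[Spectrum, ...]

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        spectra = tuple(self.spectra)
        if times.ndim != 1 or times.size != len(spectra):
            raise ValueError("times and spectra lengths must agree")
        if times.size and times[0] < 0:
            raise ValueError("times must be non-negative")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        for s in spectra[1:]:
            _require_same_grid(spectra[0].grid, s.grid)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "spectra", spectra)

    @property
    def grid(self) -> WavelengthGrid:
        return self.spectra[0].grid

    def absorbance_matrix(self) -> np.ndarray:
        """(n_times, n_wavelengths) absorbance array."""
        return np.vstack([s.absorbance for s in self.spectra])


@dataclass(frozen=True)
class RunConfig:
    """Dissolution run configuration.

    dose_mass is the drug mass loaded into the dialysis bag (mg);
    medium_volume the vessel volume (mL); membrane_mwco in kDa.
    """

    medium_volume: float  # mL
    dose_mass: float  # mg
    temperature: float = 37.0  # degC
    stirring_rate: float = 75.0  # rpm
    membrane_mwco: float = 300.0  # kDa
    sample_volume: float = 1.0  # mL of formulation in the bag

    def __post_init__(self):
        for name in (
            "medium_volume",
            "dose_mass",
            "temperature",
            "stirring_rate",
            "membrane_mwco",
            "sample_volume",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 4.0 <= self.temperature <= 60.0:
            raise ValueError("temperature outside sanity bounds [4, 60] degC")


def _require_same_grid(a: WavelengthGrid, b: WavelengthGrid) -> None:
    if len(a) != len(b) or not np.array_equal(a.values, b.values):
        raise SpectraDataError("wavelength grids differ")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_spectrum(path: str | Path) -> Spectrum:
    """Read a single spectrum from a ``wavelength_nm,absorbance`` CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraFormatError(f"{path}: missing columns {missing}")
    df = df.sort_values("wavelength_nm")
    return Spectrum(
        WavelengthGrid(df["wavelength_nm"].to_numpy()),
        df["absorbance"].to_numpy(),
    )


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    pd.DataFrame(
        {
            "wavelength_nm": spectrum.grid.values,
            "absorbance": spectrum.absorbance,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_spectral_series(path: str | Path) -> dict[str, SpectralSeries]:
    """Read a long-format series CSV into per-vessel series.

    The file must carry the header ``vessel,time_min,wavelength_nm,
    absorbance``.  Every (vessel, time) block must yield the same
    wavelength grid within a vessel; a missing or extra wavelength at
    any time point is a data error naming the offending vessel/time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraFormatError(f"{path}: missing columns {missing}")

    out: dict[str, SpectralSeries] = {}
    for vessel, vdf in df.groupby("vessel", sort=True):
        vessel = str(vessel)
        times = np.sort(vdf["time_min"].unique())
        ref_grid: WavelengthGrid | None = None
        spectra = []
        for t in times:
            block = vdf[vdf["time_min"] == t].sort_values("wavelength_nm")
            grid = WavelengthGrid(block["wavelength_nm"].to_numpy())
            if ref_grid is None:
                ref_grid = grid
            elif len(grid) != len(ref_grid) or not np.array_equal(
                grid.values, ref_grid.values
            ):
                raise SpectraDataError(
                    f"vessel {vessel!r}, time {t} min: wavelength grid "
                    "differs from the vessel's first time point"
                )
            spectra.append(Spectrum(ref_grid, block["absorbance"].to_numpy()))
        out[vessel] = SpectralSeries(vessel, times, tuple(spectra))
    return out


def write_spectral_series(
    series: Mapping[str, SpectralSeries] | SpectralSeries, path: str | Path
) -> None:
    """Write series to long-format CSV, rows ordered (vessel, time, wavelength)."""
    if isinstance(series, SpectralSeries):
        series = {series.vessel_id: series}
    frames = []
    for vessel in sorted(series):
        s = series[vessel]
        n_wl = len(s.grid)
        for t, spec in zip(s.times, s.spectra):
            frames.append(
                pd.DataFrame(
                    {
                        "vessel": np.repeat(vessel, n_wl),
                        "time_min": np.repeat(t, n_wl),
                        "wavelength_nm": s.grid.values,
                        "absorbance": spec.absorbance,
                    }
                )
            )
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=SERIES_COLUMNS)
    # %.17g keeps write -> read round-trips exact for any float64
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Resampling and baseline correction
# ---------------------------------------------------------------------------

def resample_spectrum(spectrum: Spectrum, target_grid: WavelengthGrid) -> Spectrum:
    """Linear interpolation onto ``target_grid``.

    The target must lie within the source span; extrapolation is refused
    because absorbance outside the scanned window is unknown.
    """
    lo, hi = target_grid.span
    spectrum.grid.require_window(lo, hi)
    if np.array_equal(target_grid.values, spectrum.grid.values):
        return Spectrum(target_grid, spectrum.absorbance.copy())
    resampled = np.interp(
        target_grid.values, spectrum.grid.values, spectrum.absorbance
    )
    return Spectrum(target_grid, resampled)


def baseline_correct(series: SpectralSeries, medium: Spectrum) -> SpectralSeries:
    """Subtract the dissolution-medium spectrum at every time point.

    The medium is resampled to the series grid if needed.  Small
    negative post-correction values are kept, not clamped: clamping
    would bias derivative ratios near zero.
    """
    if not np.array_equal(medium.grid.values, series.grid.values):
        medium = resample_spectrum(medium, series.grid)
    corrected = tuple(
        Spectrum(series.grid, s.absorbance - medium.absorbance)
        for s in series.spectra
    )
    return SpectralSeries(series.vessel_id, series.times, corrected)
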