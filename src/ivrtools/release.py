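"""Percent-released quantification from calibrated absorbance.

Two readouts are provided.  The single-wavelength method divides the
sample absorbance at the drug's band maximum (241 nm by default) by the
per-probe standard absorbance: fast, but every co-absorbing excipient
that leaks through the dialysis membrane inflates it.  The derivative
method instead ratios smoothed first-derivative values at a band
inflection wavelength: any spectrally flat interferent differentiates
to ~zero and drops out, so late-time excipient leakage is suppressed.

The standard solution is prepared at the concentration the medium would
reach at 100 % release, so a ratio of 1 reads as 100 %.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .exceptions import (
    CalibrationError,
    ProfileMismatchError,
    SpectraDataError,
    WavelengthSelectionError,
)
from .spectra import Spectrum, SpectralSeries, WavelengthGrid

#: Single-point analysis wavelength: the drug band maximum.
DEFAULT_ANALYSIS_NM = 241.0
#: Search window for the derivative extreme, bracketing the band's
#: long-wavelength inflection while excluding the short-wavelength limb.
DEFAULT_SEARCH_WINDOW_NM = (245.0, 265.0)
#: Derivative magnitudes below this (AU/nm) are treated as flat.
FLATNESS_THRESHOLD = 1e-4
#: Savitzky-Golay defaults for the 1 nm grid.
DEFAULT_SG_WINDOW = 7
DEFAULT_SG_POLY = 2


@dataclass(frozen=True)
class ProbeCalibration:
    """Per-probe standard spectrum with its nominal concentration.

    ``standard_concentration`` (mg/mL) equals the medium concentration
    at 100 % release; the standard spectrum must be baseline-corrected.
    """

    probe_id: str
    standard_spectrum: Spectrum
    standard_concentration: float

    def __post_init__(self):
        if self.standard_concentration <= 0:
            raise ValueError("standard_concentration must be positive")


@dataclass(frozen=True)
class ReleaseProfile:
    """Time (min) -> percent released, optionally with across-vessel SD.

    Values are deliberately not clamped to [0, 100]: interference can
    push readings above 100 %, and that signature is diagnostic.
    """

    times: np.ndarray
    percent_released: np.ndarray
    sd: np.ndarray | None = None
    method_tag: str = "single_point"

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        percent = np.asarray(self.percent_released, dtype=float)
        if times.shape != percent.shape:
            raise ValueError("times and percent_released lengths must agree")
        sd = self.sd
        if sd is not None:
            sd = np.asarray(sd, dtype=float)
            if sd.shape != times.shape:
                raise ValueError("sd length must match times")
            if np.any(sd < 0):
                raise ValueError("sd must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "percent_released", percent)
        object.__setattr__(self, "sd", sd)

    def to_csv(self, path: str | Path) -> None:
        sd = self.sd if self.sd is not None else np.full_like(self.times, np.nan)
        pd.DataFrame(
            {
                "time_min": self.times,
                "percent_released": self.percent_released,
                "sd": sd,
                "method": self.method_tag,
            }
        ).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReleaseProfile":
        df = pd.read_csv(path, float_precision="round_trip")
        sd = df["sd"].to_numpy() if "sd" in df.columns else None
        if sd is not None and np.all(np.isnan(sd)):
            sd = None
        tag = str(df["method"].iloc[0]) if "method" in df.columns else "single_point"
        return cls(df["time_min"].to_numpy(), df["percent_released"].to_numpy(), sd, tag)


def full_release_concentration(dose_mass: float, medium_volume: float) -> float:
    """Medium concentration (mg/mL) at complete release: dose / volume.

    This is the concentration at which the per-probe standard solution
    is prepared, e.g. a 2 mg dose in 500 mL gives 0.004 mg/mL.
    """
    if dose_mass <= 0 or medium_volume <= 0:
        raise ValueError("dose_mass and medium_volume must be positive")
    return dose_mass / medium_volume


def percent_released_single(
    series: SpectralSeries,
    cal: ProbeCalibration,
    wavelength: float = DEFAULT_ANALYSIS_NM,
) -> ReleaseProfile:
    """Percent released from the absorbance ratio at one wavelength.

    percent(t) = 100 * A_sample(lambda, t) / A_standard(lambda).
    The series must already be baseline-corrected.
    """
    a_std = cal.standard_spectrum.value_at(wavelength)
    if a_std <= 0:
        raise CalibrationError(
            f"standard absorbance at {wavelength} nm is {a_std:.3g} AU "
            "(must be positive)"
        )
    percent = np.array(
        [100.0 * s.value_at(wavelength) / a_std for s in series.spectra]
    )
    return ReleaseProfile(series.times, percent, method_tag="single_point")


def derivative_spectrum(
    spectrum: Spectrum,
    order: int = 1,
    window_points: int = DEFAULT_SG_WINDOW,
    poly_order: int = DEFAULT_SG_POLY,
) -> Spectrum:
    """Savitzky-Golay smoothed derivative, dA/dlambda (AU/nm) or
    d2A/dlambda2 (AU/nm^2), on the same grid.

    Edge points use one-sided polynomial fits (the filter's interpolating
    edge mode), so the output covers the full grid.  Requires a uniform
    grid; resample first otherwise.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if window_points % 2 == 0:
        raise ValueError("window_points must be odd")
    if window_points < poly_order + 2:
        raise ValueError("window_points must be >= poly_order + 2")
    if window_points > len(spectrum.grid):
        raise ValueError("window_points exceeds grid length")
    if poly_order < order:
        raise ValueError("poly_order must be >= derivative order")
    if not spectrum.grid.is_uniform():
        raise SpectraDataError(
            "derivative requires a uniform wavelength grid; resample first"
        )
    deriv = savgol_filter(
        spectrum.absorbance,
        window_length=window_points,
        polyorder=poly_order,
        deriv=order,
        delta=spectrum.grid.step,
        mode="interp",
    )
    return Spectrum(spectrum.grid, deriv)


def select_analysis_wavelength(
    standard_derivative: Spectrum,
    search_window: tuple[float, float] = DEFAULT_SEARCH_WINDOW_NM,
    flatness_threshold: float = FLATNESS_THRESHOLD,
) -> float:
    """Wavelength of the largest |derivative| of the standard in a window.

    For a Gaussian band this lands on the inflection at center + sd.
    Ties break toward the longest wavelength.  If the derivative is flat
    throughout the window (below ``flatness_threshold``), there is no
    usable extreme and selection fails.
    """
    lo, hi = search_window
    grid = standard_derivative.grid
    grid.require_window(lo, hi)
    mask = (grid.values >= lo) & (grid.values <= hi)
    wavelengths = grid.values[mask]
    magnitude = np.abs(standard_derivative.absorbance[mask])
    if magnitude.max() < flatness_threshold:
        raise WavelengthSelectionError(
            f"no usable extreme: max |derivative| in [{lo}, {hi}] nm is "
            f"{magnitude.max():.3g} AU/nm (< {flatness_threshold:g})"
        )
    # argmax over reversed array -> last (longest-wavelength) maximizer
    best = len(magnitude) - 1 - int(np.argmax(magnitude[::-1]))
    return float(wavelengths[best])


def percent_released_derivative(
    series: SpectralSeries,
    cal: ProbeCalibration,
    wavelength: float | None = None,
    order: int = 1,
    window_points: int = DEFAULT_SG_WINDOW,
    poly_order: int = DEFAULT_SG_POLY,
    search_window: tuple[float, float] = DEFAULT_SEARCH_WINDOW_NM,
    flatness_threshold: float = FLATNESS_THRESHOLD,
) -> ReleaseProfile:
    """Interference-corrected percent released from derivative ratios.

    percent(t) = 100 * D_sample(lambda, t) / D_standard(lambda), with
    signed derivative values: on a descending band limb both sample and
    standard derivatives are negative and the signs cancel, so the
    reading stays positive.  Wavelength-constant offsets (flat
    interferents, stray light) vanish under differentiation.

    If ``wavelength`` is None it is chosen by
    :func:`select_analysis_wavelength` from the standard's derivative.
    """
    d_std = derivative_spectrum(cal.standard_spectrum, order, window_points, poly_order)
    if wavelength is None:
        wavelength = select_analysis_wavelength(d_std, search_window, flatness_threshold)
    d_std_at = d_std.value_at(wavelength)
    if abs(d_std_at) < flatness_threshold:
        raise WavelengthSelectionError(
            f"standard derivative at {wavelength} nm is {d_std_at:.3g} "
            f"AU/nm, below the flatness threshold {flatness_threshold:g}"
        )
    percent = np.empty(series.times.size)
    for i, s in enumerate(series.spectra):
        d_sample = derivative_spectrum(s, order, window_points, poly_order)
        percent[i] = 100.0 * d_sample.value_at(wavelength) / d_std_at
    tag = "first_derivative" if order == 1 else "second_derivative"
    return ReleaseProfile(series.times, percent, method_tag=tag)


def aggregate_vessels(profiles: Sequence[ReleaseProfile]) -> ReleaseProfile:
    """Pointwise mean and sample SD across replicate vessel profiles."""
    if len(profiles) < 2:
        raise ProfileMismatchError("need at least 2 profiles to aggregate")
    ref = profiles[0]
    for p in profiles[1:]:
        if not np.array_equal(p.times, ref.times):
            raise ProfileMismatchError("profiles are on different time grids")
        if p.method_tag != ref.method_tag:
            raise ProfileMismatchError(
                f"method tags differ: {p.method_tag!r} vs {ref.method_tag!r}"
            )
    stack = np.vstack([p.percent_released for p in profiles])
    return ReleaseProfile(
        ref.times,
        stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=1),
        method_tag=ref.method_tag,
    )
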