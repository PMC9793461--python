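"""Synthetic fiber-optic dissolution data with known ground truth.

The generator emulates the statistical structure the pipeline assumes:

* a drug whose UV band is a Gaussian centred near 241 nm (the surrogate
  for a dexamethasone-like absorber) whose long-wavelength inflection —
  and hence the derivative analysis wavelength — falls at center + sd
  = 252 nm with the defaults;
* a spectrally near-flat placebo contribution that is zero until a late
  onset (excipients leaking through the dialysis membrane) and grows
  linearly afterwards;
* biphasic cumulative release: fast exponential phase plus linear
  terminal phase, capped at 100 %;
* homoscedastic Gaussian absorbance noise, independent per (vessel,
  wavelength, time), with per-vessel streams derived deterministically
  from a single integer seed.

Temperature enters the release rate as a Q10 multiplier and stirring as
a mild power law — phenomenological knobs for sensitivity scenarios,
not mechanistic claims.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ScenarioError
from .release import ProbeCalibration
from .spectra import (
    DEFAULT_GRID_NM,
    RunConfig,
    SpectralSeries,
    Spectrum,
    WavelengthGrid,
    write_spectral_series,
    write_spectrum,
)

#: In-situ sampling schedule (minutes) used during method development.
SCHEDULE_24H_MIN = (
    5, 10, 15, 20, 30, 45, 60, 90, 120, 150, 180, 240, 300, 360, 720, 1440,
)


def extended_schedule(max_hours: float) -> np.ndarray:
    """The 24 h schedule extended by 12 h steps up to ``max_hours``."""
    times = list(SCHEDULE_24H_MIN)
    t = 1440 + 720
    while t <= max_hours * 60:
        times.append(t)
        t += 720
    return np.asarray(times, dtype=float)


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic instrument and formulation.

    The spectral defaults place the drug band maximum at 241 nm with a
    width that puts its inflection at 252 nm; release defaults give a
    fast phase of 60 % with rate 0.005/min (slope change near 10 h) and
    a terminal slope that tops the profile out within 72 h; the placebo
    leak starts at 48 h.  A seed is mandatory — the simulator draws no
    implicit entropy.
    """

    seed: int
    drug_peak_center: float = 241.0  # nm
    drug_peak_sd: float = 11.0  # nm; inflection at center + sd = 252 nm
    drug_peak_absorbance: float = 0.8  # AU at 100 % release
    release_a: float = 60.0  # % fast-phase amplitude
    release_k1: float = 0.005  # 1/min fast-phase rate
    release_m: float = 0.015  # %/min terminal slope
    placebo_onset: float = 2880.0  # min (48 h)
    placebo_rate: float = 0.0  # AU/min post-onset at 241 nm
    placebo_tilt: float = 1e-3  # AU/nm gentle spectral slope
    noise_sd: float = 0.0  # AU
    temperature_q10: float = 2.0  # release-rate multiplier per 10 degC
    rpm_exponent: float = 0.3  # stirring sensitivity

    def __post_init__(self):
        if self.drug_peak_sd <= 0:
            raise ValueError("drug_peak_sd must be positive")
        for name in (
            "drug_peak_absorbance", "release_a", "release_k1", "release_m",
            "placebo_onset", "placebo_rate", "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Simulation bookkeeping: the true release and placebo signals."""

    times: np.ndarray
    true_percent: np.ndarray
    placebo_amplitude: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        percent = np.asarray(self.true_percent, dtype=float)
        amp = np.asarray(self.placebo_amplitude, dtype=float)
        if np.any(np.diff(percent) < 0) or np.any(percent > 100):
            raise ValueError("true_percent must be monotone and capped at 100")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "true_percent", percent)
        object.__setattr__(self, "placebo_amplitude", amp)


def drug_reference_spectrum(
    grid: WavelengthGrid, params: SimulationParams
) -> Spectrum:
    """Gaussian drug band at 100 % release."""
    lam = grid.values
    band = np.exp(
        -((lam - params.drug_peak_center) ** 2) / (2.0 * params.drug_peak_sd**2)
    )
    return Spectrum(grid, params.drug_peak_absorbance * band)


def placebo_spectrum(grid: WavelengthGrid, params: SimulationParams) -> Spectrum:
    """Unit-amplitude placebo shape: flat with a gentle tilt, value 1 at
    241 nm, clipped at zero."""
    shape = 1.0 + params.placebo_tilt * (grid.values - 241.0)
    return Spectrum(grid, np.clip(shape, 0.0, None))


def _rate_modifier(params: SimulationParams, temperature: float, rpm: float) -> float:
    return params.temperature_q10 ** ((temperature - 37.0) / 10.0) * (
        rpm / 75.0
    ) ** params.rpm_exponent


def true_release_curve(
    times: np.ndarray,
    params: SimulationParams,
    temperature: float = 37.0,
    rpm: float = 75.0,
) -> GroundTruth:
    """Biphasic cumulative release, capped at 100 %.

    F(t) = min(100, a (1 - e^{-k t}) + m t) with the fast rate and the
    terminal slope both scaled by the temperature/stirring modifier.
    The placebo amplitude in the returned truth is zero; use
    :func:`placebo_amplitude_curve` separately when composing spectra.
    """
    times = np.asarray(times, dtype=float)
    if temperature <= 0 or rpm <= 0:
        raise ValueError("temperature and rpm must be positive")
    mod = _rate_modifier(params, temperature, rpm)
    k = params.release_k1 * mod
    m = params.release_m * mod
    f = np.minimum(100.0, params.release_a * (1.0 - np.exp(-k * times)) + m * times)
    return GroundTruth(times, f, np.zeros_like(times))


def placebo_amplitude_curve(times: np.ndarray, params: SimulationParams) -> np.ndarray:
    """Placebo absorbance amplitude (AU at 241 nm): zero before onset,
    linear growth at ``placebo_rate`` afterwards."""
    times = np.asarray(times, dtype=float)
    return params.placebo_rate * np.clip(times - params.placebo_onset, 0.0, None)


def synthesize_run(
    config: RunConfig,
    params: SimulationParams,
    n_vessels: int = 6,
    times: np.ndarray | None = None,
    grid: WavelengthGrid | None = None,
) -> tuple[
    dict[str, SpectralSeries], dict[str, ProbeCalibration], Spectrum, GroundTruth
]:
    """Simulate one dissolution run.

    Returns per-vessel spectral series, per-probe calibrations (noise-
    free drug reference standards at the 100 %-release concentration),
    the medium spectrum (zero — the baseline is already abstracted), and
    the ground truth.  Noise is Normal(0, noise_sd), independent per
    (vessel, wavelength, time); each vessel's stream is spawned
    deterministically from ``params.seed``, so the same seed reproduces
    the run byte-for-byte and different vessels get independent noise.
    """
    if n_vessels < 1:
        raise ValueError("n_vessels must be >= 1")
    if grid is None:
        grid = WavelengthGrid(DEFAULT_GRID_NM)
    if times is None:
        times = extended_schedule(48.0)
    times = np.asarray(times, dtype=float)

    truth_curve = true_release_curve(times, params, config.temperature, config.stirring_rate)
    placebo_amp = placebo_amplitude_curve(times, params)
    truth = GroundTruth(times, truth_curve.true_percent, placebo_amp)

    drug_ref = drug_reference_spectrum(grid, params)
    placebo = placebo_spectrum(grid, params)
    clean = (
        np.outer(truth.true_percent / 100.0, drug_ref.absorbance)
        + np.outer(placebo_amp, placebo.absorbance)
    )

    standard_conc = config.dose_mass / config.medium_volume
    series: dict[str, SpectralSeries] = {}
    cals: dict[str, ProbeCalibration] = {}
    streams = np.random.SeedSequence(params.seed).spawn(n_vessels)
    for i in range(n_vessels):
        vessel = f"V{i + 1}"
        rng = np.random.default_rng(streams[i])
        noisy = clean + rng.normal(0.0, params.noise_sd, size=clean.shape)
        spectra = tuple(Spectrum(grid, row) for row in noisy)
        series[vessel] = SpectralSeries(vessel, times, spectra)
        cals[vessel] = ProbeCalibration(vessel, drug_ref, standard_conc)

    medium = Spectrum(grid, np.zeros(len(grid)))
    return series, cals, medium, truth


#: Scenario definitions mirroring the method-development experiments:
#: a clean 48 h run, a 72 h run with placebo leakage, and paired runs
#: probing temperature, stirring-rate and sample-volume sensitivity.
_SCENARIOS = {
    "baseline_48h",
    "placebo_leakage_72h",
    "temperature_pair",
    "rpm_pair",
    "volume_pair",
}

_BASE_CONFIG = dict(medium_volume=500.0, dose_mass=2.0, temperature=37.0,
                    stirring_rate=75.0, membrane_mwco=300.0, sample_volume=1.0)


def scenario_runs(
    scenario_name: str, seed: int
) -> list[tuple[str, RunConfig, SimulationParams, np.ndarray]]:
    """Resolve a named scenario into (label, config, params, times) runs."""
    if scenario_name not in _SCENARIOS:
        raise ScenarioError(
            f"unknown scenario {scenario_name!r}; known: {sorted(_SCENARIOS)}"
        )
    noise = dict(noise_sd=0.002)
    if scenario_name == "baseline_48h":
        return [(
            "baseline",
            RunConfig(**_BASE_CONFIG),
            SimulationParams(seed=seed, **noise),
            extended_schedule(48.0),
        )]
    if scenario_name == "placebo_leakage_72h":
        return [(
            "placebo_leakage",
            RunConfig(**_BASE_CONFIG),
            SimulationParams(seed=seed, placebo_rate=1e-4, **noise),
            extended_schedule(72.0),
        )]
    if scenario_name == "temperature_pair":
        return [
            (
                f"temp_{int(temp)}C",
                RunConfig(**{**_BASE_CONFIG, "temperature": temp}),
                SimulationParams(seed=seed + j, **noise),
                extended_schedule(48.0),
            )
            for j, temp in enumerate((25.0, 37.0))
        ]
    if scenario_name == "rpm_pair":
        return [
            (
                f"rpm_{int(rpm)}",
                RunConfig(**{**_BASE_CONFIG, "stirring_rate": rpm}),
                SimulationParams(seed=seed + j, **noise),
                extended_schedule(48.0),
            )
            for j, rpm in enumerate((50.0, 75.0))
        ]
    # volume_pair: half vs full formulation volume; dose scales with it,
    # the percent-released truth is unchanged
    return [
        (
            f"vol_{vol:g}mL",
            RunConfig(**{**_BASE_CONFIG, "sample_volume": vol,
                         "dose_mass": 2.0 * vol}),
            SimulationParams(seed=seed + j, **noise),
            extended_schedule(48.0),
        )
        for j, vol in enumerate((0.5, 1.0))
    ]


def make_fixture_dataset(directory: str | Path, scenario_name: str, seed: int) -> list[Path]:
    """Write a scenario's CSV fixture files and return their paths.

    Per run: the spectral series, per-probe standards, medium spectrum,
    ground truth (``time_min,true_percent,placebo_au``) and a JSON
    config snapshot.  Identical (scenario, seed) pairs reproduce the
    files byte-for-byte.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for label, config, params, times in scenario_runs(scenario_name, seed):
        series, cals, medium, truth = synthesize_run(
            config, params, n_vessels=6, times=times
        )
        prefix = directory / f"{scenario_name}_{label}"
        p = Path(f"{prefix}_series.csv")
        write_spectral_series(series, p)
        written.append(p)
        for vessel, cal in cals.items():
            p = Path(f"{prefix}_standard_{vessel}.csv")
            write_spectrum(cal.standard_spectrum, p)
            written.append(p)
        p = Path(f"{prefix}_medium.csv")
        write_spectrum(medium, p)
        written.append(p)
        p = Path(f"{prefix}_truth.csv")
        import pandas as pd

        pd.DataFrame(
            {
                "time_min": truth.times,
                "true_percent": truth.true_percent,
                "placebo_au": truth.placebo_amplitude,
            }
        ).to_csv(p, index=False, float_format="%.17g")
        written.append(p)
        p = Path(f"{prefix}_config.json")
        p.write_text(
            json.dumps(
                {
                    "scenario": scenario_name,
                    "label": label,
                    "run_config": dataclasses.asdict(config),
                    "params": dataclasses.asdict(params),
                    "times_min": times.tolist(),
                },
                indent=2,
            )
        )
        written.append(p)
    return written
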