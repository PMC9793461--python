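"""Percent-released quantification: single-point and derivative methods."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivrtools import (
    CalibrationError,
    ProbeCalibration,
    ProfileMismatchError,
    ReleaseProfile,
    RunConfig,
    SimulationParams,
    SpectralSeries,
    Spectrum,
    WavelengthSelectionError,
    aggregate_vessels,
    derivative_spectrum,
    full_release_concentration,
    percent_released_derivative,
    percent_released_single,
    select_analysis_wavelength,
    synthesize_run,
)
from tests.conftest import gaussian_band_derivative


def series_from_fractions(standard, fractions, extra=None):
    """Series whose spectrum at time i is fractions[i] * standard (+ extra)."""
    times = 5.0 * np.arange(1, len(fractions) + 1)
    spectra = []
    for i, a in enumerate(fractions):
        ab = a * standard.absorbance
        if extra is not None:
            ab = ab + (extra[i] if isinstance(extra, list) else extra)
        spectra.append(Spectrum(standard.grid, ab))
    return SpectralSeries("V1", times, tuple(spectra))


class TestFullReleaseConcentration:
    @pytest.mark.parametrize(
        "dose, volume, expected",
        [(2.0, 500.0, 0.004), (1.0, 500.0, 0.002), (0.004 * 123.0, 123.0, 0.004)],
    )
    def test_dose_over_volume(self, dose, volume, expected):
        assert full_release_concentration(dose, volume) == pytest.approx(expected)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            full_release_concentration(0.0, 500.0)
        with pytest.raises(ValueError):
            full_release_concentration(2.0, -1.0)


class TestSinglePoint:
    def test_sample_equal_to_standard_reads_100(self, gaussian_standard, calibration):
        series = series_from_fractions(gaussian_standard, [1.0, 1.0])
        prof = percent_released_single(series, calibration)
        np.testing.assert_allclose(prof.percent_released, 100.0)
        assert prof.method_tag == "single_point"

    def test_zero_series_reads_zero(self, gaussian_standard, calibration):
        series = series_from_fractions(gaussian_standard, [0.0, 0.0, 0.0])
        prof = percent_released_single(series, calibration)
        np.testing.assert_allclose(prof.percent_released, 0.0)

    def test_proportional_series(self, gaussian_standard, calibration):
        series = series_from_fractions(gaussian_standard, [0.25, 0.5, 1.0])
        prof = percent_released_single(series, calibration)
        np.testing.assert_allclose(prof.percent_released, [25.0, 50.0, 100.0],
                                   rtol=1e-12)

    def test_nonpositive_standard_is_calibration_error(self, grid, gaussian_standard):
        dead = ProbeCalibration("P1", Spectrum(grid, np.zeros(len(grid))), 0.004)
        series = series_from_fractions(gaussian_standard, [1.0, 1.0])
        with pytest.raises(CalibrationError):
            percent_released_single(series, dead)


class TestDerivativeSpectrum:
    def test_constant_spectrum_derivative_is_zero(self, grid):
        spec = Spectrum(grid, np.full(len(grid), 0.7))
        for order in (1, 2):
            d = derivative_spectrum(spec, order=order)
            np.testing.assert_allclose(d.absorbance, 0.0, atol=1e-12)

    def test_linear_spectrum_derivative_is_slope(self, grid):
        spec = Spectrum(grid, 0.01 * grid.values)
        d = derivative_spectrum(spec, order=1)
        np.testing.assert_allclose(d.absorbance, 0.01, atol=1e-12)

    def test_gaussian_matches_analytic_derivative(self, gaussian_standard):
        """At polynomial order 5 the smoother's bias on an 11 nm-wide band
        sampled at 1 nm is below 1e-4 of the peak derivative; the default
        order 2 trades bias (which cancels in the sample/standard ratio)
        for stronger noise suppression."""
        analytic = gaussian_band_derivative(gaussian_standard.grid.values)
        peak_mag = np.max(np.abs(analytic))
        d = derivative_spectrum(gaussian_standard, order=1, poly_order=5)
        assert np.max(np.abs(d.absorbance - analytic)) < 1e-4 * peak_mag
        d2 = derivative_spectrum(gaussian_standard, order=1)  # default poly 2
        assert np.max(np.abs(d2.absorbance - analytic)) < 0.03 * peak_mag

    def test_nonuniform_grid_rejected(self):
        from ivrtools import SpectraDataError, WavelengthGrid

        grid = WavelengthGrid(np.array([200.0, 201.0, 203.0, 204.0, 205.0,
                                        206.0, 207.0, 208.0]))
        spec = Spectrum(grid, np.zeros(len(grid)))
        with pytest.raises(SpectraDataError):
            derivative_spectrum(spec)

    def test_bad_window_rejected(self, gaussian_standard):
        with pytest.raises(ValueError):
            derivative_spectrum(gaussian_standard, window_points=6)
        with pytest.raises(ValueError):
            derivative_spectrum(gaussian_standard, window_points=3, poly_order=2)
        with pytest.raises(ValueError):
            derivative_spectrum(gaussian_standard, window_points=1001)


class TestWavelengthSelection:
    def test_gaussian_inflection_at_252(self, gaussian_standard):
        d = derivative_spectrum(gaussian_standard)
        assert select_analysis_wavelength(d, (245.0, 265.0)) == 252.0

    def test_flat_standard_is_selection_error(self, grid):
        flat = Spectrum(grid, np.full(len(grid), 1e-6))
        with pytest.raises(WavelengthSelectionError):
            select_analysis_wavelength(flat, (245.0, 265.0))

    def test_short_window_picks_edge_by_brute_force(self, gaussian_standard):
        """On 200-230 nm the |derivative| rises monotonically toward the
        short-wavelength inflection at 230 nm; brute force agrees."""
        d = derivative_spectrum(gaussian_standard)
        chosen = select_analysis_wavelength(d, (200.0, 230.0))
        mask = (d.grid.values >= 200.0) & (d.grid.values <= 230.0)
        brute = d.grid.values[mask][np.argmax(np.abs(d.absorbance[mask]))]
        assert chosen == brute == 230.0


class TestDerivativeQuantification:
    def test_sample_equal_to_standard_reads_100(self, gaussian_standard, calibration):
        series = series_from_fractions(gaussian_standard, [1.0, 1.0])
        prof = percent_released_derivative(series, calibration)
        np.testing.assert_allclose(prof.percent_released, 100.0, rtol=1e-9)
        assert prof.method_tag == "first_derivative"

    def test_constant_offset_vanishes(self, gaussian_standard, calibration):
        series = series_from_fractions(gaussian_standard, [0.4, 0.4], extra=0.3)
        prof = percent_released_derivative(series, calibration)
        np.testing.assert_allclose(prof.percent_released, 40.0, rtol=1e-9)

    def test_near_flat_placebo_error_bounded(self, grid, gaussian_standard,
                                             calibration, params):
        from ivrtools import placebo_spectrum

        placebo = placebo_spectrum(grid, params)  # tilt 1e-3 AU/nm
        series = series_from_fractions(
            gaussian_standard, [0.4], extra=[0.2 * placebo.absorbance]
        )
        prof = percent_released_derivative(series, calibration)
        assert abs(prof.percent_released[0] - 40.0) < 1.0

    def test_second_order_available(self, gaussian_standard, calibration):
        series = series_from_fractions(gaussian_standard, [0.5, 0.5])
        prof = percent_released_derivative(
            series, calibration, wavelength=241.0, order=2
        )
        np.testing.assert_allclose(prof.percent_released, 50.0, rtol=1e-6)
        assert prof.method_tag == "second_derivative"


class TestAggregate:
    def test_identical_profiles_have_zero_sd(self):
        p = ReleaseProfile(np.array([5.0, 10.0, 15.0]), np.array([10.0, 20.0, 30.0]))
        agg = aggregate_vessels([p, p])
        np.testing.assert_array_equal(agg.percent_released, p.percent_released)
        np.testing.assert_array_equal(agg.sd, 0.0)

    def test_two_point_mean_and_sd(self):
        t = np.array([5.0, 10.0, 15.0])
        a = ReleaseProfile(t, np.array([40.0, 40.0, 40.0]))
        b = ReleaseProfile(t, np.array([60.0, 60.0, 60.0]))
        agg = aggregate_vessels([a, b])
        np.testing.assert_allclose(agg.percent_released, 50.0)
        np.testing.assert_allclose(agg.sd, 20.0 / np.sqrt(2), rtol=1e-12)

    def test_mismatched_grids_or_tags_rejected(self):
        t = np.array([5.0, 10.0, 15.0])
        a = ReleaseProfile(t, np.zeros(3))
        b = ReleaseProfile(t + 1, np.zeros(3))
        with pytest.raises(ProfileMismatchError):
            aggregate_vessels([a, b])
        c = ReleaseProfile(t, np.zeros(3), method_tag="first_derivative")
        with pytest.raises(ProfileMismatchError):
            aggregate_vessels([a, c])

    def test_replicate_mean_near_truth(self, run_config):
        """Six noisy replicates: the aggregate mean stays within a
        3 sd / sqrt(6) CLT band of the simulated truth."""
        params = SimulationParams(seed=777, noise_sd=0.004)
        series, cals, _, truth = synthesize_run(run_config, params, n_vessels=6)
        profs = [percent_released_single(s, cals[v]) for v, s in series.items()]
        agg = aggregate_vessels(profs)
        band = 3.0 * agg.sd / np.sqrt(6.0)
        assert np.all(np.abs(agg.percent_released - truth.true_percent) <= band)


class TestMethodAgreementProperties:
    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_methods_agree_without_interference(self, seed):
        """With no placebo and no noise the single-point and derivative
        readouts agree to better than 0.5 % absolute."""
        params = SimulationParams(seed=seed)
        config = RunConfig(medium_volume=500.0, dose_mass=2.0)
        series, cals, _, _ = synthesize_run(config, params, n_vessels=1)
        s = series["V1"]
        single = percent_released_single(s, cals["V1"])
        deriv = percent_released_derivative(s, cals["V1"])
        assert np.max(np.abs(single.percent_released - deriv.percent_released)) < 0.5

    def test_offset_invariance_is_one_sided(self, gaussian_standard, calibration):
        """A wavelength-constant, time-varying offset shifts the
        single-point readout but leaves the derivative readout alone."""
        offsets = [0.0, 0.05, 0.2]
        base = series_from_fractions(gaussian_standard, [0.3, 0.3, 0.3])
        shifted = series_from_fractions(
            gaussian_standard, [0.3, 0.3, 0.3], extra=offsets
        )
        d0 = percent_released_derivative(base, calibration).percent_released
        d1 = percent_released_derivative(shifted, calibration).percent_released
        np.testing.assert_allclose(d0, d1, atol=1e-9)
        s0 = percent_released_single(base, calibration).percent_released
        s1 = percent_released_single(shifted, calibration).percent_released
        assert s1[1] > s0[1] and s1[2] > s0[2]

    def test_noiseless_profiles_are_monotone(self, run_config):
        params = SimulationParams(seed=5)
        series, cals, _, _ = synthesize_run(run_config, params, n_vessels=1)
        s = series["V1"]
        for prof in (
            percent_released_single(s, cals["V1"]),
            percent_released_derivative(s, cals["V1"]),
        ):
            assert np.all(np.diff(prof.percent_released) >= -1e-9)

    def test_single_point_exceeds_derivative_after_placebo_onset(self, run_config):
        """Late excipient leakage inflates the single-point readout but
        not the derivative one — the interference signature."""
        from ivrtools import extended_schedule

        params = SimulationParams(seed=5, placebo_rate=1e-4)
        series, cals, _, truth = synthesize_run(
            run_config, params, n_vessels=1, times=extended_schedule(72.0)
        )
        s = series["V1"]
        single = percent_released_single(s, cals["V1"]).percent_released
        deriv = percent_released_derivative(s, cals["V1"]).percent_released
        post = truth.times > params.placebo_onset
        assert post.any()
        assert np.all(single[post] > deriv[post])
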