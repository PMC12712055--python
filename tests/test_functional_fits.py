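"""Patch-clamp and calcium-imaging quantification operations."""

import numpy as np
import pytest

from piezoflux.functional_fits import (
    NoResponseError,
    SweepSeries,
    boltzmann,
    cell_mean_tau,
    compute_f_over_f0,
    detect_threshold,
    fit_boltzmann,
    fit_ec50,
    fit_inactivation,
    fit_iv,
    normalize_pressure_response,
    peak_sustained_ratio,
    single_channel_amplitude,
)
from piezoflux.synthgen import (
    generate_current_decay,
    generate_dose_response,
    generate_pressure_sweeps,
)


def displacement_series(peaks_pa, noise_floor=0.0, seed=0):
    """Poking-style series: 15 displacements in 0.8 um increments."""
    stimuli = 0.8 * np.arange(1, len(peaks_pa) + 1)
    time_s = np.arange(0.0, 0.4, 1e-3)
    in_stim = (time_s >= 0.1) & (time_s < 0.3)
    rng = np.random.default_rng(seed)
    currents = np.outer(peaks_pa, in_stim.astype(float))
    if noise_floor > 0:
        currents = currents + rng.normal(0, noise_floor, currents.shape)
    return SweepSeries(
        stimuli=stimuli, time_s=time_s, currents=currents,
        stim_onset_s=0.1, stim_duration_s=0.2, sample_rate_hz=1000.0,
        stimulus_unit="um",
    )


class TestThreshold:
    def test_first_supra_threshold_sweep_wins(self):
        # baseline noise sd ~1 pA; a single 7-sigma sweep
        peaks = [0.0, 0.0, 7.0, 20.0]
        series = displacement_series(peaks, noise_floor=1.0, seed=5)
        res = detect_threshold(series)
        assert res.reached
        assert res.index in (2, 3)  # noise may push sweep 3 just past the gate

    def test_all_sub_threshold_reports_not_reached(self):
        series = displacement_series([0.0] * 5, noise_floor=1.0, seed=6)
        res = detect_threshold(series)
        assert not res.reached and res.threshold is None

    def test_programmed_displacement_threshold_recovered(self):
        # response appears at the 5th stimulus = 4.0 um
        peaks = [0.0, 0.0, 0.0, 0.0, 150.0, 300.0, 450.0]
        series = displacement_series(peaks, noise_floor=2.0, seed=7)
        res = detect_threshold(series)
        assert res.threshold == pytest.approx(4.0)

    def test_zero_baseline_sd_uses_floor(self):
        series = displacement_series([0.0, 50.0])
        res = detect_threshold(series, sd_floor=1.0)
        assert res.used_sd_floor
        assert res.threshold == pytest.approx(1.6)


class TestInactivation:
    def test_noiseless_recovery_within_point_one_percent(self):
        t, i = generate_current_decay(-50.0, -400.0, 0.0, tau_ms=15.9)
        fit = fit_inactivation(t, i)
        assert fit.tau_inact_ms == pytest.approx(15.9, rel=1e-3)
        assert fit.converged

    def test_window_restricts_the_fit(self):
        t, i = generate_current_decay(0.0, 100.0, 0.0, tau_ms=10.0, duration_s=0.2)
        fit = fit_inactivation(t, i, window=(0.05, 0.2))
        # decay restarted from the window start is still the same tau
        assert fit.tau_inact_ms == pytest.approx(10.0, rel=1e-3)
        assert fit.t0 == 0.05

    def test_peak_gate_excludes_out_of_range_sweeps(self):
        fits = []
        for peak in (50.0, 120.0, 800.0, 2000.0):
            t, i = generate_current_decay(0.0, peak, 0.0, tau_ms=12.0)
            fits.append(fit_inactivation(t, i, peak=peak))
        tau, n_used = cell_mean_tau(fits)
        assert n_used == 2  # only 120 and 800 pA pass the 100-1500 pA gate
        assert tau == pytest.approx(12.0, rel=1e-3)

    def test_scaling_current_leaves_tau_unchanged(self):
        t, i = generate_current_decay(10.0, 200.0, 0.0, tau_ms=8.0, noise_sd=5.0, seed=3)
        f1 = fit_inactivation(t, i)
        f2 = fit_inactivation(t, 3.0 * i)
        assert f2.tau_inact_ms == pytest.approx(f1.tau_inact_ms, rel=1e-6)


class TestBoltzmann:
    PRESSURES = np.arange(-5.0, -85.0, -5.0)

    def test_half_maximal_at_p50_by_construction(self):
        assert boltzmann(-35.0, -35.0, 8.0) == pytest.approx(0.5)

    def test_noiseless_generated_curve_recovered_exactly(self):
        series = generate_pressure_sweeps(-42.5, 7.0, 800.0, self.PRESSURES)
        p, r = normalize_pressure_response(series)
        fit = fit_boltzmann(p, r)
        assert fit.p50_mmhg == pytest.approx(-42.5, abs=1e-6)
        assert fit.slope_mmhg == pytest.approx(7.0, rel=1e-4)
        assert fit.in_range

    def test_bias_small_over_many_noisy_cells(self):
        p50s = []
        for seed in range(200):
            series = generate_pressure_sweeps(
                -30.0, 8.0, 500.0, self.PRESSURES, noise_sd=25.0, seed=seed
            )
            p, r = normalize_pressure_response(series)
            p50s.append(fit_boltzmann(p, r).p50_mmhg)
        assert abs(np.mean(p50s) - (-30.0)) < 1.0

    def test_normalized_max_is_one_and_zero_series_errors(self):
        series = generate_pressure_sweeps(-30.0, 8.0, 500.0, self.PRESSURES)
        _, r = normalize_pressure_response(series)
        assert r.max() == pytest.approx(1.0)
        flat = generate_pressure_sweeps(-30.0, 8.0, 0.0, self.PRESSURES)
        with pytest.raises(NoResponseError):
            normalize_pressure_response(flat)

    def test_scaling_currents_leaves_p50_unchanged(self):
        series = generate_pressure_sweeps(-30.0, 8.0, 500.0, self.PRESSURES,
                                          noise_sd=20.0, seed=9)
        p, r = normalize_pressure_response(series)
        scaled = SweepSeries(
            stimuli=series.stimuli, time_s=series.time_s,
            currents=5.0 * series.currents, stim_onset_s=series.stim_onset_s,
            stim_duration_s=series.stim_duration_s,
            sample_rate_hz=series.sample_rate_hz,
        )
        p2, r2 = normalize_pressure_response(scaled)
        np.testing.assert_allclose(r, r2)


class TestPeakSustained:
    def make_trace(self, peak, sustained, tau_s=0.01):
        t = np.arange(0.0, 0.7, 5e-4)
        i = np.zeros_like(t)
        stim = (t >= 0.1) & (t < 0.6)
        ts = t[stim] - 0.1
        i[stim] = sustained + (peak - sustained) * np.exp(-ts / tau_s)
        return t, i

    def test_square_trace_has_ratio_one(self):
        t, i = self.make_trace(200.0, 200.0)
        res = peak_sustained_ratio(t, i, (0.1, 0.6))
        assert res.ratio == pytest.approx(1.0, rel=1e-6)

    def test_fully_inactivating_trace_is_capped(self):
        t, i = self.make_trace(300.0, 0.0, tau_s=0.005)
        res = peak_sustained_ratio(t, i, (0.1, 0.6))
        assert res.capped

    def test_programmed_ratio_recovered(self):
        t, i = self.make_trace(400.0, 100.0, tau_s=0.002)
        res = peak_sustained_ratio(t, i, (0.1, 0.6))
        assert res.ratio == pytest.approx(4.0, rel=1e-3)


class TestSingleChannelAmplitude:
    def test_clean_two_level_trace(self):
        rng = np.random.default_rng(0)
        state = rng.random(5000) < 0.3
        trace = np.where(state, -4.0, 0.0)
        res = single_channel_amplitude(trace)
        assert not res.no_event
        assert res.amplitude_pa == pytest.approx(4.0, abs=1e-6)
        assert res.signed_amplitude_pa == pytest.approx(-4.0, abs=1e-6)

    def test_pure_noise_flagged_no_event(self):
        rng = np.random.default_rng(1)
        res = single_channel_amplitude(rng.normal(0.0, 0.5, 5000))
        assert res.no_event

    def test_noisy_two_level_amplitude_within_five_percent(self):
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            state = rng.random(5000) < 0.3
            trace = np.where(state, -4.0, 0.0) + rng.normal(0, 0.4, 5000)
            res = single_channel_amplitude(trace)
            errs.append(abs(res.amplitude_pa - 4.0) / 4.0)
        assert np.median(errs) < 0.05


class TestIVFit:
    def test_exact_ohmic_points(self):
        v = np.arange(-140.0, -20.0, 20.0)
        i = 40.0 * (v - 0.0) / 1000.0
        fit = fit_iv(v, i)
        assert fit.conductance_ps == pytest.approx(40.0)
        assert fit.reversal_mv == pytest.approx(0.0, abs=1e-9)

    def test_two_points_give_exact_line(self):
        fit = fit_iv([-100.0, -40.0], [-4.0, -1.6])
        assert fit.conductance_ps == pytest.approx(40.0)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(2)
        v = np.arange(-140.0, -20.0, 20.0)
        i = 40.0 * v / 1000.0 + rng.normal(0, 0.2, len(v))
        fit = fit_iv(v, i)
        # closed-form OLS slope oracle
        slope = ((v - v.mean()) * (i - i.mean())).sum() / ((v - v.mean()) ** 2).sum()
        assert fit.slope_pa_per_mv == pytest.approx(slope)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            fit_iv([-100.0], [-4.0])


class TestCalcium:
    def test_constant_series_normalizes_to_one(self):
        t = np.arange(0.0, 60.0, 2.0)
        tc = compute_f_over_f0(t, np.full_like(t, 500.0))
        np.testing.assert_allclose(tc.f_over_f0, 1.0)

    def test_doubling_step_plateaus_at_two(self):
        t = np.arange(0.0, 60.0, 2.0)
        f = np.where(t < 30.0, 100.0, 200.0)
        tc = compute_f_over_f0(t, f)
        assert tc.max_response() == pytest.approx(2.0)
        assert tc.max_response(window=(30.0, 60.0)) == pytest.approx(2.0)

    def test_transient_matches_hand_computation(self):
        t = np.arange(0.0, 40.0, 2.0)
        f = 100.0 + 50.0 * np.exp(-((t - 20.0) / 5.0) ** 2)
        tc = compute_f_over_f0(t, f, control_window=(0.0, 10.0))
        f0 = f[t <= 10.0].mean()
        np.testing.assert_allclose(tc.f_over_f0, f / f0)

    def test_nonpositive_f0_rejected(self):
        t = np.arange(0.0, 20.0, 2.0)
        with pytest.raises(ValueError):
            compute_f_over_f0(t, np.zeros_like(t))


class TestEC50:
    def test_midpoint_property_and_exact_recovery(self):
        concs = 0.03 * np.logspace(-2, 2, 7)
        table = generate_dose_response(0.03, 1.0, 5.0, concs, n_cells=10, noise_sd=0.0)
        fit = fit_ec50(table)
        assert fit.ec50_um == pytest.approx(0.03, rel=1e-6)
        assert fit.bottom == pytest.approx(1.0, abs=1e-3)
        assert fit.top == pytest.approx(5.0, abs=1e-3)
        assert not fit.extrapolated

    def test_too_few_concentrations_rejected(self):
        table = generate_dose_response(0.03, 1.0, 5.0, [0.01, 0.03, 0.1], n_cells=5)
        with pytest.raises(ValueError):
            fit_ec50(table)
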