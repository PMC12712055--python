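"""Synthetic-data generators: determinism, ground truth, round trips."""

import dataclasses
import io

import numpy as np
import pandas as pd
import pytest

from piezoflux.functional_fits import (
    boltzmann,
    fit_boltzmann,
    fit_ec50,
    fit_inactivation,
    fit_iv,
    normalize_pressure_response,
    voltage_amplitudes,
)
from piezoflux.pipeline import run_minflux_pipeline
from piezoflux.pose_contacts import contact_frequency
from piezoflux.synthgen import (
    MAX_PAIR_DISTANCE_NM,
    SynthMinfluxConfig,
    generate_current_decay,
    generate_dose_response,
    generate_minflux_dataset,
    generate_pressure_sweeps,
    generate_single_channel,
    generate_toy_pose_ensemble,
)

PRESSURES = np.arange(-5.0, -85.0, -5.0)


class TestMinfluxGenerator:
    def test_identical_seed_gives_bit_identical_tables(self):
        cfg = SynthMinfluxConfig(n_trimers=15, seed=42)
        out = []
        for _ in range(2):
            table, truth = generate_minflux_dataset(cfg)
            buf = io.StringIO()
            table.to_csv(buf, index=False)
            truth.trimers.to_csv(buf, index=False)
            out.append(buf.getvalue())
        assert out[0] == out[1]

    def test_different_seed_changes_output(self):
        a, _ = generate_minflux_dataset(SynthMinfluxConfig(n_trimers=5, seed=1))
        b, _ = generate_minflux_dataset(SynthMinfluxConfig(n_trimers=5, seed=2))
        assert not a.equals(b)

    def test_zero_noise_trace_centers_hit_true_positions(self):
        cfg = SynthMinfluxConfig(
            n_trimers=5, label_efficiency=1.0, loc_sd=0.0, linkage_sd=0.0,
            background_trace_density=0.0, multi_emitter_fraction=0.0, seed=4,
        )
        table, truth = generate_minflux_dataset(cfg)
        # undo the export convention, i.e. apply the documented z correction
        table = table.assign(z_nm=table["z_nm"] * 0.7)
        centers = table.groupby("tid")[["x_nm", "y_nm", "z_nm"]].mean()
        origin = truth.traces.set_index("tid")
        true_pos = truth.protomers.set_index(["trimer_id", "protomer"])
        for tid, row in centers.iterrows():
            key = (origin.loc[tid, "trimer_id"], origin.loc[tid, "protomer"])
            np.testing.assert_allclose(
                row.to_numpy(),
                true_pos.loc[key, ["x_nm", "y_nm", "z_nm"]].to_numpy(float),
                atol=1e-9,
            )

    def test_fully_labelled_trimers_all_recovered_downstream(self):
        # tight conformational SD keeps every side well above the 8 nm
        # DBSCAN merge scale, so all ten triangles stay resolvable
        cfg = SynthMinfluxConfig(
            n_trimers=10, label_efficiency=1.0, background_trace_density=0.0,
            multi_emitter_fraction=0.0, interblade_sd=3.0, seed=8,
        )
        table, truth = generate_minflux_dataset(cfg)
        result = run_minflux_pipeline(table)
        assert len(result.trimers) == 10
        assert (truth.trimers["n_labeled"] == 3).all()

    def test_true_interblade_mean_matches_configured_regime(self):
        cfg = SynthMinfluxConfig(
            n_trimers=1000, field_size=6000.0, interblade_mean=21.7,
            interblade_sd=5.5, seed=17,
        )
        _, truth = generate_minflux_dataset(cfg)
        d = truth.trimers["interblade_nm"].to_numpy()
        sem = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean() - 21.7) < 3 * sem

    def test_no_true_pairwise_distance_exceeds_physical_bound(self):
        cfg = SynthMinfluxConfig(n_trimers=200, field_size=6000.0,
                                 interblade_mean=35.0, interblade_sd=8.0, seed=23)
        _, truth = generate_minflux_dataset(cfg)
        for _, grp in truth.protomers.groupby("trimer_id"):
            pos = grp[["x_nm", "y_nm", "z_nm"]].to_numpy()
            from scipy.spatial.distance import pdist

            assert pdist(pos).max() <= MAX_PAIR_DISTANCE_NM

    def test_ground_truth_internally_consistent(self, small_dataset):
        _, _, truth = small_dataset
        truth.check()

    @pytest.mark.parametrize(
        "bad",
        [
            {"label_efficiency": 1.2},
            {"multi_emitter_fraction": -0.1},
            {"interblade_mean": np.nan},
            {"loc_sd": np.inf},
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            SynthMinfluxConfig(**bad)

    def test_field_too_small_for_isolated_placement_rejected(self):
        with pytest.raises(ValueError, match="isolated"):
            generate_minflux_dataset(SynthMinfluxConfig(n_trimers=1000, field_size=1000.0))


class TestPressureSweeps:
    def test_noiseless_round_trip_recovers_p50(self):
        series = generate_pressure_sweeps(-30.0, 8.0, 500.0, PRESSURES, noise_sd=0.0)
        p, r = normalize_pressure_response(series)
        fit = fit_boltzmann(p, r)
        assert fit.p50_mmhg == pytest.approx(-30.0, abs=1e-6)

    def test_response_at_p50_is_half_maximal(self):
        series = generate_pressure_sweeps(-40.0, 8.0, 600.0, PRESSURES, noise_sd=0.0)
        idx = np.argmin(np.abs(series.stimuli - (-40.0)))
        peak = np.abs(series.currents[idx]).max()
        assert peak == pytest.approx(300.0)

    def test_median_p50_error_small_under_noise(self):
        errs = []
        for seed in range(200):
            series = generate_pressure_sweeps(
                -30.0, 8.0, 500.0, PRESSURES, noise_sd=0.05 * 500.0, seed=seed
            )
            p, r = normalize_pressure_response(series)
            errs.append(abs(fit_boltzmann(p, r).p50_mmhg - (-30.0)))
        assert np.median(errs) < 2.0

    def test_empty_pressure_list_rejected(self):
        with pytest.raises(ValueError):
            generate_pressure_sweeps(-30.0, 8.0, 500.0, [], noise_sd=0.0)


class TestCurrentDecay:
    def test_noiseless_tau_recovered(self):
        t, i = generate_current_decay(50.0, 400.0, 0.0, tau_ms=15.9)
        fit = fit_inactivation(t, i)
        assert fit.tau_inact_ms == pytest.approx(15.9, rel=0.01)

    def test_flat_trace_flagged_degenerate(self):
        t, i = generate_current_decay(50.0, 0.0, 0.0, tau_ms=10.0)
        fit = fit_inactivation(t, i)
        assert fit.degenerate and not fit.converged

    def test_tau_recovered_within_ten_percent_under_noise(self):
        errs = []
        for seed in range(100):
            t, i = generate_current_decay(
                50.0, 400.0, 0.0, tau_ms=15.9, noise_sd=40.0, seed=seed
            )
            fit = fit_inactivation(t, i)
            errs.append(abs(fit.tau_inact_ms - 15.9) / 15.9)
        assert np.median(errs) < 0.10

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            generate_current_decay(0.0, 100.0, 0.0, tau_ms=0.0)


class TestSingleChannel:
    def test_amplitude_follows_ohms_law_by_construction(self):
        series = generate_single_channel([-100.0], conductance_ps=40.0, reversal_mv=0.0)
        trace = series.traces[-100.0]
        levels = np.unique(trace)
        assert levels.tolist() == [-4.0, 0.0]

    def test_noiseless_iv_recovers_conductance(self):
        voltages = np.arange(-140.0, -20.0, 20.0)
        series = generate_single_channel(
            voltages, conductance_ps=40.0, reversal_mv=0.0, noise_sd_pa=0.05, seed=1
        )
        amps = voltage_amplitudes(series.traces, series.sample_rate_hz)
        fit = fit_iv(amps["voltage_mv"], amps["amplitude_pa"])
        assert fit.conductance_ps == pytest.approx(40.0, rel=0.02)

    def test_conductance_within_five_percent_under_noise(self):
        voltages = np.arange(-140.0, -20.0, 20.0)
        errs = []
        for seed in range(10):
            series = generate_single_channel(
                voltages, conductance_ps=40.0, reversal_mv=0.0,
                noise_sd_pa=0.4, seed=seed,  # 10% of the -100 mV amplitude
            )
            amps = voltage_amplitudes(series.traces, series.sample_rate_hz)
            fit = fit_iv(amps["voltage_mv"], amps["amplitude_pa"])
            errs.append(abs(fit.conductance_ps - 40.0) / 40.0)
        assert np.median(errs) < 0.05


class TestDoseResponse:
    def test_response_at_ec50_is_midpoint(self):
        table = generate_dose_response(
            0.03, 1.0, 5.0, [0.03], n_cells=3, noise_sd=0.0, bottom=1.0
        )
        assert table["max_f_over_f0"].iloc[0] == pytest.approx(3.0)

    def test_noiseless_round_trip_recovers_ec50(self):
        concs = 0.03 * np.logspace(-2, 2, 7)
        table = generate_dose_response(0.03, 1.2, 5.0, concs, n_cells=20, noise_sd=0.0)
        fit = fit_ec50(table)
        assert fit.ec50_um == pytest.approx(0.03, rel=1e-6)

    def test_log_ec50_error_small_under_noise(self):
        concs = 0.03 * np.logspace(-2, 2, 7)
        errs = []
        for seed in range(100):
            table = generate_dose_response(
                0.03, 1.2, 5.0, concs, n_cells=50, noise_sd=0.5, seed=seed
            )
            fit = fit_ec50(table)
            errs.append(abs(np.log10(fit.ec50_um) - np.log10(0.03)))
        assert np.median(errs) < 0.1


class TestToyPoses:
    def test_full_contact_reports_hundred_percent(self):
        ens = generate_toy_pose_ensemble(10, {"F1715": 1.0})
        profile = contact_frequency(ens)
        assert profile.fractions[("A", 1715, "PHE")] == 1.0

    def test_planned_fractions_reproduced_exactly(self):
        ens = generate_toy_pose_ensemble(100, {"F1715": 0.78, "A2091": 0.27}, seed=5)
        profile = contact_frequency(ens)
        assert profile.fractions[("A", 1715, "PHE")] == pytest.approx(0.78)
        assert profile.fractions[("A", 2091, "ALA")] == pytest.approx(0.27)

    def test_empty_plan_gives_no_contacts(self):
        ens = generate_toy_pose_ensemble(5, {})
        assert contact_frequency(ens).fractions == {}

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="unsatisfiable"):
            generate_toy_pose_ensemble(10, {"F1715": 1.5})
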