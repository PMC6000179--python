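"""Scenario runners: inhibitors, double shocks, diel forcing, ramps, maps."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from hsrsim import Step, integrate, steady_state
from hsrsim.experiments import (
    ArsExtension,
    ExperimentSpec,
    attach_ars_reporter,
    run_acclimation,
    run_diel,
    run_double_hs,
    run_hill_robustness,
    run_hsp_map,
    run_hp_expression,
    run_inhibitor,
    run_steady_state_scan,
    run_tau_scan,
    run_typical_hs,
)
from hsrsim.protocols import HOUR, MINUTE


@pytest.fixture(scope="module")
def tau_scan(params):
    return run_tau_scan(params)


@pytest.fixture(scope="module")
def double_hs(params):
    return run_double_hs(params)


class TestTypicalHs:
    def test_peak_fractions(self, params):
        _, summary = run_typical_hs(params)
        assert summary["misfolded_fraction"]["max"] == pytest.approx(0.05,
                                                                     rel=0.2)
        assert summary["active_kinase_fraction"]["max"] == pytest.approx(
            0.80, rel=0.15)

    def test_no_denaturation_no_response(self, params, ss25):
        # without the temperature stimulus the shock leaves no trace
        quiet = params.scaled(k_TP=1e-20)
        ss = steady_state(quiet, 25.0)
        traj = integrate(quiet, Step(25.0, 42.0, 20 * MINUTE), 2 * HOUR,
                         init=ss, n_points=201)
        assert np.max(np.abs(traj.y - traj.y[0])) < 1e-6  # pools are O(1) mM
        assert traj.misfolded_fraction.max() < 1e-6
        assert traj.active_kinase_fraction.max() < 1e-6


class TestInhibitors:
    def test_staurosporine_dose_dependence(self, params):
        res = run_inhibitor(params, "staurosporine")
        runs = [res["runs"][s] for s in (1.0, 0.6, 0.1)]
        peaks = [r["peak"] for r in runs]
        t_peaks = [r["t_peak"] for r in runs]
        assert peaks[0] > peaks[1] > peaks[2]       # reduced maximal response
        assert t_peaks[0] < t_peaks[2]              # delayed response

    def test_radicicol_amplifies_and_delays(self, params):
        res = run_inhibitor(params, "radicicol")
        runs = [res["runs"][s] for s in (1.0, 0.6, 0.3)]
        peaks = [r["peak"] for r in runs]
        t_peaks = [r["t_peak"] for r in runs]
        assert peaks[0] < peaks[1] < peaks[2]       # increased amplitude
        assert t_peaks[0] < t_peaks[2]              # delayed attenuation

    def test_unit_scale_is_exact_control(self, params):
        res = run_inhibitor(params, "staurosporine", scales=(1.0,))
        control = run_inhibitor(params, "radicicol", scales=(1.0,))
        np.testing.assert_array_equal(
            res["runs"][1.0]["trajectory"].y,
            control["runs"][1.0]["trajectory"].y)

    def test_unknown_drug_rejected(self, params):
        with pytest.raises(ValueError, match="unknown drug"):
            run_inhibitor(params, "aspirin")


class TestDoubleHs:
    def test_second_response_grows_with_interval(self, double_hs):
        gaps = sorted(double_hs)
        ratios = [double_hs[g]["mH_ratio"] for g in gaps]
        assert all(b > a for a, b in zip(ratios, ratios[1:]))
        ars = [double_hs[g]["ars_ratio"] for g in gaps]
        assert all(b > a for a, b in zip(ars, ars[1:]))

    def test_full_second_response_only_after_five_hours(self, double_hs):
        assert not double_hs[4 * HOUR]["full_second_response"]
        assert double_hs[5 * HOUR]["full_second_response"]

    def test_second_shock_misfolds_far_less_protein(self, double_hs):
        for entry in double_hs.values():
            assert entry["pm_peak_second"] < 0.5 * entry["pm_peak_first"]

    def test_reporter_follows_linear_oracle(self, double_hs):
        # integrate the reporter equations independently (integrating factor
        # + trapezoid quadrature) against the attached solution
        ars = ArsExtension()
        traj = double_hs[5 * HOUR]["trajectory"]
        got = double_hs[5 * HOUR]["ars"]["mA"]
        t, fag = traj.t, traj.species("FaG")
        growth = np.exp(ars.eta_mA * t)
        integral = cumulative_trapezoid(ars.pi_mA * fag * growth, t, initial=0)
        want = (got[0] + integral) / growth
        assert np.max(np.abs(got - want)) < 1e-3 * want.max()


class TestHpExpression:
    def test_sigmoid_rise_then_late_decline(self, params):
        res = run_hp_expression(params)
        assert res.initially_slow and res.late_decline
        assert 0 < res.t_peak < res.trajectory.t[-1]

    def test_shape_flags_match_direct_finite_differences(self, params):
        res = run_hp_expression(params)
        H, t = res.trajectory.species("H"), res.trajectory.t
        i = int(np.argmax(H))
        d2 = np.gradient(np.gradient(H, t), t)
        assert res.initially_slow == bool(np.any(d2[1:max(i, 2)] > 0))
        assert res.late_decline == bool(H[-1] < H[i])

    def test_no_translation_no_accumulation(self, params, ss25):
        # block HP translation at shock time: no chaperone accumulates
        quiet = params.scaled(pi_H=1e-12)
        traj = integrate(quiet, Step(25.0, 42.0, 0.0), 2 * HOUR, init=ss25,
                         n_points=201)
        H = traj.species("H")
        assert H.max() <= H[0] * (1 + 1e-9)     # never rises above baseline
        assert H[-1] <= H[0]                     # only slow decay remains


class TestDiel:
    def test_misfolding_stays_negligible(self, params):
        res = run_diel(params)
        assert res["max_misfolded_fraction"] < 0.0025
        assert res["max_active_kinase_fraction"] == pytest.approx(0.04,
                                                                  rel=0.3)

    def test_response_peaks_before_temperature_maximum(self, params):
        res = run_diel(params)
        assert 11.0 < res["response_max_clock_h"] < 15.0
        assert res["onset_clock_h"] < res["response_max_clock_h"]


class TestTauScan:
    def test_two_plateaus_with_large_ratio(self, tau_scan):
        assert tau_scan["plateau_ratio"] == pytest.approx(20.0, rel=0.3)

    def test_peak_nonincreasing_in_tau(self, tau_scan):
        d = np.diff(tau_scan["max_misfolded_fraction"])
        assert np.all(d <= 1e-3 * tau_scan["fast_plateau"])

    def test_fast_ramp_reproduces_step_maximum(self, params, tau_scan,
                                               step_trajectory):
        step_max = step_trajectory.misfolded_fraction.max()
        assert tau_scan["fast_plateau"] == pytest.approx(step_max, rel=0.01)


class TestAcclimation:
    def test_long_shock_reaches_quasi_steady_state(self, params):
        res = run_acclimation(params, duration=10 * HOUR)
        assert res["acclimated"]
        assert res["acclimated_from_s"] > 3 * HOUR   # after the early phase
        assert res["residual_drift"] < 2e-3
        # the observable stress level sits near its asymptotic value
        ss = res["steady_state"]
        assert res["final_state"].misfolded_fraction == pytest.approx(
            ss.misfolded_fraction, rel=1.5)

    def test_short_shock_has_no_steady_phase(self, params):
        assert not run_acclimation(params, duration=1 * HOUR)["acclimated"]


class TestSteadyStateScan:
    def test_low_temperature_plateau_and_monotonicity(self, params, ss25):
        # 50 degC sits beyond the response's capacity: flagged non-viable
        res = run_steady_state_scan(params, np.array([20.0, 25.0, 30.0,
                                                      40.0, 50.0]))
        pm = res["misfolded_fraction"]
        assert np.all(pm[:3] < 1e-3)            # plateau near zero
        viable = ~res["non_viable"]
        assert np.all(np.diff(pm[viable]) > -1e-10)  # rises with temperature
        assert pm[viable][-1] > pm[2] > pm[0]
        # consistency with the simulator's steady state at 25 degC
        assert pm[1] == pytest.approx(ss25.misfolded_fraction, rel=1e-6)
        # viability flags, if any, form an upper set in temperature
        flags = res["non_viable"]
        assert np.all(np.diff(flags.astype(int)) >= 0)


class TestHspMap:
    def test_baseline_and_monotone_accumulation(self, params):
        # monotone in duration at moderate temperature, up to the HP peak
        durations = np.array([0.0, 0.5 * HOUR, 1 * HOUR, 2 * HOUR])
        res = run_hsp_map(params, np.array([35.0]), durations)
        hp = res["relative_HP"][0]
        assert hp[0] == 1.0
        assert np.all(np.diff(hp) > 0)
        assert not res["failed"].any()

    def test_cell_matches_standalone_integration(self, params, ss25):
        from hsrsim.protocols import Pulse
        res = run_hsp_map(params, np.array([42.0]), np.array([4 * HOUR]))
        traj = integrate(params, Pulse(25.0, 42.0, 0.0, 4 * HOUR), 4 * HOUR,
                         init=ss25, n_points=401)
        want = traj.species("H")[-1] / ss25.H
        assert res["relative_HP"][0, 0] == pytest.approx(want, rel=1e-6)


class TestHillRobustness:
    def test_two_plateau_structure_is_robust(self, params):
        res = run_hill_robustness(params, m_values=(2.0, params.m),
                                  P0_values=(params.P0, 2 * params.P0))
        assert res["robust"]
        for scan in res["scans"].values():
            assert scan["plateau_ratio"] > res["ratio_threshold"]

    def test_default_pair_matches_standalone_scan(self, params):
        taus = np.array([6.0, 6.0e4])
        res = run_hill_robustness(params, m_values=(params.m,),
                                  P0_values=(params.P0,), taus=taus)
        standalone = run_tau_scan(params, taus)
        got = res["scans"][(params.m, params.P0)]
        assert got["plateau_ratio"] == pytest.approx(
            standalone["plateau_ratio"], rel=1e-9)


class TestSpecsAndTypes:
    def test_experiment_spec_validation(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            ExperimentSpec(name="x", scale_factors={"nope": 0.5})
        with pytest.raises(ValueError, match="positive"):
            ExperimentSpec(name="x", scale_factors={"kp_F": 0.0})
        spec = ExperimentSpec(name="x", scale_factors={"kp_F": 0.5})
        assert spec.apply_scales  # constructible

    def test_ars_extension_validation(self):
        with pytest.raises(ValueError):
            ArsExtension(pi_A=0.0)

    def test_reporter_has_no_feedback(self, params, step_trajectory):
        # attaching the reporter does not modify the core trajectory
        before = step_trajectory.y.copy()
        attach_ars_reporter(step_trajectory)
        np.testing.assert_array_equal(step_trajectory.y, before)
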