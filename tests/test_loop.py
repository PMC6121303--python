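"""Oxidant amplification loop: derivatives, calibration, perturbation response."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from pumploop import loop as L

ZERO = L.LoopParams(
    synth_rate=0, k_12=0, k_21=0, g_ros_shift=0, rho_basal=0, g_src_ros=0,
    delta_ros=0, g_endo=0, k_src_act=0, delta_srcp=0, g_cts_shift=0,
    a_ros=0, deg_endo=0,
)


class TestOccupancy:
    def test_zero_concentration(self):
        assert L.ouabain_occupancy(0.0, 1000.0) == 0.0

    def test_ic50_is_half_occupancy(self):
        assert L.ouabain_occupancy(1000.0, 1000.0) == pytest.approx(0.5)

    def test_hundred_micromolar_at_millimolar_ic50(self):
        assert L.ouabain_occupancy(100.0, 1000.0) == pytest.approx(1.0 / 11.0)

    def test_bad_ic50_rejected(self):
        with pytest.raises(L.LoopError):
            L.ouabain_occupancy(10.0, 0.0)


class TestDerivatives:
    def test_all_rates_zero_gives_zero_vector(self, rng):
        y = np.abs(rng.normal(size=6)) * [1e6, 1e6, 1e4, 0.1, 1.0, 10.0]
        np.testing.assert_array_equal(L.derivatives(y, ZERO), np.zeros(6))

    def test_ros_linear_balance_fixed_point(self):
        p = replace(ZERO, rho_basal=2.0, delta_ros=0.5)
        y = np.array([1e6, 1e6, 0.0, 0.0, 4.0, 0.0])  # ROS* = rho/delta = 4
        d = L.derivatives(y, p)
        assert d[4] == pytest.approx(0.0, abs=1e-14)
        y_off = y.copy()
        y_off[4] = 1.0
        assert L.derivatives(y_off, p)[4] == pytest.approx(2.0 - 0.5)

    def test_pump_mass_balance_identity(self, calibrated_params, rng):
        # oracle: summing the implemented pump terms must leave only
        # synthesis minus endo-degradation, for any state
        p = calibrated_params
        for _ in range(20):
            y = np.abs(rng.normal(size=6)) * [1e6, 1e6, 1e5, 0.2, 2.0, 10.0]
            d = L.derivatives(y, p, ouabain_conc=rng.uniform(0, 200))
            expected = p.synth_rate - p.deg_endo * y[2]
            assert d[:3].sum() == pytest.approx(expected, rel=1e-12, abs=1e-9)

    def test_negative_state_rejected(self, calibrated_params):
        with pytest.raises(L.LoopError, match="negative"):
            L.derivatives(np.array([-1e5, 1, 1, 1, 1, 1]), calibrated_params)


class TestSimulate:
    def test_zero_gain_fixed_point_stays_constant(self):
        p = replace(ZERO, k_12=0.02, k_21=0.03, rho_basal=1.0, delta_ros=0.5,
                    k_src_act=0.01, delta_srcp=0.01)
        # analytic fixed point: E1/E2 balance, ROS = rho/delta,
        # Src_p solves k_act*(pool - s) = delta * s
        n_tot = 2.0e6
        n1 = p.k_21 / (p.k_12 + p.k_21) * n_tot
        n2 = n_tot - n1
        pool = p.frac_src_controlled * p.src_total * (1.0 - n1 / n_tot)
        srcp = p.k_src_act * pool / (p.k_src_act + p.delta_srcp)
        y0 = np.array([n1, n2, 0.0, srcp, p.rho_basal / p.delta_ros, 0.0])
        traj = L.simulate(p, t_grid=np.linspace(0, 500, 51), y0=y0)
        np.testing.assert_allclose(
            traj.frame.iloc[-1][list(L.STATE_COLUMNS)].to_numpy(dtype=float),
            y0,
            rtol=1e-6,
            atol=1e-6,
        )

    def test_fig6_e1_fraction_drops_after_onset(self, fig6_trajectory):
        f = fig6_trajectory.frame
        e1 = f["N_E1"] / (f["N_E1"] + f["N_E2"])
        pre = e1[f["t"] < 2500].iloc[-1]
        assert pre == pytest.approx(0.5, abs=0.01)
        assert e1[f["t"] > 2600].max() < pre

    def test_solver_self_convergence(self, calibrated_params):
        pert = (L.Perturbation("ouabain", 500.0, 100.0),)
        coarse = L.simulate(calibrated_params, pert, t_grid=np.linspace(0, 1000, 101))
        fine = L.simulate(calibrated_params, pert, t_grid=np.linspace(0, 1000, 201))
        a = coarse.frame.set_index("t")
        b = fine.frame.set_index("t").loc[a.index]
        scale = np.maximum(np.abs(a.to_numpy()), 1.0)
        assert np.max(np.abs(a.to_numpy() - b.to_numpy()) / scale) < 1e-6

    def test_states_stay_nonnegative(self, fig6_trajectory):
        assert (fig6_trajectory.frame[list(L.STATE_COLUMNS)] >= 0).all().all()

    def test_ros_bolus_decays_back(self, calibrated_params):
        pert = (L.Perturbation("ros_bolus", 100.0, 5.0),)
        traj = L.simulate(calibrated_params, pert, t_grid=np.linspace(0, 2000, 201))
        ros = traj.frame["ROS"]
        basal = ros.iloc[0]
        assert ros.max() > basal + 2.0
        assert ros.iloc[-1] == pytest.approx(basal, rel=0.05)

    def test_bad_grid_rejected(self, calibrated_params):
        with pytest.raises(L.LoopError):
            L.simulate(calibrated_params, t_grid=np.array([0.0, 2.0, 1.0]))

    def test_unknown_perturbation_kind_rejected(self):
        with pytest.raises(L.LoopError, match="kind"):
            L.Perturbation("heat_shock", 0.0, 1.0)


class TestCalibration:
    def test_satisfied_guess_returned_unchanged(self, calibrated_params):
        assert L.calibrate_basal(calibrated_params) is calibrated_params

    def test_calibrated_e1_fraction_hits_target(self):
        bad = replace(L.LoopParams(), k_21=0.08, synth_rate=50.0)
        cal = L.calibrate_basal(bad)
        fp = L.basal_fixed_point(cal)
        assert 0.49 <= L.e1_fraction(fp) <= 0.51
        assert fp[0] + fp[1] == pytest.approx(cal.pump_total_surface, rel=1e-6)

    def test_residual_recomputed_independently(self, calibrated_params):
        fp = L.basal_fixed_point(calibrated_params)
        d = L.derivatives(fp, calibrated_params)
        scale = np.array([2e6, 2e6, 2e6, 1.0, 1.0])
        assert np.max(np.abs(d[:5]) / scale) < 1e-6

    def test_stationary_through_horizon(self, calibrated_params):
        traj = L.simulate(
            calibrated_params, t_grid=np.linspace(0, 2500, 251)
        )
        d_end = L.derivatives(traj.state_at(-1), calibrated_params)
        assert np.max(np.abs(d_end[:5]) / np.array([2e6, 2e6, 2e6, 1, 1])) < 1e-6

    def test_impossible_target_reports_failure(self):
        with pytest.raises((L.CalibrationError, L.LoopError)):
            L.calibrate_basal(
                replace(L.LoopParams(), k_21=1.0),
                L.CalibrationTargets(e1_fraction=1.0),
            )


class TestSummarize:
    def test_constant_trajectory_has_unit_folds(self, calibrated_params):
        traj = L.simulate(calibrated_params, t_grid=np.linspace(0, 500, 51))
        traj = L.Trajectory(
            frame=traj.frame,
            events=(L.Perturbation("ouabain", 250.0, 0.0),),  # null dose
        )
        m = L.summarize(traj)
        assert m["peak_ros_fold"] == pytest.approx(1.0, rel=1e-6)
        assert m["peak_srcp_fold"] == pytest.approx(1.0, rel=1e-6)
        assert m["plasma_pump_loss"] == pytest.approx(0.0, abs=1e-6)

    def test_no_perturbation_post_metrics_absent(self, calibrated_params):
        traj = L.simulate(calibrated_params, t_grid=np.linspace(0, 200, 21))
        m = L.summarize(traj)
        assert m["peak_ros_fold"] is None
        assert m["min_e1_fraction_post"] is None

    def test_fig6_directional_changes(self, fig6_trajectory):
        m = L.summarize(fig6_trajectory)
        assert m["min_e1_fraction_post"] < m["basal_e1_fraction"]
        assert m["peak_ros_fold"] > 1.0
        assert m["peak_srcp_fold"] > 1.0
        assert m["plasma_pump_loss"] > 0.0
        assert m["aging_slope_post"] > m["aging_slope_pre"]

    def test_metrics_survive_csv_round_trip(self, fig6_trajectory, tmp_path):
        path = tmp_path / "traj.csv"
        L.trajectory_to_csv(fig6_trajectory, path)
        # independent recompute from the written file
        frame = pd.read_csv(path, float_precision="round_trip")
        clone = L.Trajectory(frame=frame, events=fig6_trajectory.events)
        assert L.summarize(clone) == L.summarize(fig6_trajectory)


class TestInvariantsAndRecovery:
    def test_mass_balance_along_trajectory(self, fig6_trajectory, calibrated_params):
        resid = L.mass_balance_residual(fig6_trajectory, calibrated_params)
        assert np.max(np.abs(resid)) / calibrated_params.pump_total_surface < 1e-4

    def test_monotone_ouabain_dose_response(self, calibrated_params):
        doses = [0.0, 250.0, 500.0, 750.0, 1000.0]
        steady = []
        for c in doses:
            traj = L.simulate(
                calibrated_params,
                (L.Perturbation("ouabain", 100.0, c),),
                t_grid=np.linspace(0, 8000, 161),
            )
            steady.append(traj.frame["ROS"].iloc[-1])
        assert all(b >= a - 1e-9 for a, b in zip(steady, steady[1:]))

    def test_feed_forward_gain_amplifies_but_selflimits(self, calibrated_params):
        """Raising the g_src_ros*g_ros_shift product amplifies steady-state
        ROS monotonically while the basal fixed point stays stable: the
        additive rate coupling and finite Src pool make the loop gain
        self-limiting, so there is no finite instability threshold."""
        p = calibrated_params
        ros_prev, lam_prev = 0.0, None
        for c in [1.0, 4.0, 16.0, 64.0]:
            s = np.sqrt(c)
            cand = replace(p, g_src_ros=p.g_src_ros * s, g_ros_shift=p.g_ros_shift * s)
            fp = L.basal_fixed_point(cand)
            lam = L.leading_eigenvalue(cand, fp)
            assert lam < 0.0
            assert fp[4] > ros_prev
            ros_prev, lam_prev = fp[4], lam

    def test_parameter_recovery_within_five_percent(self, calibrated_params):
        p = calibrated_params
        pert = (L.Perturbation("ouabain", 200.0, 100.0),)
        truth = L.simulate(p, pert, t_grid=np.linspace(0, 800, 161))
        g, d = L.fit_ros_parameters(truth, p, x0=(0.2, 0.05), perturbations=pert)
        assert g == pytest.approx(p.g_src_ros, rel=0.05)
        assert d == pytest.approx(p.delta_ros, rel=0.05)
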