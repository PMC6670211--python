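"""Switched-ODE integration, steady-state detection, early-kinetics summaries."""

import numpy as np
import pytest

import hepaflux as hf
from hepaflux.errors import InsufficientData, InvalidInput
from oracles import dutycycle_ss_nh3_mm


@pytest.fixture(scope="module")
def absorption_only(baseline_scenario):
    """All enzymes and excretions off: ammonia grows linearly, closed form."""
    return baseline_scenario.with_kinetics(
        vmax_gls=0.0, vmax_cps1=0.0, vmax_glul=0.0, v_nh3_ex=0.0, v_urea_ex=0.0
    )


class TestTrajectoryStructure:
    def test_times_strictly_increasing_and_span_duration(self, baseline_traj):
        assert np.all(np.diff(baseline_traj.times) > 0)
        assert baseline_traj.times[0] == 0.0
        assert baseline_traj.times[-1] == pytest.approx(774.0, abs=1e-6)

    def test_phase_boundaries_present(self, baseline_traj):
        t = baseline_traj.times
        for k in (0, 1, 50, 179):
            assert np.any(np.isclose(t, k * 4.3, atol=1e-9))
            assert np.any(np.isclose(t, k * 4.3 + 2.87, atol=1e-9))

    def test_concentrations_nonnegative_throughout(self, baseline_traj):
        assert np.all(baseline_traj.states >= 0.0)

    def test_phase_annotation_alternates(self, baseline_traj):
        # within (0, 2.87) the phase id is 1; within (2.87, 4.3) it is 2
        t, p = baseline_traj.times, baseline_traj.phase_id
        assert set(p[(t > 0.1) & (t < 2.8)]) == {1}
        assert set(p[(t > 2.9) & (t < 4.2)]) == {2}

    def test_tidy_frame_long_format(self, baseline_traj):
        df = baseline_traj.to_frame()
        assert set(df["species"]) == {"nh3", "urea", "gln"}
        assert len(df) == 3 * len(baseline_traj.times)

    def test_zero_duration_rejected(self, baseline_scenario):
        with pytest.raises(InvalidInput):
            hf.simulate(baseline_scenario, duration_s=0.0)


class TestClosedFormOracle:
    def test_absorption_only_growth_is_linear(self, absorption_only):
        traj = hf.simulate(absorption_only, duration_s=43.0)
        k = absorption_only.kinetics
        v = absorption_only.physiology.blood_volume_l
        predicted = k.v_nh3_abs * traj.times / (60.0 * v)
        np.testing.assert_allclose(traj.nh3, predicted, rtol=1e-9, atol=1e-14)
        assert np.all(traj.urea == 5.5)
        assert np.all(traj.gln == 0.0)

    def test_linear_growth_never_reaches_steady_state(self, absorption_only):
        ss = hf.detect_steady_state(hf.simulate(absorption_only))
        assert not ss.converged

    def test_initial_rate_equals_influx_per_volume(self, absorption_only):
        traj = hf.simulate(absorption_only, duration_s=43.0)
        k = absorption_only.kinetics
        v = absorption_only.physiology.blood_volume_l
        assert hf.initial_average_rate(traj) == pytest.approx(
            k.v_nh3_abs / (60.0 * v) * 1e3, rel=1e-9
        )


class TestSteadyStateDetection:
    def test_baseline_reaches_physiological_steady_state(self, baseline_ss):
        assert baseline_ss.converged
        assert baseline_ss.ss_nh3_um == pytest.approx(17.5, rel=0.10)
        assert baseline_ss.ss_urea_mm == pytest.approx(5.5, abs=0.3)
        assert abs(baseline_ss.final_relative_rate_pct_per_s) < 0.002

    def test_steady_state_read_from_last_cycle_peak(self, baseline_ss, baseline_traj):
        assert baseline_ss.ss_nh3_mm == baseline_ss.peak_values_mm[-1]
        assert baseline_ss.peak_values_mm.size == 180
        # the peak sits at the end of the CPS1/GLS phase, not at the cycle end
        m = (baseline_ss.peak_times_s[-1] - 2.87) % 4.3
        assert min(m, 4.3 - m) < 0.2

    def test_constant_trajectory_converges_with_zero_rate(self, baseline_scenario):
        times = np.linspace(0.0, 43.0, 500)
        states = np.tile([0.02, 5.5, 0.1], (times.size, 1))
        traj = hf.Trajectory(
            times=times,
            states=states,
            phase_id=np.ones(times.size, dtype=int),
            scenario=baseline_scenario,
            schedule=hf.ZonationSchedule(),
        )
        ss = hf.detect_steady_state(traj)
        assert ss.converged
        assert ss.final_relative_rate_pct_per_s == 0.0
        assert ss.ss_nh3_mm == 0.02

    def test_fewer_than_three_cycles_is_insufficient(self, baseline_scenario):
        traj = hf.simulate(baseline_scenario, duration_s=8.6)
        with pytest.raises(InsufficientData):
            hf.detect_steady_state(traj)

    def test_rhs_time_average_vanishes_at_steady_state(self, baseline_traj):
        """Over the final full cycle the cycle-averaged derivative of every
        species is below the steady-state criterion (0.002%/s relative)."""
        t, x = baseline_traj.times, baseline_traj.states
        mask = t >= 774.0 - 4.3 - 1e-9
        tc, xc = t[mask], x[mask]
        avg_rate = (xc[-1] - xc[0]) / (tc[-1] - tc[0])  # mM/s
        swing = xc[:, 0].max() - xc[:, 0].min()
        assert abs(avg_rate[0]) * 4.3 < 1e-3 * swing
        # urea and glutamine carry no comparable intra-cycle swing; the
        # convergence criterion is defined on ammonia, so only require their
        # residual drift to be small (<0.01%/s relative)
        for i in (1, 2):
            assert abs(avg_rate[i]) / xc[-1, i] < 1e-4


class TestInvariants:
    def test_nitrogen_conserved_along_trajectory(self, baseline_traj):
        """V_blood * (nh3 + gln + 2*urea) minus the integrated net input
        (absorption - excretions) stays constant to integration tolerance."""
        s = baseline_traj.scenario
        k = s.kinetics
        v = s.physiology.blood_volume_l
        total_n = v * (baseline_traj.nh3 + baseline_traj.gln + 2.0 * baseline_traj.urea)
        net_in = (k.v_nh3_abs - k.v_nh3_ex - 2.0 * k.v_urea_ex) / 60.0
        expected = total_n[0] + net_in * baseline_traj.times
        assert np.max(np.abs(total_n - expected)) < 1e-7 * total_n[0]

    def test_duty_cycle_oracle_agrees_with_baseline(self, baseline_scenario, baseline_ss):
        oracle = dutycycle_ss_nh3_mm(baseline_scenario)
        assert baseline_ss.ss_nh3_mm == pytest.approx(oracle, rel=0.10)

    def test_refinement_stability(self, baseline_scenario, baseline_ss):
        fine = hf.SolverOptions(rtol=5e-9, atol=5e-11, points_per_phase=48)
        ss_fine = hf.detect_steady_state(
            hf.simulate(baseline_scenario, solver=fine)
        )
        assert ss_fine.ss_nh3_mm == pytest.approx(baseline_ss.ss_nh3_mm, rel=1e-3)

    def test_steady_state_monotone_in_cps1_and_absorption(self, baseline_scenario):
        cps1_ss = []
        for f in (0.5, 0.75, 1.0, 1.25, 1.5):
            s = baseline_scenario.with_kinetics(
                vmax_cps1=baseline_scenario.kinetics.vmax_cps1 * f
            )
            cps1_ss.append(hf.detect_steady_state(hf.simulate(s)).ss_nh3_mm)
        assert all(a > b for a, b in zip(cps1_ss, cps1_ss[1:]))

        abs_ss = []
        for f in (0.6, 0.8, 1.0, 1.2, 1.4):
            s = baseline_scenario.with_kinetics(
                v_nh3_abs=baseline_scenario.kinetics.v_nh3_abs * f
            )
            abs_ss.append(hf.detect_steady_state(hf.simulate(s)).ss_nh3_mm)
        assert all(a < b for a, b in zip(abs_ss, abs_ss[1:]))


class TestEarlyKinetics:
    def test_baseline_rise_rate(self, baseline_traj):
        assert hf.initial_average_rate(baseline_traj) == pytest.approx(0.55, rel=0.15)

    def test_glul_knockout_rises_faster(self, glul_knockout_traj, baseline_traj):
        assert hf.initial_average_rate(glul_knockout_traj) == pytest.approx(
            0.83, rel=0.15
        )
        assert hf.initial_average_rate(glul_knockout_traj) > hf.initial_average_rate(
            baseline_traj
        )

    def test_glul_knockout_same_steady_state_reached_sooner(
        self, glul_knockout_traj, baseline_traj, baseline_ss
    ):
        ss_ko = hf.detect_steady_state(glul_knockout_traj)
        assert ss_ko.ss_nh3_mm == pytest.approx(baseline_ss.ss_nh3_mm, rel=0.05)
        t_ko = hf.time_to_fraction(glul_knockout_traj, ss_ko.ss_nh3_mm, 0.9)
        t_base = hf.time_to_fraction(baseline_traj, baseline_ss.ss_nh3_mm, 0.9)
        assert t_ko < t_base

    def test_window_longer_than_trajectory_rejected(self, baseline_scenario):
        traj = hf.simulate(baseline_scenario, duration_s=12.9)
        with pytest.raises(InvalidInput):
            hf.initial_average_rate(traj, window_s=20.0)


class TestSchedule:
    def test_defaults_compose_the_sinusoid_transit(self):
        sched = hf.ZonationSchedule()
        assert sched.cycle_s == pytest.approx(4.3)
        assert sched.phase1_s == pytest.approx(2 * sched.phase2_s, rel=0.01)

    def test_inconsistent_cycle_rejected(self):
        with pytest.raises(InvalidInput):
            hf.ZonationSchedule(phase1_s=2.87, phase2_s=1.43, cycle_s=5.0)
        with pytest.raises(InvalidInput):
            hf.ZonationSchedule(phase1_s=-1.0)
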