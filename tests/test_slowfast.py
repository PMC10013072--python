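import numpy as np
import pytest

from rotorpool.model import ModelParams, ResourceState
from rotorpool.slowfast import (
    ActivityTable,
    adiabatic_sweep,
    apply_perturbation,
    average_activity_map,
    classify_regime,
    count_zero_crossings,
    reduced_rhs,
    simulate_reduced_oa,
    _initial_state,
)


class TestClassifyRegime:
    def test_steady(self):
        t = np.linspace(0, 100, 201)
        assert classify_regime(t, np.full(t.size, -0.05)) == "steady"

    def test_bursting_needs_recurrent_sign_changes(self):
        t = np.linspace(0, 100, 201)
        lam = 0.3 * np.sin(0.3 * t)
        assert classify_regime(t, lam) == "bursting"
        assert classify_regime(t, np.full(t.size, 0.2)) == "active"

    def test_zero_crossing_count(self):
        t = np.linspace(0, 10, 11)
        x = np.array([-1, 1, 1, -1, -1, 1, -1, 1, 1, 1, 1.0])
        assert count_zero_crossings(t, x) == 5
        assert count_zero_crossings(t, x, transient=4.0) == 3


class TestActivityTable:
    def _table(self):
        r1 = np.array([0.0, 1.0, 2.0])
        r2 = np.array([0.0, 1.0])
        A = np.array([[0.0, 1.0], [2.0, 3.0], [4.0, 5.0]])
        return ActivityTable(r1_grid=r1, r2_grid=r2, mean_A=A, mean_R=1.0 - A / 5.0)

    def test_bilinear_interpolation_bounded_by_nodes(self, rng):
        tab = self._table()
        for _ in range(50):
            x = rng.uniform(0, 2)
            y = rng.uniform(0, 1)
            v = tab.activity(x, y)
            assert tab.mean_A.min() - 1e-12 <= v <= tab.mean_A.max() + 1e-12
        assert tab.activity(0.5, 0.5) == pytest.approx(1.5)

    def test_outside_hull_rejected(self):
        tab = self._table()
        with pytest.raises(ValueError):
            tab.activity(2.5, 0.5)


class TestAverageActivityMap:
    def test_stationary_cell_matches_time_average(self, branches_ref):
        # two-method agreement: closed-form stationary activity of the
        # stable branch vs the time-averaged OA integration
        tab = average_activity_map([0.9], [2.0], 5.0)
        b1 = branches_ref[0]
        assert tab.activity(0.9, 2.0) == pytest.approx(b1.activity, abs=1e-3)
        assert tab.coherence(0.9, 2.0) == pytest.approx(b1.R, abs=1e-3)

    def test_deep_inactive_cell_is_quiescent(self):
        tab = average_activity_map([0.5], [0.5], 5.0)
        assert abs(tab.activity(0.5, 0.5)) < 1e-3


class TestReducedRhs:
    def test_fixed_point_with_zero_activity(self):
        params = ModelParams()
        grid = np.linspace(0.4, 1.6, 4)
        tab = ActivityTable(r1_grid=grid, r2_grid=grid,
                            mean_A=np.zeros((4, 4)), mean_R=np.ones((4, 4)))
        dr, dlam = reduced_rhs(ResourceState(r=params.s, lam=params.lambda0), tab, params)
        assert dr == 0
        assert dlam == pytest.approx(0.0, abs=1e-15)

    def test_activity_drives_lambda_up(self):
        params = ModelParams()
        grid = np.linspace(0.4, 1.6, 4)
        tab = ActivityTable(r1_grid=grid, r2_grid=grid,
                            mean_A=np.full((4, 4), 0.8), mean_R=np.ones((4, 4)))
        _, dlam = reduced_rhs(ResourceState(r=params.s, lam=0.0), tab, params)
        assert dlam == pytest.approx(params.lambda0 + params.gamma * 0.8)


class TestReducedOA:
    def test_bursting_at_reference_parameters(self, burst_ts_reduced):
        # the coupled reduced system reproduces collective activity
        # bursting: recurrent sign alternation of lam
        ts = burst_ts_reduced
        m = (ts.t >= 500.0)
        assert count_zero_crossings(ts.t[m], ts.lam[m]) >= 3
        assert classify_regime(ts.t, ts.lam, 500.0) == "bursting"
        # activity alternates between quiescent and active episodes
        assert np.min(ts.A[m]) < 0.05
        assert np.max(ts.A[m]) > 0.5

    def test_feedback_off_relaxes_to_layer_attractor(self):
        params = ModelParams(gamma=0.0)
        ts = simulate_reduced_oa(params, res0=ResourceState(r=params.s + 0.2, lam=0.1),
                                 t_end=2000.0, M=101)
        assert abs(ts.lam[-1] - params.lambda0) < 1e-6
        assert abs(ts.r1[-1] - params.s1) < 1e-2
        assert abs(ts.r2[-1] - params.s2) < 1e-2

    def test_steady_state_identity(self):
        # in a steady final state, lam = lambda0 + gamma * A (fixed point)
        params = ModelParams(s1=0.9)  # comfortably inside the steady region
        ts = simulate_reduced_oa(params, res0=ResourceState(r=params.s + 0.05,
                                                            lam=params.lambda0),
                                 t_end=1500.0, M=101)
        assert classify_regime(ts.t, ts.lam, 1000.0) == "steady"
        assert ts.lam[-1] == pytest.approx(params.lambda0 + params.gamma * ts.A[-1], abs=1e-3)

    def test_cross_engine_burst_counts_agree(self, burst_ts_network, burst_ts_reduced):
        # mean-field reduction and microscopic network agree on the number
        # of resource activation/deactivation events per 2000 time units
        counts = []
        for ts in (burst_ts_network, burst_ts_reduced):
            m = (ts.t >= 500.0) & (ts.t <= 2500.0)
            counts.append(count_zero_crossings(ts.t[m], ts.lam[m]))
        assert abs(counts[0] - counts[1]) <= 1

    def test_burst_mechanism_lambda_rises_only_with_activity(self, burst_ts_reduced):
        # lam can only cross zero upward while the population is active:
        # at an up-crossing, lam' > 0 requires gamma*A > -lambda0
        params = ModelParams()
        ts = burst_ts_reduced
        lam, A, t = ts.lam, ts.A, ts.t
        up = np.nonzero((lam[:-1] < 0) & (lam[1:] >= 0) & (t[1:] > 300))[0]
        assert up.size >= 2
        for i in up:
            assert A[i] > -params.lambda0 / params.gamma


class TestSweepsAndPerturbations:
    def test_sweep_chain_bookkeeping(self):
        # short reduced-OA sweep: grid, warm-start chaining, labels present
        params = ModelParams(N=100)
        sw = adiabatic_sweep(0.86, 0.90, 0.02, params, engine="reduced_oa",
                             t_sim=60.0, window=40.0, M=51)
        np.testing.assert_allclose(np.diff(sw.s1), 0.02)
        assert sw.direction == "up"
        assert len(sw.labels) == sw.s1.size == 3
        assert sw.at(0.88)["s1"] == pytest.approx(0.88)

    def test_deep_steady_sweep_is_steady_throughout(self):
        params = ModelParams()
        sw = adiabatic_sweep(0.84, 0.88, 0.02, params, engine="reduced_oa",
                             t_sim=400.0, window=200.0, M=101)
        assert all(lab == "steady" for lab in sw.labels)
        np.testing.assert_array_less(sw.max_lam, 0.0)

    def test_perturbation_protocol_validation(self):
        params = ModelParams(N=50)
        state0 = _initial_state("steady", params, "reduced_oa", 0, 51)
        with pytest.raises(ValueError):
            apply_perturbation(state0, dict(kind="nudge", value=1.0, t_p=10.0), params)
        with pytest.raises(ValueError):
            apply_perturbation(state0, dict(kind="clamp", value=1.0, t_p=10.0,
                                            duration=-5.0), params)
        with pytest.raises(ValueError):
            apply_perturbation(state0, dict(kind="reset", value=1.0, t_p=-1.0), params)

    def test_clamp_holds_lambda_then_releases(self):
        params = ModelParams(s1=0.9)
        state0 = _initial_state("steady", params, "reduced_oa", 0, 51)
        ts, verdict = apply_perturbation(
            state0, dict(kind="clamp", value=-0.3, t_p=100.0, duration=50.0),
            params, engine="reduced_oa", t_end=400.0, verdict_window=80.0)
        clamped = (ts.t > 100.5) & (ts.t < 149.5)
        np.testing.assert_allclose(ts.lam[clamped], -0.3, atol=1e-12)
        assert verdict["label_pre"] == "steady"
        # mild inhibitory clamp in the steady regime does not switch
        assert verdict["label_post"] == "steady"
        assert verdict["application_phase"] == "inactive"
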