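import math

import numpy as np
import pytest
from scipy.stats import norm

from rotorpool.model import ModelParams, ResourceState
from rotorpool.network import (
    PopulationState,
    init_population,
    full_rhs,
    simulate,
    summarize,
)


class TestInitPopulation:
    def test_stratified_quantiles(self):
        pop = init_population(5, seed=3, sampling_mode="stratified", phase_init="all_zero")
        expected = norm.ppf([0.1, 0.3, 0.5, 0.7, 0.9])
        np.testing.assert_allclose(pop.nu, expected, atol=1e-12)
        assert pop.nu[2] == 0.0
        assert np.all(pop.phases == 0.0)

    def test_determinism(self):
        a = init_population(64, seed=11)
        b = init_population(64, seed=11)
        np.testing.assert_array_equal(a.nu, b.nu)
        np.testing.assert_array_equal(a.phases, b.phases)
        c = init_population(64, seed=12)
        assert not np.array_equal(a.nu, c.nu)

    def test_iid_mean_within_clt_bound(self):
        N = 100_000
        pop = init_population(N, seed=5)
        assert abs(pop.nu.mean()) < 3.0 / math.sqrt(N)
        assert abs(pop.nu.std() - 1.0) < 0.02

    def test_heterogeneity_is_frozen(self):
        pop = init_population(10, seed=0)
        with pytest.raises(ValueError):
            pop.nu[0] = 99.0

    def test_unknown_modes_rejected(self):
        with pytest.raises(ValueError):
            init_population(5, seed=0, sampling_mode="sobol")
        with pytest.raises(ValueError):
            init_population(5, seed=0, phase_init="gaussian")


class TestFullRhs:
    def test_coupling_vanishes_at_synchrony(self):
        params = ModelParams(sigma=7.3, N=20)
        pop = PopulationState(phases=np.full(20, 0.8), nu=np.zeros(20))
        res = ResourceState(r=complex(0.9, 1.1), lam=0.0)
        dphi, _, _, A = full_rhs(pop, res, params)
        np.testing.assert_allclose(dphi, 0.9 - math.sin(0.8), atol=1e-12)
        assert A == pytest.approx(0.9 - math.sin(0.8), abs=1e-12)

    def test_activity_identity(self, rng):
        # A = r1 + r2*mean(nu) - Im Z holds exactly at finite N: the
        # mean-field coupling term averages to sigma*Im|Z|^2 = 0
        params = ModelParams(N=123)
        pop = PopulationState(phases=rng.uniform(0, 2 * np.pi, 123),
                              nu=rng.standard_normal(123))
        res = ResourceState(r=complex(0.7, 1.4), lam=0.1)
        _, _, _, A = full_rhs(pop, res, params)
        Z = np.exp(1j * pop.phases).mean()
        expected = res.r1 + res.r2 * pop.nu.mean() - Z.imag
        assert A == pytest.approx(expected, abs=1e-12)

    def test_single_rotator_rest_states(self):
        # N=1, nu=0, sigma=0, r1=0.5: fixed points at arcsin(0.5), pi - arcsin(0.5)
        params = ModelParams(sigma=0.0, N=1)
        res = ResourceState(r=complex(0.5, 0.0), lam=0.0)
        for phi in (math.asin(0.5), math.pi - math.asin(0.5)):
            pop = PopulationState(phases=np.array([phi]), nu=np.array([0.0]))
            dphi, _, _, _ = full_rhs(pop, res, params)
            assert dphi[0] == pytest.approx(0.0, abs=1e-12)

    def test_non_finite_state_rejected(self):
        params = ModelParams(N=2)
        pop = PopulationState(phases=np.array([0.0, np.nan]), nu=np.zeros(2))
        with pytest.raises(ValueError):
            full_rhs(pop, ResourceState(r=0j, lam=0.0), params)


class TestSimulate:
    def test_feedback_off_relaxes_to_rest(self):
        # gamma = 0: lambda -> lambda0 and r -> s regardless of the population
        params = ModelParams(gamma=0.0, N=50)
        pop = init_population(50, seed=1)
        res0 = ResourceState(r=params.s + (0.05 + 0.05j), lam=0.4)
        ts = simulate(pop, res0, params, t_end=2000.0, dt_out=1.0)
        assert abs(ts.lam[-1] - params.lambda0) < 1e-6
        assert abs(complex(ts.r1[-1], ts.r2[-1]) - params.s) < 1e-2

    def test_frozen_resources_settle_to_constants(self):
        # fixed (r1, r2) = (0.9, 1.0) lies in the stable-stationary regime
        params = ModelParams(N=500)
        pop = init_population(500, seed=2)
        ts = simulate(pop, ResourceState(r=complex(0.9, 1.0), lam=-1.0), params,
                      t_end=200.0, dt_out=0.5, freeze_resources=True)
        late = ts.t >= 150.0
        assert np.ptp(ts.A[late]) < 1e-3
        assert np.ptp(ts.R[late]) < 1e-3
        assert np.all(ts.lam == -1.0)

    def test_output_sampling_does_not_change_dynamics(self):
        params = ModelParams(N=40)
        pop = init_population(40, seed=9)
        res0 = ResourceState(r=params.s + 0.2, lam=0.1)
        a = simulate(pop, res0, params, t_end=20.0, dt_out=0.5)
        pop2 = PopulationState(phases=pop.phases.copy(), nu=pop.nu)
        b = simulate(pop2, res0, params, t_end=20.0, dt_out=1.0)
        np.testing.assert_allclose(a.A[::2], b.A, atol=1e-12)
        np.testing.assert_allclose(a.lam[::2], b.lam, atol=1e-12)

    def test_rk4_is_bit_reproducible(self):
        params = ModelParams(N=30)
        pop = init_population(30, seed=4)
        res0 = ResourceState(r=params.s + 0.3, lam=0.1)
        a = simulate(PopulationState(pop.phases.copy(), pop.nu), res0, params, t_end=30.0)
        b = simulate(PopulationState(pop.phases.copy(), pop.nu), res0, params, t_end=30.0)
        np.testing.assert_array_equal(a.A, b.A)
        np.testing.assert_array_equal(a.lam, b.lam)

    def test_adaptive_matches_fixed_step(self):
        params = ModelParams(N=30)
        pop = init_population(30, seed=4)
        res0 = ResourceState(r=params.s + 0.3, lam=0.1)
        a = simulate(PopulationState(pop.phases.copy(), pop.nu), res0, params,
                     t_end=30.0, method="rk4", dt=0.005)
        b = simulate(PopulationState(pop.phases.copy(), pop.nu), res0, params,
                     t_end=30.0, method="rk45", rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(a.R, b.R, atol=1e-6)
        np.testing.assert_allclose(a.lam, b.lam, atol=1e-8)


class TestSniperScaling:
    @pytest.mark.parametrize("r1", [1.02, 1.05, 1.1])
    def test_single_rotator_period(self, r1):
        # sigma = 0, r2 = 0: period of one rotator ~ 2*pi/sqrt(r1^2 - 1)
        params = ModelParams(sigma=0.0, N=1)
        pop = PopulationState(phases=np.array([0.0]), nu=np.array([0.0]))
        expected = 2 * math.pi / math.sqrt(r1 * r1 - 1.0)
        ts = simulate(pop, ResourceState(r=complex(r1, 0.0), lam=-1.0), params,
                      t_end=6 * expected, dt_out=0.01, dt=0.002, freeze_resources=True)
        # mean phase velocity = 2*pi / period for a running rotator
        measured = 2 * math.pi / ts.A[ts.t > expected].mean()
        assert measured == pytest.approx(expected, rel=0.02)

    def test_period_diverges_at_onset(self):
        params = ModelParams(sigma=0.0, N=1)
        periods = []
        for r1 in (1.1, 1.05, 1.02):
            pop = PopulationState(phases=np.array([0.0]), nu=np.array([0.0]))
            ts = simulate(pop, ResourceState(r=complex(r1, 0.0), lam=-1.0), params,
                          t_end=500.0, dt_out=0.05, dt=0.002, freeze_resources=True)
            periods.append(2 * math.pi / ts.A[ts.t > 100].mean())
        assert periods[0] < periods[1] < periods[2]


class TestSummarize:
    def _const_series(self, a=0.3, lam=-0.05):
        from rotorpool.network import TimeSeries
        t = np.linspace(0, 100, 201)
        return TimeSeries(t=t, A=np.full_like(t, a), R=np.full_like(t, 0.5),
                          Theta=np.zeros_like(t), r1=np.full_like(t, 0.9),
                          r2=np.ones_like(t), lam=np.full_like(t, lam))

    def test_constant_series(self):
        s = summarize(self._const_series(a=0.3), transient=20.0, window=50.0)
        assert s["mean_A"] == pytest.approx(0.3)
        assert s["R_range"] == 0.0
        assert s["label"] == "steady"

    def test_positive_lambda_labels_active(self):
        s = summarize(self._const_series(lam=0.2), transient=20.0, window=50.0)
        assert s["label"] == "active/bursting"

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            summarize(self._const_series(), transient=60.0, window=50.0)


class TestFiniteSizeConvergence:
    def test_error_vs_meanfield_shrinks_with_N(self):
        # finite-N stationary coherence converges to the mean-field value;
        # stratified heterogeneity sampling tightens it by ~an order of
        # magnitude over i.i.d. draws
        from rotorpool.oa import OAField, integrate_layer

        r1, r2 = 0.9, 1.0
        traj = integrate_layer(OAField.incoherent(201, r1=r1, r2=r2), 5.0, 200.0,
                               dt_out=0.5)
        R_oa = float(np.abs(traj.Z[traj.t >= 100]).mean())
        errs = {}
        for mode in ("stratified", "iid"):
            errs[mode] = []
            for N in (250, 1000, 4000):
                pop = init_population(N, seed=7, sampling_mode=mode)
                ts = simulate(pop, ResourceState(r=complex(r1, r2), lam=-1.0),
                              ModelParams(N=N), t_end=200.0, dt_out=0.5,
                              freeze_resources=True)
                errs[mode].append(abs(float(ts.R[ts.t >= 100].mean()) - R_oa))
        assert errs["stratified"][0] > errs["stratified"][1] > errs["stratified"][2]
        assert errs["stratified"][2] < errs["iid"][2]
        # i.i.d. error consistent with the N^{-1/2} fluctuation scale
        assert errs["iid"][2] < 3.0 / np.sqrt(4000)
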