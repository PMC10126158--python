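"""Clonal ODE competition model: oracles, invariants, and behavior."""
import numpy as np
import pytest

from acqcost.simulate import (SimConfig, calibrate_ratio, compete,
                              density_sweep, draw_clone_set,
                              population_phenotype, simulate_population)
from acqcost.types import CloneSet


def euler_oracle(lags, rates, n0, K, P, t_end, dt=1e-4):
    """Independent fixed-step Euler integrator (reference implementation)."""
    lags, rates = np.asarray(lags, float), np.asarray(rates, float)
    n = np.asarray(n0, float).copy()
    steps = int(round(t_end / dt))
    for k in range(steps):
        t = k * dt
        active = lags <= t + 1e-12
        n = n + dt * rates * active * n * (1.0 - (n.sum() + P) / K)
    return n


class TestIntegratorOracles:
    def test_single_clone_matches_closed_form_logistic(self):
        cfg = SimConfig(K=100.0, parents=0.0, t_end=5.0, dt_max=0.01)
        traj = simulate_population(CloneSet([0.0], [1.0], [1.0]), cfg)
        t = traj.times
        exact = 100 * np.exp(t) / (100 + np.exp(t) - 1)
        assert np.max(np.abs(traj.total - exact) / exact) < 1e-6
        assert traj.total[-1] == pytest.approx(59.986, abs=1e-2)

    def test_agrees_with_euler_on_two_clones(self):
        lags, rates, n0 = [1.0, 3.5], [0.9, 1.4], [5.0, 2.0]
        cfg = SimConfig(K=1e4, parents=100.0, t_end=8.0, dt_max=0.01)
        traj = simulate_population(CloneSet(lags, rates, n0), cfg)
        ref = euler_oracle(lags, rates, n0, 1e4, 100.0, 8.0)
        assert np.max(np.abs(traj.per_clone[:, -1] - ref) / ref) < 1e-3

    def test_parents_shift_fixed_point_to_K_minus_P(self):
        cfg = SimConfig(K=100.0, parents=50.0, t_end=40.0, dt_max=0.01)
        traj = simulate_population(CloneSet([0.0], [1.0], [1.0]), cfg)
        assert traj.total[-1] == pytest.approx(50.0, abs=1e-4)

    def test_zero_rate_population_constant(self):
        cfg = SimConfig(K=1e3, t_end=10.0, dt_max=0.05)
        traj = simulate_population(CloneSet([0.0, 2.0], [0.0, 0.0], [5.0, 7.0]), cfg)
        assert np.allclose(traj.total, 12.0)


class TestInvariants:
    def test_clone_exactly_at_inoculum_before_lag(self):
        cfg = SimConfig(K=1e3, t_end=6.0, dt_max=0.01)
        traj = simulate_population(CloneSet([3.0], [1.0], [7.0]), cfg)
        assert np.all(traj.per_clone[0, traj.times < 3.0] == 7.0)
        assert traj.per_clone[0, traj.times > 3.5].max() > 7.0

    def test_total_is_row_sum_and_bounded_by_capacity(self):
        rng = np.random.default_rng(0)
        clones = CloneSet(rng.uniform(0, 4, 8), rng.uniform(0.4, 1.2, 8),
                          rng.uniform(1, 10, 8))
        cfg = SimConfig(K=1e5, parents=200.0, t_end=30.0, dt_max=0.01)
        traj = simulate_population(clones, cfg)
        assert np.allclose(traj.total, traj.per_clone.sum(axis=0))
        assert traj.total.max() <= 1e5 - 200.0 + 1.0

    def test_seeded_determinism(self):
        def run():
            rng = np.random.default_rng(12)
            cs = draw_clone_set(500, 4, 1, growth_mean=0.6, growth_sd=0.05,
                                rng=rng)
            cfg = SimConfig(K=1e6, t_end=12.0, dt_max=0.05)
            return simulate_population(cs, cfg).total
        assert np.array_equal(run(), run())


class TestDrawCloneSet:
    def test_single_cell(self):
        cs = draw_clone_set(1, 4, 1, growth_mean=0.6, growth_sd=0.05, seed=0)
        assert cs.j == 1 and cs.n0.tolist() == [1.0]

    def test_capping_preserves_total(self):
        cs = draw_clone_set(10 ** 6, 4, 1, growth_mean=0.6, growth_sd=0.05,
                            j_max=10 ** 4, seed=0)
        assert cs.j == 10 ** 4
        assert np.allclose(cs.n0, 100.0)
        assert cs.total_n0 == pytest.approx(10 ** 6)

    def test_tradeoff_without_residual_is_exactly_affine(self):
        cs = draw_clone_set(200, 4, 1, tradeoff=(0.05, 0.3, 0.0), seed=3)
        assert np.allclose(cs.rates, 0.3 + 0.05 * cs.lags)

    def test_invalid_cell_count_rejected(self):
        with pytest.raises(ValueError):
            draw_clone_set(0, 4, 1, growth_mean=0.6, growth_sd=0.05)


class TestPopulationPhenotype:
    def test_single_clone_recovered(self):
        cfg = SimConfig(K=2e9, t_end=24.0, dt_max=0.01)
        traj = simulate_population(CloneSet([2.0], [0.8], [100.0]), cfg)
        lag, rate = population_phenotype(traj)
        assert lag == pytest.approx(2.0, rel=0.10)
        assert rate == pytest.approx(0.8, rel=0.10)

    def test_aggregation_invariance(self):
        cfg = SimConfig(K=1e8, t_end=20.0, dt_max=0.01)
        two = simulate_population(CloneSet([2.0, 2.0], [0.7, 0.7], [50.0, 50.0]), cfg)
        one = simulate_population(CloneSet([2.0], [0.7], [100.0]), cfg)
        assert population_phenotype(two) == pytest.approx(population_phenotype(one))

    def test_mixture_lag_between_components(self):
        cfg = SimConfig(K=1e9, t_end=22.0, dt_max=0.01)
        traj = simulate_population(
            CloneSet([1.0, 5.0], [0.6, 0.6], [100.0, 100.0]), cfg)
        lag, _ = population_phenotype(traj)
        assert 1.0 < lag < 5.0

    def test_flat_trajectory_rejected(self):
        cfg = SimConfig(K=1e3, t_end=5.0, dt_max=0.05)
        traj = simulate_population(CloneSet([0.0], [0.0], [10.0]), cfg)
        with pytest.raises(ValueError):
            population_phenotype(traj)


class TestSweepAndCompetition:
    @staticmethod
    def _gen(lag_mean=4.0, growth_mean=0.6):
        def gen(n_cells, rng):
            return draw_clone_set(n_cells, lag_mean, 1.0,
                                  growth_mean=growth_mean, growth_sd=0.05,
                                  j_max=500, rng=rng)
        return gen

    def test_sweep_reports_dispersion_for_stochastic_draws(self):
        cfg = SimConfig(K=1e7, t_end=16.0, dt_max=0.1, n_iterations=5, seed=2)
        tab = density_sweep(self._gen(), (100.0, 1000.0, 10000.0), cfg)
        assert len(tab) == 3
        assert (tab["sd_growth_rate"] > 0).all()

    def test_identical_generators_calibrate_to_even_ratio(self):
        cfg = SimConfig(K=1e7, t_end=16.0, dt_max=0.1, n_iterations=4, seed=4)
        ratio, achieved = calibrate_ratio(self._gen(), self._gen(), 5e3, cfg,
                                          tol=0.03)
        assert ratio == pytest.approx(1.0, rel=0.2)
        assert achieved == pytest.approx(0.5, abs=0.03)

    def test_calibration_compensates_faster_opponent(self):
        cfg = SimConfig(K=1e7, t_end=16.0, dt_max=0.1, n_iterations=4, seed=4)
        fast_b = self._gen(growth_mean=0.66)  # B grows 10% faster
        ratio, achieved = calibrate_ratio(self._gen(), fast_b, 5e3, cfg, tol=0.03)
        assert ratio > 1.0  # A gets the head start
        m, _, _ = compete(self._gen(), fast_b, ratio, 5e3, cfg)
        assert m == pytest.approx(0.5, abs=0.05)

    def test_symmetric_competition_splits_evenly(self):
        cfg = SimConfig(K=1e7, t_end=16.0, dt_max=0.1, n_iterations=6, seed=6)
        m, s, fr = compete(self._gen(), self._gen(), 1.0, 5e3, cfg)
        assert m == pytest.approx(0.5, abs=0.05)
        assert len(fr) == 6

    def test_shorter_lag_wins_without_tradeoff(self):
        cfg = SimConfig(K=1e7, t_end=16.0, dt_max=0.1, n_iterations=4, seed=8)
        m, _, _ = compete(self._gen(lag_mean=2.5), self._gen(lag_mean=5.0),
                          1.0, 5e3, cfg)
        assert m > 0.5
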