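"""Unit and property tests for the logistic growth-curve quantification."""
import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import pearsonr

from acqcost.growth import (fit_logistic, instantaneous_growth_rate,
                            invert_logistic_for_threshold, logistic_model,
                            manual_growth_rate, time_to_threshold)
from acqcost.types import DomainError, FitConvergenceError


class TestLogisticModel:
    @pytest.mark.parametrize("t,params,expected", [
        (1000.0, (1.0, 1.0, 2.0), 1.0),                    # t -> inf limit is A
        (2.0, (1.0, 1.0, 2.0), 1 / (1 + np.e ** 2)),       # value at t = lam
        (6.0, (1.0, 0.5, 3.0), 1 / (1 + np.exp(-4.0))),    # direct evaluation
    ])
    def test_pointwise_values(self, t, params, expected):
        assert logistic_model(t, *params) == pytest.approx(expected, rel=1e-9)

    def test_vectorized_and_scaled_by_A(self):
        t = np.linspace(0, 24, 97)
        assert np.allclose(logistic_model(t, 2.0, 0.5, 3.0),
                           2.0 * logistic_model(t, 1.0, 0.25, 3.0))

    def test_nonpositive_A_rejected(self):
        with pytest.raises(DomainError):
            logistic_model(1.0, 0.0, 0.5, 3.0)


class TestInverse:
    def test_analytic_value(self):
        assert invert_logistic_for_threshold(1, 0.5, 3, 0.8) == pytest.approx(
            3 + 0.5 * (2 + np.log(4)), rel=1e-12)  # 4.69315 h

    def test_threshold_at_lag_point(self):
        theta = 1 / (1 + np.e ** 2)
        assert invert_logistic_for_threshold(1, 0.5, 3, theta) == pytest.approx(3.0)

    @pytest.mark.parametrize("theta", [0.2, 0.5, 0.8])
    def test_round_trip(self, theta):
        t_star = invert_logistic_for_threshold(1.0, 0.4, 5.0, theta)
        assert logistic_model(t_star, 1.0, 0.4, 5.0) == pytest.approx(theta, rel=1e-12)

    def test_threshold_above_A_rejected(self):
        with pytest.raises(DomainError):
            invert_logistic_for_threshold(1.0, 0.5, 3.0, 1.0)


class TestFitLogistic:
    def test_noiseless_recovery(self, time_grid):
        v = logistic_model(time_grid, 1.0, 0.4, 5.0)
        fit = fit_logistic(times=time_grid, values=v)
        assert fit.converged
        assert fit.A == pytest.approx(1.0, rel=1e-4)
        assert fit.mu_m == pytest.approx(0.4, rel=1e-4)
        assert fit.lam == pytest.approx(5.0, rel=1e-4)
        assert fit.rss < 1e-12

    def test_noisy_recovery_within_5pct(self, curve_factory):
        c = curve_factory(A=1.0, mu=0.4, lam=5.0, noise_sd=0.01, seed=0)
        fit = fit_logistic(c)
        assert fit.A == pytest.approx(1.0, rel=0.05)
        assert fit.mu_m == pytest.approx(0.4, rel=0.05)
        assert fit.lam == pytest.approx(5.0, rel=0.05)

    def test_rss_matches_model_residuals(self, curve_factory):
        c = curve_factory(noise_sd=0.02, seed=3)
        fit = fit_logistic(c)
        resid = c.values - logistic_model(c.times, fit.A, fit.mu_m, fit.lam)
        assert fit.rss == pytest.approx(float(resid @ resid), rel=1e-9)

    def test_constant_curve_rejected(self, time_grid):
        with pytest.raises(FitConvergenceError):
            fit_logistic(times=time_grid, values=np.zeros_like(time_grid))

    def test_negative_times_rejected(self, time_grid):
        with pytest.raises(ValueError):
            fit_logistic(times=time_grid - 5.0,
                         values=logistic_model(time_grid, 1, 0.5, 3))

    def test_fitted_lag_tracks_detection_time(self, time_grid):
        """Fitted lag correlates (r >= 0.9) with first above-floor time."""
        rng = np.random.default_rng(42)
        lams, detect, fitted = [], [], []
        for _ in range(40):
            lam = rng.uniform(1, 9)
            mu = rng.uniform(0.3, 0.8)
            v = logistic_model(time_grid, 1.0, mu, lam)
            v = v + rng.normal(0, 0.01, len(v))
            v[v < 0.05] = 0.0
            fit = fit_logistic(times=time_grid, values=np.clip(v, 0, None))
            lams.append(lam)
            fitted.append(fit.lam)
            detect.append(time_grid[np.argmax(v > 0)])
        assert pearsonr(fitted, detect).statistic >= 0.9


class TestTimeToThreshold:
    def test_immediate_crossing_returns_first_time(self, time_grid):
        v = np.full_like(time_grid, 0.9)
        assert time_to_threshold(times=time_grid, values=v) == time_grid[0]

    def test_interpolate_matches_analytic_inverse(self, time_grid):
        v = logistic_model(time_grid, 1.0, 0.5, 3.0)
        t_true = invert_logistic_for_threshold(1.0, 0.5, 3.0, 0.8)
        ti = time_to_threshold(times=time_grid, values=v, mode="interpolate")
        tn = time_to_threshold(times=time_grid, values=v, mode="nearest_sample")
        assert ti == pytest.approx(t_true, abs=2e-2)  # 0.25-h grid sag
        assert abs(tn - t_true) <= 0.25  # within one sampling interval

    def test_never_reaching_flagged_not_raised(self, time_grid):
        v = logistic_model(time_grid, 0.5, 0.5, 3.0)
        assert np.isnan(time_to_threshold(times=time_grid, values=v, threshold=0.8))

    def test_monotone_in_lag_and_rate(self, time_grid):
        t_fine = np.arange(0, 40, 0.05)
        ttts_lag = [time_to_threshold(times=t_fine,
                                      values=logistic_model(t_fine, 1, 0.5, lam),
                                      mode="interpolate")
                    for lam in (1, 3, 5, 7)]
        assert np.all(np.diff(ttts_lag) > 0)
        ttts_mu = [time_to_threshold(times=t_fine,
                                     values=logistic_model(t_fine, 1, mu, 3),
                                     mode="interpolate")
                   for mu in (0.2, 0.4, 0.8)]
        assert np.all(np.diff(ttts_mu) < 0)

    def test_threshold_invariance_of_cost_ranking(self):
        """Ranking of plasmid costs is unchanged across thresholds."""
        from acqcost.synth import SynthConfig, gen_phenotypes

        rankings = []
        for theta in (0.5, 0.8, 0.95):
            costs = []
            for target in (1.2, 1.5, 1.8):
                cfg = SynthConfig(n_colonies=150, target_cost=target, seed=10,
                                  threshold=theta)
                phen = gen_phenotypes(cfg)
                dn = phen.loc[phen.population == "de_novo", "ttt_true_h"].mean()
                ad = phen.loc[phen.population == "adapted", "ttt_true_h"].mean()
                costs.append(dn / ad)
            rankings.append(tuple(np.argsort(costs)))
        assert rankings[0] == rankings[1] == rankings[2] == (0, 1, 2)


class TestManualGrowthRate:
    def test_linear_curve_exact(self):
        t = np.arange(0, 6.01, 0.25)
        assert manual_growth_rate(times=t, values=0.1 * t) == pytest.approx(0.1)

    def test_logistic_curve_matches_analytic_secant(self, time_grid):
        # inflection at t = lam + A/(2 mu) = 4.0 lies exactly on the grid, so
        # the +/-2-sample secant equals expit(1) - expit(-1) analytically
        v = logistic_model(time_grid, 1.0, 0.5, 3.0)
        expected = expit(1.0) - expit(-1.0)
        assert manual_growth_rate(times=time_grid, values=v) == pytest.approx(
            expected, rel=1e-6)

    def test_monotone_decreasing_curve_rejected(self):
        t = np.arange(0, 6.01, 0.25)
        with pytest.raises(ValueError):
            manual_growth_rate(times=t, values=1.0 - 0.1 * t)


class TestInstantaneousRate:
    def test_doubling_in_quarter_hour(self):
        t = np.arange(0, 2.01, 0.25)
        v = 100.0 * 2 ** (t / 0.25)
        rates = instantaneous_growth_rate(times=t, values=v)
        assert np.allclose(rates, np.log(2) / 0.25)

    def test_constant_curve_all_zero(self):
        t = np.arange(0, 2.01, 0.25)
        rates = instantaneous_growth_rate(times=t, values=np.full(len(t), 5.0))
        assert np.allclose(rates, 0.0)

    def test_exponential_recovers_rate_and_length(self):
        t = np.arange(0, 10.01, 0.25)
        rates = instantaneous_growth_rate(times=t, values=np.exp(0.5 * t))
        assert len(rates) == len(t) - 1
        assert np.allclose(rates, 0.5)

    def test_zero_entries_flagged_as_nan(self):
        t = np.arange(0, 2.01, 0.25)
        v = np.array([0, 0, 1, 2, 4, 8, 16, 32, 64.0])
        rates = instantaneous_growth_rate(times=t, values=v)
        assert np.isnan(rates[0]) and np.isnan(rates[1])
        assert np.allclose(rates[2:], np.log(2) / 0.25)


def test_fit_round_trip_small_grid(time_grid):
    """Noiseless forward-model curves return their generating parameters."""
    for A in (0.6, 1.0, 1.4):
        for mu in (0.15, 0.5, 0.9):
            for lam in (0.0, 4.0, 8.0):
                v = logistic_model(time_grid, A, mu, lam)
                fit = fit_logistic(times=time_grid, values=v)
                assert fit.A == pytest.approx(A, rel=1e-4)
                assert fit.mu_m == pytest.approx(mu, rel=1e-4)
                assert fit.lam == pytest.approx(lam, rel=1e-4, abs=1e-4)
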