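import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from airpolicy import (
    BsmParams,
    BsmSpec,
    DailySeries,
    RegressorSet,
    SeasonalSpec,
    build_date_index,
    build_state_space,
    fit_ml,
    forecast,
    kalman_filter,
    kalman_smoother,
    loglik_at,
    policy_dummies,
    significance_stars,
    transitory_decay_regressor,
)
from airpolicy.ssm import _Packer

from gaussian_oracle import oracle_loglik, oracle_smoothed_means
from conftest import random_small_instance


class TestStateSpaceStructure:
    def test_quarterly_rotation_one_step(self):
        """k=1, s=4: a noiseless cycle state (1,0) rotates to (0,-1)."""
        spec = BsmSpec(seasonal=SeasonalSpec(4, 1))
        p = BsmParams(sigma2_eps=1.0, sigma2_level=0.0)
        mats = build_state_space(spec, p, None, n=4)
        state = np.array([0.0, 0.0, 1.0, 0.0])
        nxt = mats.T @ state
        np.testing.assert_allclose(nxt, [0.0, 0.0, 0.0, -1.0], atol=1e-12)

    def test_harmonics_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="harmonics"):
            SeasonalSpec(4, 3)

    def test_noiseless_llt_reproduces_constant_slope_path(self):
        """With all state variances zero the transition is the exact
        constant-slope recursion: level_t = level_0 + t*slope_0."""
        spec = BsmSpec(seasonal=None)
        p = BsmParams(sigma2_eps=0.5, sigma2_level=0.0, sigma2_slope=0.0)
        mats = build_state_space(spec, p, None, n=10)
        state = np.array([2.0, 0.3])
        for t in range(1, 6):
            state = mats.T @ state
            assert state[0] == pytest.approx(2.0 + 0.3 * t)
            assert state[1] == pytest.approx(0.3)

    def test_transitory_recursion_decay(self):
        """lambda=0.5, delta0=1 at t0: w path is 1, 0.5, 0.25."""
        idx = build_date_index("2019-01-01", "2019-01-06")
        reg = RegressorSet(policy_dummies(idx, "2019-01-03"))
        spec = BsmSpec(seasonal=None, include_transitory=True)
        p = BsmParams(sigma2_eps=1.0, sigma2_level=0.0, delta0=1.0, lam=0.5)
        mats = build_state_space(spec, p, reg)
        w = np.zeros(mats.m)
        path = []
        for t in range(len(idx)):
            w = mats.T @ w + mats.c[t] if t else mats.c[0]
            path.append(w[-1])
        assert path == pytest.approx([0.0, 0.0, 1.0, 0.5, 0.25, 0.125])

    def test_decay_regressor_matches_recursion(self):
        np.testing.assert_allclose(
            transitory_decay_regressor(6, 2, 0.5),
            [0.0, 0.0, 1.0, 0.5, 0.25, 0.125],
        )


class TestFilterOracle:
    def test_pure_noise_closed_form(self):
        """Known level, zero state variance: likelihood is the sum of
        univariate Gaussian log-densities."""
        spec = BsmSpec(seasonal=None)
        p = BsmParams(sigma2_eps=0.7, sigma2_level=0.0, sigma2_slope=0.0)
        mats = build_state_space(spec, p, None, n=25)
        mats.a0 = np.array([1.5, 0.0])
        mats.P0 = np.zeros((2, 2))
        mats.burn = 0
        rng = np.random.default_rng(5)
        y = 1.5 + rng.normal(0, np.sqrt(0.7), 25)
        out = kalman_filter(mats, y)
        expected = norm(1.5, np.sqrt(0.7)).logpdf(y).sum()
        assert out.loglik == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_gaussian(self, seed):
        rng = np.random.default_rng(seed)
        mats, y = random_small_instance(rng)
        out = kalman_filter(mats, y)
        ll = oracle_loglik(mats, y)
        assert abs(out.loglik - ll) <= 1e-8 * max(1.0, abs(ll))

    def test_missing_data_consistency(self):
        """Masking a value gives the likelihood of the reduced vector."""
        rng = np.random.default_rng(42)
        mats, y = random_small_instance(rng, with_missing=False)
        y2 = y.copy()
        y2[len(y2) // 2] = np.nan
        out = kalman_filter(mats, y2)
        assert out.loglik == pytest.approx(oracle_loglik(mats, y2), rel=1e-9)
        assert out.nobs == len(y2) - 1

    def test_all_missing_rejected(self):
        spec = BsmSpec(seasonal=None)
        mats = build_state_space(spec, BsmParams(1.0, 0.1), None, n=5)
        with pytest.raises(ValueError, match="missing"):
            kalman_filter(mats, np.full(5, np.nan))

    def test_innovation_variances_positive(self):
        rng = np.random.default_rng(7)
        mats, y = random_small_instance(rng)
        out = kalman_filter(mats, y)
        finite = np.isfinite(out.innovation_var)
        assert (out.innovation_var[finite] > 0).all()


class TestSmoother:
    def test_matches_gaussian_conditioning(self):
        rng = np.random.default_rng(10)
        mats, y = random_small_instance(rng)
        out = kalman_smoother(mats, y)
        expected = oracle_smoothed_means(mats, y)
        np.testing.assert_allclose(out.alpha_smooth, expected, rtol=1e-8, atol=1e-8)

    def test_single_observation_smoothed_equals_filtered(self):
        spec = BsmSpec(seasonal=None)
        mats = build_state_space(spec, BsmParams(0.5, 0.1, 0.01), None, n=1)
        out = kalman_smoother(mats, np.array([2.0]))
        np.testing.assert_allclose(out.alpha_smooth[0], out.a_filt[0], rtol=1e-10)

    def test_noiseless_states_give_centered_residuals(self):
        """All state variances zero: the smoothed signal is the deterministic
        trajectory and eps_hat are the residuals around it."""
        spec = BsmSpec(seasonal=None)
        p = BsmParams(sigma2_eps=0.2, sigma2_level=0.0, sigma2_slope=0.0)
        mats = build_state_space(spec, p, None, n=40)
        mats.a0 = np.array([3.0, 0.0])
        mats.P0 = np.zeros((2, 2))
        mats.burn = 0
        rng = np.random.default_rng(2)
        y = 3.0 + rng.normal(0, np.sqrt(0.2), 40)
        out = kalman_smoother(mats, y)
        np.testing.assert_allclose(out.alpha_smooth[:, 0], 3.0, atol=1e-9)
        np.testing.assert_allclose(out.eps_smooth, y - 3.0, atol=1e-9)

    def test_eps_missing_where_observation_missing(self):
        rng = np.random.default_rng(3)
        mats, y = random_small_instance(rng, with_missing=False)
        y[4] = np.nan
        out = kalman_smoother(mats, y)
        assert np.isnan(out.eps_smooth[4])
        assert np.isfinite(np.delete(out.eps_smooth, 4)).all()


class TestForecast:
    def _rw_setup(self, n=60):
        spec = BsmSpec(seasonal=None)
        p = BsmParams(sigma2_eps=0.2, sigma2_level=0.05, sigma2_slope=0.0)
        mats = build_state_space(spec, p, None, n=n)
        rng = np.random.default_rng(8)
        y = np.cumsum(rng.normal(0, 0.2, n)) + 5.0
        return mats, kalman_filter(mats, y)

    def test_one_step_equals_filter_prediction(self):
        mats, filt = self._rw_setup()
        t0 = 30
        pred = forecast(mats, filt, t0, 1)
        assert pred[0] == pytest.approx(
            mats.Z @ filt.a_pred[t0 + 1] + mats.offset[t0 + 1], rel=1e-12)

    def test_random_walk_forecast_constant_in_h(self):
        mats, filt = self._rw_setup()
        preds = forecast(mats, filt, 30, 10)
        # slope state is diffuse: after many updates it is ~0, level dominates
        np.testing.assert_allclose(preds, preds[0] + np.arange(10) * filt.a_filt[30, 1],
                                   rtol=1e-9)

    def test_deterministic_signal_forecast_exact(self):
        """Variances zero except observation noise: forecasts reproduce the
        deterministic trend."""
        spec = BsmSpec(seasonal=None)
        p = BsmParams(sigma2_eps=0.3, sigma2_level=0.0, sigma2_slope=0.0)
        mats = build_state_space(spec, p, None, n=50)
        mats.a0 = np.array([1.0, 0.1])
        mats.P0 = np.zeros((2, 2))
        mats.burn = 0
        rng = np.random.default_rng(4)
        signal = 1.0 + 0.1 * np.arange(50)
        y = signal + rng.normal(0, np.sqrt(0.3), 50)
        filt = kalman_filter(mats, y)
        preds = forecast(mats, filt, 20, 10)
        np.testing.assert_allclose(preds, signal[21:31], rtol=1e-10)

    def test_horizon_beyond_sample_rejected(self):
        mats, filt = self._rw_setup(n=40)
        with pytest.raises(ValueError, match="unavailable"):
            forecast(mats, filt, 35, 10)


class TestTransitoryEquivalence:
    def test_state_form_equals_decay_regressor(self):
        """The transitory state and the deterministic lambda-decay offset
        give identical likelihoods at fixed parameters."""
        rng = np.random.default_rng(14)
        n = 200
        idx = build_date_index("2019-01-01", pd.Timestamp("2019-01-01") + pd.Timedelta(days=n - 1))
        pos = 120
        reg = RegressorSet(policy_dummies(idx, idx[pos]))
        y = 2.0 + np.cumsum(rng.normal(0, 0.05, n)) + rng.normal(0, 0.15, n)
        y[pos:] += -0.4 * 0.7 ** np.arange(n - pos)
        spec_state = BsmSpec(seasonal=None, include_transitory=True)
        p_state = BsmParams(0.0225, 0.0025, coef={}, delta0=-0.4, lam=0.7)
        ll_state = loglik_at(spec_state, reg, pd.Series(y, index=idx), p_state)

        spec_det = BsmSpec(seasonal=None)
        p_det = BsmParams(0.0225, 0.0025)
        mats = build_state_space(spec_det, p_det, None, n=n)
        mats.offset = -0.4 * transitory_decay_regressor(n, pos, 0.7)
        ll_det = kalman_filter(mats, y).loglik
        assert abs(ll_state - ll_det) <= 1e-10 * max(1.0, abs(ll_det))


class TestFitMl:
    def test_too_few_observations_rejected(self):
        spec = BsmSpec(seasonal=None)
        idx = build_date_index("2019-01-01", "2019-01-03")
        obs = DailySeries("s", "NOx", pd.Series([1.0, np.nan, np.nan], index=idx),
                          log_scale=True)
        with pytest.raises(ValueError, match="non-missing"):
            fit_ml(spec, None, obs)

    def test_boundary_variance_pinned_without_crash(self, small_study):
        """True slope/seasonal variances are zero: estimates sit at (or
        numerically near) the boundary and SEs stay available for the rest."""
        sc = small_study.scenario
        spec = sc.target_spec()
        fit = fit_ml(spec, small_study.regressors, small_study.target_log,
                     n_starts=1, seed=0)
        assert fit.params.sigma2_slope < 1e-6
        assert fit.params.sigma2_seasonal < 1e-4
        assert np.isfinite(fit.se["counterfactual"])
        assert np.isnan(fit.se["sigma2_slope"])  # held fixed at the boundary

    def test_tstat_equals_estimate_over_se(self, small_study):
        sc = small_study.scenario
        spec = sc.target_spec()
        fit = fit_ml(spec, small_study.regressors, small_study.target_log,
                     n_starts=1, seed=0)
        for name, t in fit.tstats.items():
            se = fit.se[name]
            if np.isfinite(t):
                est = fit.params.coef.get(name)
                if est is None:
                    est = {"sigma2_eps": fit.params.sigma2_eps,
                           "sigma2_level": fit.params.sigma2_level,
                           "sigma2_slope": fit.params.sigma2_slope,
                           "sigma2_seasonal": fit.params.sigma2_seasonal,
                           "delta0": fit.params.delta0,
                           "lambda": fit.params.lam}[name]
                assert t == pytest.approx(est / se, rel=1e-9)

    def test_loglik_never_decreases_when_parameter_freed(self, small_study):
        """Nesting sanity: adding the counterfactual regressor cannot lower
        the maximized likelihood."""
        obs = small_study.target_log
        reg = small_study.regressors
        spec_small = BsmSpec(seasonal=SeasonalSpec(365, 1))
        spec_big = BsmSpec(seasonal=SeasonalSpec(365, 1), regressors=("counterfactual",))
        ll_small = fit_ml(spec_small, None, obs, n_starts=1, seed=0, compute_se=False).loglik
        ll_big = fit_ml(spec_big, reg, obs, n_starts=1, seed=0, compute_se=False,
                        ).loglik
        assert ll_big >= ll_small - 1e-6

    def test_lambda_link_round_trip(self):
        spec = BsmSpec(seasonal=None, include_transitory=True, lambda_bounds=(0.0, 1.0))
        packer = _Packer(spec)
        p = BsmParams(0.1, 0.01, delta0=-0.2, lam=0.73)
        back = packer.unpack(packer.pack(p))
        assert back.lam == pytest.approx(0.73, abs=1e-9)
        assert back.delta0 == pytest.approx(-0.2)


class TestSignificance:
    @pytest.mark.parametrize("t,stars", [
        (0.5, ""), (1.7, "*"), (2.0, "**"), (3.0, "***"), (-2.2, "**"), (np.nan, ""),
    ])
    def test_star_thresholds(self, t, stars):
        assert significance_stars(t) == stars
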