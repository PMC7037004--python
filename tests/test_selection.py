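import math

import numpy as np
import pandas as pd
import pytest

from airpolicy import (
    BsmParams,
    BsmSpec,
    CvPlan,
    DailySeries,
    RegressorSet,
    SeasonalSpec,
    assemble_final_spec,
    build_date_index,
    information_criteria,
    rolling_origin_cv,
    select_counterfactual,
    select_harmonics,
    stepwise_residual_screen,
)
from airpolicy.selection import STEPWISE_TERMS, StepwiseResult
from airpolicy.synthetic_data import SimScenario, simulate_study

PLAN = CvPlan("2016-12-31", "2017-01-01", "2017-12-31")


class TestCvPlan:
    def test_defaults_are_contiguous(self):
        plan = CvPlan()
        assert plan.train_end == "2018-02-24"
        assert len(build_date_index(plan.test_start, plan.test_end)) == 365

    def test_reversed_plan_rejected(self):
        with pytest.raises(ValueError):
            CvPlan("2018-02-24", "2018-02-20", "2019-02-24")

    def test_gap_between_train_and_test_rejected(self):
        with pytest.raises(ValueError):
            CvPlan("2018-02-24", "2018-03-01", "2019-02-24")


class TestRollingOriginCv:
    def test_iteration_count_matches_test_window(self, small_study):
        cv = rolling_origin_cv(
            BsmSpec(seasonal=SeasonalSpec(365, 1)), None,
            small_study.target_log, PLAN, n_starts=1, seed=0)
        assert cv.n_iter == 365
        assert np.isfinite(cv.msfe).all()

    def test_per_horizon_denominators_shrink_at_window_edge(self, small_study):
        cv = rolling_origin_cv(
            BsmSpec(seasonal=SeasonalSpec(365, 1)), None,
            small_study.target_log, PLAN, n_starts=1, seed=0)
        np.testing.assert_array_equal(cv.n_per_h, 365 - np.arange(10))

    def test_deterministic_given_seed(self, small_study):
        spec = BsmSpec(seasonal=SeasonalSpec(365, 1))
        cv1 = rolling_origin_cv(spec, None, small_study.target_log, PLAN, n_starts=1, seed=0)
        cv2 = rolling_origin_cv(spec, None, small_study.target_log, PLAN, n_starts=1, seed=0)
        np.testing.assert_array_equal(cv1.msfe, cv2.msfe)
        np.testing.assert_array_equal(cv1.sq_errors, cv2.sq_errors)

    def test_msfe_near_noise_variance_for_true_deterministic_model(self):
        """Deterministic signal + pure noise, model = truth with fixed
        parameters: MSFE(h) ~ observation variance at every horizon."""
        sc = SimScenario(start="2015-01-01", end="2017-12-31", policy_date=None,
                         sigma2_level=0.0, theta=0.0,
                         phi=(), sigma2_eps=0.03)
        study = simulate_study(sc, seed=5)
        truth = BsmParams(sigma2_eps=0.03, sigma2_level=0.0)
        cv = rolling_origin_cv(BsmSpec(seasonal=SeasonalSpec(365, 1)), None,
                               study.target_log, PLAN, params=truth)
        np.testing.assert_allclose(cv.msfe, 0.03, rtol=0.25)


class TestInformationCriteria:
    def test_formula_toy_values(self):
        aicc, bic = information_criteria(0.0, 2, 100)
        assert aicc == pytest.approx(4 + 12 / 97)
        assert bic == pytest.approx(2 * math.log(100))

    def test_zero_parameters(self):
        aicc, bic = information_criteria(-10.0, 0, 50)
        assert aicc == 20.0
        assert bic == 20.0

    def test_aicc_undefined_when_sample_too_small(self):
        aicc, _ = information_criteria(0.0, 10, 11)
        assert np.isnan(aicc)

    def test_explicit_call_requires_counts(self):
        with pytest.raises(ValueError):
            information_criteria(1.0)


class TestHarmonicSelection:
    def test_single_true_harmonic_recovered(self, small_study):
        rep = select_harmonics(small_study.target_log, PLAN,
                               k_range=range(1, 5), n_starts=1, seed=0)
        assert rep.chosen == 1
        assert 1 in rep.eligible

    def test_two_strong_harmonics_recovered(self):
        """A pronounced semi-annual component on top of the annual one is
        detected when it is strong relative to the level noise."""
        sc = SimScenario(start="2015-01-01", end="2017-12-31", policy_date=None,
                         k_true=2,
                         seasonal_amplitudes=((0.4, 0.2), (0.5, 0.3)),
                         sigma2_eps=0.01, sigma2_level=0.0005)
        wins = 0
        for s in range(5):
            study = simulate_study(sc, seed=6000 + s)
            rep = select_harmonics(study.target_log, PLAN,
                                   k_range=range(1, 4), n_starts=1, seed=0)
            wins += rep.chosen == 2
        assert wins >= 3

    def test_flat_criteria_tie_breaks_to_smallest_k(self):
        """No seasonality in truth: every candidate is equally wrong and the
        parsimony tie-break keeps the smallest harmonic count."""
        sc = SimScenario(start="2015-01-01", end="2017-12-31", policy_date=None,
                         seasonal_amplitudes=((0.0, 0.0),), theta=0.0, phi=())
        study = simulate_study(sc, seed=77)
        rep = select_harmonics(study.target_log, PLAN,
                               k_range=range(1, 4), n_starts=1, seed=0)
        assert rep.chosen == 1


class TestCounterfactualSelection:
    def test_correlated_candidate_recovered(self, small_study):
        rep = select_counterfactual(small_study.candidates_log,
                                    small_study.target_log, PLAN,
                                    harmonics=1, n_starts=1, seed=0)
        assert rep.chosen == "pavia"
        trace_pavia = [e for e in rep.trace if e.get("candidate") == "pavia"][0]
        assert trace_pavia["theta_positive"]

    def test_self_explanation_limit(self, small_study):
        """The target itself as candidate: selected with theta ~ 1."""
        cands = dict(small_study.candidates_log)
        cands["self"] = DailySeries("self", "NOx",
                                    small_study.target_log.values.copy(),
                                    log_scale=True)
        rep = select_counterfactual(cands, small_study.target_log, PLAN,
                                    harmonics=1, n_starts=1, seed=0)
        assert rep.chosen == "self"
        theta = [e["theta"] for e in rep.trace if e.get("candidate") == "self"][0]
        assert theta == pytest.approx(1.0, abs=0.05)

    def test_pure_noise_candidates_flagged_and_alphabetical(self):
        sc = SimScenario(start="2015-01-01", end="2017-12-31", policy_date=None,
                         theta=0.0, phi=())
        study = simulate_study(sc, seed=13)
        rep = select_counterfactual(study.candidates_log, study.target_log, PLAN,
                                    harmonics=1, n_starts=1, seed=0, tolerance=0.05)
        if rep.no_clear_winner:
            assert rep.chosen == rep.eligible[0]  # alphabetically first

    def test_excessive_missingness_excluded(self, small_study):
        cands = dict(small_study.candidates_log)
        broken = cands["lodi"].values.copy()
        broken.iloc[: int(0.5 * len(broken))] = np.nan
        cands["lodi"] = DailySeries("lodi", "NOx", broken, log_scale=True)
        rep = select_counterfactual(cands, small_study.target_log, PLAN,
                                    harmonics=1, n_starts=1, seed=0)
        assert "lodi" not in rep.candidates

    def test_no_candidates_rejected(self, small_study):
        with pytest.raises(ValueError):
            select_counterfactual({}, small_study.target_log, PLAN)


class TestStepwise:
    def _covariates(self, n, rng):
        cols = {}
        for i, name in enumerate(STEPWISE_TERMS):
            cols[name] = rng.normal(0, 1, n)
        idx = build_date_index("2014-01-01", pd.Timestamp("2014-01-01") + pd.Timedelta(days=n - 1))
        return pd.DataFrame(cols, index=idx)

    def test_exact_linear_relation_retained(self):
        rng = np.random.default_rng(1)
        cov = self._covariates(300, rng)[["q_sw"]]
        eps = 2.5 * cov["q_sw"]
        res = stepwise_residual_screen(eps, cov, "bic")
        assert res.retained == ("q_sw",)

    def test_pure_noise_bic_drops_everything(self):
        rng = np.random.default_rng(2)
        cov = self._covariates(5000, rng)
        eps = pd.Series(rng.normal(0, 1, 5000), index=cov.index)
        res = stepwise_residual_screen(eps, cov, "bic")
        assert res.retained == ()

    def test_strong_wind_signal_retained_under_both_criteria(self):
        rng = np.random.default_rng(3)
        cov = self._covariates(1500, rng)
        eps = -0.5 * cov["q_sw"] + pd.Series(rng.normal(0, 0.2, 1500), index=cov.index)
        for crit in ("aic", "bic"):
            res = stepwise_residual_screen(eps, cov, crit)
            assert "q_sw" in res.retained

    def test_collinear_column_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(4)
        cov = self._covariates(200, rng)
        cov["q_se"] = 2.0 * cov["q_sw"]  # exact collinearity
        eps = pd.Series(rng.normal(0, 1, 200), index=cov.index)
        res = stepwise_residual_screen(eps, cov, "bic")
        assert "q_se" in res.dropped_collinear

    def test_column_order_invariance(self):
        rng = np.random.default_rng(6)
        cov = self._covariates(800, rng)
        eps = (-0.4 * cov["q_sw"] + 0.3 * cov["weekend"]
               + pd.Series(rng.normal(0, 0.3, 800), index=cov.index))
        res1 = stepwise_residual_screen(eps, cov, "bic")
        res2 = stepwise_residual_screen(eps, cov[list(reversed(cov.columns))], "bic")
        assert set(res1.retained) == set(res2.retained)

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            stepwise_residual_screen(pd.Series([1.0]), pd.DataFrame({"a": [1.0]}), "hqic")


class TestFinalSpec:
    def _stepwise(self, retained):
        return StepwiseResult(start_terms=STEPWISE_TERMS, retained=retained, criterion="bic")

    def test_wind_only_screen(self):
        spec = assemble_final_spec(self._stepwise(("q_sw",)))
        assert spec.regressors == (
            "counterfactual", "holidays", "weekend", "saturday_holidays",
            "sunday_holidays", "q_sw", "q_nw", "policy_step")
        assert spec.include_transitory

    def test_extra_weather_term_carried(self):
        spec = assemble_final_spec(self._stepwise(("q_sw", "q_nw", "rainfall")))
        assert "rainfall" in spec.regressors

    def test_empty_screen_keeps_calendar_and_wind_override(self):
        spec = assemble_final_spec(self._stepwise(()))
        for term in ("holidays", "weekend", "saturday_holidays",
                     "sunday_holidays", "q_sw", "q_nw"):
            assert term in spec.regressors
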