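"""Three-step model selection for the structural model.

Step 1 picks the number of trigonometric harmonics (k = 1..10), step 2 the
counterfactual city series, both by combining rolling-origin cross-validated
multi-step forecast error (MSFE at horizons 1..10) with information criteria
(AICc, BIC); step 3 screens residual weather/calendar covariates by
backward-forward stepwise regression of the smoothed observation
disturbances on the candidate terms. All steps use pre-policy data only.

The joint MSFE/criteria decision the study applies by visual inspection is
operationalized as: candidates whose mean MSFE over the horizons lies
within a tolerance (default 2%) of the pointwise-minimal curve are eligible,
and the eligible candidate with the lowest BIC wins; ties break to the
smallest harmonic count / alphabetically first city. Every step emits a
full trace.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DailySeries, RegressorSet
from .ssm import (
    BsmParams,
    BsmSpec,
    FitResult,
    SeasonalSpec,
    build_state_space,
    fit_ml,
    forecast,
    kalman_filter,
    kalman_smoother,
)

logger = logging.getLogger("airpolicy")


# ---------------------------------------------------------------------------
# cross-validation plan and MSFE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CvPlan:
    """Rolling-origin CV layout: train through ``train_end``, score on the
    contiguous daily test window, forecasting 1..h_max steps ahead."""

    train_end: str = "2018-02-24"
    test_start: str = "2018-02-25"
    test_end: str = "2019-02-24"
    h_max: int = 10
    score_beyond_window: bool = False

    def __post_init__(self) -> None:
        if not (pd.Timestamp(self.train_end) < pd.Timestamp(self.test_start)):
            raise ValueError("training end must precede the test window")
        if pd.Timestamp(self.test_start) > pd.Timestamp(self.test_end):
            raise ValueError("empty test window")
        if (pd.Timestamp(self.test_start) - pd.Timestamp(self.train_end)).days != 1:
            raise ValueError("test window must start the day after the training end")


@dataclass
class CvResult:
    """MSFE(h) curve with the per-iteration squared errors behind it."""

    label: str
    msfe: np.ndarray            # (h_max,)
    sq_errors: np.ndarray       # (n_iter, h_max), NaN where unscored
    n_per_h: np.ndarray         # (h_max,) denominators actually used
    n_iter: int
    fit: FitResult | None = None

    @property
    def mean_msfe(self) -> float:
        return float(np.mean(self.msfe))


def rolling_origin_cv(
    spec: BsmSpec,
    regressors: RegressorSet | None,
    observations: DailySeries,
    plan: CvPlan,
    label: str = "",
    params: BsmParams | None = None,
    **fit_kwargs,
) -> CvResult:
    """Rolling-origin CV with parameters estimated once on the training set.

    The filter is advanced over all data up to each origin (so every origin
    conditions on its full past), and 1..h_max-step forecasts are scored on
    the log scale. By default only targets inside the test window are
    scored, so the per-horizon denominator shrinks for the last origins;
    ``plan.score_beyond_window`` scores against later observations instead
    when they exist.
    """
    y = observations.values
    idx = pd.DatetimeIndex(y.index)
    t_train_end = idx.get_loc(pd.Timestamp(plan.train_end))
    i0 = idx.get_loc(pd.Timestamp(plan.test_start))
    i1 = idx.get_loc(pd.Timestamp(plan.test_end))
    n_iter = i1 - i0 + 1

    if params is None:
        train_idx = idx[: t_train_end + 1]
        train_obs = DailySeries(
            observations.station_id, observations.variable,
            y.iloc[: t_train_end + 1], log_scale=observations.log_scale,
        )
        train_reg = regressors.subset(train_idx) if regressors is not None else None
        fit = fit_ml(spec, train_reg, train_obs, **fit_kwargs)
        params = fit.params
    else:
        fit = None

    limit = len(idx) - 1 if plan.score_beyond_window else i1
    full_reg = regressors.subset(idx[: limit + 1]) if regressors is not None else None
    mats = build_state_space(spec, params, full_reg, index=idx[: limit + 1], n=limit + 1)
    yv = y.iloc[: limit + 1].to_numpy()
    filt = kalman_filter(mats, yv)

    sq = np.full((n_iter, plan.h_max), np.nan)
    for j in range(n_iter):
        origin = i0 - 1 + j
        h_avail = min(plan.h_max, limit - origin)
        if h_avail < 1:
            break
        preds = forecast(mats, filt, origin, h_avail)
        actual = yv[origin + 1: origin + 1 + h_avail]
        sq[j, :h_avail] = (preds - actual) ** 2
    n_per_h = np.sum(np.isfinite(sq), axis=0)
    with np.errstate(invalid="ignore"):
        msfe = np.nanmean(sq, axis=0)
    return CvResult(label=label, msfe=msfe, sq_errors=sq, n_per_h=n_per_h, n_iter=n_iter, fit=fit)


# ---------------------------------------------------------------------------
# information criteria
# ---------------------------------------------------------------------------

def information_criteria(fit_or_loglik, n_params: int | None = None, nobs: int | None = None):
    """(AICc, BIC) from a FitResult or an explicit (loglik, p, n) triple.

    AIC = -2l + 2p, AICc = AIC + 2p(p+1)/(n-p-1), BIC = -2l + p log n.
    For a FitResult, p is the effective parameter count (free ML parameters
    plus diffusely initialized state elements) and n the number of
    observations contributing to the likelihood. AICc is NaN when
    n - p - 1 <= 0.
    """
    if isinstance(fit_or_loglik, FitResult):
        ll = fit_or_loglik.loglik
        p = fit_or_loglik.k_params if n_params is None else n_params
        n = fit_or_loglik.nobs if nobs is None else nobs
    else:
        ll = float(fit_or_loglik)
        if n_params is None or nobs is None:
            raise ValueError("explicit loglik needs n_params and nobs")
        p, n = n_params, nobs
    aic = -2.0 * ll + 2.0 * p
    aicc = aic + (2.0 * p * (p + 1) / (n - p - 1) if n - p - 1 > 0 else np.nan)
    bic = -2.0 * ll + p * math.log(n)
    return aicc, bic


# ---------------------------------------------------------------------------
# joint MSFE / criteria rule
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Outcome of one selection step with its full rule trace."""

    candidates: list
    msfe: dict
    criteria: dict              # label -> (aicc, bic)
    chosen: object
    eligible: list
    trace: list = field(default_factory=list)
    no_clear_winner: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lab in self.candidates:
            aicc, bic = self.criteria[lab]
            row = {"candidate": lab, "aicc": aicc, "bic": bic,
                   "mean_msfe": float(np.mean(self.msfe[lab])),
                   "eligible": lab in self.eligible, "chosen": lab == self.chosen}
            for h, val in enumerate(self.msfe[lab], start=1):
                row[f"msfe_{h}"] = val
            rows.append(row)
        return pd.DataFrame(rows)


def _joint_rule(candidates, msfe, criteria, tolerance):
    """Eligibility by mean-MSFE tolerance around the pointwise-min curve,
    then lowest BIC among the eligible; candidate order breaks ties."""
    curves = np.vstack([msfe[lab] for lab in candidates])
    pointwise_min = np.nanmin(curves, axis=0)
    ref = float(np.nanmean(pointwise_min))
    means = {lab: float(np.nanmean(msfe[lab])) for lab in candidates}
    eligible = [lab for lab in candidates if means[lab] <= (1.0 + tolerance) * ref]
    if not eligible:
        eligible = list(candidates)
    chosen = min(eligible, key=lambda lab: (criteria[lab][1], candidates.index(lab)))
    bics = [criteria[lab][1] for lab in eligible]
    no_clear = (max(bics) - min(bics)) < 2.0 and len(eligible) == len(candidates)
    if no_clear:
        # criteria indistinguishable: parsimony/alphabetical tie-break
        chosen = eligible[0]
    trace = [
        {"candidate": lab, "mean_msfe": means[lab], "aicc": criteria[lab][0],
         "bic": criteria[lab][1], "eligible": lab in eligible}
        for lab in candidates
    ]
    trace.append({"rule": f"mean MSFE within {tolerance:.1%} of pointwise-min curve "
                          f"(ref {ref:.6g}), lowest BIC among eligible", "chosen": chosen})
    return chosen, eligible, trace, no_clear


# ---------------------------------------------------------------------------
# step 1: harmonics
# ---------------------------------------------------------------------------

def select_harmonics(
    observations: DailySeries,
    plan: CvPlan,
    k_range=range(1, 11),
    period: int = 365,
    tolerance: float = 0.02,
    **fit_kwargs,
) -> SelectionReport:
    """Choose the harmonic count for the trigonometric seasonality.

    Candidate models are the bare structural model (trend + seasonality, no
    regressors) with k = 1..10 harmonics, each fit once on the training set.
    So that likelihoods are comparable across k, the criteria are evaluated
    on the common post-burn sample of the largest candidate (the effective
    parameter count already counts the diffuse states per candidate).
    """
    ks = list(k_range)
    common_burn = 2 + 2 * max(ks)
    y = observations.values
    idx = pd.DatetimeIndex(y.index)
    t_train_end = idx.get_loc(pd.Timestamp(plan.train_end))
    y_train = y.iloc[: t_train_end + 1].to_numpy()

    msfe, criteria = {}, {}
    for k in ks:
        spec = BsmSpec(seasonal=SeasonalSpec(period, k))
        cv = rolling_origin_cv(spec, None, observations, plan, label=f"k={k}", **fit_kwargs)
        msfe[k] = cv.msfe
        fit = cv.fit
        mats = build_state_space(spec, fit.params, None, n=t_train_end + 1)
        mats.burn = common_burn
        common = kalman_filter(mats, y_train)
        criteria[k] = information_criteria(common.loglik, fit.k_params, common.nobs_used)
    chosen, eligible, trace, ncw = _joint_rule(ks, msfe, criteria, tolerance)
    if ncw:
        logger.info("harmonic selection: criteria within tolerance for all k, "
                    "smallest-k tie-break applied (k=%d)", chosen)
    return SelectionReport(candidates=ks, msfe=msfe, criteria=criteria, chosen=chosen,
                           eligible=eligible, trace=trace, no_clear_winner=ncw)


# ---------------------------------------------------------------------------
# step 2: counterfactual
# ---------------------------------------------------------------------------

def select_counterfactual(
    candidates_log: dict[str, DailySeries],
    observations: DailySeries,
    plan: CvPlan,
    harmonics: int = 1,
    period: int = 365,
    tolerance: float = 0.02,
    max_missing_frac: float = 0.20,
    **fit_kwargs,
) -> SelectionReport:
    """Choose the counterfactual city among log-scale candidate series.

    Each candidate enters the measurement equation as the single regressor
    theta * x_t on top of the chosen seasonal model. Candidates missing more
    than ``max_missing_frac`` of the training window are flagged and
    excluded. The estimated sign of theta is reported as a diagnostic (a
    positive loading is expected for a genuine areal control), never used as
    a constraint. Alphabetical order breaks ties.
    """
    if not candidates_log:
        raise ValueError("no counterfactual candidates supplied")
    cities = sorted(candidates_log)
    idx = pd.DatetimeIndex(observations.values.index)
    train_mask = idx <= pd.Timestamp(plan.train_end)

    msfe, criteria, thetas = {}, {}, {}
    flagged = []
    usable = []
    for city in cities:
        series = candidates_log[city]
        if not series.log_scale:
            raise ValueError(f"candidate {city!r} must be log-transformed")
        x = series.values.reindex(idx)
        frac_missing = float(x[train_mask].isna().mean())
        if frac_missing > max_missing_frac:
            flagged.append(city)
            logger.warning("candidate %s excluded: %.0f%% missing in training window",
                           city, 100 * frac_missing)
            continue
        usable.append(city)
        reg = RegressorSet(x.rename("counterfactual").to_frame())
        spec = BsmSpec(seasonal=SeasonalSpec(period, harmonics), regressors=("counterfactual",))
        cv = rolling_origin_cv(spec, reg, observations, plan, label=city, **fit_kwargs)
        msfe[city] = cv.msfe
        criteria[city] = information_criteria(cv.fit)
        thetas[city] = cv.fit.params.coef["counterfactual"]
    if not usable:
        raise ValueError("all counterfactual candidates excluded for missingness")
    chosen, eligible, trace, ncw = _joint_rule(usable, msfe, criteria, tolerance)
    for entry in trace:
        if "candidate" in entry:
            entry["theta"] = thetas[entry["candidate"]]
            entry["theta_positive"] = thetas[entry["candidate"]] > 0
    if flagged:
        trace.append({"excluded_for_missingness": flagged})
    if ncw:
        logger.info("counterfactual selection: no clear winner, alphabetical "
                    "tie-break applied (%s)", chosen)
    return SelectionReport(candidates=usable, msfe=msfe, criteria=criteria, chosen=chosen,
                           eligible=eligible, trace=trace, no_clear_winner=ncw)


# ---------------------------------------------------------------------------
# step 3: stepwise residual screen
# ---------------------------------------------------------------------------

#: the auxiliary-regression covariate roster
STEPWISE_TERMS = (
    "holidays", "weekend", "saturday_holidays", "sunday_holidays",
    "temperature", "rainfall", "radiation", "humidity",
    "q_ne", "q_nw", "q_sw", "q_se",
)


@dataclass
class StepwiseResult:
    """Retained covariate subsets of the residual screen."""

    start_terms: tuple[str, ...]
    retained: tuple[str, ...]
    criterion: str
    path: list = field(default_factory=list)
    dropped_collinear: tuple[str, ...] = ()


def _ols_crit(y: np.ndarray, X: np.ndarray, penalty: float) -> float:
    n = y.size
    if X.shape[1] == 0:
        rss = float(y @ y)
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss = float(r @ r)
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + penalty * X.shape[1]


def stepwise_residual_screen(
    eps: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
    criterion: str = "bic",
) -> StepwiseResult:
    """Backward-forward stepwise OLS of smoothed disturbances on covariates.

    Starts from the full model (no intercept: the disturbances are mean
    zero by construction), iteratively applies the single drop or re-add
    that most improves the criterion, and stops when no move improves.
    Rows with missing response or covariates are dropped; exactly collinear
    columns are removed up front with a warning.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    if isinstance(eps, np.ndarray):
        eps = pd.Series(eps, index=covariates.index[: len(eps)])
    cov = covariates.reindex(eps.index)
    rows = eps.notna() & cov.notna().all(axis=1)
    y = eps[rows].to_numpy(dtype=float)
    frame = cov.loc[rows]
    n = y.size
    penalty = 2.0 if criterion == "aic" else math.log(n)

    # drop exactly collinear columns (QR rank revealing), keeping first seen
    terms = list(frame.columns)
    X_full = frame.to_numpy(dtype=float)
    keep, dropped = [], []
    for j in range(X_full.shape[1]):
        trial = X_full[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            dropped.append(terms[j])
            logger.warning("stepwise: dropping collinear column %r", terms[j])
    terms = [terms[j] for j in keep]
    cols = {t: frame[t].to_numpy(dtype=float) for t in terms}

    def crit(subset) -> float:
        X = (np.column_stack([cols[t] for t in subset])
             if subset else np.empty((n, 0)))
        return _ols_crit(y, X, penalty)

    current = list(terms)
    removed: list[str] = []
    best = crit(current)
    path = [{"action": "start", "terms": tuple(current), "criterion": best}]
    while True:
        moves = []
        for t in current:
            trial = [u for u in current if u != t]
            moves.append((crit(trial), "drop", t, trial))
        for t in removed:
            trial = current + [t]
            moves.append((crit(trial), "add", t, trial))
        if not moves:
            break
        moves.sort(key=lambda mv: (mv[0], mv[1], mv[2]))
        val, action, term, trial = moves[0]
        if val >= best - 1e-10:
            break
        best = val
        current = trial
        if action == "drop":
            removed.append(term)
        else:
            removed.remove(term)
        path.append({"action": action, "term": term, "criterion": best})
    retained = tuple(t for t in terms if t in current)
    return StepwiseResult(
        start_terms=tuple(terms), retained=retained, criterion=criterion,
        path=path, dropped_collinear=tuple(dropped),
    )


def smoothed_disturbances(
    spec: BsmSpec,
    regressors: RegressorSet | None,
    observations: DailySeries,
    fit: FitResult,
) -> pd.Series:
    """Smoothed observation disturbances of a fitted model, on the data index."""
    idx = pd.DatetimeIndex(observations.values.index)
    mats = build_state_space(spec, fit.params, regressors, index=idx, n=len(idx))
    out = kalman_smoother(mats, observations.values)
    return pd.Series(out.eps_smooth, index=idx)


# ---------------------------------------------------------------------------
# final specification
# ---------------------------------------------------------------------------

#: calendar terms always carried into the final model
CALENDAR_BLOCK = ("holidays", "weekend", "saturday_holidays", "sunday_holidays")
#: wind terms kept by documented override regardless of the screen
WIND_OVERRIDE = ("q_sw", "q_nw")


def assemble_final_spec(
    stepwise: StepwiseResult,
    harmonics: int = 1,
    period: int = 365,
    include_transitory: bool = True,
    lambda_bounds: tuple[float, float] = (0.0, 1.0),
    fix_lambda: float | None = None,
) -> BsmSpec:
    """Final model regressors: full calendar block, BIC-retained weather
    terms, the westerly-wind override, the counterfactual, and the policy
    step (plus the transitory state). Retained terms beyond the documented
    final set are carried over and logged as deviations."""
    final = ["counterfactual"]
    final += list(CALENDAR_BLOCK)
    for t in WIND_OVERRIDE:
        if t not in final:
            final.append(t)
    extras = [t for t in stepwise.retained
              if t not in final and t not in CALENDAR_BLOCK]
    for t in extras:
        logger.info("final spec: carrying screened term %r beyond the documented set", t)
        final.append(t)
    final.append("policy_step")
    return BsmSpec(
        seasonal=SeasonalSpec(period, harmonics),
        regressors=tuple(final),
        include_transitory=include_transitory,
        lambda_bounds=lambda_bounds,
        fix_lambda=fix_lambda,
    )
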