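"""Policy-effect estimation and reporting on the final selected model.

The intervention enters the measurement equation as a step dummy from the
policy date (permanent effect delta1, a lasting level shift of log
concentrations) plus a transitory state w_t = lambda*w_{t-1} +
delta0*impulse_t (an adaptation shock decaying geometrically). Both are
estimated jointly with all other parameters by maximum likelihood; effects
are reported on the log scale and as percentage changes exp(estimate) - 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import DailySeries, RegressorSet
from .ssm import BsmSpec, FitResult, fit_ml, significance_stars

logger = logging.getLogger("airpolicy")

#: ratio of SE to |estimate| beyond which the transitory effect is flagged
WEAK_INFO_RATIO = 10.0


@dataclass
class PolicyEffect:
    """Permanent and transitory policy effects with inference."""

    station_id: str
    pollutant: str
    delta1: float
    delta1_se: float
    delta0: float
    delta0_se: float
    lam: float
    lam_se: float
    fit: FitResult
    trajectory: pd.Series       # total effect delta1 + w_t per day (log scale)
    weak_transitory: bool = False

    @property
    def delta1_t(self) -> float:
        return self.delta1 / self.delta1_se if _pos(self.delta1_se) else np.nan

    @property
    def delta0_t(self) -> float:
        return self.delta0 / self.delta0_se if _pos(self.delta0_se) else np.nan

    @property
    def delta1_pct(self) -> float:
        """Permanent effect as a relative concentration change."""
        return float(np.exp(self.delta1) - 1.0)

    @property
    def delta0_pct(self) -> float:
        return float(np.exp(self.delta0) - 1.0)


def _pos(x: float) -> bool:
    return np.isfinite(x) and x > 0


def estimate_policy(
    spec: BsmSpec,
    regressors: RegressorSet,
    observations: DailySeries,
    policy_date=None,
    min_post_days: int = 30,
    **fit_kwargs,
) -> PolicyEffect:
    """Joint ML fit of the final model with the policy terms.

    The policy date must lie strictly inside the estimation window with at
    least ``min_post_days`` post-policy days; the total-effect trajectory
    delta1*D1_t + delta0*lambda^(t-t0) is evaluated per day.
    """
    if "policy_step" not in spec.regressors:
        raise ValueError("final spec must include the policy step regressor")
    idx = regressors.dates
    policy = pd.Timestamp(policy_date) if policy_date is not None else regressors.policy_date
    if policy is None:
        raise ValueError("no policy date available")
    if policy <= idx[0] or policy > idx[-1] - pd.Timedelta(days=min_post_days - 1):
        raise ValueError(
            f"policy date {policy.date()} must lie inside "
            f"{idx[0].date()}..{idx[-1].date()} with >= {min_post_days} post-policy days"
        )

    fit = fit_ml(spec, regressors, observations, **fit_kwargs)
    p = fit.params
    delta1 = p.coef.get("policy_step", 0.0)
    step = (idx >= policy).astype(float)
    decay = np.zeros(len(idx))
    if spec.include_transitory:
        pos = int(np.searchsorted(idx.values, np.datetime64(policy)))
        t = np.arange(len(idx) - pos)
        decay[pos:] = p.lam ** t
    trajectory = pd.Series(delta1 * step + p.delta0 * decay, index=idx)

    d0_se = fit.se.get("delta0", np.nan)
    weak = bool(
        spec.include_transitory
        and np.isfinite(d0_se)
        and d0_se > WEAK_INFO_RATIO * abs(p.delta0)
    )
    if weak:
        logger.warning(
            "transitory effect weakly identified (SE %.3g vs estimate %.3g); "
            "flagged, not dropped", d0_se, p.delta0,
        )
    return PolicyEffect(
        station_id=observations.station_id,
        pollutant=observations.variable,
        delta1=delta1,
        delta1_se=fit.se.get("policy_step", np.nan),
        delta0=p.delta0,
        delta0_se=d0_se,
        lam=p.lam,
        lam_se=fit.se.get("lambda", np.nan),
        fit=fit,
        trajectory=trajectory,
        weak_transitory=weak,
    )


def report_effects(effects: list[PolicyEffect]) -> pd.DataFrame:
    """Effects table: one row per station/pollutant/effect kind.

    Columns mirror the study's reporting layout (estimate, SE, t, stars);
    percentage changes are included alongside. t and stars are blank when
    the SE is unavailable. An empty input yields a header-only frame.
    """
    columns = ["station_id", "pollutant", "effect", "estimate", "se", "t",
               "stars", "pct_change", "flag"]
    rows = []
    for e in effects:
        for kind, est, se_, t in (
            ("permanent", e.delta1, e.delta1_se, e.delta1_t),
            ("transitory", e.delta0, e.delta0_se, e.delta0_t),
        ):
            flag = ""
            if not _pos(se_):
                flag = "se_unavailable"
            elif kind == "transitory" and e.weak_transitory:
                flag = "weak_information"
            rows.append(
                {
                    "station_id": e.station_id,
                    "pollutant": e.pollutant,
                    "effect": kind,
                    "estimate": est,
                    "se": se_ if _pos(se_) else np.nan,
                    "t": t,
                    "stars": significance_stars(t),
                    "pct_change": float(np.exp(est) - 1.0),
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows, columns=columns)
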