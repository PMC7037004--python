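"""Synthetic daily air-quality datasets drawn from the structural model.

Generates a target-city pollutant series from the exact model recursions
(local linear trend, trigonometric seasonality, counterfactual loading,
calendar and wind effects, optional step + decaying-impulse intervention),
an independent set of candidate counterfactual city series, and weather /
calendar covariates, so that every pipeline stage can be exercised and
parameter recovery can be verified against known truth.

Default magnitudes are the study conditions of the Milan analysis this
package implements: counterfactual loading theta = 0.6, weekend/holiday
effects around -0.1, westerly-wind effects -0.2 to -0.3, observation
variance 0.03 and level variance 0.004 on the log scale, slope and seasonal
variances zero (so the annual cycle is a fixed one-harmonic sinusoid), and a
policy intervention with permanent effect 0.3 and transitory impulse -0.1
decaying at rate 0.8.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    DailySeries,
    RegressorSet,
    assemble_regressors,
    build_calendar,
    build_date_index,
    log_transform,
)
from .ssm import BsmParams, BsmSpec, SeasonalSpec

CANDIDATE_CITIES = ("bergamo", "brescia", "cremona", "lodi", "pavia", "saronno", "treviglio")

#: calendar/wind coefficient defaults (log scale)
DEFAULT_PHI = (
    ("holidays", -0.06),
    ("weekend", -0.10),
    ("saturday_holidays", 0.10),
    ("sunday_holidays", 0.09),
    ("q_sw", -0.30),
    ("q_nw", -0.20),
)


@dataclass(frozen=True)
class SimScenario:
    """Complete description of one synthetic study."""

    start: str = "2014-01-01"
    end: str = "2019-09-30"
    policy_date: str | None = "2019-02-25"

    # target-series truth
    k_true: int = 1
    seasonal_amplitudes: tuple[tuple[float, float], ...] = ((0.30, 0.10),)
    level0: float = 3.7
    slope0: float = 0.0
    theta: float = 0.6
    phi: tuple[tuple[str, float], ...] = DEFAULT_PHI
    delta1: float = 0.3
    delta0: float = -0.1
    lam: float = 0.8
    sigma2_eps: float = 0.03
    sigma2_level: float = 0.004
    sigma2_slope: float = 0.0
    sigma2_seasonal: float = 0.0

    # counterfactual generator (its own independent structural path)
    cf_level0: float = 3.6
    cf_slope0: float = 0.0
    cf_amplitudes: tuple[tuple[float, float], ...] = ((0.35, 0.05),)
    cf_sigma2_eps: float = 0.03
    cf_sigma2_level: float = 0.004
    cf_sigma2_slope: float = 0.0
    cf_sigma2_seasonal: float = 0.0

    cities: tuple[str, ...] = CANDIDATE_CITIES
    true_city: str = "pavia"

    # weather generator (right-skewed nonnegative wind speeds)
    wind_gamma_shape: float = 1.5
    wind_gamma_scale: float = 0.8
    wind_persistence: float = 0.8
    missing_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in (self.sigma2_eps, self.sigma2_level,
                               self.sigma2_slope, self.sigma2_seasonal)):
            raise ValueError("variances must be >= 0")
        if abs(self.lam) >= 1:
            raise ValueError("|lambda| must be < 1")
        if len(self.seasonal_amplitudes) != self.k_true:
            raise ValueError("need one amplitude pair per true harmonic")
        if self.true_city not in self.cities:
            raise ValueError(f"true_city {self.true_city!r} not among cities")

    def replace(self, **kw) -> "SimScenario":
        return dataclasses.replace(self, **kw)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return build_date_index(self.start, self.end)

    @property
    def phi_dict(self) -> dict[str, float]:
        return dict(self.phi)

    def truth_params(self) -> BsmParams:
        """The generator's parameters in fitting form (BsmParams)."""
        coef = dict(self.phi)
        coef["counterfactual"] = self.theta
        if self.policy_date is not None:
            coef["policy_step"] = self.delta1
        return BsmParams(
            sigma2_eps=self.sigma2_eps,
            sigma2_level=self.sigma2_level,
            sigma2_slope=self.sigma2_slope,
            sigma2_seasonal=self.sigma2_seasonal,
            coef=coef,
            delta0=self.delta0 if self.policy_date is not None else 0.0,
            lam=self.lam,
        )

    def target_spec(self, include_transitory: bool | None = None, fix_lambda: float | None = None) -> BsmSpec:
        """The BsmSpec matching the generating equations."""
        names = ["counterfactual"] + [n for n, _ in self.phi]
        if self.policy_date is not None:
            names.append("policy_step")
        if include_transitory is None:
            include_transitory = self.policy_date is not None
        return BsmSpec(
            seasonal=SeasonalSpec(365, self.k_true),
            regressors=tuple(names),
            include_transitory=include_transitory,
            fix_lambda=fix_lambda,
        )


# ---------------------------------------------------------------------------
# component simulators
# ---------------------------------------------------------------------------

def _simulate_structural_path(
    rng: np.random.Generator,
    n: int,
    level0: float,
    slope0: float,
    amplitudes,
    s2_level: float,
    s2_slope: float,
    s2_seasonal: float,
    period: int = 365,
) -> np.ndarray:
    """Signal path mu_t + gamma_t from the exact transition recursions."""
    mu, beta = level0, slope0
    gam = [list(ab) for ab in amplitudes]
    out = np.empty(n)
    eta = rng.normal(0.0, math.sqrt(s2_level), n) if s2_level > 0 else np.zeros(n)
    zeta = rng.normal(0.0, math.sqrt(s2_slope), n) if s2_slope > 0 else np.zeros(n)
    om = (rng.normal(0.0, math.sqrt(s2_seasonal), (n, len(gam), 2))
          if s2_seasonal > 0 else np.zeros((n, len(gam), 2)))
    for t in range(n):
        out[t] = mu + sum(g[0] for g in gam)
        # advance states to t+1
        mu = mu + beta + eta[t]
        beta = beta + zeta[t]
        for j, g in enumerate(gam):
            ang = 2.0 * math.pi * (j + 1) / period
            c, s = math.cos(ang), math.sin(ang)
            g0 = c * g[0] + s * g[1] + om[t, j, 0]
            g1 = -s * g[0] + c * g[1] + om[t, j, 1]
            g[0], g[1] = g0, g1
    return out


def simulate_counterfactual(scenario: SimScenario, rng: np.random.Generator, city: str | None = None):
    """One candidate city's series: independent trend + seasonal + noise path.

    Returns (raw, log) DailySeries; the raw series is the exponentiated log
    path so that ingest-side log transformation round-trips exactly.
    """
    city = city or scenario.true_city
    dates = scenario.dates
    n = len(dates)
    signal = _simulate_structural_path(
        rng, n, scenario.cf_level0, scenario.cf_slope0, scenario.cf_amplitudes,
        scenario.cf_sigma2_level, scenario.cf_sigma2_slope, scenario.cf_sigma2_seasonal,
    )
    noise = (rng.normal(0.0, math.sqrt(scenario.cf_sigma2_eps), n)
             if scenario.cf_sigma2_eps > 0 else np.zeros(n))
    logged = signal + noise
    log_series = DailySeries(city, "NOx", pd.Series(logged, index=dates), log_scale=True)
    raw = DailySeries(city, "NOx", pd.Series(np.exp(logged), index=dates))
    return raw, log_series


def simulate_weather_calendar(scenario: SimScenario, rng: np.random.Generator):
    """Calendar dummies plus simulated wind-quadrant and weather covariates.

    Wind-quadrant speeds are i.i.d. Gamma draws (nonnegative, right-skewed);
    temperature/radiation carry an annual cycle; rainfall is zero-inflated
    exponential. The weather block only exists to exercise covariate
    screening, it does not feed back into the target signal beyond the
    configured wind coefficients.
    """
    dates = scenario.dates
    n = len(dates)
    calendar = build_calendar(dates)
    # persistent wind regimes: AR(1) Gaussian copula with Gamma marginals,
    # so speeds stay nonnegative and right-skewed but last several days
    rho = scenario.wind_persistence
    z = np.empty((n, 4))
    z[0] = rng.normal(0.0, 1.0, 4)
    innov = rng.normal(0.0, 1.0, (n, 4))
    for t in range(1, n):
        z[t] = rho * z[t - 1] + math.sqrt(1.0 - rho * rho) * innov[t]
    u = stats.norm.cdf(z)
    speeds = (stats.gamma.ppf(u, scenario.wind_gamma_shape, scale=scenario.wind_gamma_scale)
              if scenario.wind_gamma_scale > 0 else np.zeros((n, 4)))
    quads = pd.DataFrame(speeds, index=dates, columns=["q_ne", "q_se", "q_sw", "q_nw"])
    doy = dates.dayofyear.to_numpy()
    phase = 2.0 * np.pi * (doy - 110) / 365.25
    weather = pd.DataFrame(
        {
            "temperature": 13.0 + 10.0 * np.sin(phase) + rng.normal(0, 3.0, n),
            "rainfall": np.where(rng.random(n) < 0.3, rng.exponential(5.0, n), 0.0),
            "radiation": np.clip(130.0 + 90.0 * np.sin(phase) + rng.normal(0, 40.0, n), 0.0, None),
            "humidity": np.clip(70.0 + rng.normal(0, 12.0, n), 5.0, 100.0),
        },
        index=dates,
    )
    return calendar, quads, weather


def simulate_target(
    scenario: SimScenario,
    counterfactual_log: DailySeries,
    regressors: RegressorSet,
    rng: np.random.Generator,
):
    """Target-city series from the full measurement equation.

    Draws the disturbances with the scenario variances, builds the states by
    the exact recursions, assembles y_t = mu_t + gamma_t + theta x_t +
    Z_t phi + delta1 D1_t + w_t + eps_t, and applies the optional
    missingness mask. Returns (raw, log, components) where components holds
    the latent paths for recovery checks.
    """
    dates = scenario.dates
    n = len(dates)
    signal = _simulate_structural_path(
        rng, n, scenario.level0, scenario.slope0, scenario.seasonal_amplitudes,
        scenario.sigma2_level, scenario.sigma2_slope, scenario.sigma2_seasonal,
    )
    x = counterfactual_log.values.reindex(dates).to_numpy()
    phi = scenario.phi_dict
    Xcal = regressors.matrix(tuple(phi), index=dates)
    reg_part = Xcal @ np.array(list(phi.values()))

    w = np.zeros(n)
    step = np.zeros(n)
    if scenario.policy_date is not None:
        p = pd.Timestamp(scenario.policy_date)
        step = (dates >= p).to_numpy() if hasattr(dates >= p, "to_numpy") else np.asarray(dates >= p)
        step = step.astype(float)
        pos = int(np.searchsorted(dates.values, np.datetime64(p)))
        w_val = 0.0
        for t in range(n):
            impulse = scenario.delta0 if t == pos else 0.0
            w_val = scenario.lam * w_val + impulse
            w[t] = w_val
    eps = rng.normal(0.0, math.sqrt(scenario.sigma2_eps), n) if scenario.sigma2_eps > 0 else np.zeros(n)
    logged = signal + scenario.theta * x + reg_part + scenario.delta1 * step + w + eps

    if scenario.missing_prob > 0:
        mask = rng.random(n) < scenario.missing_prob
        logged = np.where(mask, np.nan, logged)

    log_series = DailySeries("milano_sim", "NOx", pd.Series(logged, index=dates), log_scale=True)
    raw = DailySeries("milano_sim", "NOx", pd.Series(np.exp(logged), index=dates))
    components = {"trend_seasonal": signal, "transitory": w, "step": step, "noise": eps}
    return raw, log_series, components


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclass
class SimStudy:
    """Everything one synthetic run produces."""

    scenario: SimScenario
    target_raw: DailySeries
    target_log: DailySeries
    candidates_raw: dict[str, DailySeries]
    candidates_log: dict[str, DailySeries]
    regressors: RegressorSet
    components: dict[str, np.ndarray]

    @property
    def truth(self) -> BsmParams:
        return self.scenario.truth_params()


def simulate_study(scenario: SimScenario, seed: int | None = None) -> SimStudy:
    """Generate the complete dataset: candidates, weather, calendar, target.

    Only the ``true_city`` candidate feeds the target (through theta), the
    other candidates are independent paths — correlation with the target is
    structural, mirroring the regression form of the measurement equation.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    candidates_raw: dict[str, DailySeries] = {}
    candidates_log: dict[str, DailySeries] = {}
    for city in scenario.cities:
        raw, logs = simulate_counterfactual(scenario, rng, city)
        candidates_raw[city] = raw
        candidates_log[city] = logs
    calendar, quads, weather = simulate_weather_calendar(scenario, rng)
    regressors = assemble_regressors(
        calendar, quads, candidates_log[scenario.true_city],
        policy_date=scenario.policy_date, weather=weather,
    )
    target_raw, target_log, components = simulate_target(
        scenario, candidates_log[scenario.true_city], regressors, rng
    )
    return SimStudy(
        scenario=scenario, target_raw=target_raw, target_log=target_log,
        candidates_raw=candidates_raw, candidates_log=candidates_log,
        regressors=regressors, components=components,
    )


def write_study(study: SimStudy, outdir) -> dict[str, str]:
    """Emit the study as the CSV dialect the ingest reads, plus truth.json.

    Wind is written as four pseudo-stations sitting at the quadrant centres
    (45/135/225/315 degrees) so that quadrant reconstruction at ingest
    reproduces the generated quadrant speeds.
    """
    os.makedirs(outdir, exist_ok=True)
    rows = []

    def _emit(sid: str, var: str, series: pd.Series) -> None:
        for date, val in series.items():
            if np.isfinite(val):
                rows.append((date.date().isoformat(), sid, var, repr(float(val))))

    _emit(study.target_raw.station_id, "NOx", study.target_raw.values)
    for city, s in study.candidates_raw.items():
        _emit(city, "NOx", s.values)
    frame = study.regressors.frame
    for var in ("temperature", "rainfall", "radiation", "humidity"):
        _emit("meteo_sim", var, frame[var])
    centers = {"q_ne": 45.0, "q_se": 135.0, "q_sw": 225.0, "q_nw": 315.0}
    for col, deg in centers.items():
        sid = f"wind_{col[2:]}"
        _emit(sid, "wind_speed", frame[col])
        _emit(sid, "wind_direction", pd.Series(deg, index=frame.index))

    data_path = os.path.join(outdir, "data.csv")
    with open(data_path, "w") as fh:
        fh.write("date,station_id,variable,value\n")
        fh.writelines(",".join(r) + "\n" for r in rows)

    meta_path = os.path.join(outdir, "stations.csv")
    with open(meta_path, "w") as fh:
        fh.write("station_id,name,kind,role\n")
        fh.write("milano_sim,Synthetic Milan,air_quality,milan\n")
        for city in study.scenario.cities:
            fh.write(f"{city},{city.title()},air_quality,counterfactual\n")
        fh.write("meteo_sim,Synthetic weather,weather,milan\n")
        for col in centers:
            fh.write(f"wind_{col[2:]},Synthetic wind {col},weather,milan\n")

    truth_path = os.path.join(outdir, "truth.json")
    truth = dataclasses.asdict(study.scenario)
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
    return {"data": data_path, "stations": meta_path, "truth": truth_path}
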