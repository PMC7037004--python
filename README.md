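# airpolicy

Early-stage impact assessment of urban traffic restrictions on air quality,
built around the case of Milan's extended limited-traffic zone ("Area B",
active from 25 February 2019) and the vehicle-generated pollutants NOx and
NO2 measured in ug/m3 by the regional monitoring network.

The package is aimed at environmental statisticians and policy analysts who
want to ask: *after adjusting for weather, calendar effects, and the common
trend of the surrounding region, did concentrations change when the policy
started?* It provides the full analysis chain — ingest, descriptive
pre/post comparison, structural time-series modelling, model selection,
intervention estimation — plus a synthetic-data generator drawn from the
same equations so every stage is testable without any data download.

## The model

Daily log concentrations are decomposed with a Gaussian basic structural
model (BSM) augmented by regressors and a policy intervention:

```
y_t  = mu_t + gamma_t + theta * x_t + Z_t' Phi + delta1 * D1_t + w_t + eps_t
mu_t = mu_{t-1} + beta_{t-1} + eta_t          (local linear trend: level)
beta_t = beta_{t-1} + zeta_t                  (local linear trend: slope)
gamma_t = sum_j gamma_{j,t}                   (trigonometric seasonality,
                                               harmonics rotating at 2*pi*j/s, s = 365)
w_t  = lambda * w_{t-1} + delta0 * D2_t       (transitory policy effect)
```

where `x_t` is the log concentration of a counterfactual city (a
neighbouring urban centre that shares weather and socio-economic conditions
but is untouched by the policy), `Z_t` holds calendar dummies (holidays,
weekends, and their interactions) and wind-quadrant speeds, `D1_t` is a
step dummy from the policy date (permanent effect `delta1`) and `D2_t` an
impulse on the policy date whose effect decays geometrically with
persistence `lambda` (transitory effect `delta0`). All disturbances are
Gaussian white noise; estimation is exact maximum likelihood through a
Kalman filter with diffuse initialization of the nonstationary states.
Because the response is on the log scale, coefficients read as relative
concentration changes (`exp(estimate) - 1`).

Model selection follows a three-step procedure on pre-policy data only:

1. **harmonics** — fit k = 1..10 harmonics; compare rolling-origin
   cross-validated MSFE at horizons 1–10 with AICc/BIC;
2. **counterfactual** — same comparison across candidate cities entering as
   `theta * x_t`;
3. **covariates** — backward-forward stepwise regression (AIC and BIC) of
   the smoothed observation disturbances on twelve calendar/weather terms.

The descriptive `prepost` stage computes dAVG and dMED: differences of
mean and median concentration between the treatment window (25 Feb–30 Sep
of the policy year) and the matched multi-year calendar-day average.

## Worked example

```python
from airpolicy import (SimScenario, simulate_study, estimate_policy,
                       report_effects, prepost_compare)

scenario = SimScenario(seed=42)   # 2014-01-01..2019-09-30, policy 2019-02-25
study = simulate_study(scenario)

pp = prepost_compare(study.target_raw, treat_year=2019,
                     control_years=range(2014, 2019))
print(f"dAVG = {pp.d_avg:.2f} ug/m3, dMED = {pp.d_med:.2f} ug/m3")

effect = estimate_policy(scenario.target_spec(), study.regressors,
                         study.target_log, n_starts=3, seed=0)
print(report_effects([effect]).to_string(index=False))
```

prints

```
dAVG = -381.39 ug/m3, dMED = -344.56 ug/m3
station_id pollutant     effect  estimate       se         t stars  pct_change flag
milano_sim       NOx  permanent  0.272297 0.174495  1.560487          0.312977
milano_sim       NOx transitory -0.356014 0.221672 -1.606038         -0.299537
```

The permanent effect is estimated at 0.27 on the log scale (truth 0.3 in
this scenario), i.e. a +31% level shift relative to the counterfactual-
adjusted baseline, not significant at 5% in this single draw (|t| < 1.96);
the counterfactual loading is recovered at 0.610 (truth 0.6). The large
negative dAVG/dMED illustrate why the raw pre/post differences alone cannot
be read causally: the unanchored stochastic trend drifts over five years,
exactly the confounding the structural model adjusts for.

The same pipeline runs from the shell:

```sh
airpolicy simulate --seed 1 --out data/
airpolicy prepost --data data/data.csv --treat-year 2019 --control-years 2014-2018
airpolicy run-all --simulate --seed 1 --out run/
airpolicy report --run-dir run/
```

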