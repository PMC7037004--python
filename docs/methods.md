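# Methods

## Model

The observation model for daily pollutant concentrations `Y_t` (ug/m3) is
Gaussian on the natural-log scale, `y_t = log Y_t`:

```
y_t   = mu_t + gamma_t + theta x_t + Z_t' Phi + delta1 D1_t + w_t + eps_t,
eps_t ~ N(0, sigma2_eps)
```

- **Local linear trend.** `mu_t = mu_{t-1} + beta_{t-1} + eta_t`,
  `beta_t = beta_{t-1} + zeta_t`, with `eta ~ WN(0, sigma2_level)` and
  `zeta ~ WN(0, sigma2_slope)`. The level absorbs slow drifts
  (de-carbonization, meteorological regimes); the slope allows a locally
  linear direction of travel.
- **Trigonometric seasonality.** `gamma_t = sum_{j=1..k} gamma_{j,t}` with
  each harmonic pair rotating by `2*pi*j/s` per day (`s = 365`) and sharing
  one disturbance variance `sigma2_seasonal` across both components of
  every pair. With `sigma2_seasonal = 0` the harmonic is a fixed sinusoid
  whose amplitude is learned through the diffuse initial state.
- **Counterfactual.** `x_t` is the log concentration of a control city; its
  coefficient `theta` absorbs region-wide weather and socio-economic
  variation. The expected sign is positive; the code reports the sign as a
  diagnostic but never constrains it.
- **Intervention.** `D1_t` steps from 0 to 1 at the policy date (permanent
  log-scale shift `delta1`); `w_t = lambda w_{t-1} + delta0 D2_t` converts
  a unit impulse on the policy date into a geometrically decaying
  adaptation shock. `lambda` is constrained to (0, 1) by default — an
  adaptation shock that decays — with a flag for (-1, 1). The state form
  and the deterministic regressor `delta0 * lambda^(t-t0)` are exactly
  equivalent (the transitory state carries no noise); the equivalence is a
  tested property.
- All regression terms (counterfactual, calendar dummies, wind-quadrant
  speeds, step dummy) enter the measurement equation as a deterministic
  offset and are estimated as ML parameters, so they come with standard
  errors directly.

Coefficients on the log scale read as relative concentration changes;
reports include `exp(estimate) - 1`.

## Estimation

Likelihood is evaluated by the Kalman filter (prediction-error
decomposition). Numerical choices:

- **Initialization.** Nonstationary states (level, slope, seasonal) use a
  large-variance proxy for the diffuse prior: `P0 = kappa I` with
  `kappa = 1e6`, and the first `2 + 2k` non-missing likelihood terms are
  excluded. The transitory state starts at exactly 0 with zero variance.
  The proxy (rather than an exact-diffuse sweep) keeps the filter a single
  uniform recursion and matches the convention of the reference
  implementation used for cross-checks; with `kappa = 1e6` and five years
  of data the remaining approximation is far below estimation noise.
- **Missing data** are skipped in the update step (prediction only), never
  imputed. Rows with missing regressor values are treated as missing
  observations, with a logged count.
- **Parameterization.** Variances are optimized as logs (bounded in
  [-30, 5]); `lambda` through a logistic link onto its bounds. Optimization
  is L-BFGS-B with numerical gradients; `n_starts` dispersed starting
  points (default 3) are tried and the best likelihood kept. Start values
  are data-driven: OLS (with a throwaway intercept) for coefficients, and
  the local-level moment estimator for the variance split —
  `Var(dy) = sigma2_level + 2 sigma2_eps`, `Cov(dy_t, dy_{t-1}) =
  -sigma2_eps` — clipped away from the boundary. The moment-based start
  matters: with a naive equal split the likelihood's flat ridge between
  level noise and observation noise can trap the optimizer in a collapsed
  level-variance local optimum.
- **Standard errors** come from the inverse observed information, computed
  by central differences at the optimum on the transformed scale and
  mapped to the natural scale by the delta method. Variances pinned at the
  lower bound (estimated as zero, e.g. the slope and seasonal variances in
  the default scenario) carry no curvature and are held fixed — their SEs
  are reported as unavailable rather than fabricated. t-statistics use the
  +-1.96 two-sided 5% rule; stars: * p<0.10, ** p<0.05, *** p<0.01.
- The filter kernel exploits the block structure of the transition matrix
  (level/slope shear, 2x2 rotations, scalar decay), so a likelihood
  evaluation at n = 2099 costs well under a millisecond and the
  Monte-Carlo studies below run in minutes on one CPU.

## Model selection

- **Rolling-origin cross-validation.** Parameters are estimated once on
  the training window (through 24 Feb of the pre-policy year) and held
  fixed. The filter then runs over the full pre-policy sample so each
  origin conditions on its entire past; 1–10-step forecasts are scored on
  the log scale against the test window (25 Feb–24 Feb, 365 origins).
  The last nine origins lack some h-step targets inside the window: the
  MSFE at horizon h averages only over errors whose target exists, and the
  per-horizon denominators (365, 364, …, 356) are reported. A flag scores
  against later observations instead when they exist.
- **Information criteria.** `AIC = -2l + 2p`, `AICc` with the small-sample
  correction, `BIC = -2l + p log n`, where `n` counts observations
  contributing to the likelihood. `p` counts the free ML parameters
  *plus the diffusely initialized state elements* (Harvey's convention for
  structural models). The seasonal variance is shared across harmonics, so
  without the diffuse-state count every harmonic candidate would have the
  same `p` and the criteria could not penalize the extra fixed amplitudes
  at all — nested seasonal models would be incomparable.
- **Joint rule.** The study's "inspect the MSFE curves and the criteria
  together" is operationalized as: candidates whose mean MSFE over
  h = 1..10 lies within a tolerance (default 2%) of the mean of the
  pointwise-minimal curve are eligible; the eligible candidate with lowest
  BIC wins. Ties, and the all-candidates-indistinguishable case (BIC
  spread < 2), break to the smallest harmonic count / alphabetically first
  city, and are logged.
- **Harmonic comparability.** For the harmonic step the candidate
  likelihoods are re-evaluated on the common post-burn sample of the
  largest candidate so that `l` values are comparable across k.
- **Stepwise screen.** OLS of the smoothed observation disturbances on the
  twelve calendar/weather terms, no intercept (the disturbances are
  mean-zero by construction); backward-forward moves (best single drop or
  re-add) until no move improves the criterion; exactly collinear columns
  are removed up front with a warning. The criterion is
  `n log(RSS/n) + penalty * p` with penalty 2 (AIC) or `log n` (BIC).
- **Final specification.** The full calendar block and the
  southwest/northwest wind speeds are always carried (the study's
  documented override); any further BIC-retained term is carried too and
  logged as a deviation; the counterfactual, the step dummy and the
  transitory state complete the model.

## Synthetic data

The generator draws every component from the exact model recursions, so
fitting the generating specification to its own output is a sharp test of
the estimation code. Defaults are the study's conditions (magnitudes of
the fitted Milan NOx models): `theta = 0.6`; calendar effects
holidays -0.06, weekend -0.10, Saturday-holiday +0.10, Sunday-holiday
+0.09; wind effects QSW -0.30, QNW -0.20 (per m/s); `sigma2_eps = 0.03`,
`sigma2_level = 0.004`, `sigma2_slope = sigma2_seasonal = 0` (annual cycle
a fixed one-harmonic sinusoid of amplitude ~0.3); intervention
`delta1 = 0.3`, `delta0 = -0.1`, `lambda = 0.8`. The counterfactual city
is an independent structural path with the same variance magnitudes;
correlation with the target is structural (the target loads it with
`theta`), mirroring the regression form. Seven candidate cities are
emitted; only the configured true city feeds the target.

Weather covariates exist to exercise the stepwise screen: wind-quadrant
speeds are Gamma(1.5, 0.8) marginals driven by an AR(1) Gaussian copula
with persistence 0.8 — nonnegative, right-skewed, and persistent over
days, the feature of real wind regimes that lets the stochastic level and
a wind regressor be told apart. Temperature and radiation carry annual
cycles; rainfall is zero-inflated exponential. Missingness is independent
per-day dropout with configurable probability.

What the generator does **not** emulate: heavy-tailed extreme events,
measurement-campaign gaps, autocorrelated observation noise,
cross-pollutant structure, or any anchoring of the stochastic trend. In
particular the unanchored random-walk level drifts substantially over five
years, so raw-scale quantities (e.g. the dAVG/dMED of a synthetic run) are
realization-dominated in a way real anchored series are not. Passing tests
therefore certify the statistical machinery under the model's own
assumptions, not distributional realism of ARPA data.

## Simulation-study designs

- **Recovery/calibration** (50 replicates): full 2099-day design with the
  intervention, fitting the complete model including the transitory block;
  checks mean recovery of `theta` and 95%-interval coverage for `theta`
  and `delta1`.
- **Size and power of the delta1 t-test** (200 null replicates; 100
  common-random-number replicates per grid level delta1 in
  {0, 0.1, 0.2, 0.4}): run on a 2015–2018 window with the policy 218 days
  before the end, mirroring the study's post-policy span. Under this
  study's truth `delta0 = 0`, so the fitted model omits the transitory
  block — it is then correctly specified. Including the truly-zero,
  weakly identified (delta0, lambda) pair inflates SE(delta1) from ~0.15
  to ~0.36 and would make the power difference between delta1 = 0 and 0.1
  invisible at these replicate counts; the permanent-only design makes the
  monotone power ordering detectable. Common random numbers across grid
  levels remove most between-level Monte-Carlo noise (the model is
  shift-equivariant in delta1).
- **Selection recovery** (20 replicates per step): three-year design
  (two training years, 365 test days) — the procedure is identical to the
  full-scale plan at a quarter of the cost. The two-strong-harmonics
  check uses a larger second amplitude and smaller level noise, because a
  semi-annual sinusoid of modest amplitude is nearly indistinguishable
  from random-walk level drift at ten-day horizons (the random-walk level
  absorbs signals whose per-day increment is small against its own
  innovation scale).
- **Null stepwise screen** (pure-noise response): n = 5000, so the
  per-term BIC retention probability (~P(chi2_1 > log n)) is small enough
  that the all-terms-dropped outcome is stable across 20 replicates.
- Monte-Carlo fits use a single (data-driven) start; final and single
  fits keep the 3-start default.

## Known limitations

- Approximate (large-kappa) diffuse initialization, not the exact diffuse
  filter; likelihood values are comparable across models only at the same
  kappa and burn-in convention.
- SEs for variances at the zero boundary are unavailable by design; the
  delta1/delta0 decomposition is weakly identified when the post-policy
  window is short, which the reports flag rather than hide.
- The stepwise screen inherits OLS assumptions; the smoothed disturbances
  are serially correlated by construction, so its retention decisions are
  a screening heuristic, not inference.
- One model per station: no spatial pooling or multivariate state space;
  no sub-daily data; Gaussian observation density only.
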