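"""Gaussian basic structural model (BSM) for daily log concentrations.

The observed series decomposes as

    y_t = mu_t + gamma_t + x_t' beta + w_t + eps_t,      eps_t ~ N(0, s2_eps)

with a local linear trend (level mu_t driven by its slope, both random
walks), trigonometric seasonality of period ``s`` built from k stochastic
harmonic pairs rotating at angles 2*pi*j/s, deterministic regressors
entering the measurement equation as an offset (counterfactual city series,
calendar dummies, wind-quadrant speeds, policy step dummy), and optionally a
transitory policy state w_t = lambda*w_{t-1} + delta0*impulse_t that decays
geometrically after the policy date.

Estimation is by maximum likelihood through the Kalman filter
(prediction-error decomposition); nonstationary states are initialized with
a large-variance diffuse proxy and the corresponding burn-in terms are
excluded from the likelihood. Standard errors come from the numerically
differentiated observed information at the optimum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize

from .data_model import DailySeries, RegressorSet

logger = logging.getLogger("airpolicy")

LOGVAR_LO, LOGVAR_HI = -30.0, 5.0   # bounds for log-variances in optimization
ZLAM_BOUND = 8.0                    # bound for the lambda link argument
DEFAULT_KAPPA = 1e6                 # diffuse-proxy prior variance

VARIANCE_NAMES = ("sigma2_eps", "sigma2_level", "sigma2_slope", "sigma2_seasonal")


# ---------------------------------------------------------------------------
# model specification and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeasonalSpec:
    """Trigonometric seasonality: period ``s`` (days) and harmonic count ``k``."""

    period: int = 365
    harmonics: int = 1

    def __post_init__(self) -> None:
        if self.period < 2:
            raise ValueError(f"seasonal period must be >= 2, got {self.period}")
        if not (1 <= self.harmonics <= self.period // 2):
            raise ValueError(
                f"harmonics must lie in [1, {self.period // 2}] for period "
                f"{self.period}, got {self.harmonics}"
            )


@dataclass(frozen=True)
class BsmSpec:
    """Configuration of one BSM fit.

    ``regressors`` are column names resolved against a RegressorSet; the
    policy step dummy ("policy_step") is an ordinary regressor whose
    coefficient is the permanent effect delta1. ``include_transitory`` adds
    the decaying policy state (impulse from "policy_impulse"). ``fix_lambda``
    freezes the persistence instead of estimating it.
    """

    seasonal: SeasonalSpec | None = field(default_factory=SeasonalSpec)
    regressors: tuple[str, ...] = ()
    include_transitory: bool = False
    lambda_bounds: tuple[float, float] = (0.0, 1.0)
    fix_lambda: float | None = None
    kappa: float = DEFAULT_KAPPA

    @property
    def k(self) -> int:
        return 0 if self.seasonal is None else self.seasonal.harmonics

    @property
    def n_diffuse(self) -> int:
        """Level + slope + seasonal states, all initialized diffusely."""
        return 2 + 2 * self.k

    @property
    def state_dim(self) -> int:
        return self.n_diffuse + (1 if self.include_transitory else 0)

    @property
    def n_free_params(self) -> int:
        """Free ML parameters: variances, coefficients, delta0, lambda."""
        n = 3 + (1 if self.k else 0) + len(self.regressors)
        if self.include_transitory:
            n += 1 + (0 if self.fix_lambda is not None else 1)
        return n


@dataclass
class BsmParams:
    """Parameter vector of the BSM on natural scale.

    ``coef`` maps regressor names to coefficients (the counterfactual
    coefficient theta and permanent effect delta1 live here under their
    column names); ``delta0``/``lam`` drive the transitory state.
    """

    sigma2_eps: float
    sigma2_level: float
    sigma2_slope: float = 0.0
    sigma2_seasonal: float = 0.0
    coef: dict[str, float] = field(default_factory=dict)
    delta0: float = 0.0
    lam: float = 0.0

    def __post_init__(self) -> None:
        for name in VARIANCE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.lam) >= 1 and self.delta0 != 0.0:
            raise ValueError("|lambda| must be < 1 when the transitory effect is active")


# ---------------------------------------------------------------------------
# state-space matrices
# ---------------------------------------------------------------------------

@dataclass
class SsmMatrices:
    """Assembled system matrices for one spec/params/data combination."""

    T: np.ndarray          # (m, m) transition
    RQR: np.ndarray        # (m, m) state-noise covariance
    Z: np.ndarray          # (m,) observation loading
    h: float               # observation variance
    c: np.ndarray          # (n, m) state intercept (policy impulse)
    offset: np.ndarray     # (n,) measurement offset x_t' beta
    a0: np.ndarray         # (m,) prior state mean
    P0: np.ndarray         # (m, m) prior state covariance
    burn: int              # likelihood terms excluded for the diffuse proxy
    k: int = 0             # harmonic count (transition structure)
    has_w: bool = False    # transitory state present
    lam: float = 0.0       # transitory persistence
    index: pd.DatetimeIndex | None = None

    @property
    def n(self) -> int:
        return self.offset.shape[0]

    @property
    def m(self) -> int:
        return self.a0.shape[0]


def build_state_space(
    spec: BsmSpec,
    params: BsmParams,
    regressors: RegressorSet | None = None,
    index: pd.DatetimeIndex | None = None,
    n: int | None = None,
) -> SsmMatrices:
    """Assemble transition/observation matrices for the spec and parameters.

    The regressor offset is built from ``regressors`` over ``index`` (or the
    regressor set's own index); rows where a used regressor is missing get a
    NaN offset, which the filter treats as a missing observation.
    """
    if regressors is not None:
        if index is None:
            index = regressors.dates
        n = len(index)
    if n is None:
        raise ValueError("either regressors/index or n must be given")

    k = spec.k
    m = spec.state_dim
    s = spec.seasonal.period if spec.seasonal is not None else 0

    T = np.zeros((m, m))
    T[0, 0] = T[0, 1] = T[1, 1] = 1.0  # local linear trend block
    Z = np.zeros(m)
    Z[0] = 1.0
    for j in range(1, k + 1):
        lam_j = 2.0 * math.pi * j / s
        cj, sj = math.cos(lam_j), math.sin(lam_j)
        i = 2 * j
        T[i, i] = cj
        T[i, i + 1] = sj
        T[i + 1, i] = -sj
        T[i + 1, i + 1] = cj
        Z[i] = 1.0

    diag = np.zeros(m)
    diag[0] = params.sigma2_level
    diag[1] = params.sigma2_slope
    for j in range(k):
        diag[2 + 2 * j] = params.sigma2_seasonal
        diag[3 + 2 * j] = params.sigma2_seasonal
    RQR = np.diag(diag)

    c = np.zeros((n, m))
    if spec.include_transitory:
        w = m - 1
        Z[w] = 1.0
        lam = spec.fix_lambda if spec.fix_lambda is not None else params.lam
        T[w, w] = lam
        if regressors is None or "policy_impulse" not in regressors.frame.columns:
            raise ValueError("transitory effect requires a 'policy_impulse' regressor column")
        d2 = regressors.frame["policy_impulse"].reindex(index).to_numpy()
        c[:, w] = params.delta0 * np.nan_to_num(d2)

    offset = np.zeros(n)
    if spec.regressors:
        if regressors is None:
            raise ValueError(f"spec names regressors {spec.regressors} but none were supplied")
        X = regressors.matrix(spec.regressors, index=index)
        beta = np.array([params.coef.get(name, 0.0) for name in spec.regressors])
        offset = X @ beta

    a0 = np.zeros(m)
    P0 = np.zeros((m, m))
    np.fill_diagonal(P0[: spec.n_diffuse, : spec.n_diffuse], spec.kappa)

    lam_w = 0.0
    if spec.include_transitory:
        lam_w = spec.fix_lambda if spec.fix_lambda is not None else params.lam
    return SsmMatrices(
        T=T, RQR=RQR, Z=Z, h=params.sigma2_eps, c=c, offset=offset,
        a0=a0, P0=P0, burn=spec.n_diffuse, k=k, has_w=spec.include_transitory,
        lam=lam_w, index=index,
    )


def transitory_decay_regressor(n: int, policy_index: int, lam: float) -> np.ndarray:
    """Deterministic equivalent of the transitory state: lam^(t-t0) for t >= t0.

    With coefficient delta0 this reproduces w_t exactly (the state carries no
    noise), which is the tested equivalence between the two implementations.
    """
    out = np.zeros(n)
    if 0 <= policy_index < n:
        t = np.arange(n - policy_index)
        out[policy_index:] = lam ** t
    return out


# ---------------------------------------------------------------------------
# Kalman filter / smoother kernels
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _t_vec(k, has_w, lam, cs, sn, x):  # pragma: no cover - jitted
    """x <- T x in place (LLT shear, harmonic rotations, scalar decay)."""
    x[0] = x[0] + x[1]
    for j in range(k):
        i = 2 + 2 * j
        g0 = cs[j] * x[i] + sn[j] * x[i + 1]
        g1 = -sn[j] * x[i] + cs[j] * x[i + 1]
        x[i] = g0
        x[i + 1] = g1
    if has_w:
        x[x.shape[0] - 1] = lam * x[x.shape[0] - 1]


@njit(cache=True)
def _kf_loglik(y, offset, k, has_w, lam, cs, sn, qdiag, Z, h, c, a0, P0, burn):  # pragma: no cover
    """Likelihood-only filter pass (no stored paths) for the optimizer."""
    n = y.shape[0]
    m = a0.shape[0]
    a = np.empty(m)
    P = np.empty((m, m))
    PZ = np.empty(m)
    for i in range(m):
        a[i] = a0[i] + c[0, i]
        for j in range(m):
            P[i, j] = P0[i, j]
    ll = 0.0
    nobs = 0
    n_used = 0
    for t in range(n):
        if t > 0:
            _t_vec(k, has_w, lam, cs, sn, a)
            for i in range(m):
                a[i] += c[t, i]
            for j in range(m):
                col = P[:, j]
                _t_vec(k, has_w, lam, cs, sn, col)
            for i in range(m):
                _t_vec(k, has_w, lam, cs, sn, P[i])
            for i in range(m):
                P[i, i] += qdiag[i]
            for i in range(m):
                for j in range(i + 1, m):
                    s = 0.5 * (P[i, j] + P[j, i])
                    P[i, j] = s
                    P[j, i] = s
        Ft = h
        za = 0.0
        for i in range(m):
            s = 0.0
            for j in range(m):
                s += P[i, j] * Z[j]
            PZ[i] = s
        for i in range(m):
            Ft += Z[i] * PZ[i]
            za += Z[i] * a[i]
        yt = y[t] - offset[t]
        if np.isfinite(yt) and Ft > 0.0:
            vt = yt - za
            inv = 1.0 / Ft
            for i in range(m):
                a[i] += PZ[i] * vt * inv
                for j in range(i, m):
                    s = P[i, j] - PZ[i] * PZ[j] * inv
                    P[i, j] = s
                    P[j, i] = s
            if nobs >= burn:
                ll += -0.5 * (math.log(2.0 * math.pi) + math.log(Ft) + vt * vt * inv)
                n_used += 1
            nobs += 1
    return ll, nobs, n_used


@njit(cache=True)
def _kf_core(y, offset, k, has_w, lam, cs, sn, qdiag, Z, h, c, a0, P0, burn):  # pragma: no cover
    n = y.shape[0]
    m = a0.shape[0]
    a_pred = np.zeros((n, m))
    P_pred = np.zeros((n, m, m))
    a_filt = np.zeros((n, m))
    P_filt = np.zeros((n, m, m))
    v = np.full(n, np.nan)
    F = np.full(n, np.nan)
    PZ = np.zeros(m)
    ll = 0.0
    nobs = 0
    n_used = 0
    for t in range(n):
        ap = a_pred[t]
        Pp = P_pred[t]
        if t == 0:
            for i in range(m):
                ap[i] = a0[i] + c[0, i]
                for j in range(m):
                    Pp[i, j] = P0[i, j]
        else:
            af = a_filt[t - 1]
            Pf = P_filt[t - 1]
            for i in range(m):
                ap[i] = af[i]
            _t_vec(k, has_w, lam, cs, sn, ap)
            for i in range(m):
                ap[i] += c[t, i]
            # Pp = T Pf T' + diag(qdiag): transform columns then rows
            for i in range(m):
                for j in range(m):
                    Pp[i, j] = Pf[i, j]
            for j in range(m):
                col = Pp[:, j]
                _t_vec(k, has_w, lam, cs, sn, col)
            for i in range(m):
                _t_vec(k, has_w, lam, cs, sn, Pp[i])
            for i in range(m):
                Pp[i, i] += qdiag[i]
            # enforce symmetry against round-off drift
            for i in range(m):
                for j in range(i + 1, m):
                    s = 0.5 * (Pp[i, j] + Pp[j, i])
                    Pp[i, j] = s
                    Pp[j, i] = s
        # innovation moments (Z picks level, harmonic cosines, w)
        Ft = h
        za = 0.0
        for i in range(m):
            s = 0.0
            for j in range(m):
                s += Pp[i, j] * Z[j]
            PZ[i] = s
        for i in range(m):
            Ft += Z[i] * PZ[i]
            za += Z[i] * ap[i]
        yt = y[t] - offset[t]
        af = a_filt[t]
        Pf = P_filt[t]
        if np.isfinite(yt) and Ft > 0.0:
            vt = yt - za
            v[t] = vt
            F[t] = Ft
            inv = 1.0 / Ft
            for i in range(m):
                af[i] = ap[i] + PZ[i] * vt * inv
                for j in range(i, m):
                    s = Pp[i, j] - PZ[i] * PZ[j] * inv
                    Pf[i, j] = s
                    Pf[j, i] = s
            if nobs >= burn:
                ll += -0.5 * (math.log(2.0 * math.pi) + math.log(Ft) + vt * vt * inv)
                n_used += 1
            nobs += 1
        else:
            for i in range(m):
                af[i] = ap[i]
                for j in range(m):
                    Pf[i, j] = Pp[i, j]
    return ll, nobs, n_used, a_pred, P_pred, a_filt, P_filt, v, F


@njit(cache=True)
def _smoother_core(T, Z, a_pred, P_pred, v, F):  # pragma: no cover - jitted
    n, m = a_pred.shape
    alpha = np.zeros((n, m))
    V = np.zeros((n, m, m))
    r = np.zeros(m)
    N = np.zeros((m, m))
    for t in range(n - 1, -1, -1):
        if np.isfinite(v[t]):
            Finv = 1.0 / F[t]
            K = T @ (P_pred[t] @ Z) * Finv
            L = T - np.outer(K, Z)
            r_new = Z * (Finv * v[t]) + L.T @ r
            N_new = np.outer(Z, Z) * Finv + L.T @ N @ L
        else:
            r_new = T.T @ r
            N_new = T.T @ N @ T
        alpha[t] = a_pred[t] + P_pred[t] @ r_new
        Vt = P_pred[t] - P_pred[t] @ N_new @ P_pred[t]
        V[t] = 0.5 * (Vt + Vt.T)
        r = r_new
        N = N_new
    return alpha, V


def _kernel_args(matrices: "SsmMatrices"):
    k = matrices.k
    s_angles = np.array(
        [math.atan2(matrices.T[2 + 2 * j, 2 + 2 * j + 1], matrices.T[2 + 2 * j, 2 + 2 * j])
         for j in range(k)]
    ) if k else np.zeros(0)
    cs = np.cos(s_angles)
    sn = np.sin(s_angles)
    qdiag = np.ascontiguousarray(np.diag(matrices.RQR))
    return (k, matrices.has_w, float(matrices.lam), cs, sn, qdiag)


@dataclass
class FilterOutput:
    """Per-time filter (and optionally smoother) quantities."""

    loglik: float
    nobs: int              # non-missing observations
    nobs_used: int         # observations contributing to the likelihood
    a_pred: np.ndarray     # (n, m) one-step-ahead state means
    P_pred: np.ndarray
    a_filt: np.ndarray     # (n, m) filtered state means
    P_filt: np.ndarray
    innovations: np.ndarray    # v_t, NaN where missing
    innovation_var: np.ndarray
    alpha_smooth: np.ndarray | None = None
    V_smooth: np.ndarray | None = None
    eps_smooth: np.ndarray | None = None


def kalman_filter(matrices: SsmMatrices, observations) -> FilterOutput:
    """Run the filter over ``observations`` (array or Series on the index).

    Missing observations are skipped in the update (prediction only); the
    Gaussian log-likelihood excludes the first ``burn`` non-missing terms.
    Raises if every observation is missing.
    """
    y = _as_array(matrices, observations)
    if not np.isfinite(y).any():
        raise ValueError("all observations are missing")
    k, has_w, lam, cs, sn, qdiag = _kernel_args(matrices)
    ll, nobs, n_used, ap, Pp, af, Pf, v, F = _kf_core(
        y, matrices.offset, k, has_w, lam, cs, sn, qdiag, matrices.Z,
        float(matrices.h), matrices.c, matrices.a0, matrices.P0, matrices.burn,
    )
    return FilterOutput(
        loglik=float(ll), nobs=int(nobs), nobs_used=int(n_used),
        a_pred=ap, P_pred=Pp, a_filt=af, P_filt=Pf,
        innovations=v, innovation_var=F,
    )


def kalman_smoother(matrices: SsmMatrices, observations, filt: FilterOutput | None = None) -> FilterOutput:
    """Fixed-interval smoothing; fills smoothed states and disturbances.

    The smoothed observation disturbance is eps_t = y_t - offset_t - Z a_t|n,
    missing where the observation is missing.
    """
    y = _as_array(matrices, observations)
    if filt is None:
        filt = kalman_filter(matrices, y)
    alpha, V = _smoother_core(
        matrices.T, matrices.Z, filt.a_pred, filt.P_pred,
        filt.innovations, filt.innovation_var,
    )
    eps = y - matrices.offset - alpha @ matrices.Z
    filt.alpha_smooth = alpha
    filt.V_smooth = V
    filt.eps_smooth = eps
    return filt


def forecast(matrices: SsmMatrices, filt: FilterOutput, origin_t: int, h_max: int) -> np.ndarray:
    """Mean forecasts y_hat_{t+h}, h = 1..h_max, from the filtered state at origin.

    Future regressor values must be present in the matrices (they were built
    over the full index); an origin whose horizon runs past the sample is
    rejected.
    """
    n = matrices.n
    if not (0 <= origin_t < n):
        raise ValueError(f"origin {origin_t} outside sample of length {n}")
    if origin_t + h_max >= n:
        raise ValueError(
            f"future regressor rows unavailable beyond index {n - 1} "
            f"(origin {origin_t}, horizon {h_max})"
        )
    a = filt.a_filt[origin_t].copy()
    out = np.empty(h_max)
    for h in range(1, h_max + 1):
        a = matrices.T @ a + matrices.c[origin_t + h]
        out[h - 1] = matrices.Z @ a + matrices.offset[origin_t + h]
    return out


def _as_array(matrices: SsmMatrices, observations) -> np.ndarray:
    if isinstance(observations, DailySeries):
        observations = observations.values
    if isinstance(observations, pd.Series):
        if matrices.index is not None:
            observations = observations.reindex(matrices.index)
        observations = observations.to_numpy()
    y = np.asarray(observations, dtype=float)
    if y.shape[0] != matrices.n:
        raise ValueError(f"observation length {y.shape[0]} != model length {matrices.n}")
    return y


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """ML estimates with standard errors and fit diagnostics."""

    spec: BsmSpec
    params: BsmParams
    se: dict[str, float]
    tstats: dict[str, float]
    loglik: float
    nobs: int            # observations contributing to the likelihood
    n_free: int          # free ML parameters
    n_diffuse: int       # diffusely initialized state elements
    converged: bool
    message: str
    x: np.ndarray        # internal (transformed) parameter vector
    cov: np.ndarray | None = None
    n_starts: int = 1

    @property
    def k_params(self) -> int:
        """Effective parameter count for information criteria (free ML
        parameters plus diffuse state elements, Harvey's convention)."""
        return self.n_free + self.n_diffuse

    def significance(self, name: str) -> str:
        return significance_stars(self.tstats.get(name, np.nan))


def significance_stars(t: float) -> str:
    """Two-sided normal stars: * p<0.10, ** p<0.05, *** p<0.01."""
    if not np.isfinite(t):
        return ""
    a = abs(t)
    if a > 2.5758:
        return "***"
    if a > 1.96:
        return "**"
    if a > 1.6449:
        return "*"
    return ""


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


class _Packer:
    """Bijection between BsmParams and the internal optimization vector.

    Order: log-variances (eps, level, slope[, seasonal]), regression
    coefficients in spec order, then delta0 and the lambda link argument when
    the transitory effect is estimated.
    """

    def __init__(self, spec: BsmSpec):
        self.spec = spec
        names = ["sigma2_eps", "sigma2_level", "sigma2_slope"]
        if spec.k:
            names.append("sigma2_seasonal")
        self.n_var = len(names)
        names.extend(spec.regressors)
        if spec.include_transitory:
            names.append("delta0")
            if spec.fix_lambda is None:
                names.append("lambda")
        self.names = names
        self.size = len(names)

    def bounds(self):
        b: list[tuple[float | None, float | None]] = [(LOGVAR_LO, LOGVAR_HI)] * self.n_var
        b += [(None, None)] * len(self.spec.regressors)
        if self.spec.include_transitory:
            b.append((None, None))
            if self.spec.fix_lambda is None:
                b.append((-ZLAM_BOUND, ZLAM_BOUND))
        return b

    def pack(self, p: BsmParams) -> np.ndarray:
        x = [math.log(max(p.sigma2_eps, 1e-12)),
             math.log(max(p.sigma2_level, 1e-12)),
             math.log(max(p.sigma2_slope, 1e-12))]
        if self.spec.k:
            x.append(math.log(max(p.sigma2_seasonal, 1e-12)))
        x.extend(p.coef.get(name, 0.0) for name in self.spec.regressors)
        if self.spec.include_transitory:
            x.append(p.delta0)
            if self.spec.fix_lambda is None:
                lo, hi = self.spec.lambda_bounds
                frac = min(max((p.lam - lo) / (hi - lo), 1e-6), 1 - 1e-6)
                x.append(math.log(frac / (1 - frac)))
        return np.array(x)

    def unpack(self, x: np.ndarray) -> BsmParams:
        spec = self.spec
        i = 0
        s2_eps = math.exp(x[0]); s2_lvl = math.exp(x[1]); s2_slp = math.exp(x[2])
        i = 3
        s2_sea = 0.0
        if spec.k:
            s2_sea = math.exp(x[3]); i = 4
        coef = {name: float(x[i + j]) for j, name in enumerate(spec.regressors)}
        i += len(spec.regressors)
        delta0, lam = 0.0, 0.0
        if spec.include_transitory:
            delta0 = float(x[i]); i += 1
            if spec.fix_lambda is None:
                lo, hi = spec.lambda_bounds
                lam = lo + (hi - lo) * _sigmoid(float(x[i])); i += 1
            else:
                lam = spec.fix_lambda
        return BsmParams(
            sigma2_eps=s2_eps, sigma2_level=s2_lvl, sigma2_slope=s2_slp,
            sigma2_seasonal=s2_sea, coef=coef, delta0=delta0, lam=lam,
        )

    def natural_scale_jacobian(self, x: np.ndarray, p: BsmParams) -> np.ndarray:
        """d(natural)/d(internal) for the delta-method on standard errors."""
        jac = np.ones(self.size)
        jac[0] = p.sigma2_eps
        jac[1] = p.sigma2_level
        jac[2] = p.sigma2_slope
        if self.spec.k:
            jac[3] = p.sigma2_seasonal
        if self.spec.include_transitory and self.spec.fix_lambda is None:
            lo, hi = self.spec.lambda_bounds
            s = _sigmoid(float(x[-1]))
            jac[-1] = (hi - lo) * s * (1 - s)
        return jac


def _default_start(spec: BsmSpec, y: np.ndarray, X: np.ndarray | None) -> BsmParams:
    """Truth-agnostic start: OLS for coefficients, difference-variance split."""
    mask = np.isfinite(y)
    coef: dict[str, float] = {}
    resid = y.copy()
    if X is not None and X.shape[1]:
        rows = mask & np.all(np.isfinite(X), axis=1)
        design = np.column_stack([np.ones(rows.sum()), X[rows]])
        b, *_ = np.linalg.lstsq(design, y[rows], rcond=None)
        coef = {name: float(b[1 + j]) for j, name in enumerate(spec.regressors)}
        resid = y - X @ b[1:]
    r = resid[np.isfinite(resid)]
    dr = np.diff(r)
    var_dr = float(np.var(dr)) if dr.size > 1 else 1.0
    var_dr = max(var_dr, 1e-8)
    # local-level moment estimator: Var(dy) = s2_level + 2*s2_eps and
    # Cov(dy_t, dy_{t-1}) = -s2_eps, clipped away from the boundary
    acov1 = float(np.mean(dr[1:] * dr[:-1]) - np.mean(dr) ** 2) if dr.size > 2 else 0.0
    s2_eps0 = min(max(-acov1, 0.05 * var_dr), 0.49 * var_dr)
    s2_lvl0 = max(var_dr - 2.0 * s2_eps0, 0.02 * var_dr)
    return BsmParams(
        sigma2_eps=s2_eps0,
        sigma2_level=s2_lvl0,
        sigma2_slope=1e-4 * var_dr,
        sigma2_seasonal=(1e-4 * var_dr if spec.k else 0.0),
        coef=coef,
        delta0=(-0.05 if spec.include_transitory else 0.0),
        lam=(spec.fix_lambda if spec.fix_lambda is not None
             else 0.5 * sum(spec.lambda_bounds)),
    )


def _central_hessian(fun, x: np.ndarray, active: np.ndarray, step: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian over the active coordinates."""
    idx = np.flatnonzero(active)
    q = idx.size
    H = np.zeros((q, q))
    hs = step * (1.0 + np.abs(x[idx]))
    f0 = fun(x)
    for a in range(q):
        i = idx[a]
        ei = np.zeros_like(x); ei[i] = hs[a]
        fpp = fun(x + ei); fmm = fun(x - ei)
        H[a, a] = (fpp - 2.0 * f0 + fmm) / hs[a] ** 2
        for b in range(a + 1, q):
            j = idx[b]
            ej = np.zeros_like(x); ej[j] = hs[b]
            f1 = fun(x + ei + ej); f2 = fun(x + ei - ej)
            f3 = fun(x - ei + ej); f4 = fun(x - ei - ej)
            H[a, b] = H[b, a] = (f1 - f2 - f3 + f4) / (4.0 * hs[a] * hs[b])
    return H


def fit_ml(
    spec: BsmSpec,
    regressors: RegressorSet | None,
    observations,
    start_params: BsmParams | None = None,
    n_starts: int = 3,
    seed: int = 0,
    maxiter: int = 300,
    compute_se: bool = True,
) -> FitResult:
    """Maximum-likelihood fit of the BSM.

    Variances are optimized on the log scale and lambda through a logistic
    link onto its bounds (L-BFGS-B). ``n_starts`` dispersed starting points
    are tried and the best likelihood kept. Standard errors come from the
    inverse observed information (central differences) with boundary-pinned
    variances held fixed; they are reported on the natural scale by the
    delta method.
    """
    index = regressors.dates if regressors is not None else None
    if isinstance(observations, DailySeries):
        if observations.station_id and not observations.log_scale:
            logger.warning("fitting a series not marked log-scale")
        observations = observations.values
    if isinstance(observations, pd.Series):
        if index is not None:
            observations = observations.reindex(index)
        else:
            index = pd.DatetimeIndex(observations.index)
        observations = observations.to_numpy()
    y = np.asarray(observations, dtype=float)
    n = y.size
    X = regressors.matrix(spec.regressors, index=index) if spec.regressors else None
    if X is not None:
        bad_rows = ~np.all(np.isfinite(X), axis=1)
        if bad_rows.any():
            logger.info("fit_ml: %d rows with missing regressors treated as missing", int(bad_rows.sum()))
            y = y.copy()
            y[bad_rows] = np.nan
            X = np.nan_to_num(X)
    n_eff_check = int(np.isfinite(y).sum()) - spec.n_diffuse
    if n_eff_check < 2:
        raise ValueError("need at least 2 non-missing observations after the diffuse period")

    packer = _Packer(spec)

    # precompute everything that does not depend on the parameter vector
    spec_bare = replace(spec, regressors=())
    template = build_state_space(
        spec_bare, BsmParams(1.0, 1.0, 1.0, 1.0, coef={}, delta0=0.0, lam=0.0),
        regressors if spec.include_transitory else None, index=index, n=n,
    )
    k_, hw_, _, cs_, sn_, _ = _kernel_args(template)
    Z_, a0_, P0_, burn_ = template.Z, template.a0, template.P0, template.burn
    m = template.m
    d2 = None
    if spec.include_transitory:
        d2 = regressors.frame["policy_impulse"].reindex(index).to_numpy()
        d2 = np.nan_to_num(np.asarray(d2, dtype=float))
    cbuf = np.zeros((n, m))
    nv = packer.n_var
    npreg = len(spec.regressors)

    def negloglik(x: np.ndarray) -> float:
        h = math.exp(x[0])
        qdiag = np.zeros(m)
        qdiag[0] = math.exp(x[1])
        qdiag[1] = math.exp(x[2])
        if spec.k:
            s2_sea = math.exp(x[3])
            for j in range(spec.k):
                qdiag[2 + 2 * j] = s2_sea
                qdiag[3 + 2 * j] = s2_sea
        offset = X @ x[nv:nv + npreg] if X is not None else np.zeros(n)
        lam_w = 0.0
        if spec.include_transitory:
            delta0 = x[nv + npreg]
            if spec.fix_lambda is not None:
                lam_w = spec.fix_lambda
            else:
                lo, hi = spec.lambda_bounds
                lam_w = lo + (hi - lo) * _sigmoid(float(x[-1]))
            cbuf[:, m - 1] = delta0 * d2
        ll, _, _ = _kf_loglik(
            y, offset, k_, hw_, lam_w, cs_, sn_, qdiag, Z_, h,
            cbuf, a0_, P0_, burn_,
        )
        if not np.isfinite(ll):
            return 1e12
        return -ll

    base = start_params if start_params is not None else _default_start(spec, y, X)
    x0 = packer.pack(base)
    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        pert = x0.copy()
        pert[: packer.n_var] += rng.normal(0.0, 1.0, packer.n_var)
        pert[packer.n_var:] += rng.normal(0.0, 0.2, packer.size - packer.n_var)
        starts.append(pert)

    best = None
    for x_start in starts:
        res = optimize.minimize(
            negloglik, x_start, method="L-BFGS-B", bounds=packer.bounds(),
            options={"maxiter": maxiter, "maxfun": 10 * maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    x_hat = np.asarray(best.x)
    params = packer.unpack(x_hat)

    # effective sample size at the optimum
    mats = build_state_space(spec, params, regressors, index=index, n=n)
    k_, hw_, lam_, cs_, sn_, qd_ = _kernel_args(mats)
    ll, nobs, n_used = _kf_loglik(
        y, mats.offset, k_, hw_, lam_, cs_, sn_, qd_, mats.Z, float(mats.h),
        mats.c, mats.a0, mats.P0, mats.burn,
    )

    se: dict[str, float] = {name: np.nan for name in packer.names}
    cov_full = None
    if compute_se:
        # variances pinned at the lower bound (estimated as zero) and a
        # saturated lambda link carry no curvature: hold them fixed
        active = np.ones(packer.size, dtype=bool)
        active[: packer.n_var] = x_hat[: packer.n_var] > LOGVAR_LO + 12.0
        if spec.include_transitory and spec.fix_lambda is None:
            active[-1] = abs(x_hat[-1]) < ZLAM_BOUND - 0.5
        H = _central_hessian(negloglik, x_hat, active)
        try:
            cov_act = np.linalg.inv(H)
            bad = np.diag(cov_act) <= 0
            jac = packer.natural_scale_jacobian(x_hat, params)
            cov_full = np.full((packer.size, packer.size), np.nan)
            act_idx = np.flatnonzero(active)
            for a, i in enumerate(act_idx):
                for b, j in enumerate(act_idx):
                    cov_full[i, j] = cov_act[a, b] * jac[i] * jac[j]
            for a, i in enumerate(act_idx):
                se[packer.names[i]] = (
                    float(math.sqrt(cov_act[a, a]) * jac[i]) if not bad[a] else np.nan
                )
        except np.linalg.LinAlgError:
            logger.warning("singular observed information: standard errors unavailable")

    est = {name: _natural_value(packer, params, name) for name in packer.names}
    tstats = {
        name: (est[name] / se[name] if np.isfinite(se.get(name, np.nan)) and se[name] > 0 else np.nan)
        for name in packer.names
    }
    return FitResult(
        spec=spec, params=params, se=se, tstats=tstats,
        loglik=float(ll), nobs=int(n_used), n_free=packer.size,
        n_diffuse=spec.n_diffuse, converged=bool(best.success),
        message=str(best.message), x=x_hat, cov=cov_full, n_starts=len(starts),
    )


def _natural_value(packer: _Packer, p: BsmParams, name: str):
    if name in VARIANCE_NAMES:
        return getattr(p, name)
    if name == "delta0":
        return p.delta0
    if name == "lambda":
        return p.lam
    return p.coef[name]


def fit_summary(fit: FitResult) -> pd.DataFrame:
    """Coefficient table: estimate, SE, t, stars, plus variances and loglik."""
    rows = []
    packer = _Packer(fit.spec)
    for name in packer.names:
        est = _natural_value(packer, fit.params, name)
        rows.append(
            {
                "term": name,
                "estimate": est,
                "se": fit.se.get(name, np.nan),
                "t": fit.tstats.get(name, np.nan),
                "stars": significance_stars(fit.tstats.get(name, np.nan)),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["loglik"] = fit.loglik
    df.attrs["nobs"] = fit.nobs
    return df


def loglik_at(spec: BsmSpec, regressors, observations, params: BsmParams) -> float:
    """Likelihood evaluation at fixed parameters (no optimization)."""
    index = regressors.dates if regressors is not None else None
    if isinstance(observations, DailySeries):
        observations = observations.values
    if isinstance(observations, pd.Series) and index is not None:
        observations = observations.reindex(index)
    y = np.asarray(observations, dtype=float)
    mats = build_state_space(spec, params, regressors, index=index, n=y.size)
    return kalman_filter(mats, y).loglik
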