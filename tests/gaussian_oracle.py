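"""Brute-force joint-Gaussian oracle for small state-space instances.

Builds the exact joint distribution of the observation vector by unrolling
the state recursions (no filtering), so that filter likelihoods and
smoothed state means can be checked against direct Gaussian conditioning.
Only feasible for small n; deliberately independent of the Kalman code
paths it validates.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal


def _state_moments(mats):
    """Means of alpha_t and the cross-covariance builder Cov(alpha_t, alpha_s)."""
    n, m = mats.n, mats.m
    T, RQR, P0 = mats.T, mats.RQR, mats.P0
    powers = [np.eye(m)]
    for _ in range(n):
        powers.append(T @ powers[-1])
    means = np.zeros((n, m))
    cur = mats.a0 + mats.c[0]
    means[0] = cur
    for t in range(1, n):
        cur = T @ cur + mats.c[t]
        means[t] = cur

    def crosscov(t, s):
        out = powers[t] @ P0 @ powers[s].T
        for u in range(1, min(t, s) + 1):
            out += powers[t - u] @ RQR @ powers[s - u].T
        return out

    return means, crosscov


def observation_moments(mats):
    """Mean vector and covariance matrix of (y_1..y_n)."""
    n = mats.n
    Z = mats.Z
    means, crosscov = _state_moments(mats)
    ymean = means @ Z + mats.offset
    ycov = np.empty((n, n))
    for t in range(n):
        for s in range(t, n):
            val = Z @ crosscov(t, s) @ Z
            ycov[t, s] = val
            ycov[s, t] = val
    ycov[np.diag_indices(n)] += mats.h
    return ymean, ycov


def oracle_loglik(mats, y):
    """Log-density of the observed (non-missing) subvector."""
    ymean, ycov = observation_moments(mats)
    obs = np.isfinite(np.asarray(y, dtype=float))
    return float(
        multivariate_normal(ymean[obs], ycov[np.ix_(obs, obs)], allow_singular=True)
        .logpdf(np.asarray(y)[obs])
    )


def oracle_smoothed_means(mats, y):
    """E[alpha_t | observed y] for every t, by Gaussian conditioning."""
    y = np.asarray(y, dtype=float)
    n, m = mats.n, mats.m
    Z = mats.Z
    means, crosscov = _state_moments(mats)
    ymean, ycov = observation_moments(mats)
    obs = np.flatnonzero(np.isfinite(y))
    resid = y[obs] - ymean[obs]
    solve = np.linalg.solve(ycov[np.ix_(obs, obs)], resid)
    out = np.empty((n, m))
    for t in range(n):
        cov_ty = np.column_stack([crosscov(t, s) @ Z for s in obs])
        out[t] = means[t] + cov_ty @ solve
    return out
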