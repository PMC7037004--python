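import numpy as np
import pandas as pd
import pytest

from airpolicy import BsmParams, BsmSpec, SeasonalSpec, build_state_space
from airpolicy.synthetic_data import SimScenario, simulate_study


@pytest.fixture(scope="session")
def small_scenario() -> SimScenario:
    """Three calendar years, policy-free: cheap enough for repeated fits."""
    return SimScenario(start="2015-01-01", end="2017-12-31", policy_date=None)


@pytest.fixture(scope="session")
def small_study(small_scenario):
    return simulate_study(small_scenario, seed=11)


@pytest.fixture(scope="session")
def policy_scenario() -> SimScenario:
    """Shorter sample with an intervention 218 days before the end."""
    return SimScenario(start="2015-01-01", end="2018-09-30", policy_date="2018-02-25")


def random_small_instance(rng: np.random.Generator, with_missing: bool = True):
    """A random small model + data draw for oracle comparisons.

    Uses a proper (finite, random) initial state distribution so the filter
    likelihood equals the joint Gaussian density exactly (burn = 0).
    """
    n = int(rng.integers(8, 31))
    k = int(rng.integers(0, 3))
    period = int(rng.integers(2 * max(k, 1) + 1, 30))
    spec = BsmSpec(seasonal=SeasonalSpec(period, k) if k else None)
    params = BsmParams(
        sigma2_eps=float(rng.uniform(0.05, 2.0)),
        sigma2_level=float(rng.uniform(0.0, 1.0)),
        sigma2_slope=float(rng.uniform(0.0, 0.2)),
        sigma2_seasonal=float(rng.uniform(0.0, 0.5)) if k else 0.0,
    )
    mats = build_state_space(spec, params, None, n=n)
    m = mats.m
    mats.a0 = rng.normal(0.0, 1.0, m)
    A = rng.normal(0.0, 0.6, (m, m))
    mats.P0 = A @ A.T + 0.1 * np.eye(m)
    mats.burn = 0
    mats.offset = rng.normal(0.0, 0.5, n)

    ymean_state = mats.a0.copy()
    y = np.empty(n)
    alpha = rng.multivariate_normal(mats.a0, mats.P0)
    for t in range(n):
        if t > 0:
            noise = rng.multivariate_normal(np.zeros(m), mats.RQR + 1e-12 * np.eye(m))
            alpha = mats.T @ alpha + noise
        y[t] = mats.Z @ alpha + mats.offset[t] + rng.normal(0.0, np.sqrt(mats.h))
    if with_missing and n > 4:
        drop = rng.choice(n, size=int(rng.integers(1, n // 3)), replace=False)
        y[drop] = np.nan
    return mats, y
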