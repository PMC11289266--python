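"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately separate from the package implementation:
closed-form / bisection solutions of the gamma-variate kinetics and a
from-scratch paired t-test, used to cross-check the pipeline's estimates.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from icgperf.synthgen import ConditionSpec, ScenarioConfig


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def gamma_variate_value(x: float, alpha: float) -> float:
    """Normalized gamma-variate x^a * exp(a*(1-x)); peak 1 at x=1."""
    if x <= 0:
        return 0.0
    return x**alpha * math.exp(alpha * (1.0 - x))


def half_rise_time(tau: float, alpha: float, tol: float = 1e-9) -> float:
    """Time from onset to 50% of peak, by bisection on (0, tau)."""
    lo, hi = 0.0, 1.0
    while hi - lo > tol / tau:
        mid = 0.5 * (lo + hi)
        if gamma_variate_value(mid, alpha) < 0.5:
            lo = mid
        else:
            hi = mid
    return tau * 0.5 * (lo + hi)


def paired_t_oracle(x, y):
    """From-scratch paired t-test (formula evaluation, no scipy.stats.ttest)."""
    from scipy.special import betainc

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    d = x - y
    n = len(d)
    md = d.sum() / n
    var = ((d - md) ** 2).sum() / (n - 1)
    t = md / math.sqrt(var / n)
    df = n - 1
    # two-sided p from the incomplete beta form of the t CDF
    p = betainc(df / 2.0, 0.5, df / (df + t * t))
    return t, float(p)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def still_scene() -> ScenarioConfig:
    """Noiseless, motionless single-bolus scene with known kinetics."""
    return ScenarioConfig(
        conditions=[
            ConditionSpec(label="baseline", slope_mean=12.5, slope_sd=0.0)
        ],
        condition_duration=60.0,
        bolus_period=60.0,
        subject_cv=0.0,
        subject_factor=1.0,
        tau_range=(8.0, 8.0),
        onset_range=(2.0, 2.0),
        alpha=2.0,
        accumulation_c_inf=0.0,
        motion_amplitude_px=0.0,
        drift_rate_px_s=0.0,
        noise_sd=0.0,
        image_size=(64, 64),
        seed=0,
    )


@pytest.fixture
def moving_scene(still_scene) -> ScenarioConfig:
    """Noiseless scene with programmed sinusoidal motion (amplitude 3 px)."""
    return still_scene.model_copy(
        update={"motion_amplitude_px": 3.0, "motion_period_s": 4.0}
    )
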