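"""Weibull survival curves, per-cycle transition probabilities and fitting.

The model extrapolates Kaplan-Meier curves with the two-parameter Weibull
survival function

    S(t) = P(T >= t) = exp(-lambda * t**gamma)

whose shape gamma lets the hazard rise (gamma > 1) or fall with time.  The
probability of leaving a state during cycle t (given occupancy at t-1) is

    P_t = 1 - S(t)/S(t-1) = 1 - exp(lambda*(t-1)**gamma - lambda*t**gamma)

so the product of per-cycle survivals telescopes back to S(t) exactly.

A proportional-hazards effect (hazard ratio h) multiplies the scale:
S_h(t) = S(t)**h.  Fitting uses ordinary least squares on the
complementary-log-log linearisation ln(-ln S) = ln(lambda) + gamma*ln(t),
which is why adjusted R-squared and the correlation coefficient are the
reported fit diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, log

import numpy as np
from scipy import stats

from .parameters import DAYS_PER_MONTH, WeibullParams


@dataclass(frozen=True)
class KmCurve:
    """A Kaplan-Meier step curve: survival fractions at nondecreasing times.

    Time is in model units (cycles unless stated otherwise).  Duplicate times
    are deduplicated keeping the last (lowest) survival value.
    """

    times: np.ndarray
    survival: np.ndarray

    def __init__(self, times, survival):
        t = np.asarray(times, dtype=float)
        s = np.asarray(survival, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("times and survival must be 1-d arrays of equal length")
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("times must be nondecreasing")
        if np.any(t < 0):
            raise ValueError("times must be nonnegative")
        if np.any(s > 1.0) or np.any(s < 0.0):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be nonincreasing")
        # deduplicate ties keeping the last value
        if t.size:
            keep = np.r_[t[1:] != t[:-1], True]
            t, s = t[keep], s[keep]
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)


@dataclass(frozen=True)
class FitResult:
    """Recovered Weibull parameters plus linear-fit diagnostics."""

    params: WeibullParams
    adj_r2: float
    correlation: float


def survival_at(params: WeibullParams, t) -> float | np.ndarray:
    """S(t) = exp(-scale * t**shape); vectorised over t."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    out = np.exp(-params.scale * t_arr ** params.shape)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def cycle_transition_prob(params: WeibullParams, t: int) -> float:
    """Probability of the event during cycle t, conditional on survival to t-1."""
    if t < 1:
        raise ValueError("cycle index must be >= 1")
    lam, gam = params.scale, params.shape
    return 1.0 - exp(lam * (t - 1) ** gam - lam * t ** gam)


def apply_hazard_ratio(params: WeibullParams, hr: float) -> WeibullParams:
    """Scale the hazard by ``hr`` (Weibull PH: scale -> scale*hr, shape kept)."""
    if not hr > 0:
        raise ValueError("hazard ratio must be positive")
    return WeibullParams(params.scale * hr, params.shape, time_unit=params.time_unit)


def median_survival(params: WeibullParams) -> float:
    """Closed-form median (ln 2 / scale)**(1/shape), in the curve's time unit."""
    return (log(2.0) / params.scale) ** (1.0 / params.shape)


def rescale_to_median(params: WeibullParams, median: float) -> WeibullParams:
    """Recalibrate the scale so the curve's median equals ``median``.

    Keeps the shape.  Used to pin a digitised curve to a quoted median when
    the time unit of published parameters is ambiguous.
    """
    if not median > 0:
        raise ValueError("median must be positive")
    return WeibullParams(log(2.0) / median ** params.shape, params.shape,
                         time_unit=params.time_unit)


def to_cycle_units(params: WeibullParams, cycle_days: float) -> WeibullParams:
    """Express a curve on the model's cycle clock.

    For a per-month curve, t_months = t_cycles * (cycle_days / days-per-month),
    so the scale becomes scale * ratio**shape.  Per-cycle curves pass through.
    """
    if params.time_unit == "cycle":
        return params
    ratio = cycle_days / DAYS_PER_MONTH
    return WeibullParams(params.scale * ratio ** params.shape, params.shape,
                         adj_r2=params.adj_r2, time_unit="cycle")


def fit_weibull(curve: KmCurve, min_points: int = 3) -> FitResult:
    """Least-squares Weibull fit on the complementary-log-log linearisation.

    Points with t == 0 or S outside (0, 1) carry no information on the
    transformed scale and are dropped.  Requires at least ``min_points``
    usable points and non-degenerate survival values.
    """
    t = curve.times
    s = curve.survival
    usable = (t > 0) & (s > 0.0) & (s < 1.0)
    t, s = t[usable], s[usable]
    if t.size < min_points:
        raise ValueError(
            f"need at least {min_points} points with t > 0 and 0 < S < 1, got {t.size}"
        )
    if np.allclose(s, s[0]):
        raise ValueError("degenerate curve: all survival values equal")
    x = np.log(t)
    y = np.log(-np.log(s))
    res = stats.linregress(x, y)
    gamma = float(res.slope)
    lam = float(np.exp(res.intercept))
    n = t.size
    r2 = float(res.rvalue) ** 2
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return FitResult(
        params=WeibullParams(lam, gamma, adj_r2=min(max(adj_r2, 0.0), 1.0)),
        adj_r2=adj_r2,
        correlation=float(res.rvalue),
    )
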