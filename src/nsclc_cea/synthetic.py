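"""Pseudo individual-patient survival data with known Weibull structure.

The curve-fitting stage normally consumes survival fractions digitised from
published Kaplan-Meier figures.  This module generates the equivalent input
with known ground truth — Weibull event times by inverse-transform sampling,
administratively censored at a trial-duration cutoff, summarised by the
product-limit estimator — so parameter recovery through
``km_estimate -> fit_weibull`` is testable end to end without external data.

Administrative censoring only: no random censoring distribution, matching
the truncation of a trial follow-up window.  Real digitised curves also
carry digitisation error and non-administrative censoring that this
generator deliberately omits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .parameters import WeibullParams
from .survival import KmCurve


@dataclass(frozen=True)
class SyntheticCohort:
    """Event/censoring times for one simulated cohort plus its ground truth."""

    event_times: np.ndarray
    event_flags: np.ndarray
    truth: WeibullParams
    censor_time: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.event_times,
                             "event": self.event_flags.astype(int)})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate_cohort(truth: WeibullParams, n: int, censor_time: float = np.inf,
                    seed: int = 0) -> SyntheticCohort:
    """Draw n Weibull event times T = (−ln U / λ)^(1/γ), censored at censor_time."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not censor_time > 0:
        raise ValueError("censor_time must be positive")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    t = (-np.log(u) / truth.scale) ** (1.0 / truth.shape)
    events = t <= censor_time
    times = np.minimum(t, censor_time)
    return SyntheticCohort(event_times=times, event_flags=events,
                           truth=truth, censor_time=float(censor_time), seed=seed)


def km_estimate(cohort: SyntheticCohort) -> KmCurve:
    """Product-limit curve over the distinct event times, starting at (0, 1)."""
    if not cohort.event_flags.any():
        raise ValueError("cohort has no events; product-limit curve undefined")
    kmf = KaplanMeierFitter()
    kmf.fit(cohort.event_times, event_observed=cohort.event_flags)
    event_times = np.unique(cohort.event_times[cohort.event_flags])
    times = np.concatenate([[0.0], event_times])
    # right-continuous step values at the event times
    surv = np.concatenate(
        [[1.0], kmf.survival_function_at_times(event_times).to_numpy(dtype=float)]
    )
    return KmCurve(times, surv)


def km_to_csv(curve: KmCurve, path) -> None:
    pd.DataFrame({"time": curve.times, "survival": curve.survival}).to_csv(path, index=False)


def km_from_csv(path) -> KmCurve:
    """Read a (time, survival) CSV in the dialect the fitting stage consumes."""
    df = pd.read_csv(path)
    if not {"time", "survival"} <= set(df.columns):
        raise ValueError("KM CSV must have 'time' and 'survival' columns")
    return KmCurve(df["time"].to_numpy(), df["survival"].to_numpy())
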