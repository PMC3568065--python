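"""One-way (tornado), two-way and probabilistic sensitivity analyses.

The tornado re-runs the full model with each registry parameter pushed to
its published low and high bound (everything else at base) and ranks
parameters by the spread of the resulting ICERs.  The two-way analysis grids
EGFR-mutation frequency against genotyping cost.  The PSA draws every
non-fixed parameter from its assigned family — log-normal for costs, beta
for utilities/probabilities/proportions, both moment-matched to mean = base
and SD = 25% of the mean; the hazard ratio log-normal is matched to its
published 95% CI — and records the incremental (ΔCost, ΔQALY) pair of each
iteration.  Cost-effectiveness probabilities are the fraction of iterations
with positive net monetary health benefit at a willingness-to-pay threshold;
sweeping the threshold yields the acceptability curve (CEAC).

Weibull scale/shape are held fixed in the PSA: the publication assigns
distributions only to costs, utilities and probabilities/proportions, and
PFS uncertainty is carried by the hazard ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .economics import Comparison, evaluate_comparison, nmhb
from .parameters import ModelParams, Param, PsaFamily

#: Relative SD assumed when a parameter's dispersion is not reported.
DEFAULT_REL_SD = 0.25


@dataclass(frozen=True)
class TornadoEntry:
    param_name: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _icer(params: ModelParams) -> float:
    _, _, cmp_ = evaluate_comparison(params)
    if cmp_.icer_per_qaly is None:
        raise ValueError("ICER undefined (zero incremental QALYs)")
    return cmp_.icer_per_qaly


def tornado(params: ModelParams) -> list[TornadoEntry]:
    """One-way sensitivity analysis over every registry parameter.

    Returns entries sorted by ICER spread, widest first.  Model errors are
    re-raised annotated with the offending parameter.
    """
    entries = []
    for p in params.iter_params():
        try:
            icer_lo = _icer(params.with_value(p.name, p.low))
            icer_hi = _icer(params.with_value(p.name, p.high))
        except Exception as exc:
            raise RuntimeError(f"tornado step failed for {p.name}: {exc}") from exc
        entries.append(TornadoEntry(p.name, p.low, p.high, icer_lo, icer_hi))
    return sorted(entries, key=lambda e: e.spread, reverse=True)


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.param_name, e.low, e.high, e.icer_at_low, e.icer_at_high, e.spread)
         for e in entries],
        columns=["param", "low", "high", "icer_at_low", "icer_at_high", "spread"],
    )


def two_way(params: ModelParams, freq_grid, genotyping_cost_grid) -> pd.DataFrame:
    """ICER surface over EGFR-mutation frequency × genotyping cost."""
    freq_grid = list(freq_grid)
    cost_grid = list(genotyping_cost_grid)
    if not freq_grid or not cost_grid:
        raise ValueError("grids must be nonempty")
    rows = []
    for f in freq_grid:
        for c in cost_grid:
            mp = params.with_values({"egfr_mutation_freq": f, "cost_genotyping": c})
            rows.append((f, c, _icer(mp)))
    return pd.DataFrame(rows, columns=["egfr_mutation_freq", "cost_genotyping", "icer"])


# ------------------------------------------------------------------ PSA sampling

def _lognormal_moment_matched(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Log-normal draw with the requested arithmetic mean and SD."""
    if mean <= 0:
        return 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - 0.5 * sigma2
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _beta_moment_matched(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Beta draw with the requested mean and SD, SD shrunk to feasibility.

    The beta family requires sd² < mean(1−mean); an infeasible request falls
    back to 95% of the boundary SD.
    """
    if mean <= 0.0 or mean >= 1.0:
        return float(np.clip(mean, 0.0, 1.0))
    var_max = mean * (1.0 - mean)
    var = sd * sd
    if var >= var_max:
        var = (0.95 ** 2) * var_max
    nu = mean * (1.0 - mean) / var - 1.0
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def _lognormal_from_ci(rng: np.random.Generator, median: float,
                       low: float, high: float) -> float:
    """Log-normal with the given median and 95% interval (CI inversion)."""
    sigma = (math.log(high) - math.log(low)) / (2.0 * 1.959963984540054)
    return float(rng.lognormal(math.log(median), sigma))


def sample_param(param: Param, rng: np.random.Generator,
                 rel_sd: float = DEFAULT_REL_SD) -> float:
    """One PSA draw of a single parameter from its assigned family."""
    if param.psa is PsaFamily.FIXED:
        return param.base
    if param.psa is PsaFamily.LOGNORMAL:
        return _lognormal_moment_matched(rng, param.base, rel_sd * param.base)
    if param.psa is PsaFamily.BETA:
        return _beta_moment_matched(rng, param.base, rel_sd * param.base)
    if param.psa is PsaFamily.LOGNORMAL_FROM_CI:
        return _lognormal_from_ci(rng, param.base, param.low, param.high)
    raise ValueError(f"unknown PSA family {param.psa!r}")  # pragma: no cover


@dataclass(frozen=True)
class PsaDraw:
    """Sampled values of all non-fixed parameters for one iteration."""

    index: int
    values: dict[str, float]

    def apply(self, params: ModelParams) -> ModelParams:
        return params.with_values(self.values)


def sample_draw(params: ModelParams, rng: np.random.Generator,
                index: int = 0, rel_sd: float = DEFAULT_REL_SD) -> PsaDraw:
    """Sample every non-fixed registry parameter independently."""
    values = {p.name: sample_param(p, rng, rel_sd)
              for p in params.iter_params() if p.psa is not PsaFamily.FIXED}
    return PsaDraw(index=index, values=values)


@dataclass(frozen=True)
class PsaResult:
    """Incremental (ΔCost, ΔQALY) pairs over all PSA iterations."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    n_iterations: int
    seed: int

    def probability_cost_effective(self, wtp: float) -> float:
        """Fraction of iterations with positive NMHB at the given threshold."""
        return float(np.mean(wtp * self.delta_qaly - self.delta_cost > 0.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(self.n_iterations),
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
        })


def run_psa(params: ModelParams, n_iterations: int = 1000, seed: int = 0,
            rel_sd: float = DEFAULT_REL_SD) -> PsaResult:
    """Monte-Carlo re-evaluation of both strategies under parameter uncertainty.

    Fully reproducible from the seed; iteration i uses the i-th draw of a
    single seeded generator.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    dc = np.empty(n_iterations)
    dq = np.empty(n_iterations)
    for i in range(n_iterations):
        draw = sample_draw(params, rng, index=i, rel_sd=rel_sd)
        try:
            _, _, cmp_ = evaluate_comparison(draw.apply(params))
        except Exception as exc:
            raise RuntimeError(f"PSA iteration {i} failed: {exc}") from exc
        dc[i] = cmp_.delta_cost
        dq[i] = cmp_.delta_qaly
    return PsaResult(delta_cost=dc, delta_qaly=dq, n_iterations=n_iterations, seed=seed)


def ceac(result: PsaResult, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid.

    Default grid: $0 to $100,000 per QALY in $1,000 steps.
    """
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 100001.0, 1000.0)
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("WTP grid must be nonempty")
    probs = [result.probability_cost_effective(w) for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "probability": probs})
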