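"""Discounted cost and outcome accrual, GPAP logic, ICER and NMHB.

Costs and QALYs are discounted at an annual rate applied on the cycle grid;
life-years are reported undiscounted by default (a registry flag exposes the
discounted variant).  Accrual runs over cycles 1..N on occupancy measured
after each cycle's transitions; cycle 0 carries only the one-time genotyping
cost.

Cost components, each switchable off by zeroing its parameter:

* one-time EGFR genotyping for genotyped arms;
* daily gefitinib (250 mg/day) for progression-free occupants of the
  maintenance arm — under the patient-assistance program (GPAP) patients pay
  full price only for the first six months of treatment (prorated within the
  fractional cycle) and receive the drug free afterwards;
* routine follow-up visits amortised per cycle of survivorship (every 4
  months in years 0-2, yearly thereafter);
* serious-adverse-event management, charged per progression-free cycle at
  the platinum-chemotherapy SAE cost scaled by the ratio of cumulative SAE
  probabilities;
* 2nd-line chemotherapy for the first 4 cycles after progression (the median
  number of cycles), supportive care afterwards and for the supportive arm;
* a one-time end-of-life cost at the death transition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .markov import ArmSpec, CohortTrace, HealthState, StrategyArms, run_strategy
from .parameters import DAYS_PER_MONTH, DAYS_PER_YEAR, ModelParams


@dataclass(frozen=True)
class StrategyResult:
    """Discounted cost and (PF-)life-year/QALY totals for one strategy."""

    strategy: str
    cost: float
    pf_ly: float
    ly: float
    qaly: float
    pf_ly_discounted: float
    ly_discounted: float
    cost_breakdown: dict[str, float]

    def __post_init__(self) -> None:
        if self.pf_ly > self.ly + 1e-9:
            raise ValueError("progression-free life-years cannot exceed life-years")
        if self.qaly > self.ly + 1e-9:
            raise ValueError("QALYs cannot exceed life-years (utilities <= 1)")


DOMINANT = "dominant"      # cheaper and more effective
DOMINATED = "dominated"    # costlier and less effective
UNDEFINED = "undefined"    # zero effectiveness difference


@dataclass(frozen=True)
class Comparison:
    """Incremental results of gefitinib vs control (gefitinib minus control)."""

    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer_per_qaly: float | None
    icer_per_ly: float | None
    dominance: Literal["dominant", "dominated", "undefined", ""] = ""


def discount_factor(cycle, annual_rate: float, cycle_days: float) -> np.ndarray | float:
    """(1+r)^(-t) with t the elapsed years at the given cycle index."""
    if annual_rate < 0:
        raise ValueError("annual_rate must be nonnegative")
    years = np.asarray(cycle, dtype=float) * cycle_days / DAYS_PER_YEAR
    out = (1.0 + annual_rate) ** (-years)
    return float(out) if out.ndim == 0 else out


def _accrual_weights(params: ModelParams) -> np.ndarray:
    """Per-cycle accrual weight over cycles 0..N (cycle 0 accrues nothing).

    With the half-cycle correction enabled, cycles 1..N accrue at weight 1
    except the first and a trailing half-cycle, approximating mid-cycle
    transitions.
    """
    n = params.n_cycles()
    w = np.ones(n + 1)
    w[0] = 0.0
    if params.half_cycle_correction:
        w[1] = 0.5
    return w


def accrue_effects(trace: CohortTrace, params: ModelParams):
    """(pf_ly, ly, qaly, pf_ly_discounted, ly_discounted) for one trace.

    Each occupied alive cycle contributes cycle_days/365.25 years, weighted
    by the state utility for QALYs (always discounted).
    """
    n = trace.n_cycles
    cycles = np.arange(n + 1)
    df = discount_factor(cycles, params.discount_annual, params.cycle_days)
    w = _accrual_weights(params)
    dt_years = params.cycle_days / DAYS_PER_YEAR

    pd_occ = trace.pd_2l + trace.pd_sc
    pf_ly = float(np.sum(w * trace.pfs)) * dt_years
    ly = float(np.sum(w * trace.alive())) * dt_years
    pf_ly_d = float(np.sum(w * df * trace.pfs)) * dt_years
    ly_d = float(np.sum(w * df * trace.alive())) * dt_years
    qaly = float(
        np.sum(w * df * (params.utility_pfs.base * trace.pfs
                         + params.utility_pd.base * pd_occ))
    ) * dt_years
    return pf_ly, ly, qaly, pf_ly_d, ly_d


def sae_cost_per_cycle(p_sae_arm: float, params: ModelParams) -> float:
    """Per-cycle SAE management cost for an arm with cumulative SAE risk p.

    Platinum-chemotherapy SAE cost per cycle scaled by the ratio of the arm's
    cumulative SAE probability to platinum chemotherapy's.
    """
    p_plat = params.p_sae_platinum.base
    if not p_plat > 0:
        raise ValueError("platinum SAE probability must be positive")
    return params.cost_sae_platinum_cycle.base * p_sae_arm / p_plat


def gpap_paid_weights(params: ModelParams) -> np.ndarray:
    """Fraction of the gefitinib price payable at each accrual cycle.

    Six months of 30.44-day months span 182.625/21 ≈ 8.696 cycles: cycles
    1..8 are paid in full, cycle 9 is prorated, later cycles are donated.
    Without GPAP every cycle is fully paid.
    """
    n = params.n_cycles()
    t = np.arange(n + 1, dtype=float)
    if not params.gpap_enabled:
        w = np.ones(n + 1)
    else:
        paid_cycles = params.gpap_paid_months * DAYS_PER_MONTH / params.cycle_days
        w = np.clip(paid_cycles - (t - 1.0), 0.0, 1.0)
    w[0] = 0.0
    return w


def followup_cost_per_cycle(params: ModelParams) -> np.ndarray:
    """Amortised follow-up cost per occupied cycle (array over cycles 0..N).

    One visit per 4 months during the first two years, one per year after,
    spread uniformly over the cycles of each regime.
    """
    n = params.n_cycles()
    years = np.arange(n + 1, dtype=float) * params.cycle_days / DAYS_PER_YEAR
    early = years <= params.followup_switch_years
    per_cycle_early = (params.cost_followup_visit.base * params.cycle_days
                       / (params.followup_interval_early_months * DAYS_PER_MONTH))
    per_cycle_late = (params.cost_followup_visit.base * params.cycle_days
                      / (params.followup_interval_late_months * DAYS_PER_MONTH))
    return np.where(early, per_cycle_early, per_cycle_late)


def accrue_costs(trace: CohortTrace, arm: ArmSpec, params: ModelParams) -> dict[str, float]:
    """Discounted cost of one arm's trace, by component.

    Returns a dict with per-component totals and their sum under ``"total"``.
    """
    n = trace.n_cycles
    cycles = np.arange(n + 1)
    df = discount_factor(cycles, params.discount_annual, params.cycle_days)
    w = _accrual_weights(params)

    out: dict[str, float] = {}
    out["genotyping"] = params.cost_genotyping.base if arm.genotyped else 0.0

    if arm.receives_gefitinib:
        per_cycle_drug = params.cycle_days * params.cost_gefitinib_250mg.base
        paid = gpap_paid_weights(params)
        out["gefitinib"] = float(np.sum(w * paid * df * trace.pfs) * per_cycle_drug)
    else:
        out["gefitinib"] = 0.0

    followup_occ = trace.alive() if params.followup_all_states else trace.pfs
    out["followup"] = float(np.sum(w * df * followup_occ * followup_cost_per_cycle(params)))

    p_sae = (params.p_sae_gefitinib.base if arm.receives_gefitinib
             else params.p_sae_control.base)
    out["sae"] = float(np.sum(w * df * trace.pfs) * sae_cost_per_cycle(p_sae, params))

    # 2nd-line chemotherapy for the first `secondline_cycles` cycles on the
    # subcohort clock (k = 0..m-1), supportive care for that state afterwards.
    on_chemo = trace.pd_occupancy_within_clock(HealthState.PD_2L, params.secondline_cycles)
    post_chemo = trace.pd_2l - on_chemo
    out["secondline"] = float(np.sum(w * df * on_chemo) * params.cost_secondline_cycle.base)
    out["supportive"] = float(
        np.sum(w * df * (post_chemo + trace.pd_sc)) * params.cost_supportive_cycle.base
    )

    out["endoflife"] = float(np.sum(w * df * trace.new_deaths) * params.cost_endoflife.base)

    out["total"] = sum(v for k, v in out.items())
    return out


def evaluate_strategy(strategy: str, params: ModelParams,
                      arms: StrategyArms | None = None) -> StrategyResult:
    """Run (or reuse) a strategy's arms and aggregate weighted results."""
    if arms is None:
        arms = run_strategy(strategy, params)
    cost = pf = ly = q = pf_d = ly_d = 0.0
    breakdown: dict[str, float] = {}
    for weight, arm, trace in arms.arms:
        if weight == 0.0:
            continue
        comp = accrue_costs(trace, arm, params)
        cost += weight * comp["total"]
        for k, v in comp.items():
            if k != "total":
                breakdown[k] = breakdown.get(k, 0.0) + weight * v
        e = accrue_effects(trace, params)
        pf += weight * e[0]
        ly += weight * e[1]
        q += weight * e[2]
        pf_d += weight * e[3]
        ly_d += weight * e[4]
    report_pf, report_ly = (pf_d, ly_d) if params.discount_life_years else (pf, ly)
    return StrategyResult(
        strategy=arms.strategy, cost=cost, pf_ly=report_pf, ly=report_ly, qaly=q,
        pf_ly_discounted=pf_d, ly_discounted=ly_d, cost_breakdown=breakdown,
    )


def compare(control: StrategyResult, gefitinib: StrategyResult) -> Comparison:
    """Incremental cost-effectiveness of gefitinib vs control."""
    dc = gefitinib.cost - control.cost
    dq = gefitinib.qaly - control.qaly
    dl = gefitinib.ly - control.ly
    dominance = ""
    if dq == 0.0 and dl == 0.0:
        dominance = UNDEFINED
    elif dc <= 0.0 and dq >= 0.0 and (dc < 0.0 or dq > 0.0):
        dominance = DOMINANT
    elif dc >= 0.0 and dq <= 0.0 and (dc > 0.0 or dq < 0.0):
        dominance = DOMINATED
    return Comparison(
        delta_cost=dc,
        delta_qaly=dq,
        delta_ly=dl,
        icer_per_qaly=dc / dq if dq != 0.0 else None,
        icer_per_ly=dc / dl if dl != 0.0 else None,
        dominance=dominance,
    )


def evaluate_comparison(params: ModelParams) -> tuple[StrategyResult, StrategyResult, Comparison]:
    """Convenience wrapper: run both strategies and compare them."""
    control = evaluate_strategy("control", params)
    gefitinib = evaluate_strategy("gefitinib", params)
    return control, gefitinib, compare(control, gefitinib)


def nmhb(wtp: float, comparison: Comparison) -> float:
    """Net monetary health benefit: WTP × ΔQALY − ΔCost (positive ⇒ cost-effective)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be nonnegative")
    return wtp * comparison.delta_qaly - comparison.delta_cost
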