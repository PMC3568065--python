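"""Semi-Markov cohort engine over the four health states.

States: progression-free (PFS), progressed on 2nd-line chemotherapy (PD_2L),
progressed on supportive care (PD_SC) and DEATH (absorbing).  The cohort
starts progression-free.  Each cycle a Weibull hazard moves a fraction of
PFS occupants to a progressed state, split ``p_secondline`` : 1-p between
2nd-line chemotherapy and supportive care.  Post-progression mortality
follows the overall-survival Weibull of the receiving state evaluated on a
*subcohort clock* that restarts at progression (the published OS curves are
measured from 2nd-line initiation, not from model start), which makes the
engine semi-Markov: progressed occupancy is stratified by entry cycle and
each stratum dies along its own clock.

The engine is deterministic — a cohort model, not a microsimulation — and
occupancy at cycle t is measured *after* the cycle-t transitions, with
accrual downstream running over cycles 1..N.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ModelParams, WeibullParams
from .survival import apply_hazard_ratio, survival_at, to_cycle_units


class HealthState(enum.Enum):
    PFS = "PFS"
    PD_2L = "PD_2L"
    PD_SC = "PD_SC"
    DEATH = "DEATH"


@dataclass(frozen=True)
class ArmSpec:
    """One homogeneous sub-cohort: its PFS curve and cost-relevant flags."""

    label: str
    pfs_params: WeibullParams
    receives_gefitinib: bool = False
    genotyped: bool = False

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("arm label must be nonempty")


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy plus the entry-time ledger of progressors.

    All arrays are indexed by cycle 0..n_cycles.  ``entry_2l``/``entry_sc``
    hold the fraction of the cohort entering each progressed state at each
    cycle; together with the tunnel survival vectors ``tunnel_s_2l[k]`` and
    ``tunnel_s_sc[k]`` (probability of being alive k cycles after entry) they
    reconstruct progressed occupancy stratified by time-since-progression,
    which the economics layer needs to cap 2nd-line chemotherapy at its
    median number of cycles.
    """

    n_cycles: int
    pfs: np.ndarray
    pd_2l: np.ndarray
    pd_sc: np.ndarray
    death: np.ndarray
    new_progressions: np.ndarray
    new_deaths: np.ndarray
    entry_2l: np.ndarray
    entry_sc: np.ndarray
    tunnel_s_2l: np.ndarray
    tunnel_s_sc: np.ndarray

    def occupancy(self) -> np.ndarray:
        """(n_cycles+1, 4) matrix in HealthState order; rows sum to 1."""
        return np.column_stack([self.pfs, self.pd_2l, self.pd_sc, self.death])

    def alive(self) -> np.ndarray:
        return self.pfs + self.pd_2l + self.pd_sc

    def pd_occupancy_within_clock(self, state: HealthState, k_max: int) -> np.ndarray:
        """Occupancy of a progressed state restricted to subcohort clock < k_max.

        Element t is the fraction of the cohort that is in ``state`` at cycle t
        and progressed fewer than ``k_max`` cycles ago (clock k = 0..k_max-1).
        """
        if state is HealthState.PD_2L:
            entries, tunnel = self.entry_2l, self.tunnel_s_2l
        elif state is HealthState.PD_SC:
            entries, tunnel = self.entry_sc, self.tunnel_s_sc
        else:
            raise ValueError("clock-stratified occupancy exists only for progressed states")
        k_max = min(k_max, self.n_cycles + 1)
        if k_max <= 0:
            return np.zeros(self.n_cycles + 1)
        return np.convolve(entries, tunnel[:k_max])[: self.n_cycles + 1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format (cycle, state, fraction) table."""
        occ = self.occupancy()
        rows = []
        for i, state in enumerate(HealthState):
            for t in range(self.n_cycles + 1):
                rows.append((t, state.value, occ[t, i]))
        return pd.DataFrame(rows, columns=["cycle", "state", "fraction"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        doc = {
            "n_cycles": self.n_cycles,
            "occupancy": {s.value: getattr(self, a).tolist()
                          for s, a in zip(HealthState, ("pfs", "pd_2l", "pd_sc", "death"))},
            "new_progressions": self.new_progressions.tolist(),
            "new_deaths": self.new_deaths.tolist(),
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _tunnel_survival(params: WeibullParams, n: int) -> np.ndarray:
    """S(k) on the subcohort clock for k = 0..n (S(0) = 1)."""
    return np.asarray(survival_at(params, np.arange(n + 1, dtype=float)))


def run_arm(arm: ArmSpec, params: ModelParams) -> CohortTrace:
    """Deterministic cohort trace for one arm over the model horizon.

    PFS occupancy follows the arm's Weibull exactly (the per-cycle exit
    probabilities telescope to S(t)); progressors split between the two
    progressed states and die along tunnel clocks.
    """
    n = params.n_cycles()
    pfs_w = to_cycle_units(arm.pfs_params, params.cycle_days)
    p2l = params.p_secondline.base

    t_idx = np.arange(n + 1, dtype=float)
    pfs = np.asarray(survival_at(pfs_w, t_idx))
    new_prog = np.zeros(n + 1)
    new_prog[1:] = pfs[:-1] - pfs[1:]

    entry_2l = p2l * new_prog
    entry_sc = (1.0 - p2l) * new_prog

    s2l = _tunnel_survival(to_cycle_units(params.os_secondline, params.cycle_days), n)
    ssc = _tunnel_survival(to_cycle_units(params.os_supportive, params.cycle_days), n)

    pd_2l = np.convolve(entry_2l, s2l)[: n + 1]
    pd_sc = np.convolve(entry_sc, ssc)[: n + 1]

    # deaths during cycle t: subcohort entered at tau loses S(k-1)-S(k) at k = t-tau
    d2l = -np.diff(s2l, prepend=1.0)  # d2l[k] = S(k-1)-S(k), zero at k=0
    dsc = -np.diff(ssc, prepend=1.0)
    new_deaths = (np.convolve(entry_2l, d2l) + np.convolve(entry_sc, dsc))[: n + 1]
    death = np.cumsum(new_deaths)

    return CohortTrace(
        n_cycles=n,
        pfs=pfs,
        pd_2l=pd_2l,
        pd_sc=pd_sc,
        death=death,
        new_progressions=new_prog,
        new_deaths=new_deaths,
        entry_2l=entry_2l,
        entry_sc=entry_sc,
        tunnel_s_2l=s2l,
        tunnel_s_sc=ssc,
    )


CONTROL = "control"
GEFITINIB = "gefitinib"


@dataclass(frozen=True)
class StrategyArms:
    """Weighted arms composing a strategy; downstream results weight-average."""

    strategy: str
    arms: tuple[tuple[float, ArmSpec, CohortTrace], ...]


def strategy_arms(strategy: str, params: ModelParams) -> list[tuple[float, ArmSpec]]:
    """The (weight, arm) decomposition of a strategy.

    Control: everyone on routine follow-up, no genotyping.  Gefitinib: the
    whole cohort is genotyped; the EGFR-mutation-positive stratum (weight =
    mutation frequency) receives maintenance gefitinib with the PFS hazard
    scaled by the published hazard ratio, the negative stratum follows the
    control PFS curve (routine follow-up only).
    """
    pfs = params.pfs_control
    if strategy == CONTROL:
        return [(1.0, ArmSpec("control", pfs))]
    if strategy == GEFITINIB:
        freq = params.egfr_mutation_freq.base
        hr = params.hr_pfs_gefitinib_egfr_pos.base
        return [
            (freq, ArmSpec("egfr_pos_gefitinib", apply_hazard_ratio(pfs, hr),
                           receives_gefitinib=True, genotyped=True)),
            (1.0 - freq, ArmSpec("egfr_neg_followup", pfs, genotyped=True)),
        ]
    raise ValueError(f"unknown strategy {strategy!r}")


def run_strategy(strategy: str, params: ModelParams) -> StrategyArms:
    """Run every arm of a strategy and return the weighted traces."""
    arms = tuple(
        (w, arm, run_arm(arm, params)) for w, arm in strategy_arms(strategy, params)
    )
    return StrategyArms(strategy=strategy, arms=arms)
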