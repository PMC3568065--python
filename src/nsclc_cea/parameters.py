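"""Typed registry of model inputs.

Every number the model consumes — Weibull survival parameters, transition
probabilities, unit costs, utilities and the run settings (cycle length,
horizon, discount rate, willingness-to-pay thresholds) — lives here, each
with its base value, the published low/high range and the distribution
family used by the probabilistic sensitivity analysis.  Costs are 2012 USD
throughout; no inflation or currency conversion is applied.

The default registry (:func:`default_params`) encodes the published base
case.  A flat YAML config can override any entry (:func:`load_config`);
a shipped ``data/default_params.yaml`` reproduces the defaults and doubles
as schema documentation.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator

import yaml

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0  # 30.4375


class PsaFamily(str, enum.Enum):
    """Distribution family assigned to a parameter for the PSA."""

    LOGNORMAL = "lognormal"            # costs: moment-matched, SD = 25% of mean
    BETA = "beta"                      # utilities / probabilities / proportions
    LOGNORMAL_FROM_CI = "lognormal_from_ci"  # hazard ratio: CI inversion
    FIXED = "fixed"                    # held at base in the PSA


class ParamError(ValueError):
    """A parameter value violates its invariant."""


@dataclass(frozen=True)
class WeibullParams:
    """Scale λ and shape γ of a Weibull survival curve S(t) = exp(−λ t^γ).

    ``time_unit`` records the clock the parameters are expressed on: the
    default is the model's own 3-week cycle; ``"month"`` marks a curve
    digitised on a monthly axis (the engine rescales it onto the cycle grid).
    ``adj_r2`` is the adjusted R² of the linearised least-squares fit that
    produced the parameters, when known.
    """

    scale: float
    shape: float
    adj_r2: float | None = None
    time_unit: str = "cycle"

    def __post_init__(self) -> None:
        if not (self.scale > 0.0) or not math.isfinite(self.scale):
            raise ParamError(f"Weibull scale must be positive, got {self.scale!r}")
        if not (self.shape > 0.0) or not math.isfinite(self.shape):
            raise ParamError(f"Weibull shape must be positive, got {self.shape!r}")
        if self.adj_r2 is not None and not (0.0 <= self.adj_r2 <= 1.0):
            raise ParamError(f"adj_r2 must lie in [0, 1], got {self.adj_r2!r}")
        if self.time_unit not in ("cycle", "month"):
            raise ParamError(f"time_unit must be 'cycle' or 'month', got {self.time_unit!r}")


@dataclass(frozen=True)
class Param:
    """One scalar model input with its sensitivity range and PSA family."""

    name: str
    base: float
    low: float
    high: float
    psa: PsaFamily = PsaFamily.FIXED
    units: str = ""

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ParamError(
                f"{self.name}: base {self.base} outside range [{self.low}, {self.high}]"
            )
        if self.psa is PsaFamily.BETA:
            if not (0.0 <= self.low and self.high <= 1.0):
                raise ParamError(f"{self.name}: beta-distributed values must lie in [0, 1]")
        if self.name.startswith("cost_") and self.low < 0.0:
            raise ParamError(f"{self.name}: costs must be nonnegative")


#: Per-cycle cost of one 2nd-line chemotherapy cycle, as the published weighted
#: mean of the drug mix (50% docetaxel, 20% gefitinib, 15% erlotinib, 15%
#: pemetrexed).  The mix is retained for sensitivity use.
SECONDLINE_DRUG_MIX: tuple[tuple[str, float, float], ...] = (
    ("docetaxel", 0.50, 1942.4),
    ("gefitinib", 0.20, 1921.1),
    ("erlotinib", 0.15, 2265.5),
    ("pemetrexed", 0.15, 4383.3),
)


@dataclass(frozen=True)
class ModelParams:
    """The full base case: survival curves, scalar parameters and settings."""

    # Weibull survival curves (model time unit: one 3-week cycle)
    pfs_control: WeibullParams = WeibullParams(0.1559, 1.045, adj_r2=0.976)
    os_supportive: WeibullParams = WeibullParams(0.04006, 1.156, adj_r2=0.9898)
    os_secondline: WeibullParams = WeibullParams(0.03897, 1.509, adj_r2=0.981)

    # Clinical scalars
    hr_pfs_gefitinib_egfr_pos: Param = Param(
        "hr_pfs_gefitinib_egfr_pos", 0.17, 0.07, 0.42, PsaFamily.LOGNORMAL_FROM_CI
    )
    egfr_mutation_freq: Param = Param("egfr_mutation_freq", 0.50, 0.08, 0.70, PsaFamily.BETA)
    p_secondline: Param = Param("p_secondline", 0.566, 0.26, 0.72, PsaFamily.BETA)
    p_sae_gefitinib: Param = Param("p_sae_gefitinib", 0.07, 0.0525, 0.0875, PsaFamily.BETA)
    p_sae_control: Param = Param("p_sae_control", 0.03, 0.0225, 0.0375, PsaFamily.BETA)
    p_sae_platinum: Param = Param("p_sae_platinum", 0.80, 0.60, 1.00, PsaFamily.BETA)

    # Costs (2012 USD)
    cost_genotyping: Param = Param(
        "cost_genotyping", 507.9, 381.0, 634.9, PsaFamily.LOGNORMAL, "USD, one-time"
    )
    cost_gefitinib_250mg: Param = Param(
        "cost_gefitinib_250mg", 77.8, 38.9, 77.8, PsaFamily.LOGNORMAL, "USD per 250 mg dose"
    )
    cost_followup_visit: Param = Param(
        "cost_followup_visit", 55.6, 41.7, 69.4, PsaFamily.LOGNORMAL, "USD per visit"
    )
    cost_secondline_cycle: Param = Param(
        "cost_secondline_cycle", 2352.7, 1921.1, 4383.3, PsaFamily.LOGNORMAL, "USD per cycle"
    )
    cost_endoflife: Param = Param(
        "cost_endoflife", 3664.3, 21.4, 48750.2, PsaFamily.LOGNORMAL, "USD, one-time"
    )
    cost_supportive_cycle: Param = Param(
        "cost_supportive_cycle", 337.5, 158.7, 793.7, PsaFamily.LOGNORMAL, "USD per cycle"
    )
    cost_sae_platinum_cycle: Param = Param(
        "cost_sae_platinum_cycle", 507.4, 189.7, 825.0, PsaFamily.LOGNORMAL, "USD per cycle"
    )

    # Utilities
    utility_pfs: Param = Param("utility_pfs", 0.65, 0.26, 0.87, PsaFamily.BETA)
    utility_pd: Param = Param("utility_pd", 0.47, 0.19, 0.58, PsaFamily.BETA)

    # Settings
    cycle_days: float = 21.0
    horizon_years: float = 10.0
    discount_annual: float = 0.03
    followup_interval_early_months: float = 4.0   # years 0–2: one visit per 4 months
    followup_interval_late_months: float = 12.0   # thereafter: one visit per year
    followup_switch_years: float = 2.0
    secondline_cycles: int = 4                    # median number of 2nd-line cycles
    gpap_enabled: bool = False
    gpap_paid_months: float = 6.0                 # patient pays 6 months, then donation
    wtp_thresholds: tuple[float, float] = (16349.1, 38733.3)  # 3× GDP China / Shanghai
    half_cycle_correction: bool = False
    followup_all_states: bool = True              # charge follow-up to all alive states
    discount_life_years: bool = False             # report LY/PF-LY undiscounted by default

    # ------------------------------------------------------------------ helpers

    def __post_init__(self) -> None:
        if self.cycle_days <= 0:
            raise ParamError("cycle_days must be positive")
        if self.horizon_years <= 0:
            raise ParamError("horizon_years must be positive")
        if self.discount_annual < 0:
            raise ParamError("discount_annual must be nonnegative")
        if self.gpap_paid_months < 0:
            raise ParamError("gpap_paid_months must be nonnegative")
        if self.secondline_cycles < 0:
            raise ParamError("secondline_cycles must be nonnegative")
        for p in self.iter_params():
            if p.name in ("utility_pfs", "utility_pd") and p.high > 1.0:
                raise ParamError(f"{p.name}: utility cannot exceed 1")

    def iter_params(self) -> Iterator[Param]:
        """Every scalar :class:`Param` in the registry, each exactly once.

        This is the set varied by the tornado analysis and sampled by the PSA.
        """
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, Param):
                yield v

    def param_names(self) -> list[str]:
        return [p.name for p in self.iter_params()]

    def get(self, name: str) -> Param:
        p = getattr(self, name, None)
        if not isinstance(p, Param):
            raise KeyError(name)
        return p

    def with_value(self, name: str, value: float) -> "ModelParams":
        """Copy of the registry with one parameter's base replaced.

        The low/high range is widened if needed so the invariant holds for
        mid-analysis overrides (e.g. a tornado step at the range edge).
        """
        p = self.get(name)
        new = replace(p, base=value, low=min(p.low, value), high=max(p.high, value))
        return replace(self, **{name: new})

    def with_values(self, values: dict[str, float]) -> "ModelParams":
        mp = self
        for k, v in values.items():
            mp = mp.with_value(k, v)
        return mp

    def n_cycles(self) -> int:
        """Number of model cycles covering the horizon (10 y → 174)."""
        return int(round(self.horizon_years * DAYS_PER_YEAR / self.cycle_days))

    # -------------------------------------------------------------- serialization

    def to_dict(self) -> dict:
        d: dict = {"weibull": {}, "params": {}, "settings": {}}
        for name in ("pfs_control", "os_supportive", "os_secondline"):
            w: WeibullParams = getattr(self, name)
            d["weibull"][name] = {
                "scale": w.scale,
                "shape": w.shape,
                "adj_r2": w.adj_r2,
                "time_unit": w.time_unit,
            }
        for p in self.iter_params():
            d["params"][p.name] = {
                "base": p.base,
                "low": p.low,
                "high": p.high,
                "distribution": p.psa.value,
                "units": p.units,
            }
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (Param, WeibullParams)):
                d["settings"][f.name] = list(v) if isinstance(v, tuple) else v
        return d

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def default_params() -> ModelParams:
    """The published base case, exactly as printed."""
    return ModelParams()


def from_dict(doc: dict) -> ModelParams:
    """Build a validated :class:`ModelParams` from a (possibly partial) mapping.

    Missing entries fall back to the base case.  Raises :class:`ParamError`
    naming the offending parameter on any invariant violation.
    """
    base = default_params()
    if not isinstance(doc, dict):
        raise ParamError(f"config root must be a mapping, got {type(doc).__name__}")
    overrides: dict = {}

    for name, spec in (doc.get("weibull") or {}).items():
        cur = getattr(base, name, None)
        if not isinstance(cur, WeibullParams):
            raise ParamError(f"unknown Weibull curve {name!r}")
        kwargs = {
            "scale": spec.get("scale", cur.scale),
            "shape": spec.get("shape", cur.shape),
            "adj_r2": spec.get("adj_r2", cur.adj_r2),
            "time_unit": spec.get("time_unit", cur.time_unit),
        }
        overrides[name] = WeibullParams(**kwargs)

    for name, spec in (doc.get("params") or {}).items():
        cur = getattr(base, name, None)
        if not isinstance(cur, Param):
            raise ParamError(f"unknown parameter {name!r}")
        if isinstance(spec, (int, float)):
            spec = {"base": float(spec)}
        b = float(spec.get("base", cur.base))
        lo = float(spec.get("low", min(cur.low, b)))
        hi = float(spec.get("high", max(cur.high, b)))
        fam = PsaFamily(spec.get("distribution", cur.psa.value))
        overrides[name] = Param(name, b, lo, hi, fam, spec.get("units", cur.units))

    for name, value in (doc.get("settings") or {}).items():
        if name not in {f.name for f in dataclasses.fields(base)}:
            raise ParamError(f"unknown setting {name!r}")
        if name == "wtp_thresholds":
            value = tuple(float(v) for v in value)
        overrides[name] = value

    return replace(base, **overrides)


def load_config(path) -> ModelParams:
    """Load and validate a YAML config file (flat schema, see shipped default)."""
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
            raise ParamError(f"could not parse {path}: {exc}") from exc
    return from_dict(doc or {})


def save_config(params: ModelParams, path) -> None:
    """Serialize a registry to the YAML schema read by :func:`load_config`."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def default_config_text() -> str:
    """YAML text of the shipped default config (reproduces the base case)."""
    return resources.files("nsclc_cea").joinpath("data/default_params.yaml").read_text()
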