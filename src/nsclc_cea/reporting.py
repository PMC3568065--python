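"""Tabular report generation and run manifests.

Reports mirror the base-case summary layout (strategy × cost / PF-LYs /
LYs / QALYs / incremental cost per QALY and per LY), per horizon and GPAP
mode.  Monetary values are rounded to one decimal in reports; internal
computation is full precision.  Every output set is written alongside a
RunManifest JSON sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from . import __version__
from .economics import compare, evaluate_strategy
from .parameters import ModelParams

log = logging.getLogger("nsclc_cea")


@dataclass(frozen=True)
class RunManifest:
    """Provenance of one analysis run: enough to reproduce it exactly."""

    command: str
    config: str | None
    horizons: list[float]
    gpap_modes: list[bool]
    seed: int | None
    outdir: str
    package_version: str = __version__
    timestamp: str = ""

    def write(self, outdir: Path) -> Path:
        doc = dataclasses.asdict(self)
        doc["timestamp"] = doc["timestamp"] or datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
        path = outdir / f"manifest_{self.command.replace(' ', '_')}.json"
        path.write_text(json.dumps(doc, indent=2) + "\n")
        return path


def base_case_table(params: ModelParams, horizons=(1, 2, 5, 10),
                    gpap_modes=(False, True)) -> pd.DataFrame:
    """Strategy-level results with incremental ratios, per horizon and GPAP mode.

    The control strategy is unaffected by GPAP and is reported once per
    horizon (``gpap`` column empty).
    """
    rows = []
    for horizon in horizons:
        mp_h = replace(params, horizon_years=float(horizon))
        control = evaluate_strategy("control", mp_h)
        rows.append({
            "horizon_years": horizon, "strategy": "control", "gpap": "",
            "cost": control.cost, "pf_ly": control.pf_ly, "ly": control.ly,
            "qaly": control.qaly, "icer_per_qaly": None, "icer_per_ly": None,
        })
        for gpap in gpap_modes:
            mp = replace(mp_h, gpap_enabled=gpap)
            gef = evaluate_strategy("gefitinib", mp)
            cmp_ = compare(control, gef)
            rows.append({
                "horizon_years": horizon, "strategy": "gefitinib",
                "gpap": "gpap" if gpap else "no_gpap",
                "cost": gef.cost, "pf_ly": gef.pf_ly, "ly": gef.ly, "qaly": gef.qaly,
                "icer_per_qaly": cmp_.icer_per_qaly, "icer_per_ly": cmp_.icer_per_ly,
            })
        log.info("base case horizon %s y done", horizon)
    df = pd.DataFrame(rows)
    for col in ("cost", "icer_per_qaly", "icer_per_ly"):
        df[col] = df[col].round(1)
    for col in ("pf_ly", "ly", "qaly"):
        df[col] = df[col].round(4)
    return df


def write_report(df: pd.DataFrame, outdir: Path, stem: str) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(outdir / f"{stem}.csv", index=False)
    df.to_json(outdir / f"{stem}.json", orient="records", indent=2)
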