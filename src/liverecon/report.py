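"""Output-table writers and run manifests.

CSV outputs carry unrounded values; display rounding (nearest dollar,
billions to three significant figures, vial counts in three-significant-
figure scientific notation) is applied only in the companion display
columns and console tables.  Every output set is written alongside a
``manifest.json`` capturing the command, inputs, seed and package version.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .bioliver import LiverCostBreakdown
from .uncertainty import MonteCarloResult, sensitivity_report

__all__ = [
    "RunManifest",
    "round_dollars",
    "billions_3sf",
    "sci_3sf",
    "write_manifest",
    "write_forecast",
    "write_costs",
    "write_psa",
    "write_sensitivity",
    "write_bioliver",
]


@dataclass(frozen=True)
class RunManifest:
    command: str
    config: str
    seed: int | None
    n_draws: int | None
    out_dir: str
    package_version: str = __version__
    timestamp: str = ""

    @staticmethod
    def create(command: str, config: str, out_dir: str | Path,
               seed: int | None = None, n_draws: int | None = None) -> "RunManifest":
        return RunManifest(
            command=command,
            config=config,
            seed=seed,
            n_draws=n_draws,
            out_dir=str(out_dir),
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )


def round_dollars(x: float) -> int:
    return int(round(x))


def billions_3sf(x: float) -> float:
    """Dollars -> billions, three significant figures."""
    b = x / 1e9
    return float(f"{b:.3g}")


def sci_3sf(x: float) -> str:
    return f"{x:.2E}"


def _outdir(path: str | Path) -> Path:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    return out


def write_manifest(manifest: RunManifest, out_dir: str | Path) -> Path:
    out = _outdir(out_dir) / "manifest.json"
    out.write_text(json.dumps(asdict(manifest), indent=1))
    return out


def write_forecast(df: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    out = _outdir(out_dir)
    csv_path = out / "cohort_forecast.csv"
    df.to_csv(csv_path, index=False, float_format="%.17g")
    json_path = out / "cohort_forecast.json"
    json_path.write_text(df.to_json(orient="records", indent=1))
    return [csv_path, json_path]


def write_costs(df: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    out = _outdir(out_dir)
    csv_path = out / "phase_costs.csv"
    df.to_csv(csv_path, index=False, float_format="%.17g")
    disp = df.copy()
    for col in disp.columns:
        if col in ("listing_year", "calendar_year"):
            continue
        disp[col] = disp[col].map(round_dollars)
    disp["national_total_billions"] = df["national_total"].map(billions_3sf)
    disp_path = out / "phase_costs_display.csv"
    disp.to_csv(disp_path, index=False)
    json_path = out / "phase_costs.json"
    json_path.write_text(df.to_json(orient="records", indent=1))
    return [csv_path, disp_path, json_path]


def write_psa(result: MonteCarloResult, out_dir: str | Path) -> list[Path]:
    out = _outdir(out_dir)
    csv_path = out / "uncertainty.csv"
    result.summaries.to_csv(csv_path, index=False, float_format="%.17g")
    json_path = out / "uncertainty.json"
    json_path.write_text(result.summaries.to_json(orient="records", indent=1))
    return [csv_path, json_path]


def write_sensitivity(result: MonteCarloResult, out_dir: str | Path) -> list[Path]:
    out = _outdir(out_dir)
    frames = []
    for metric, df in sensitivity_report(result).items():
        d = df.copy()
        d.insert(0, "metric", metric)
        frames.append(d)
    table = pd.concat(frames, ignore_index=True)
    csv_path = out / "sensitivity.csv"
    table.to_csv(csv_path, index=False, float_format="%.17g")
    json_path = out / "sensitivity.json"
    json_path.write_text(table.to_json(orient="records", indent=1))
    return [csv_path, json_path]


def write_bioliver(breakdown: LiverCostBreakdown, out_dir: str | Path) -> list[Path]:
    out = _outdir(out_dir)
    rows = [
        {
            "item": "reprogramming",
            "cells": "",
            "cells_per_vial": "",
            "vials": "",
            "price_per_vial": "",
            "cost": breakdown.reprogramming_cost,
        }
    ]
    for line in breakdown.lines:
        rows.append(
            {
                "item": line.name,
                "cells": sci_3sf(line.cells_required_whole_liver * breakdown.fraction_of_liver),
                "cells_per_vial": sci_3sf(line.cells_per_vial),
                "vials": sci_3sf(breakdown.vials[line.name]),
                "price_per_vial": line.price_per_vial,
                "cost": breakdown.line_costs[line.name],
            }
        )
    rows.append({"item": "total", "cells": "", "cells_per_vial": "", "vials": "",
                 "price_per_vial": "", "cost": breakdown.total})
    df = pd.DataFrame(rows)
    csv_path = out / "bioliver_ledger.csv"
    df.to_csv(csv_path, index=False, float_format="%.17g")
    json_path = out / "bioliver_ledger.json"
    json_path.write_text(
        json.dumps(
            {
                "fraction_of_liver": breakdown.fraction_of_liver,
                "reprogramming_cost": breakdown.reprogramming_cost,
                "vials": breakdown.vials,
                "line_costs": breakdown.line_costs,
                "cell_cost": breakdown.cell_cost,
                "total": breakdown.total,
            },
            indent=1,
        )
    )
    return [csv_path, json_path]
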