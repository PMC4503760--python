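"""Catalog-price cost ledger for bioengineering an autologous liver graft.

The calculator projects what it would cost today to buy, as individual
cryovials at catalog list pricing, every cell needed to seed a whole
bioengineered liver from iPSC-derived lines: ~1.5e11 hepatocytes plus
endothelial cells (40 % of the hepatocyte count) and fibroblasts (10 %).
No in-graft proliferation is assumed — every cell is purchased — which makes
the estimate deliberately conservative.  A fixed reprogramming charge
(deriving the patient's iPSC line, non-GMP list price) is added once and does
not scale with graft size, so partial grafts (auxiliary transplantation of
35 % or 15 % of a liver) scale only the cell costs.

Vial counts are left fractional: the ledger prices cells, not packaging, and
fractional vials reproduce the published catalog totals exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .parameters import DomainError

__all__ = [
    "CellLineSpec",
    "LiverCostBreakdown",
    "DEFAULT_CELL_LINES",
    "DEFAULT_REPROGRAMMING_COST",
    "vials_required",
    "build_cost",
    "price_decline_scenario",
    "load_price_list",
]

#: One-time cost of reprogramming patient tissue to iPSCs (non-GMP list
#: price); independent of graft fraction.
DEFAULT_REPROGRAMMING_COST = 15_000.0


@dataclass(frozen=True)
class CellLineSpec:
    """One cell line: whole-liver requirement, vial size and vial price."""

    name: str
    cells_required_whole_liver: float
    cells_per_vial: float
    price_per_vial: float

    def __post_init__(self) -> None:
        for field_name in ("cells_required_whole_liver", "cells_per_vial"):
            if getattr(self, field_name) <= 0:
                raise DomainError(f"{self.name}: {field_name} must be positive")
        # Zero is allowed so price-decline scenarios can model a free line.
        if self.price_per_vial < 0:
            raise DomainError(f"{self.name}: price_per_vial must be non-negative")


#: Catalog baseline (CDI list pricing): hepatocytes dominate both the cell
#: count and the cost; endothelial and fibroblast requirements are stored as
#: absolute counts (40 % and 10 % of the hepatocyte requirement).
DEFAULT_CELL_LINES: tuple[CellLineSpec, ...] = (
    CellLineSpec("hepatocytes", 1.50e11, 9.00e6, 1500.0),
    CellLineSpec("endothelial_cells", 6.00e10, 3.20e7, 800.0),
    CellLineSpec("fibroblasts", 1.50e10, 1.00e7, 800.0),
)


@dataclass(frozen=True)
class LiverCostBreakdown:
    """Cells -> vials -> dollars ledger for a (partial) bioengineered liver."""

    fraction_of_liver: float
    reprogramming_cost: float
    lines: tuple[CellLineSpec, ...]
    vials: dict[str, float]
    line_costs: dict[str, float]

    @property
    def cell_cost(self) -> float:
        return sum(self.line_costs.values())

    @property
    def total(self) -> float:
        return self.reprogramming_cost + self.cell_cost


def vials_required(spec: CellLineSpec, fraction: float = 1.0) -> float:
    """Vials needed for a graft fraction (fractional vials allowed)."""
    if not 0.0 < fraction <= 1.0:
        raise DomainError(f"fraction {fraction} outside (0, 1]")
    return fraction * spec.cells_required_whole_liver / spec.cells_per_vial


def build_cost(
    lines: tuple[CellLineSpec, ...] | list[CellLineSpec] = DEFAULT_CELL_LINES,
    fraction: float = 1.0,
    reprogramming: float = DEFAULT_REPROGRAMMING_COST,
) -> LiverCostBreakdown:
    """Full catalog-price ledger for a whole or partial liver.

    Cell quantities (hence vial costs) scale linearly with the graft
    fraction; the reprogramming charge does not.
    """
    if not lines:
        raise DomainError("at least one cell line is required")
    lines = tuple(lines)
    vials = {s.name: vials_required(s, fraction) for s in lines}
    costs = {s.name: vials[s.name] * s.price_per_vial for s in lines}
    return LiverCostBreakdown(
        fraction_of_liver=fraction,
        reprogramming_cost=reprogramming,
        lines=lines,
        vials=vials,
        line_costs=costs,
    )


def price_decline_scenario(
    lines: tuple[CellLineSpec, ...] | list[CellLineSpec],
    price_multipliers: dict[str, float],
    fraction: float = 1.0,
    reprogramming: float = DEFAULT_REPROGRAMMING_COST,
) -> LiverCostBreakdown:
    """Re-price the ledger under per-line price multipliers.

    Models manufacturing-scale price declines: multipliers below one shrink a
    line's vial price; lines absent from the mapping keep catalog pricing.
    """
    scaled = []
    for s in lines:
        m = price_multipliers.get(s.name, 1.0)
        if m < 0:
            raise DomainError(f"price multiplier for {s.name} must be non-negative")
        scaled.append(
            CellLineSpec(s.name, s.cells_required_whole_liver, s.cells_per_vial,
                         s.price_per_vial * m)
        )
    return build_cost(tuple(scaled), fraction, reprogramming)


def load_price_list(path: str | Path) -> tuple[CellLineSpec, ...]:
    """Read a price-list CSV: name, cells per liver, cells per vial, price per vial."""
    lines = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            lines.append(
                CellLineSpec(
                    name=row["name"],
                    cells_required_whole_liver=float(row["cells_per_liver"]),
                    cells_per_vial=float(row["cells_per_vial"]),
                    price_per_vial=float(row["price_per_vial"]),
                )
            )
    if not lines:
        raise DomainError(f"price list {path} is empty")
    return tuple(lines)
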