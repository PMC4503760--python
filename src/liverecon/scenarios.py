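"""Scenario bundles: the packaged baseline and randomized valid variants.

The baseline bundle carries the published input table together with the
published with-MELD listing anchors.  ``random_scenario`` perturbs every
input multiplicatively and then repairs the structural constraints (share
vectors renormalised, cumulative schedules re-sorted monotone, fractions
clipped), so that every generated table passes full validation and can be
pushed end-to-end through the epidemiology, cost and uncertainty stages.
Repair-by-construction keeps generation deterministic and O(1) per
parameter — no rejection sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from ._baseline import WITH_MELD_ANCHORS, baseline_parameters
from .parameters import (
    AGE_GROUPS,
    MELD_CATEGORIES,
    MORTALITY_HORIZONS,
    DistributionSpec,
    DomainError,
    Parameter,
    ParameterTable,
)

__all__ = ["ScenarioBundle", "baseline_bundle", "random_scenario"]


@dataclass(frozen=True)
class ScenarioBundle:
    """A named, validated parameter table plus optional printed anchors."""

    name: str
    params: ParameterTable
    anchors: Mapping[int, float] | None
    provenance: dict[str, str]


def baseline_bundle() -> ScenarioBundle:
    """The published input table with its with-MELD listing anchors."""
    params = ParameterTable(baseline_parameters())
    return ScenarioBundle(
        name="table1_baseline",
        params=params,
        anchors=dict(WITH_MELD_ANCHORS),
        provenance={name: "published" for name in params.names()},
    )


def _clip_unit(lo, base, hi):
    base = min(max(base, 0.0), 1.0)
    if lo is not None:
        lo = min(max(lo, 0.0), 1.0)
        lo = min(lo, base)
    if hi is not None:
        hi = min(max(hi, 0.0), 1.0)
        hi = max(hi, base)
    return lo, base, hi


def random_scenario(seed: int, perturbation_scale: float = 0.2) -> ScenarioBundle:
    """Deterministic randomized variant of the baseline table.

    Each base value (and its bounds, proportionally) is multiplied by an
    independent factor in [1 - s, 1 + s]; share vectors are renormalised,
    survival and cumulative-mortality schedules re-sorted to preserve
    monotonicity, and unit-interval quantities clipped.  Scale 0 reproduces
    the baseline exactly.  Printed anchors are *not* attached: they describe
    the published scenario only.
    """
    if not 0.0 <= perturbation_scale <= 0.5:
        raise DomainError("perturbation_scale must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    base_params = baseline_parameters()

    specs: dict[str, list] = {}
    for p in base_params:
        factor = 1.0 + perturbation_scale * rng.uniform(-1.0, 1.0)
        s = p.spec
        lo = None if s.low is None else s.low * factor
        hi = None if s.high is None else s.high * factor
        specs[p.name] = [s.base * factor, lo, hi]

    # Renormalise share vectors so downstream sum checks hold exactly.
    for names in (
        [f"meld.baseline_share.{c.slug}" for c in MELD_CATEGORIES],
        [f"cohort.age_share.{g}" for g in AGE_GROUPS],
    ):
        norm = sum(specs[n][0] for n in names)
        if abs(norm - 1.0) > 1e-12:
            for n in names:
                specs[n] = [v if v is None else v / norm for v in specs[n]]

    # Repair monotone schedules by sorting.
    surv_names = [f"survival.y{k}" for k in range(1, 11)]
    surv = sorted(
        (min(max(specs[n][0], 1e-9), 1.0) for n in surv_names), reverse=True
    )
    for n, v in zip(surv_names, surv):
        specs[n][0] = v
    for cat, horizons in MORTALITY_HORIZONS.items():
        names = [f"mortality.{cat.slug}.{h}" for h in horizons]
        vals = sorted(min(max(specs[n][0], 0.0), 1.0) for n in names)
        for n, v in zip(names, vals):
            specs[n][0] = v

    params_out: list[Parameter] = []
    provenance: dict[str, str] = {}
    for p in base_params:
        base, lo, hi = specs[p.name]
        if p.units in ("fraction", "probability"):
            lo, base, hi = _clip_unit(lo, base, hi)
        params_out.append(
            replace(p, spec=DistributionSpec(kind=p.spec.kind, base=base, low=lo, high=hi))
        )
        provenance[p.name] = (
            "published" if perturbation_scale == 0.0 else f"perturbed(seed={seed})"
        )
    return ScenarioBundle(
        name=f"random_{seed}",
        params=ParameterTable(params_out),
        anchors=None,
        provenance=provenance,
    )
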