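"""Typed, validated registry of every model input.

The 20-year liver-transplantation forecasting model is driven entirely by a
table of published aggregate inputs: the 2012 U.S. waitlist cohort size and
composition (OPTN/SRTR), annual percent changes for listings and MELD-category
shares, waitlist mortality/severe-illness schedules (Wiesner et al. composite),
waiting times per MELD band (OPTN), hospital-admission case mix and cost
multipliers (Showstack et al.), a 10-year post-transplant survival schedule,
complication frequencies and added costs (Ammori et al.), unit costs (Milliman,
Axelrod et al., CPMC), and cost escalation / discount rates.  Each input is a
:class:`DistributionSpec` carrying both its deterministic base value and the
uncertainty distribution used by the Monte Carlo analysis.

This module is the single source of truth for parameter names, units and
validation; every other module reads values from a :class:`ParameterTable`.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping

import yaml

__all__ = [
    "DistributionKind",
    "DistributionSpec",
    "MeldCategory",
    "Parameter",
    "ParameterTable",
    "SimulationClock",
    "ParameterError",
    "MissingParameterError",
    "UnknownParameterError",
    "RangeError",
    "DomainError",
    "load_parameters",
    "point_estimate",
    "MELD_CATEGORIES",
    "AGE_GROUPS",
    "ADMISSION_COMPONENTS",
    "CASEMIX_CHARACTERISTICS",
    "COMPLICATIONS",
    "MORTALITY_HORIZONS",
    "HORIZON_DAYS",
    "VARIABLE_ANALOGUE",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class ParameterError(ValueError):
    """Base class for parameter validation failures."""


class MissingParameterError(ParameterError):
    """A required parameter is absent from a configuration document."""


class UnknownParameterError(ParameterError):
    """A configuration document names a parameter the model does not define."""


class RangeError(ParameterError):
    """A distribution's low/base/high ordering is violated."""


class DomainError(ParameterError):
    """A value lies outside its semantic domain (e.g. a negative fraction)."""


# ---------------------------------------------------------------------------
# Distribution specification
# ---------------------------------------------------------------------------

class DistributionKind(str, Enum):
    FIXED = "fixed"
    TRIANGULAR = "triangular"
    UNIFORM = "uniform"
    VARIABLE = "variable"


@dataclass(frozen=True)
class DistributionSpec:
    """Base value plus uncertainty distribution for one model input.

    ``triangular`` uses ``base`` as the mode (the Crystal-Ball convention);
    ``uniform`` samples on ``[low, high]`` with ``base`` reported as the
    midpoint; ``variable`` marks inputs whose published bounds are unstated —
    their sampling bounds are resolved from an analogue row (see
    :data:`VARIABLE_ANALOGUE`).
    """

    kind: DistributionKind
    base: float
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        kind = DistributionKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if not math.isfinite(self.base):
            raise DomainError(f"base must be finite, got {self.base!r}")
        if kind is DistributionKind.FIXED:
            for b in (self.low, self.high):
                if b is not None and b != self.base:
                    raise RangeError(
                        f"fixed distribution with bounds differing from base: {self}"
                    )
        elif kind in (DistributionKind.TRIANGULAR, DistributionKind.UNIFORM):
            if self.low is None or self.high is None:
                raise MissingParameterError(
                    f"{kind.value} distribution requires low and high: {self}"
                )
            if self.low > self.high:
                raise RangeError(f"low > high: {self}")
            if not (self.low <= self.base <= self.high):
                raise RangeError(f"base outside [low, high]: {self}")
        elif kind is DistributionKind.VARIABLE:
            if self.low is not None or self.high is not None:
                raise RangeError(
                    f"variable distribution carries no printed bounds: {self}"
                )

    def to_dict(self) -> dict:
        out: dict = {"kind": self.kind.value, "base": self.base}
        if self.low is not None:
            out["low"] = self.low
        if self.high is not None:
            out["high"] = self.high
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "DistributionSpec":
        extra = set(d) - {"kind", "base", "low", "high"}
        if extra:
            raise UnknownParameterError(f"unknown distribution fields: {sorted(extra)}")
        if "kind" not in d or "base" not in d:
            raise MissingParameterError(f"distribution requires kind and base: {d}")
        return cls(
            kind=DistributionKind(d["kind"]),
            base=float(d["base"]),
            low=None if d.get("low") is None else float(d["low"]),
            high=None if d.get("high") is None else float(d["high"]),
        )


def point_estimate(spec: DistributionSpec) -> float:
    """Deterministic base-case value of a distribution (its base, any kind)."""
    return spec.base


# ---------------------------------------------------------------------------
# Categorical axes
# ---------------------------------------------------------------------------

class MeldCategory(str, Enum):
    """The five MELD-score severity categories used throughout the model.

    Higher MELD means sicker patients, higher allocation priority and much
    shorter waiting time, which is why the two axes (pre-transplant monthly
    spending and waiting duration) both key on this categorisation.
    """

    LT9 = "<9"
    M10_19 = "10-19"
    M20_29 = "20-29"
    M30_39 = "30-39"
    GT40 = ">40"

    @property
    def slug(self) -> str:
        return _MELD_SLUGS[self]


_MELD_SLUGS = {
    MeldCategory.LT9: "lt9",
    MeldCategory.M10_19: "10_19",
    MeldCategory.M20_29: "20_29",
    MeldCategory.M30_39: "30_39",
    MeldCategory.GT40: "gt40",
}

MELD_CATEGORIES: tuple[MeldCategory, ...] = tuple(MeldCategory)

AGE_GROUPS: tuple[str, ...] = ("18_34", "35_49", "50_64", "65plus")

ADMISSION_COMPONENTS: tuple[str, ...] = (
    "immunosuppressive",
    "anti_infective",
    "other_medications",
    "blood_products",
    "operating_room",
    "respiratory_services",
    "special_care",
    "other_room_and_care",
    "immunosuppressive_monitoring",
    "other_laboratory",
    "chest_radiography",
    "ultrasound",
    "other_imaging",
    "pathology",
    "material_services",
    "miscellaneous",
)

#: Patient/donor characteristics that carry a hospital-cost uplift multiplier.
CASEMIX_CHARACTERISTICS: tuple[str, ...] = (
    "retransplant",
    "hosp_not_icu",
    "icu",
    "donor_60plus",
    "recipient_60plus",
    "ald",
    "child_pugh_c",
)

COMPLICATIONS: tuple[str, ...] = (
    "acute_cellular_rejection",
    "biliary",
    "hepatic_artery_thrombosis",
    "skin_infection",
    "pneumonia",
    "bloodstream_infection",
    "peritonitis",
    "urinary_tract_infection",
    "cdiff_colitis",
    "other_infections",
    "venous_thromboembolism",
    "reoperation",
    "primary_nonfunction",
    "hepatic_vein_stenosis",
    "acute_renal_failure",
)

#: Horizons at which the cumulative waitlist mortality/severe-illness
#: schedules are published, per MELD category.
MORTALITY_HORIZONS: dict[MeldCategory, tuple[str, ...]] = {
    MeldCategory.LT9: ("3m", "1y", "2y", "3y", "4y", "5y", "6y", "7y", "8y", "9y", "10y"),
    MeldCategory.M10_19: ("3m", "1y", "2y", "3y", "4y", "5y"),
    MeldCategory.M20_29: ("3m",),
    MeldCategory.M30_39: ("3m",),
    MeldCategory.GT40: ("3m",),
}

# A model month is 365/12 days, so 3 months = 91.25 days.
HORIZON_DAYS: dict[str, float] = {"3m": 3 * 365.0 / 12}
HORIZON_DAYS.update({f"{k}y": 365.0 * k for k in range(1, 11)})

#: Resolution rule for "variable" rows: (analogue parameter, mode).
#: "relative" scales the analogue's low/high ratios onto this base (used for
#: the MELD>40 monthly spending, analogue MELD 30-39); "additive" shifts by
#: the analogue's low-base / high-base offsets (used for the per-category
#: share changes, whose bases are near zero so ratios are meaningless).
VARIABLE_ANALOGUE: dict[str, tuple[str, str]] = {
    "cost.monthly_pre_lt.gt40": ("cost.monthly_pre_lt.30_39", "relative"),
    "growth.meld_share.lt9": ("growth.srtr_share.6_14", "additive"),
    "growth.meld_share.10_19": ("growth.srtr_share.6_14", "additive"),
    "growth.meld_share.20_29": ("growth.srtr_share.15_34", "additive"),
    "growth.meld_share.30_39": ("growth.srtr_share.gt35", "additive"),
    "growth.meld_share.gt40": ("growth.srtr_share.gt35", "additive"),
}


# ---------------------------------------------------------------------------
# Parameter + table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Parameter:
    """One registry entry: a named, sourced distribution with units.

    ``psa`` marks inputs varied in the cost-metric probabilistic sensitivity
    analysis; epidemiology growth inputs are held at base there (they feed
    cohort sizes, not per-patient costs) unless joint sampling is requested.
    """

    name: str
    spec: DistributionSpec
    units: str = ""
    group: str = ""
    source: str = ""
    psa: bool = False


@dataclass(frozen=True)
class SimulationClock:
    """Calendar bookkeeping: data year 2012, Year 1 = 2014, 20-year horizon."""

    base_data_year: int = 2012
    first_model_year: int = 2014
    horizon_years: int = 20

    def __post_init__(self) -> None:
        if self.horizon_years < 1:
            raise DomainError("horizon_years must be >= 1")
        if self.first_model_year <= self.base_data_year:
            raise DomainError("first_model_year must follow base_data_year")

    def calendar_year(self, model_year: int) -> int:
        self.check_model_year(model_year)
        return self.first_model_year + model_year - 1

    def model_year(self, calendar_year: int) -> int:
        return calendar_year - self.first_model_year + 1

    def growth_exponent(self, calendar_year: int) -> int:
        """Years of compounding since the base data year."""
        return calendar_year - self.base_data_year

    def check_model_year(self, model_year: int) -> None:
        if not 1 <= model_year <= self.horizon_years:
            raise DomainError(
                f"model_year {model_year} outside 1..{self.horizon_years}"
            )

    @property
    def model_years(self) -> range:
        return range(1, self.horizon_years + 1)


class ParameterTable:
    """Ordered mapping of parameter name -> :class:`Parameter`, validated."""

    def __init__(self, parameters: Iterator[Parameter] | list[Parameter]):
        self._params: dict[str, Parameter] = {}
        for p in parameters:
            if p.name in self._params:
                raise ParameterError(f"duplicate parameter {p.name!r}")
            self._params[p.name] = p
        self.validate()

    # -- mapping protocol ---------------------------------------------------

    def __getitem__(self, name: str) -> Parameter:
        try:
            return self._params[name]
        except KeyError:
            raise MissingParameterError(f"unknown parameter {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __iter__(self) -> Iterator[str]:
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterTable):
            return NotImplemented
        return self._params == other._params

    def names(self) -> list[str]:
        return list(self._params)

    def parameters(self) -> list[Parameter]:
        return list(self._params.values())

    def value(self, name: str) -> float:
        """Deterministic base value of a parameter."""
        return point_estimate(self[name].spec)

    # -- derived views ------------------------------------------------------

    def meld_baseline_shares(self) -> dict[MeldCategory, float]:
        return {c: self.value(f"meld.baseline_share.{c.slug}") for c in MELD_CATEGORIES}

    def meld_share_changes(self) -> dict[MeldCategory, float]:
        return {c: self.value(f"growth.meld_share.{c.slug}") for c in MELD_CATEGORIES}

    def age_shares(self) -> dict[str, float]:
        return {g: self.value(f"cohort.age_share.{g}") for g in AGE_GROUPS}

    def age_share_changes(self) -> dict[str, float]:
        return {g: self.value(f"growth.age_share.{g}") for g in AGE_GROUPS}

    def survival_schedule(self) -> list[float]:
        """Cumulative post-transplant survival S(k), k = 1..10."""
        return [self.value(f"survival.y{k}") for k in range(1, 11)]

    def mortality_schedule(self, category: MeldCategory) -> list[tuple[float, float]]:
        """(days, cumulative probability) knots of the waitlist schedule."""
        return [
            (HORIZON_DAYS[h], self.value(f"mortality.{category.slug}.{h}"))
            for h in MORTALITY_HORIZONS[category]
        ]

    def complication_rows(self) -> list[tuple[str, float, float]]:
        return [
            (
                c,
                self.value(f"complication.{c}.frequency"),
                self.value(f"complication.{c}.cost"),
            )
            for c in COMPLICATIONS
        ]

    # -- sampling support ---------------------------------------------------

    def sampling_bounds(self, name: str) -> tuple[float, float]:
        """Effective [low, high] for sampling, resolving ``variable`` rows."""
        p = self[name]
        spec = p.spec
        if spec.kind in (DistributionKind.TRIANGULAR, DistributionKind.UNIFORM):
            assert spec.low is not None and spec.high is not None
            return spec.low, spec.high
        if spec.kind is DistributionKind.FIXED:
            return spec.base, spec.base
        analogue_name, mode = VARIABLE_ANALOGUE[name]
        a = self[analogue_name].spec
        assert a.low is not None and a.high is not None
        if mode == "relative":
            return spec.base * a.low / a.base, spec.base * a.high / a.base
        low = spec.base + (a.low - a.base)
        high = spec.base + (a.high - a.base)
        return low, high

    def with_values(self, overrides: Mapping[str, float]) -> "ParameterTable":
        """New table with the named bases replaced (bounds widened if needed).

        Used to materialise a Monte Carlo draw as a full parameter table.
        Sampled values always lie inside the original bounds, so widening only
        triggers for ``variable`` rows whose resolved bounds are not stored.
        """
        new = dict(self._params)
        for name, value in overrides.items():
            p = self[name]
            spec = p.spec
            low, high = spec.low, spec.high
            if low is not None:
                low = min(low, value)
            if high is not None:
                high = max(high, value)
            new[name] = replace(p, spec=replace(spec, base=float(value), low=low, high=high))
        table = ParameterTable.__new__(ParameterTable)
        table._params = new
        table.validate()
        return table

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for p in self._params.values():
            base = p.spec.base
            if p.units in ("fraction", "probability") and not 0.0 <= base <= 1.0:
                raise DomainError(f"{p.name}: fraction {base} outside [0, 1]")
            if p.units == "USD" and base < 0 and not p.name.startswith("complication."):
                raise DomainError(f"{p.name}: negative monetary base {base}")
            if p.units == "days" and base < 0:
                raise DomainError(f"{p.name}: negative duration {base}")

        shares = [self.value(f"meld.baseline_share.{c.slug}") for c in MELD_CATEGORIES]
        if abs(sum(shares) - 1.0) > 1e-3:
            raise DomainError(f"MELD baseline shares sum to {sum(shares)}, not 1")
        ages = [self.value(f"cohort.age_share.{g}") for g in AGE_GROUPS]
        if abs(sum(ages) - 1.0) > 1e-3:
            raise DomainError(f"age shares sum to {sum(ages)}, not 1")

        surv = self.survival_schedule()
        for k, s in enumerate(surv, start=1):
            if not 0.0 < s <= 1.0:
                raise DomainError(f"survival.y{k} = {s} outside (0, 1]")
        if any(b > a for a, b in zip(surv, surv[1:])):
            raise DomainError("post-transplant survival schedule must be non-increasing")

        for c in MELD_CATEGORIES:
            sched = [p for _, p in self.mortality_schedule(c)]
            if any(b < a for a, b in zip(sched, sched[1:])):
                raise DomainError(f"mortality schedule for {c.value} must be non-decreasing")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, dict]:
        return {name: p.spec.to_dict() for name, p in self._params.items()}

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path: str | Path | None = None) -> str:
        """Registry dump: one row per parameter with units and source."""
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["name", "kind", "base", "low", "high", "units", "group", "source"])
        for p in self._params.values():
            w.writerow(
                [p.name, p.spec.kind.value, p.spec.base, p.spec.low, p.spec.high,
                 p.units, p.group, p.source]
            )
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _baseline_table() -> ParameterTable:
    from ._baseline import baseline_parameters

    return ParameterTable(baseline_parameters())


def load_parameters(source: str | Path | Mapping) -> ParameterTable:
    """Build a validated :class:`ParameterTable` from a config source.

    ``source`` may be the packaged baseline name ``"table1_baseline"``, a path
    to a YAML/JSON document, or an already-parsed mapping.  A document either
    supplies a flat ``{name: {kind, base, low, high}}`` mapping covering every
    model parameter, or selects ``baseline: table1_baseline`` and optionally
    overrides named entries.  Unknown keys are an error, not a warning: a
    silently ignored typo would corrupt a 20-year forecast.
    """
    if isinstance(source, str) and source == "table1_baseline":
        return _baseline_table()
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text()
        doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if not isinstance(doc, Mapping):
            raise ParameterError(f"config document {path} is not a mapping")
        return load_parameters(doc)

    doc = dict(source)
    baseline_name = doc.pop("baseline", None)
    overrides = doc.pop("overrides", None)
    schema = _baseline_table()

    if baseline_name is not None:
        if baseline_name != "table1_baseline":
            raise UnknownParameterError(f"unknown baseline {baseline_name!r}")
        if doc:
            raise UnknownParameterError(
                f"unexpected keys alongside 'baseline': {sorted(doc)}"
            )
        table = schema
        if overrides:
            table = _apply_overrides(table, overrides)
        return table

    if overrides is not None:
        raise ParameterError("'overrides' requires a 'baseline' key")

    unknown = set(doc) - set(schema.names())
    if unknown:
        raise UnknownParameterError(f"unknown parameters: {sorted(unknown)}")
    missing = set(schema.names()) - set(doc)
    if missing:
        raise MissingParameterError(f"missing parameters: {sorted(missing)}")
    params = [
        replace(schema[name], spec=DistributionSpec.from_dict(doc[name]))
        for name in schema.names()
    ]
    return ParameterTable(params)


def _apply_overrides(table: ParameterTable, overrides: Mapping) -> ParameterTable:
    params = {name: table[name] for name in table.names()}
    for name, value in overrides.items():
        if name not in params:
            raise UnknownParameterError(f"unknown parameter {name!r}")
        p = params[name]
        if isinstance(value, Mapping):
            spec = DistributionSpec.from_dict(value)
        else:
            spec = replace(p.spec, base=float(value))
        params[name] = replace(p, spec=spec)
    return ParameterTable(list(params.values()))
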