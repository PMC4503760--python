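"""Waitlist demand forecasting: cohort arithmetic over 2014-2033.

The model is deterministic cohort arithmetic, not microsimulation.  Each
calendar year's newly listed cohort is obtained by compounding the 2012
baseline at published annual percent changes:

* total new listings grow at ``growth.new_listings`` (+1.1 %/yr base);
* the five MELD-category shares are compounded at their own annual changes
  and renormalised to sum to one, so the mix shifts toward sicker patients;
* the "with-MELD" subset removes listings with no reported MELD score or
  inactive status.  Compounding those two shares at their published changes
  cannot reproduce the published 2033 with-MELD total, so *anchored* mode
  substitutes the published totals (7,934 in 2014; 8,006 in 2020; 7,600 in
  2033) where available; *computed* mode always compounds.

Waitlist attrition applies each category's cumulative mortality/severe-illness
schedule over that category's waiting duration (linear interpolation between
published horizons, held flat beyond the last), then removes the fraction of
eligible patients who never proceed to transplant; the remainder are
transplanted.  Admission deaths, re-transplants and 10-year survivor counts
follow as fixed fractions of the operated cohort.

Fractional persons are carried unrounded through the pipeline; rounding to
whole patients happens only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._baseline import WITH_MELD_ANCHORS
from .parameters import (
    AGE_GROUPS,
    MELD_CATEGORIES,
    DomainError,
    MeldCategory,
    ParameterTable,
    SimulationClock,
)

__all__ = [
    "CohortYear",
    "WaitlistOutcomes",
    "WITH_MELD_ANCHORS",
    "AGE_MIDPOINTS",
    "CATEGORY_WAIT_BAND",
    "project_new_listings",
    "evolve_meld_shares",
    "project_with_meld_listings",
    "meld_category_counts",
    "cumulative_waitlist_mortality",
    "waitlist_attrition",
    "admission_outcomes",
    "survivors_at_year",
    "mean_age_at_listing",
    "cohort_year",
    "forecast_cohorts",
    "aggregate_attrition",
]

#: Age-group midpoints (years) used for the mean age at listing; the open top
#: bin uses 72.
AGE_MIDPOINTS: dict[str, float] = {"18_34": 26.0, "35_49": 42.0, "50_64": 57.0, "65plus": 72.0}

#: MELD category -> waiting-time band.  The published bands (<10, 11-18,
#: 19-24, >=25 and status 1) straddle the five cost categories; this mapping
#: is monotone in severity and uses each band once, with both MELD >=30
#: categories on the >=25 band.  Status-1 (6 days) is available as an
#: override for the sickest category.
CATEGORY_WAIT_BAND: dict[MeldCategory, str] = {
    MeldCategory.LT9: "waiting_days.band_lt10",
    MeldCategory.M10_19: "waiting_days.band_11_18",
    MeldCategory.M20_29: "waiting_days.band_19_24",
    MeldCategory.M30_39: "waiting_days.band_ge25",
    MeldCategory.GT40: "waiting_days.band_ge25",
}


@dataclass(frozen=True)
class CohortYear:
    """One calendar year's newly listed cohort."""

    calendar_year: int
    model_year: int
    new_listings: float
    with_meld_listings: float
    meld_shares: dict[MeldCategory, float]
    meld_counts: dict[MeldCategory, float]
    age_shares: dict[str, float]

    def __post_init__(self) -> None:
        if self.with_meld_listings > self.new_listings + 0.5:
            raise DomainError("with-MELD listings exceed total listings")
        if abs(sum(self.meld_shares.values()) - 1.0) > 1e-9:
            raise DomainError("MELD shares must sum to 1")
        if abs(sum(self.meld_counts.values()) - self.with_meld_listings) > 0.5:
            raise DomainError("MELD counts must sum to the with-MELD total")


@dataclass(frozen=True)
class WaitlistOutcomes:
    """Fate of a listed cohort: pre-transplant attrition and downstream counts."""

    listed: float
    transplanted: float
    died_or_severe_on_list: float
    not_transplanted_other: float
    died_during_admission: float
    retransplanted: float
    survivors_by_post_year: tuple[float, ...]  # k = 1..10
    by_category: dict[MeldCategory, dict[str, float]]


# ---------------------------------------------------------------------------
# Cohort projection
# ---------------------------------------------------------------------------

def project_new_listings(
    params: ParameterTable, clock: SimulationClock, model_year: int
) -> float:
    """Total new waitlist registrations in a model year (unrounded).

    The 2012 baseline compounds at the annual listings change for every year
    elapsed since 2012, i.e. exponent ``model_year + 1`` under the Year-1 =
    2014 convention.
    """
    clock.check_model_year(model_year)
    g = params.value("growth.new_listings")
    exponent = clock.growth_exponent(clock.calendar_year(model_year))
    return params.value("cohort.new_listings_2012") * (1.0 + g) ** exponent


def evolve_meld_shares(
    params: ParameterTable, calendar_year: int
) -> dict[MeldCategory, float]:
    """MELD-category shares of the listed cohort in a calendar year.

    Each baseline share is compounded at its per-category annual change from
    2012 and the five values are renormalised to sum to one.
    """
    if calendar_year < 2012:
        raise DomainError(f"calendar_year {calendar_year} precedes the 2012 data year")
    t = calendar_year - 2012
    base = params.meld_baseline_shares()
    delta = params.meld_share_changes()
    raw = {c: base[c] * (1.0 + delta[c]) ** t for c in MELD_CATEGORIES}
    total = sum(raw.values())
    return {c: v / total for c, v in raw.items()}


def project_with_meld_listings(
    params: ParameterTable,
    clock: SimulationClock,
    model_year: int,
    mode: str = "computed",
    anchors: Mapping[int, float] | None = None,
) -> float:
    """New listings carrying a usable MELD score (active, score reported).

    ``computed`` compounds the no-MELD and inactive shares at their annual
    changes; ``anchored`` returns the published total for that calendar year
    (error if none); ``auto`` prefers the anchor when available.
    """
    clock.check_model_year(model_year)
    year = clock.calendar_year(model_year)
    if mode not in ("computed", "anchored", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode in ("anchored", "auto"):
        if anchors is not None and year in anchors:
            return float(anchors[year])
        if mode == "anchored":
            raise DomainError(f"no published with-MELD anchor for {year}")
    t = clock.growth_exponent(year)
    no_meld = params.value("cohort.share_no_meld_2012") * (
        1.0 + params.value("growth.share_no_meld")
    ) ** t
    inactive = params.value("cohort.share_inactive_2012") * (
        1.0 + params.value("growth.share_inactive")
    ) ** t
    frac = 1.0 - no_meld - inactive
    if frac < 0.0:
        frac = 0.0
    return project_new_listings(params, clock, model_year) * frac


def meld_category_counts(
    shares: Mapping[MeldCategory, float], with_meld_total: float
) -> dict[MeldCategory, float]:
    """Split a with-MELD cohort across categories (fractional counts)."""
    if with_meld_total < 0:
        raise DomainError("with_meld_total must be non-negative")
    if abs(sum(shares.values()) - 1.0) > 1e-9:
        raise DomainError("shares must sum to 1")
    return {c: shares[c] * with_meld_total for c in MELD_CATEGORIES}


# ---------------------------------------------------------------------------
# Attrition and downstream outcomes
# ---------------------------------------------------------------------------

def cumulative_waitlist_mortality(
    params: ParameterTable, category: MeldCategory, days: float
) -> float:
    """Cumulative death/severe-illness probability after ``days`` on the list.

    Linear interpolation in time on the cumulative schedule, anchored at
    (0, 0); beyond the last published horizon the schedule is held flat.
    """
    if days < 0:
        raise DomainError("waiting duration must be non-negative")
    knots = params.mortality_schedule(category)
    xs = np.array([0.0] + [d for d, _ in knots])
    ys = np.array([0.0] + [p for _, p in knots])
    return float(np.interp(days, xs, ys))


def waitlist_attrition(
    params: ParameterTable,
    cohort: CohortYear,
    status1_for_top: bool = False,
) -> WaitlistOutcomes:
    """Partition a listed cohort into transplanted / died-or-severe / other.

    Per MELD category: the cumulative mortality/severe-illness schedule is
    applied over that category's waiting duration; the published fraction of
    eligible patients who do not proceed to transplant is removed from the
    survivors; the remainder are transplanted.  Admission deaths,
    re-transplants and year-k survivors follow from the operated count.
    """
    not_going = params.value("attrition.pct_not_transplanted")
    survival = params.survival_schedule()
    by_cat: dict[MeldCategory, dict[str, float]] = {}
    for c in MELD_CATEGORIES:
        band = CATEGORY_WAIT_BAND[c]
        if status1_for_top and c is MeldCategory.GT40:
            band = "waiting_days.status1"
        wait = params.value(band)
        mort = cumulative_waitlist_mortality(params, c, wait)
        listed = cohort.meld_counts[c]
        died = listed * mort
        eligible = listed - died
        not_tx = eligible * not_going
        transplanted = eligible - not_tx
        by_cat[c] = {
            "listed": listed,
            "died_or_severe_on_list": died,
            "not_transplanted_other": not_tx,
            "transplanted": transplanted,
        }
    listed = sum(v["listed"] for v in by_cat.values())
    transplanted = sum(v["transplanted"] for v in by_cat.values())
    died = sum(v["died_or_severe_on_list"] for v in by_cat.values())
    not_tx = sum(v["not_transplanted_other"] for v in by_cat.values())
    adm = admission_outcomes(params, transplanted)
    survivors = tuple(transplanted * s for s in survival)
    return WaitlistOutcomes(
        listed=listed,
        transplanted=transplanted,
        died_or_severe_on_list=died,
        not_transplanted_other=not_tx,
        died_during_admission=adm["died"],
        retransplanted=adm["retransplanted"],
        survivors_by_post_year=survivors,
        by_category=by_cat,
    )


def admission_outcomes(params: ParameterTable, transplanted: float) -> dict[str, float]:
    """In-hospital deaths and re-transplants among operated patients."""
    if transplanted < 0:
        raise DomainError("transplanted count must be non-negative")
    return {
        "died": transplanted * params.value("admission.frac.died"),
        "retransplanted": transplanted * params.value("admission.frac.retransplant"),
    }


def survivors_at_year(params: ParameterTable, operated: float, k: int) -> float:
    """Patients alive k years after transplant (cumulative survival S(k))."""
    if not 1 <= k <= 10:
        raise DomainError(f"post-transplant year {k} outside 1..10")
    return operated * params.value(f"survival.y{k}")


def mean_age_at_listing(params: ParameterTable, calendar_year: int) -> float:
    """Average age of newly listed patients, from evolved age-group shares."""
    if calendar_year < 2012:
        raise DomainError(f"calendar_year {calendar_year} precedes the 2012 data year")
    t = calendar_year - 2012
    base = params.age_shares()
    delta = params.age_share_changes()
    raw = {g: base[g] * (1.0 + delta[g]) ** t for g in AGE_GROUPS}
    total = sum(raw.values())
    return sum(AGE_MIDPOINTS[g] * v / total for g, v in raw.items())


# ---------------------------------------------------------------------------
# Full-horizon tables
# ---------------------------------------------------------------------------

def cohort_year(
    params: ParameterTable,
    clock: SimulationClock,
    model_year: int,
    mode: str = "computed",
    anchors: Mapping[int, float] | None = None,
) -> CohortYear:
    year = clock.calendar_year(model_year)
    shares = evolve_meld_shares(params, year)
    with_meld = project_with_meld_listings(params, clock, model_year, mode, anchors)
    t = year - 2012
    base_age = params.age_shares()
    delta_age = params.age_share_changes()
    raw = {g: base_age[g] * (1.0 + delta_age[g]) ** t for g in AGE_GROUPS}
    tot = sum(raw.values())
    return CohortYear(
        calendar_year=year,
        model_year=model_year,
        new_listings=project_new_listings(params, clock, model_year),
        with_meld_listings=with_meld,
        meld_shares=shares,
        meld_counts=meld_category_counts(shares, with_meld),
        age_shares={g: v / tot for g, v in raw.items()},
    )


def forecast_cohorts(
    params: ParameterTable,
    clock: SimulationClock | None = None,
    mode: str = "computed",
    anchors: Mapping[int, float] | None = None,
) -> pd.DataFrame:
    """Per-year cohort table over the full horizon, with attrition splits."""
    clock = clock or SimulationClock()
    rows = []
    for m in clock.model_years:
        cy = cohort_year(params, clock, m, mode, anchors)
        out = waitlist_attrition(params, cy)
        row: dict[str, float] = {
            "calendar_year": cy.calendar_year,
            "model_year": cy.model_year,
            "new_listings": cy.new_listings,
            "with_meld_listings": cy.with_meld_listings,
        }
        for c in MELD_CATEGORIES:
            row[f"share_{c.slug}"] = cy.meld_shares[c]
            row[f"count_{c.slug}"] = cy.meld_counts[c]
        for g in AGE_GROUPS:
            row[f"age_share_{g}"] = cy.age_shares[g]
        row["mean_age"] = mean_age_at_listing(params, cy.calendar_year)
        row["transplanted"] = out.transplanted
        row["died_or_severe_on_list"] = out.died_or_severe_on_list
        row["not_transplanted_other"] = out.not_transplanted_other
        row["died_during_admission"] = out.died_during_admission
        row["retransplanted"] = out.retransplanted
        row["survivors_10y"] = out.survivors_by_post_year[-1]
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_attrition(
    params: ParameterTable,
    clock: SimulationClock | None = None,
    mode: str = "computed",
    anchors: Mapping[int, float] | None = None,
) -> dict[str, float]:
    """Attrition splits pooled over every cohort of the simulation horizon.

    Returns absolute counts plus fractions of the pooled with-MELD cohort.
    """
    clock = clock or SimulationClock()
    totals = {"listed": 0.0, "transplanted": 0.0, "died_or_severe_on_list": 0.0,
              "not_transplanted_other": 0.0, "died_during_admission": 0.0,
              "survivors_10y": 0.0}
    for m in clock.model_years:
        out = waitlist_attrition(params, cohort_year(params, clock, m, mode, anchors))
        totals["listed"] += out.listed
        totals["transplanted"] += out.transplanted
        totals["died_or_severe_on_list"] += out.died_or_severe_on_list
        totals["not_transplanted_other"] += out.not_transplanted_other
        totals["died_during_admission"] += out.died_during_admission
        totals["survivors_10y"] += out.survivors_by_post_year[-1]
    listed = totals["listed"]
    fractions = {
        f"frac_{k}": (v / listed if listed else 0.0)
        for k, v in totals.items()
        if k != "listed"
    }
    return {**totals, **fractions}
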