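"""Discounted per-patient treatment costs by phase and listing year.

Three cost phases are modelled per listing-year cohort, all in 2014 USD:

* **pre-transplant** — per MELD category.  Categories whose waiting time is
  under one year ("severe illness": MELD >= 20) are costed as the 12 months
  preceding transplant at the category's average monthly spending.  The
  less-sick categories (MELD < 20) accrue monthly spending over their full
  waiting duration (which itself lengthens at the annual time-to-transplant
  change), plus a last-30-days adjustment escalated to the transplant date.
* **admission** — organ procurement + physician fees + hospital admission,
  the hospital component uplifted by the expected case-mix multiplier
  (population fraction x percent cost increase, summed over characteristics).
* **post-transplant (10-year)** — first-90-days base cost + expected
  complication add-ons (frequency x added cost, one entry negative) + ten
  annual immunosuppression payments escalated year by year.  Costs are
  conditional on 10-year survival (no survival weighting).

Cost escalation (base 4.9 %/yr) and discounting to present value (3 %/yr)
compose into a single net annual factor (1+r)/(1+d); a cohort listed in year
t carries the Year-1 price scaled by that factor to the power t-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .epidemiology import (
    CATEGORY_WAIT_BAND,
    evolve_meld_shares,
    project_new_listings,
)
from .parameters import (
    CASEMIX_CHARACTERISTICS,
    MELD_CATEGORIES,
    DomainError,
    MeldCategory,
    ParameterTable,
    SimulationClock,
)

__all__ = [
    "MONTH_DAYS",
    "SEVERE_WAIT_DAYS",
    "EscalationRates",
    "PhaseCosts",
    "NationalExpenditure",
    "escalation_factor",
    "pre_lt_cost",
    "weighted_pre_lt_cost",
    "admission_cost",
    "post_lt_cost",
    "total_per_patient",
    "national_expenditure",
    "phase_costs",
    "phase_cost_table",
    "complication_expected_cost",
    "casemix_expected_uplift",
]

#: A model month is 365/12 days, keeping monthly accrual consistent with
#: annual escalation.
MONTH_DAYS = 365.0 / 12

#: Waiting time at or below which a category is costed under the
#: severe-illness rule (12 months of pre-transplant spending).
SEVERE_WAIT_DAYS = 365.0


@dataclass(frozen=True)
class EscalationRates:
    """Annual cost increase ``r`` and annual discount rate ``d``."""

    r: float
    d: float

    def __post_init__(self) -> None:
        if self.r <= -1.0 or self.d <= -1.0:
            raise DomainError("rates must exceed -1")

    @classmethod
    def from_table(cls, params: ParameterTable) -> "EscalationRates":
        return cls(r=params.value("rates.cost_increase"), d=params.value("rates.discount"))


@dataclass(frozen=True)
class PhaseCosts:
    """Discounted per-patient costs of one listing-year cohort."""

    listing_year: int
    pre_lt_by_meld: dict[MeldCategory, float]
    pre_lt_weighted: float
    admission: float
    post_lt_10yr: float

    @property
    def total_per_patient(self) -> float:
        return self.pre_lt_weighted + self.admission + self.post_lt_10yr


@dataclass(frozen=True)
class NationalExpenditure:
    model_year: int
    demand: float
    per_patient: float

    @property
    def total_usd(self) -> float:
        return self.per_patient * self.demand


# ---------------------------------------------------------------------------
# Kernels (float or ndarray inputs; shared with the Monte Carlo module)
# ---------------------------------------------------------------------------

def _net_factor(r, d, years):
    return ((1.0 + r) / (1.0 + d)) ** years


def severe_pre_lt_kernel(monthly, r, d, listing_year):
    """12 months of spending, priced at the listing year."""
    return 12.0 * monthly * _net_factor(r, d, listing_year - 1)


def accrual_pre_lt_kernel(monthly, wait_days, ttt_growth, last30, r, d, listing_year):
    """Month-by-month waitlist accrual in closed form.

    The waiting duration grows at the annual time-to-transplant change for
    later cohorts; each month's spending escalates from the listing date at
    the net monthly rate; the last-30-days adjustment escalates to the
    transplant date; the whole is then priced at the listing year.
    """
    months = wait_days * (1.0 + ttt_growth) ** (listing_year - 1) / MONTH_DAYS
    f = (1.0 + r) / (1.0 + d)
    q = f ** (1.0 / 12.0)
    whole = np.floor(months)
    frac = months - whole
    geo = np.where(np.abs(q - 1.0) < 1e-12, whole, (q ** whole - 1.0) / np.where(q == 1.0, 1.0, q - 1.0))
    accrual = monthly * (geo + frac * q ** whole)
    total = accrual + last30 * f ** (months / 12.0)
    return total * _net_factor(r, d, listing_year - 1)


def admission_kernel(procurement, physician, hospital, uplift, r, d, listing_year):
    base = procurement + physician + hospital * (1.0 + uplift)
    return base * _net_factor(r, d, listing_year - 1)


def post_lt_kernel(post90, complication_expected, immunosuppression, r, d, listing_year):
    f = (1.0 + r) / (1.0 + d)
    stream = np.where(
        np.abs(f - 1.0) < 1e-12,
        10.0,
        f * (f ** 10 - 1.0) / np.where(f == 1.0, 1.0, f - 1.0),
    )
    total = post90 + complication_expected + immunosuppression * stream
    return total * _net_factor(r, d, listing_year - 1)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def escalation_factor(rates: EscalationRates, years: float):
    """Net real escalation ((1+r)/(1+d))**years applied to a Year-1 price."""
    if np.any(np.asarray(years) < 0):
        raise DomainError("years must be non-negative")
    return _net_factor(rates.r, rates.d, years)


def _check_listing_year(listing_year: int, clock: SimulationClock | None) -> None:
    horizon = (clock or SimulationClock()).horizon_years
    if not 1 <= listing_year <= horizon:
        raise DomainError(f"listing_year {listing_year} outside 1..{horizon}")


def is_severe(params: ParameterTable, meld: MeldCategory) -> bool:
    """Severe-illness costing applies when base waiting time <= one year."""
    return params.value(CATEGORY_WAIT_BAND[meld]) <= SEVERE_WAIT_DAYS


def pre_lt_cost(
    params: ParameterTable,
    meld: MeldCategory,
    listing_year: int,
    clock: SimulationClock | None = None,
) -> float:
    """Discounted pre-transplant cost per to-be-transplanted patient."""
    meld = MeldCategory(meld)
    _check_listing_year(listing_year, clock)
    r = params.value("rates.cost_increase")
    d = params.value("rates.discount")
    monthly = params.value(f"cost.monthly_pre_lt.{meld.slug}")
    if is_severe(params, meld):
        return float(severe_pre_lt_kernel(monthly, r, d, listing_year))
    return float(
        accrual_pre_lt_kernel(
            monthly,
            params.value(CATEGORY_WAIT_BAND[meld]),
            params.value("growth.time_to_transplant"),
            params.value("cost.last30d_adjustment"),
            r,
            d,
            listing_year,
        )
    )


def weighted_pre_lt_cost(
    params: ParameterTable,
    listing_year: int,
    meld_shares: Mapping[MeldCategory, float] | None = None,
    clock: SimulationClock | None = None,
) -> float:
    """MELD-mix-weighted pre-transplant cost for one listing-year cohort.

    Defaults to the evolved shares of the listing calendar year.
    """
    _check_listing_year(listing_year, clock)
    if meld_shares is None:
        clk = clock or SimulationClock()
        meld_shares = evolve_meld_shares(params, clk.calendar_year(listing_year))
    if abs(sum(meld_shares.values()) - 1.0) > 1e-9:
        raise DomainError("meld_shares must sum to 1")
    return sum(
        meld_shares[c] * pre_lt_cost(params, c, listing_year, clock)
        for c in MELD_CATEGORIES
    )


def casemix_expected_uplift(params: ParameterTable) -> float:
    """Expected hospital-cost uplift: sum of fraction x multiplier."""
    return sum(
        params.value(f"admission.frac.{name}") * params.value(f"cost.casemix_uplift.{name}")
        for name in CASEMIX_CHARACTERISTICS
    )


def admission_cost(
    params: ParameterTable, listing_year: int, clock: SimulationClock | None = None
) -> float:
    """Discounted transplant-hospitalisation cost per operated patient."""
    _check_listing_year(listing_year, clock)
    return float(
        admission_kernel(
            params.value("cost.organ_procurement"),
            params.value("cost.physician_fees"),
            params.value("cost.hospital_admission"),
            casemix_expected_uplift(params),
            params.value("rates.cost_increase"),
            params.value("rates.discount"),
            listing_year,
        )
    )


def complication_expected_cost(params: ParameterTable) -> float:
    """Expected complication add-on: sum of frequency x added cost."""
    return sum(freq * cost for _, freq, cost in params.complication_rows())


def post_lt_cost(
    params: ParameterTable, listing_year: int, clock: SimulationClock | None = None
) -> float:
    """Discounted 10-year post-transplant cost per 10-year survivor."""
    _check_listing_year(listing_year, clock)
    return float(
        post_lt_kernel(
            params.value("cost.post90d_base"),
            complication_expected_cost(params),
            params.value("cost.immunosuppression_annual"),
            params.value("rates.cost_increase"),
            params.value("rates.discount"),
            listing_year,
        )
    )


def phase_costs(
    params: ParameterTable, listing_year: int, clock: SimulationClock | None = None
) -> PhaseCosts:
    by_meld = {
        c: pre_lt_cost(params, c, listing_year, clock) for c in MELD_CATEGORIES
    }
    clk = clock or SimulationClock()
    shares = evolve_meld_shares(params, clk.calendar_year(listing_year))
    weighted = sum(shares[c] * by_meld[c] for c in MELD_CATEGORIES)
    return PhaseCosts(
        listing_year=listing_year,
        pre_lt_by_meld=by_meld,
        pre_lt_weighted=weighted,
        admission=admission_cost(params, listing_year, clock),
        post_lt_10yr=post_lt_cost(params, listing_year, clock),
    )


def total_per_patient(phase: PhaseCosts) -> float:
    """Exact sum of the three phase costs."""
    return phase.total_per_patient


def national_expenditure(per_patient: float, demand: float) -> float:
    """Potential national spend: per-patient total x demand (all survive)."""
    if per_patient < 0 or demand < 0:
        raise DomainError("per_patient and demand must be non-negative")
    return per_patient * demand


def phase_cost_table(
    params: ParameterTable, clock: SimulationClock | None = None
) -> pd.DataFrame:
    """Per-listing-year phase costs plus national totals over the horizon.

    National demand is the *total* new-listings forecast (a correction for
    patients excluded from the with-MELD cohort by reporting status).
    """
    clk = clock or SimulationClock()
    rows = []
    for m in clk.model_years:
        pc = phase_costs(params, m, clk)
        demand = project_new_listings(params, clk, m)
        row: dict[str, float] = {
            "listing_year": m,
            "calendar_year": clk.calendar_year(m),
        }
        for c in MELD_CATEGORIES:
            row[f"pre_lt_{c.slug}"] = pc.pre_lt_by_meld[c]
        row["pre_lt_weighted"] = pc.pre_lt_weighted
        row["admission"] = pc.admission
        row["post_lt_10yr"] = pc.post_lt_10yr
        row["total_per_patient"] = pc.total_per_patient
        row["demand"] = demand
        row["national_total"] = national_expenditure(pc.total_per_patient, demand)
        rows.append(row)
    return pd.DataFrame(rows)
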