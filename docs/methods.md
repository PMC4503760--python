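# Model description and methods

`liverecon` implements a deterministic, cohort-level economic model of U.S.
liver transplantation over a 20-year horizon (Year 1 = calendar 2014, Year
20 = 2033), with a probabilistic layer on top.  This note records the model
equations, the conventions chosen where published sources under-determine
them, and what the package's tests do and do not establish.

## Epidemiology model

All quantities are aggregates compounded from a 2012 base-year snapshot
(OPTN/SRTR-derived).  Fractional persons are carried unrounded through every
stage; rounding to whole patients happens only at report time.

**New listings.**  `N(y) = 10,143 x (1 + g)^(y - 2012)` with `g` the annual
listings change (base 0.011).  The exponent counts calendar years since the
data year, so Year 1 (2014) uses exponent 2.  This is the only indexing
convention that reproduces both published endpoints (10,367 and 12,763) from
the 2012 count.

**MELD mix.**  The five severity categories (<9, 10–19, 20–29, 30–39, >40)
start from the Wiesner-composite 2012 shares and each compounds at its own
annual change; the five evolved shares are renormalised to sum to one.
Category counts are shares times the with-MELD cohort.

**With-MELD cohort.**  Listings excluding records with no reported MELD
score or inactive status.  Compounding those two exclusion shares at their
published annual changes (+7.6 %/yr and −0.5 %/yr) reproduces the published
2014 total within 1 % but cannot reproduce the published 2020 peak or the
2033 total (the published treatment of these growth rates over time is not
stated).  The package therefore supports three modes: `computed`
(compounding), `anchored` (published totals 7,934 / 8,006 / 7,600 for
2014/2020/2033, error elsewhere) and `auto` (anchor where available).  The
baseline scenario bundle carries the anchors; randomized scenarios do not.

**Waitlist attrition.**  Each category is assigned one published
waiting-time band: <9 → 1,776 d, 10–19 → 639 d, 20–29 → 106 d, and both
MELD ≥ 30 categories → 20 d (the band boundaries straddle the cost
categories; this mapping is monotone in severity and uses each band once;
the 6-day status-1 band is exposed as an override for the sickest
category).  Cumulative death/severe-illness probability over the wait is
linearly interpolated in time on the published cumulative schedule, anchored
at (0, 0) and held flat beyond the last published horizon — the simplest
monotone completion.  A "month" is 365/12 days throughout, so the 3-month
horizon is 91.25 days.  Of those surviving the wait, a uniform 21.3 % do not
proceed to transplant; the remainder are transplanted.  Admission deaths
(6 %), re-transplants (3 %) and year-k survivors (cumulative S(k), k = 1..10,
from 0.90 down to 0.63) are fixed fractions of the operated cohort.

**Mean age at listing.**  Age-group shares compound and renormalise like the
MELD shares; group midpoints are 26 / 42 / 57 / 72 years (interval
midpoints, open top bin set to 72).  The published means are only matched
within ±1.5 years because the source does not state its midpoints.

## Treatment-cost model

All monetary inputs are 2014 USD (the inputs were already price-adjusted at
source; no deflator is applied at run time).  Cost escalation `r` (base
4.9 %/yr) and discounting to present value `d` (3 %/yr) combine into a
single net factor `f = (1+r)/(1+d)`; a cohort listed in year `t` carries the
Year-1 price scaled by `f^(t-1)`.  This composition is forced by the exact
Year-20/Year-1 ratios of the severe pre-transplant and post-transplant
metrics (both equal `f^19 ≈ 1.41523`).

**Pre-transplant.**  Categories waiting at most one year (MELD ≥ 20 under
the adopted band mapping) are *severely ill* and costed as 12 months of the
category's average monthly spending — forced by 12 × $51,085 = $613,020
matching the published MELD > 40 Year-1 value exactly.  The two low-MELD
categories accrue monthly spending over the full wait: the duration grows by
(1 + 1.7 %)^(t−1) for later cohorts, each month escalates from the listing
date at `f^(1/12)` (closed-form geometric series, fractional final month
pro-rated), and a last-30-days adjustment ($26,469) escalates to the
transplant date.  Two deliberate conventions here:

* the last-30-days adjustment is applied only to the accrual-costed
  categories, although its source labels it "MELD < 30"; including it for
  20–29 overshoots the published weighted average by ~4 %, excluding it
  lands within ~1 %;
* no attempt is made to force-fit the published low-MELD values ($49,407 /
  $71,621): the implemented ledger lands within ~2 % at Year 1 but ~18 % at
  Year 20, and the interaction of wait-time growth with accrual for late
  cohorts is under-determined in the source.  These two cells are treated as
  soft (±20 %) checks only.

**Admission.**  `procurement + physician fees + hospital x (1 + U)` with
`U = Σ fraction_j x multiplier_j` over the seven case-mix characteristics
(re-transplant, hospitalised non-ICU, ICU, donor 60+, recipient 60+,
alcoholic liver disease, Child–Pugh C); `U = 0.3674` at base.  Uplifting
only the hospital component is the closest reconstruction of the published
Year-1 total ($588,580; the component base is −2.5 % under it, versus +5 %
if the uplift were applied to all components).  The published Year-20
admission value exceeds Year-1 × `f^19` by ~0.5 %; the source of that extra
growth is unstated and not modelled.

**Post-transplant (10-year).**  First-90-days base cost, plus the expected
complication add-on `Σ frequency_i x cost_i` over 15 complications (the
superficial-skin-infection entry is negative and handled with its sign),
plus ten annual immunosuppression payments escalated year by year
(`Σ_{k=1..10} $36,708 x f^k`).  Costs are conditional on 10-year survival —
the metric is per surviving patient, so no survival weighting is applied.

**National expenditure.**  Per-patient total (all three phases) times
*total* new listings — not the with-MELD subset — since excluded-by-
reporting patients still need livers.

## Uncertainty and sensitivity analysis

30,000 Monte Carlo iterations by default, single seeded NumPy generator,
inputs sampled independently (no correlation structure is published) in
fixed registry order, so runs are bit-reproducible given (seed, n).
Triangular rows sample with the base as **mode** (the spreadsheet-PSA
convention; whether the published "base" is mode or median is not stated —
mode is adopted and recorded here).  Uniform rows sample on [low, high].
Rows whose bounds are published only as "variable" resolve bounds from an
analogue row: the MELD > 40 monthly spending reuses the 30–39 row's
*relative* spread; the five per-category share changes reuse their
analogue's *additive* offsets (three of the five have bases identical to
their analogue, and additive offsets remain well-defined for near-zero or
negative rates where ratios are not).

Cost-metric analyses hold epidemiology growth inputs at base (the metrics
are per-patient costs, not national totals); `include_epidemiology=True`
enables joint sampling.  The 16 hospital line-item shares do not appear in
the deterministic admission formula, but they compose the fixed hospital
charge, so draws scale the hospital component by the ratio of sampled to
base share sums (ratio 1 at base, leaving the deterministic case unchanged).

*Certainty to base* is the fraction of draws at or above the deterministic
base case (ties count, so a fully degenerate model reports 100 %).  It falls
near 37 % for every Year-20 metric chiefly because the escalation-rate prior
is left-skewed (mean 4.51 % vs mode 4.9 %), which 19 years of compounding
amplifies into a ~5 % downward mean shift.

Sensitivity uses signed contribution-to-variance: `index_i = sign(ρ_i) ρ_i² /
Σ_j ρ_j²` with ρ the Spearman rank correlation of input i with the output,
computed per metric over the inputs that feed it.  A constant output has no
rank variance; its indices are reported as undefined (NaN), not zero.

## Scenario generation

`random_scenario(seed, s)` multiplies every base value (and its bounds,
proportionally, preserving low ≤ base ≤ high) by an independent factor in
[1−s, 1+s], then repairs structure rather than rejecting: share vectors are
renormalised, survival and cumulative-mortality schedules re-sorted
monotone, and unit-interval quantities clipped.  Generated tables pass the
full validator and run end-to-end.  The generator perturbs the *published*
aggregate world; it does not emulate registry microdata, patient-level
heterogeneity, or correlated shocks (e.g. a policy change moving listings
and severity together), so passing tests demonstrate structural robustness
of the pipeline, not calibration to any alternative real-world regime.
Perturbation is capped at ±50 %; beyond that, clipping would distort the
share vectors it is meant to preserve.

## Numerical choices and degenerate inputs

* Net factors use exact powers; no log-space approximation is needed at
  these magnitudes.
* The accrual geometric series switches to its `q → 1` limit (month count)
  when |q − 1| < 1e-12, so `r = d` is exact, not 0/0.
* Phase totals are defined as the literal float sum of the three phases, so
  additivity is machine-exact by construction.
* Validation errors are typed: missing/unknown parameter names, bound
  ordering (`RangeError`), and domain violations (`DomainError`, e.g.
  negative fractions, non-monotone schedules).  Unknown config keys are
  errors, never warnings.
* The bioengineered-liver ledger allows fractional vials (it prices cells,
  not packaging); rounding vials up would add $500 to the whole-liver total
  and break the published ledger identity.  Reprogramming is held constant
  across graft fractions and GMP status (the published figure is non-GMP;
  scaling under GMP is not stated).

## Problem sizes

The default analyses are small: 20 cohort-years of closed-form arithmetic,
and 30,000-draw Monte Carlo runs that vectorise to well under a minute on a
single core.  The test suite's property checks use 50 random scenarios at
64 draws each and convergence checks at 4,000/16,000 draws, which keeps the
full suite in the seconds-to-minutes range while still exercising every
stage end-to-end.

## Known limitations

* Cohort arithmetic only — no patient-level microsimulation, no
  cost-effectiveness (QALY) analysis, and no MELD stratification of
  admission or post-transplant costs (no published data).
* The with-MELD trajectory between anchor years is not published; `auto`
  mode mixes anchored and computed values and is therefore not smooth across
  2014/2020/2033 boundaries.
* Low-MELD pre-transplant costs at late listing years depend on an accrual
  convention the sources do not pin down; they are reported but should be
  read with ±20 % humility.
* Published waitlist inputs are taken as given; nothing is re-estimated from
  primary registries.
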