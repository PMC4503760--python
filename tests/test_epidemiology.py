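"""Cohort forecasting: listings growth, MELD mix, attrition, survival."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liverecon import epidemiology as epi
from liverecon.parameters import DomainError, MeldCategory as M, SimulationClock
from liverecon.scenarios import random_scenario

from conftest import override

CATS = list(M)


class TestNewListings:
    def test_reproduces_published_anchor_years(self, baseline, clock):
        assert round(epi.project_new_listings(baseline, clock, 1)) == 10_367
        assert round(epi.project_new_listings(baseline, clock, 20)) == 12_763

    def test_twenty_year_rise_is_23_percent(self, baseline, clock):
        y1 = epi.project_new_listings(baseline, clock, 1)
        y20 = epi.project_new_listings(baseline, clock, 20)
        assert round((y20 / y1 - 1) * 100) == 23

    def test_zero_growth_freezes_the_cohort(self, clock):
        params = override({"growth.new_listings": 0.0})
        for m in (1, 7, 20):
            assert epi.project_new_listings(params, clock, m) == 10_143

    def test_positive_growth_is_strictly_monotone(self, baseline, clock):
        series = [epi.project_new_listings(baseline, clock, m) for m in clock.model_years]
        assert all(b > a for a, b in zip(series, series[1:]))

    def test_out_of_range_model_year(self, baseline, clock):
        with pytest.raises(DomainError):
            epi.project_new_listings(baseline, clock, 0)


class TestMeldShares:
    def test_2012_returns_renormalized_baseline(self, baseline):
        shares = epi.evolve_meld_shares(baseline, 2012)
        base = baseline.meld_baseline_shares()
        norm = sum(base.values())
        for c in CATS:
            assert shares[c] == pytest.approx(base[c] / norm, rel=1e-12)

    def test_largest_category_shifts_from_10_19_to_20_29(self, baseline):
        s14 = epi.evolve_meld_shares(baseline, 2014)
        s33 = epi.evolve_meld_shares(baseline, 2033)
        assert max(s14, key=s14.get) is M.M10_19
        assert round(s14[M.M10_19] * 100) == 51
        assert max(s33, key=s33.get) is M.M20_29
        assert round(s33[M.M20_29] * 100) == 39

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000), year=st.integers(2012, 2045))
    def test_shares_always_sum_to_one(self, seed, year):
        params = random_scenario(seed, perturbation_scale=0.4).params
        shares = epi.evolve_meld_shares(params, year)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(v >= 0 for v in shares.values())


class TestWithMeldListings:
    def test_anchored_mode_returns_published_totals(self, baseline, bundle, clock):
        anchors = bundle.anchors
        assert epi.project_with_meld_listings(baseline, clock, 1, "anchored", anchors) == 7_934
        assert epi.project_with_meld_listings(baseline, clock, 7, "anchored", anchors) == 8_006
        assert epi.project_with_meld_listings(baseline, clock, 20, "anchored", anchors) == 7_600

    def test_anchored_mode_errors_without_an_anchor(self, baseline, bundle, clock):
        with pytest.raises(DomainError):
            epi.project_with_meld_listings(baseline, clock, 2, "anchored", bundle.anchors)

    def test_computed_mode_lands_within_1pct_of_2014_anchor(self, baseline, clock):
        computed = epi.project_with_meld_listings(baseline, clock, 1, "computed")
        assert computed == pytest.approx(7_934, rel=0.01)

    def test_auto_prefers_anchor_then_falls_back(self, baseline, bundle, clock):
        assert epi.project_with_meld_listings(baseline, clock, 1, "auto", bundle.anchors) == 7_934
        auto = epi.project_with_meld_listings(baseline, clock, 2, "auto", bundle.anchors)
        computed = epi.project_with_meld_listings(baseline, clock, 2, "computed")
        assert auto == computed


class TestCategoryCounts:
    def test_uniform_shares_split_evenly(self):
        shares = {c: 0.2 for c in CATS}
        counts = epi.meld_category_counts(shares, 100)
        assert all(v == pytest.approx(20) for v in counts.values())

    def test_published_category_swings(self, baseline):
        c14 = epi.meld_category_counts(epi.evolve_meld_shares(baseline, 2014), 7_934)
        c33 = epi.meld_category_counts(epi.evolve_meld_shares(baseline, 2033), 7_600)
        assert round((c33[M.LT9] / c14[M.LT9] - 1) * 100) == -55
        assert round((c33[M.GT40] / c14[M.GT40] - 1) * 100) == 76

    def test_negative_total_rejected(self):
        with pytest.raises(DomainError):
            epi.meld_category_counts({c: 0.2 for c in CATS}, -1)


class TestAttrition:
    def test_mortality_interpolates_linearly_from_zero(self, baseline):
        # 20 days into the 3-month horizon for the sickest category.
        got = epi.cumulative_waitlist_mortality(baseline, M.GT40, 20.0)
        assert got == pytest.approx(0.793 * 20.0 / (3 * 365 / 12), rel=1e-12)
        # Between the published 4- and 5-year knots for the mildest category.
        days = 1776.0
        t4, t5 = 4 * 365.0, 5 * 365.0
        expect = 0.076 + (0.084 - 0.076) * (days - t4) / (t5 - t4)
        assert epi.cumulative_waitlist_mortality(baseline, M.LT9, days) == pytest.approx(expect, rel=1e-12)

    def test_schedule_held_flat_beyond_last_horizon(self, baseline):
        assert epi.cumulative_waitlist_mortality(baseline, M.M20_29, 5_000.0) == 0.235

    def test_outcomes_partition_the_cohort(self, baseline, clock, bundle):
        cohort = epi.cohort_year(baseline, clock, 1, "auto", bundle.anchors)
        out = epi.waitlist_attrition(baseline, cohort)
        total = out.transplanted + out.died_or_severe_on_list + out.not_transplanted_other
        assert total == pytest.approx(out.listed, abs=1e-9)
        assert out.died_during_admission <= out.transplanted

    def test_zero_mortality_zero_dropout_means_everyone_transplants(self, clock):
        from liverecon.parameters import MORTALITY_HORIZONS

        overrides = {"attrition.pct_not_transplanted": {"kind": "fixed", "base": 0.0}}
        for c, horizons in MORTALITY_HORIZONS.items():
            for h in horizons:
                overrides[f"mortality.{c.slug}.{h}"] = 0.0
        params = override(overrides)
        cohort = epi.cohort_year(params, clock, 1)
        out = epi.waitlist_attrition(params, cohort)
        assert out.transplanted == pytest.approx(out.listed, rel=1e-12)

    def test_twenty_cohort_aggregate_matches_published_splits(self, baseline, clock, bundle):
        agg = epi.aggregate_attrition(baseline, clock, "auto", bundle.anchors)
        assert agg["frac_transplanted"] == pytest.approx(0.65, abs=0.03)
        assert agg["frac_not_transplanted_other"] == pytest.approx(0.18, abs=0.03)

    def test_negative_wait_rejected(self, baseline):
        with pytest.raises(DomainError):
            epi.cumulative_waitlist_mortality(baseline, M.LT9, -1.0)


class TestDownstream:
    def test_admission_outcomes_apply_published_fractions(self, baseline):
        out = epi.admission_outcomes(baseline, 100)
        assert out["died"] == pytest.approx(6.0)
        assert epi.admission_outcomes(baseline, 0) == {"died": 0.0, "retransplanted": 0.0}
        assert epi.admission_outcomes(baseline, 5_000)["retransplanted"] == pytest.approx(150.0)

    def test_survivors_follow_the_schedule(self, baseline):
        assert epi.survivors_at_year(baseline, 1_000, 10) == pytest.approx(630.0)
        assert epi.survivors_at_year(baseline, 1_000, 1) == pytest.approx(900.0)
        assert epi.survivors_at_year(baseline, 0, 5) == 0.0
        series = [epi.survivors_at_year(baseline, 1_000, k) for k in range(1, 11)]
        assert all(b <= a for a, b in zip(series, series[1:]))
        with pytest.raises(DomainError):
            epi.survivors_at_year(baseline, 10, 11)

    def test_mean_age_rises_toward_62(self, baseline):
        assert epi.mean_age_at_listing(baseline, 2014) == pytest.approx(57.7, abs=1.5)
        assert epi.mean_age_at_listing(baseline, 2033) == pytest.approx(62.0, abs=1.5)

    def test_single_age_group_returns_its_midpoint(self):
        overrides = {f"cohort.age_share.{g}": 0.0 for g in ("18_34", "35_49", "65plus")}
        overrides["cohort.age_share.50_64"] = 1.0
        overrides.update({f"growth.age_share.{g}": 0.0
                          for g in ("18_34", "35_49", "50_64", "65plus")})
        params = override(overrides)
        assert epi.mean_age_at_listing(params, 2025) == epi.AGE_MIDPOINTS["50_64"]


def test_three_year_forecast_matches_spreadsheet_arithmetic(baseline):
    """Brute-force cell-by-cell recomputation of a short horizon."""
    clock = SimulationClock(horizon_years=3)
    df = epi.forecast_cohorts(baseline, clock, mode="computed")
    for i, year in enumerate((2014, 2015, 2016)):
        t = year - 2012
        listings = 10_143 * 1.011 ** t
        no_meld = 0.094 * 1.076 ** t
        inactive = 0.129 * 0.995 ** t
        with_meld = listings * (1 - no_meld - inactive)
        assert df.loc[i, "new_listings"] == pytest.approx(listings, rel=1e-9)
        assert df.loc[i, "with_meld_listings"] == pytest.approx(with_meld, rel=1e-9)
        raw = {
            "lt9": 0.036 * 0.973 ** t,
            "10_19": 0.524 * 0.997 ** t,
            "20_29": 0.319 * 1.022 ** t,
            "30_39": 0.086 * 1.034 ** t,
            "gt40": 0.035 * 1.045 ** t,
        }
        norm = sum(raw.values())
        for slug, v in raw.items():
            assert df.loc[i, f"count_{slug}"] == pytest.approx(
                with_meld * v / norm, rel=1e-9
            )


def test_forecast_table_is_share_consistent(baseline, clock, bundle):
    df = epi.forecast_cohorts(baseline, clock, "auto", bundle.anchors)
    share_cols = [f"share_{c.slug}" for c in CATS]
    assert np.allclose(df[share_cols].sum(axis=1), 1.0, atol=1e-12)
    count_cols = [f"count_{c.slug}" for c in CATS]
    assert np.allclose(df[count_cols].sum(axis=1), df["with_meld_listings"], atol=0.5)
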