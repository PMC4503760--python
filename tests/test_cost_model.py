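"""Phase costs: escalation/discounting, severe vs accrual rules, totals."""

import math

import pytest

from liverecon import cost_model as cm
from liverecon.parameters import DomainError, MeldCategory as M

from conftest import override

SEVERE = (M.M20_29, M.M30_39, M.GT40)
ACCRUAL = (M.LT9, M.M10_19)


class TestEscalationFactor:
    def test_year_zero_is_unity(self):
        assert cm.escalation_factor(cm.EscalationRates(0.049, 0.03), 0) == 1.0

    @pytest.mark.parametrize("rate", [0.0, 0.03, 0.12])
    def test_equal_rates_cancel(self, rate):
        rates = cm.EscalationRates(rate, rate)
        for years in (1, 7, 19):
            assert cm.escalation_factor(rates, years) == pytest.approx(1.0, rel=1e-12)

    def test_nineteen_year_net_factor(self, baseline):
        factor = cm.escalation_factor(cm.EscalationRates.from_table(baseline), 19)
        assert factor == pytest.approx((1.049 / 1.03) ** 19, rel=1e-12)
        # The factor carries the severe-category Year-1 price to Year 20.
        assert 613_020 * factor == pytest.approx(867_564, rel=1e-3)

    def test_negative_years_rejected(self):
        with pytest.raises(DomainError):
            cm.escalation_factor(cm.EscalationRates(0.049, 0.03), -1)

    def test_rates_below_minus_one_rejected(self):
        with pytest.raises(DomainError):
            cm.EscalationRates(-1.5, 0.03)


class TestPreTransplant:
    def test_severe_rule_is_twelve_months_of_spending(self, baseline):
        assert cm.pre_lt_cost(baseline, M.GT40, 1) == 613_020.0  # 12 x 51,085

    def test_year20_severe_values_match_published(self, baseline):
        assert cm.pre_lt_cost(baseline, M.GT40, 20) == pytest.approx(867_564, rel=1e-3)
        assert cm.pre_lt_cost(baseline, M.M30_39, 20) == pytest.approx(537_402, rel=1e-3)

    def test_low_meld_values_within_wide_band(self, baseline):
        # The accrual convention behind these published values is
        # under-determined; agreement is only expected loosely.
        assert cm.pre_lt_cost(baseline, M.LT9, 1) == pytest.approx(49_407, rel=0.20)
        assert cm.pre_lt_cost(baseline, M.LT9, 20) == pytest.approx(71_621, rel=0.20)

    def test_severity_classification_follows_waiting_time(self, baseline):
        for c in SEVERE:
            assert cm.is_severe(baseline, c)
        for c in ACCRUAL:
            assert not cm.is_severe(baseline, c)

    def test_accrual_matches_month_by_month_ledger(self, baseline):
        """Closed-form geometric series vs an explicit monthly ledger."""
        for cat, band in ((M.LT9, "waiting_days.band_lt10"),
                          (M.M10_19, "waiting_days.band_11_18")):
            monthly = baseline.value(f"cost.monthly_pre_lt.{cat.slug}")
            last30 = baseline.value("cost.last30d_adjustment")
            ttt = baseline.value("growth.time_to_transplant")
            r, d = 0.049, 0.03
            f = (1 + r) / (1 + d)
            for year in (1, 7, 20):
                months = baseline.value(band) * (1 + ttt) ** (year - 1) / (365 / 12)
                ledger = 0.0
                m = 0
                while m < math.floor(months):
                    ledger += monthly * f ** (m / 12)
                    m += 1
                ledger += (months - math.floor(months)) * monthly * f ** (math.floor(months) / 12)
                ledger += last30 * f ** (months / 12)
                ledger *= f ** (year - 1)
                assert cm.pre_lt_cost(baseline, cat, year) == pytest.approx(ledger, rel=1e-9)

    def test_weighted_average_matches_published(self, baseline):
        assert cm.weighted_pre_lt_cost(baseline, 1) == pytest.approx(168_386, rel=0.03)
        assert cm.weighted_pre_lt_cost(baseline, 20) == pytest.approx(307_610, rel=0.05)

    def test_degenerate_weight_reduces_to_single_category(self, baseline):
        shares = {c: 0.0 for c in M}
        shares[M.GT40] = 1.0
        assert cm.weighted_pre_lt_cost(baseline, 1, shares) == cm.pre_lt_cost(baseline, M.GT40, 1)

    def test_listing_year_out_of_range(self, baseline):
        with pytest.raises(DomainError):
            cm.pre_lt_cost(baseline, M.GT40, 21)


class TestAdmission:
    def test_component_sum_without_casemix(self):
        overrides = {f"admission.frac.{n}": 0.0 for n in
                     ("retransplant", "hosp_not_icu", "icu", "donor_60plus",
                      "recipient_60plus", "ald", "child_pugh_c")}
        params = override(overrides)
        assert cm.admission_cost(params, 1) == pytest.approx(452_793, abs=0.5)

    def test_expected_casemix_uplift(self, baseline):
        assert cm.casemix_expected_uplift(baseline) == pytest.approx(0.3674, abs=1e-9)

    def test_year1_within_published_tolerance(self, baseline):
        assert cm.admission_cost(baseline, 1) == pytest.approx(588_580, rel=0.07)


class TestPostTransplant:
    def test_expected_complication_addon(self, baseline):
        # Hand-computed sum of frequency x added cost over the 15 rows,
        # including the negative skin-infection entry.
        assert cm.complication_expected_cost(baseline) == pytest.approx(131_993.1, abs=1.0)

    def test_year1_and_year20_within_tolerance(self, baseline):
        y1 = cm.post_lt_cost(baseline, 1)
        y20 = cm.post_lt_cost(baseline, 20)
        assert y1 == pytest.approx(670_839, rel=0.05)
        assert y20 == pytest.approx(949_391, rel=0.05)
        rates = cm.EscalationRates.from_table(baseline)
        assert y20 / y1 == pytest.approx(cm.escalation_factor(rates, 19), rel=1e-12)

    def test_negative_complication_reduces_cost_by_freq_times_cost(self, baseline):
        zeroed = override({"complication.skin_infection.cost":
                           {"kind": "fixed", "base": 0.0}})
        diff = cm.post_lt_cost(zeroed, 1) - cm.post_lt_cost(baseline, 1)
        assert diff == pytest.approx(0.16 * 2_883, rel=1e-9)


class TestTotals:
    def test_phase_total_is_exactly_additive(self, baseline):
        for year in (1, 10, 20):
            pc = cm.phase_costs(baseline, year)
            assert pc.total_per_patient == pc.pre_lt_weighted + pc.admission + pc.post_lt_10yr

    def test_published_components_sum_to_published_totals(self):
        assert 168_386 + 588_580 + 670_839 == 1_427_805
        y20 = cm.PhaseCosts(20, {}, 307_610, 836_788, 949_391)
        assert cm.total_per_patient(y20) == 2_093_789

    def test_national_expenditure_is_a_product(self):
        assert cm.national_expenditure(1_427_805, 10_367) == pytest.approx(14.8e9, rel=0.005)
        assert cm.national_expenditure(2_093_789, 12_763) == pytest.approx(26.7e9, rel=0.005)
        assert cm.national_expenditure(2_093_789, 0) == 0.0
        with pytest.raises(DomainError):
            cm.national_expenditure(-1.0, 10.0)

    def test_scaling_law_for_escalation_only_phases(self, baseline):
        rates = cm.EscalationRates.from_table(baseline)
        for t in (5, 13, 20):
            factor = cm.escalation_factor(rates, t - 1)
            for c in SEVERE:
                ratio = cm.pre_lt_cost(baseline, c, t) / cm.pre_lt_cost(baseline, c, 1)
                assert ratio == pytest.approx(factor, rel=1e-12)
            assert cm.admission_cost(baseline, t) / cm.admission_cost(baseline, 1) == pytest.approx(factor, rel=1e-12)
            assert cm.post_lt_cost(baseline, t) / cm.post_lt_cost(baseline, 1) == pytest.approx(factor, rel=1e-12)

    def test_discounting_monotonicity(self, baseline):
        higher_d = override({"rates.discount": 0.045})
        higher_r = override({"rates.cost_increase": 0.0604})
        for year in (2, 20):
            pc = cm.phase_costs(baseline, year)
            pc_d = cm.phase_costs(higher_d, year)
            pc_r = cm.phase_costs(higher_r, year)
            for attr in ("pre_lt_weighted", "admission", "post_lt_10yr"):
                assert getattr(pc_d, attr) <= getattr(pc, attr)
                assert getattr(pc_r, attr) >= getattr(pc, attr)

    def test_phase_cost_table_is_consistent(self, baseline):
        df = cm.phase_cost_table(baseline)
        assert len(df) == 20
        total = df["pre_lt_weighted"] + df["admission"] + df["post_lt_10yr"]
        assert (df["total_per_patient"] == total).all()
        assert (df["national_total"] == df["total_per_patient"] * df["demand"]).all()
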