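import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adhere.claims_io import DrugClass
from adhere.monthly_plot import (
    DrugType,
    PlotConfig,
    ReassignRule,
    build_monthly_grid,
    classify_tag,
    days_between,
    estimate_daily_dose,
)

from conftest import make_claim, make_patient, monthly_claims


class TestDaysBetween:
    @pytest.mark.parametrize(
        "d1, d2, expected",
        [
            (dt.date(2014, 1, 16), dt.date(2014, 4, 23), 97),
            (dt.date(2013, 2, 25), dt.date(2013, 5, 18), 82),
            (dt.date(2015, 6, 1), dt.date(2015, 6, 1), 0),
        ],
    )
    def test_start_exclusive_difference(self, d1, d2, expected):
        assert days_between(d1, d2) == expected

    def test_reversed_dates_rejected(self):
        with pytest.raises(ValueError):
            days_between(dt.date(2015, 2, 1), dt.date(2015, 1, 1))


class TestDailyDose:
    def stream(self, qty, gap_days, n=4, start=dt.date(2015, 1, 5)):
        return [
            make_claim(date=start + dt.timedelta(days=i * gap_days), qty=qty)
            for i in range(n)
        ]

    def test_sixty_units_per_thirty_days_snaps_to_two(self):
        assert estimate_daily_dose(self.stream(60, 30)) == 2.0

    def test_single_claim_defaults_to_one(self):
        assert estimate_daily_dose(self.stream(28, 30, n=1)) == 1.0

    def test_thirty_per_thirty_is_one(self):
        assert estimate_daily_dose(self.stream(30, 30)) == 1.0

    def test_one_gap_is_not_evidence(self):
        # an isolated 88-day delay must not halve the assumed dose
        assert estimate_daily_dose(self.stream(30, 88, n=2)) == 1.0

    def test_off_ratio_falls_back_to_default(self):
        # 30 units per ~43 days: no plausible dose within 20%
        assert estimate_daily_dose(self.stream(30, 43)) == 1.0

    def test_unstable_gaps_fall_back_to_default(self):
        dates = [dt.date(2015, 1, 1), dt.date(2015, 1, 11), dt.date(2015, 4, 20),
                 dt.date(2015, 4, 29), dt.date(2015, 9, 1)]
        claims = [make_claim(date=d, qty=60) for d in dates]
        assert estimate_daily_dose(claims) == 1.0


class TestGrid:
    def test_twelve_monthly_claims_populate_twelve_cells(self):
        p = make_patient(claims=monthly_claims("P1", [(2015, m) for m in range(1, 13)]))
        plot = build_monthly_grid(p, DrugType.MPH)
        populated = [i for i, c in enumerate(plot.months) if c.units_assigned]
        assert len(populated) == 12
        assert populated == list(range(36, 48))

    def test_short_supply_claim_is_flagged_not_counted(self):
        p = make_patient(claims=[make_claim(qty=7)])
        plot = build_monthly_grid(p, DrugType.MPH)
        cells = [c for c in plot.months if c.units_assigned]
        assert len(cells) == 1
        assert cells[0].short_supply_flag and not cells[0].counts_as_issue

    def test_rule1_moves_late_claim_into_empty_next_month(self):
        # stable monthly pattern; March holds the 2nd and the 28th, April empty
        months = [(2015, 1), (2015, 2)]
        claims = monthly_claims("P1", months)
        claims.append(make_claim(date=dt.date(2015, 3, 2)))
        claims.append(make_claim(date=dt.date(2015, 3, 28)))
        claims += monthly_claims("P1", [(2015, 5), (2015, 6)])
        plot = build_monthly_grid(make_patient(claims=claims), DrugType.MPH)
        assert max(c.n_issues for c in plot.months) == 1
        assert len(plot.decisions) == 1
        assert plot.decisions[0].rule is ReassignRule.RULE1

    def test_close_refills_without_trend_stay_put(self):
        claims = [
            make_claim(date=dt.date(2015, 3, 5)),
            make_claim(date=dt.date(2015, 3, 15), qty=60),
        ]
        plot = build_monthly_grid(make_patient(claims=claims), DrugType.MPH)
        assert not plot.decisions
        assert sum(c.n_issues for c in plot.months) == 2

    def test_rule2_attributes_early_refill_to_next_month(self):
        # regular 30/month trend, one early refill 18 days after the last
        claims = monthly_claims("P1", [(2015, 1), (2015, 2)])
        claims.append(make_claim(date=dt.date(2015, 3, 10)))
        claims.append(make_claim(date=dt.date(2015, 3, 28)))
        claims += monthly_claims("P1", [(2015, 5), (2015, 6)])
        plot = build_monthly_grid(make_patient(claims=claims), DrugType.MPH)
        assert len(plot.decisions) == 1
        assert plot.decisions[0].rule is ReassignRule.RULE2
        assert max(c.n_issues for c in plot.months) == 1

    def test_consolidated_grid_is_idempotent(self):
        p = make_patient(claims=monthly_claims("P1", [(2015, m) for m in range(1, 13)]))
        plot = build_monthly_grid(p, DrugType.MPH)
        assert plot.decisions == []

    @given(st.lists(st.tuples(st.integers(0, 59), st.integers(1, 27), st.integers(7, 90)),
                    min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_unit_conservation_under_reassignment(self, triples):
        claims = []
        for m, day, qty in triples:
            claims.append(
                make_claim(date=dt.date(2012 + m // 12, m % 12 + 1, min(day, 27)), qty=qty)
            )
        plot = build_monthly_grid(make_patient(claims=claims), DrugType.MPH)
        assert plot.total_units == sum(q for _, _, q in triples)
        for d in plot.decisions:
            assert abs(d.assigned_month - d.original_month) == 1


class TestTag:
    def grid(self, months_with_issue, pid="P1"):
        p = make_patient(pid=pid, claims=[
            make_claim(pid=pid, date=dt.date(2012 + m // 12, m % 12 + 1, 14))
            for m in months_with_issue
        ])
        return build_monthly_grid(p, DrugType.MPH)

    def test_twelve_consecutive_issues_qualify(self):
        t = classify_tag([self.grid(range(20, 32))])
        assert t.tag and t.total_monthly_issues == 12 and t.max_issues_in_any_12_months == 12

    def test_eleven_issues_fail_the_total_criterion(self):
        assert classify_tag([self.grid(range(20, 31))]).tag is False

    def test_sparse_issues_fail_and_only_or_policy_rescues(self):
        months = list(range(0, 60, 5))  # 12 issues, max 3 per rolling year
        t_and = classify_tag([self.grid(months)])
        assert t_and.total_monthly_issues == 12
        assert t_and.max_issues_in_any_12_months == 3
        assert t_and.tag is False
        t_or = classify_tag([self.grid(months)], PlotConfig(tag_policy="OR"))
        assert t_or.tag is True

    def test_rolling_window_matches_exhaustive_oracle(self):
        import random

        rng = random.Random(4)
        for _ in range(25):
            months = sorted(rng.sample(range(60), rng.randint(1, 30)))
            t = classify_tag([self.grid(months)])
            flags = [m in months for m in range(60)]
            oracle = max(sum(flags[i : i + 12]) for i in range(49))
            assert t.max_issues_in_any_12_months == oracle
            assert t.total_monthly_issues == len(months)

    def test_month_with_both_drug_types_counts_once(self):
        mph = self.grid(range(30, 40))
        p = make_patient(claims=[
            make_claim(code="FLX-20", name="fluoxetine", qty=30, strength=20,
                       drug_class=DrugClass.AD_SSRI,
                       date=dt.date(2012 + m // 12, m % 12 + 1, 16))
            for m in range(30, 40)
        ])
        ad = build_monthly_grid(p, DrugType.AD)
        t = classify_tag([mph, ad])
        assert t.total_monthly_issues == 10

    def test_adding_an_issue_never_revokes_tag(self):
        base = list(range(20, 33))
        with_tag = classify_tag([self.grid(base)])
        assert with_tag.tag
        more = classify_tag([self.grid(base + [50])])
        assert more.tag
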