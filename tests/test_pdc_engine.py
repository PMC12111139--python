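import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adhere.pdc_engine import (
    AssessmentPeriod,
    CoverageInterval,
    PdcConfig,
    average_pdc,
    compute_pdd,
    coverage_intervals,
    covered_days,
    predict_next_supply,
    segment_periods,
)

from conftest import make_claim


def ivs(date_supply_pairs):
    return [
        CoverageInterval(start=dt.date.fromisoformat(d), supply_days=s)
        for d, s in date_supply_pairs
    ]


def brute_force_covered(start, end, issues):
    days = set()
    for iv in issues:
        d = iv.start
        for _ in range(iv.supply_days):
            if start <= d < end:
                days.add(d)
            d += dt.timedelta(days=1)
    return len(days)


class TestPredictNextSupply:
    @pytest.mark.parametrize(
        "issue, supply, expected",
        [
            ("2014-03-20", 30, "2014-04-19"),
            ("2014-10-30", 30, "2014-11-29"),
        ],
    )
    def test_calculated_proceeding_supply_date(self, issue, supply, expected):
        got = predict_next_supply(dt.date.fromisoformat(issue), supply)
        assert got == dt.date.fromisoformat(expected)

    def test_supply_floor_is_one_day(self):
        d = dt.date(2015, 1, 1)
        assert predict_next_supply(d, 0) == d + dt.timedelta(days=1)


class TestCoveredDays:
    def test_terminal_two_issue_stream_covers_57_days(self):
        issues = ivs([("2016-11-02", 30), ("2016-12-05", 30)])
        assert covered_days(dt.date(2016, 11, 2), dt.date(2017, 1, 1), issues) == 57

    def test_single_supply_inside_period(self):
        issues = ivs([("2015-02-01", 30)])
        assert covered_days(dt.date(2015, 2, 1), dt.date(2015, 5, 2), issues) == 30

    def test_fully_overlapping_supplies_do_not_double_count(self):
        issues = ivs([("2015-02-01", 30), ("2015-02-01", 30)])
        start, end = dt.date(2015, 2, 1), dt.date(2015, 5, 2)
        assert covered_days(start, end, issues) == 30
        assert covered_days(start, end, issues) == brute_force_covered(start, end, issues)

    @given(
        st.lists(st.tuples(st.integers(0, 400), st.integers(1, 120)), min_size=0, max_size=15),
        st.integers(0, 200),
        st.integers(1, 400),
    )
    @settings(max_examples=120, deadline=None)
    def test_union_matches_day_enumeration_oracle(self, pairs, start_off, length):
        base = dt.date(2014, 1, 1)
        issues = [
            CoverageInterval(start=base + dt.timedelta(days=o), supply_days=s)
            for o, s in pairs
        ]
        start = base + dt.timedelta(days=start_off)
        end = start + dt.timedelta(days=length)
        assert covered_days(start, end, issues) == brute_force_covered(start, end, issues)


class TestSegmentation:
    def periods_for(self, worked_records, pid):
        rec = worked_records[pid]
        return segment_periods(coverage_intervals(rec.claims), PdcConfig())

    def test_coverage_overrun_extends_to_the_next_issue(self, worked_records):
        first = self.periods_for(worked_records, "WX-A")[0]
        assert first.duration_days == 97

    def test_delayed_refill_without_successor_extends_to_supply_end(self, worked_records):
        (only,) = self.periods_for(worked_records, "WX-B")
        assert only.duration_days == 118
        assert only.covered == 60

    def test_late_fourth_issue_of_regular_pattern_closes_at_125(self, worked_records):
        first = self.periods_for(worked_records, "WX-C")[0]
        assert first.duration_days == 125

    def test_empty_month_closes_the_period_early_at_82(self, worked_records):
        ps = self.periods_for(worked_records, "WX-D")
        assert ps[0].duration_days == 82
        assert ps[1].duration_days == 91 and ps[1].covered == 60

    def test_terminal_period_truncates_at_database_end(self, worked_records):
        (only,) = self.periods_for(worked_records, "WX-E")
        assert only.duration_days == 60 and only.covered == 57

    def test_empty_stream_segments_to_nothing(self):
        assert segment_periods([], PdcConfig()) == []

    def test_refill_gap_opens_a_new_episode(self):
        issues = ivs([("2013-01-10", 30), ("2014-06-10", 30), ("2014-07-12", 30)])
        ps = segment_periods(issues, PdcConfig())
        assert len(ps) == 2
        assert ps[0].start == dt.date(2013, 1, 10) and ps[0].duration_days == 90
        assert ps[1].start == dt.date(2014, 6, 10)

    @given(
        st.lists(st.tuples(st.integers(0, 1700), st.integers(10, 120), st.integers(15, 90)),
                 min_size=1, max_size=25)
    )
    @settings(max_examples=100, deadline=None)
    def test_totality_and_duration_bounds(self, triples):
        base = dt.date(2012, 1, 5)
        issues = sorted(
            (CoverageInterval(start=base + dt.timedelta(days=o), supply_days=s,
                              quantity_units=q)
             for o, s, q in triples),
            key=lambda iv: iv.start,
        )
        cfg = PdcConfig()
        periods = segment_periods(issues, cfg)
        assert periods
        # non-overlapping, ordered
        for a, b in zip(periods, periods[1:]):
            assert a.end <= b.start
        for p in periods:
            assert 1 <= p.duration_days <= 129
            assert 0 <= p.covered <= p.duration_days
        # every issue falls in exactly one period
        for iv in issues:
            owners = [p for p in periods if p.start <= iv.start < p.end]
            if not owners:
                owners = [p for p in periods if p.start == iv.start]
            assert len(owners) == 1
        # only a terminal / pre-gap close may be shorter than 60 days
        for p in periods[:-1]:
            assert p.duration_days >= 60


class TestAveragePdc:
    def test_unweighted_mean(self):
        mk = lambda pdc: AssessmentPeriod(
            start=dt.date(2015, 1, 1),
            end=dt.date(2015, 1, 1) + dt.timedelta(days=100),
            covered=int(100 * pdc),
            rule=None,
        )
        assert average_pdc([mk(0.95), mk(0.55)]) == pytest.approx(0.75)

    def test_no_periods_reported_missing_not_zero(self):
        assert average_pdc([]) is None

    def test_perfect_refills_average_to_one(self):
        # 30-day refills with no gaps across ~2.5 years
        base = dt.date(2013, 1, 10)
        issues = [
            CoverageInterval(start=base + dt.timedelta(days=30 * i), supply_days=30)
            for i in range(30)
        ]
        periods = segment_periods(issues, PdcConfig())
        assert len(periods) >= 10
        assert average_pdc(periods) == pytest.approx(1.0, abs=0.01)

    def test_deleting_claims_never_raises_mean_pdc(self):
        base = dt.date(2013, 1, 10)
        full = [
            CoverageInterval(start=base + dt.timedelta(days=30 * i), supply_days=30)
            for i in range(20)
        ]
        cfg = PdcConfig()
        full_mean = average_pdc(segment_periods(full, cfg))
        import random

        rng = random.Random(9)
        for _ in range(10):
            kept = [iv for iv in full if rng.random() > 0.3] or full[:1]
            assert average_pdc(segment_periods(kept, cfg)) <= full_mean + 1e-12


class TestPdd:
    def test_three_monthly_scripts_at_ten_mg(self):
        claims = [make_claim(strength=10, qty=30) for _ in range(3)]
        r = compute_pdd(claims, 90)
        assert r.pdd_mg_per_day == pytest.approx(10.0)

    def test_sixty_units_over_twenty_days(self):
        claims = [make_claim(strength=10, qty=60)]
        r = compute_pdd(claims, 20, ddd_mg=30)
        assert r.pdd_mg_per_day == pytest.approx(30.0)
        assert r.ratio_to_ddd == pytest.approx(1.0)

    def test_zero_covered_days_reported_missing(self):
        assert compute_pdd([make_claim()], 0) is None
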