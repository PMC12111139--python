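from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adhere.stats import (
    ContingencyTable2x2,
    age_band,
    dichotomise_pdc,
    fisher_exact,
    fit_tag_logistic,
    month_proportions,
)
from adhere.synthetic_claims import simulate_tag_design


def fisher_enumeration_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration with exact integer ordering."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    obs = comb(r1, a) * comb(r2, c)
    num = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = comb(r1, x) * comb(r2, c1 - x)
        if p <= obs:
            num += p
    return num / comb(n, c1)


class TestFisher:
    def test_symmetric_table_gives_one(self):
        assert fisher_exact(ContingencyTable2x2(5, 5, 5, 5)) == 1.0

    def test_two_by_two_identity_table(self):
        # only two tables share these margins; both are equally probable
        assert fisher_exact(ContingencyTable2x2(1, 0, 0, 1)) == pytest.approx(1.0)
        assert fisher_enumeration_oracle(1, 0, 0, 1) == 1.0

    def test_zero_margin_convention(self):
        assert fisher_exact(ContingencyTable2x2(0, 0, 3, 4)) == 1.0

    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15))
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            return
        p = fisher_exact(ContingencyTable2x2(a, b, c, d))
        assert p == pytest.approx(fisher_enumeration_oracle(a, b, c, d), abs=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestDichotomise:
    def test_simple_split(self):
        pdc = pd.Series({"A": 0.9, "B": 0.7})
        grp = pd.Series({"A": True, "B": True})
        table, n_missing = dichotomise_pdc(pdc, grp)
        assert (table.a, table.b) == (1, 1) and n_missing == 0

    def test_threshold_is_inclusive(self):
        pdc = pd.Series({"A": 0.8, "B": 0.8})
        grp = pd.Series({"A": True, "B": False})
        table, _ = dichotomise_pdc(pdc, grp, threshold=0.8)
        assert table.b == 0 and table.d == 0
        assert table.a == 1 and table.c == 1

    def test_missing_pdc_dropped_and_counted(self):
        pdc = pd.Series({"A": 0.9, "B": np.nan, "C": 0.5})
        grp = pd.Series({"A": True, "B": True, "C": False})
        table, n_missing = dichotomise_pdc(pdc, grp)
        assert n_missing == 1
        assert table.total == 2


class TestLogistic:
    def test_single_binary_covariate_reproduces_table_odds_ratio(self):
        # a=30 exposed/adherent, b=10, c=15, d=25 -> OR = ad/bc = 5
        rows = []
        for exposed, tag, k in ((1, 1, 30), (1, 0, 10), (0, 1, 15), (0, 0, 25)):
            rows += [{"exposure": bool(exposed), "tag": bool(tag)}] * k
        df = pd.DataFrame(rows)
        fit = fit_tag_logistic(df[["exposure"]], df["tag"].tolist())
        assert fit.status == "ok"
        assert fit.odds_ratios["exposure"] == pytest.approx((30 * 25) / (10 * 15), rel=1e-4)

    def test_constant_outcome_is_degenerate_status(self):
        df = pd.DataFrame({"exposure": [True, False] * 20})
        fit = fit_tag_logistic(df, [True] * 40)
        assert fit.status == "degenerate_outcome"

    def test_null_covariate_recovers_unit_odds_ratio(self):
        df = simulate_tag_design(n=500, seed=17, or_ad=1.0)
        fit = fit_tag_logistic(df[["ad_cotherapy", "null_cov"]], df["tag"].tolist())
        assert fit.status == "ok"
        assert 0.7 < fit.odds_ratios["ad_cotherapy"] < 1.4
        assert 0.7 < fit.odds_ratios["null_cov"] < 1.4

    def test_type3_lrt_invariant_to_covariate_order(self):
        df = simulate_tag_design(n=400, seed=3, or_ad=4.0)
        cols = ["ad_cotherapy", "null_cov"]
        f1 = fit_tag_logistic(df[cols], df["tag"].tolist())
        f2 = fit_tag_logistic(df[list(reversed(cols))], df["tag"].tolist())
        for term in cols:
            assert f1.type3_lrt_p[term] == pytest.approx(f2.type3_lrt_p[term], rel=1e-6)

    def test_separation_is_flagged_not_raised(self):
        df = pd.DataFrame({"exposure": [True] * 20 + [False] * 20})
        outcome = [True] * 20 + [False] * 20
        fit = fit_tag_logistic(df, outcome)
        assert fit.status == "separation"


class TestAgeBand:
    @pytest.mark.parametrize(
        "age, band",
        [(20.2, "20-24"), (24.9, "20-24"), (25.0, "25-29"), (33.5, "30-34"), (39.0, "35-39")],
    )
    def test_banding(self, age, band):
        assert age_band(age) == band


class TestMonthProportions:
    def test_equal_months_split_evenly(self):
        props, mean_mph, mean_ad, _ = month_proportions([("A", 10, 10)])
        assert props[0].mph_share == 0.5 and mean_ad == 0.5

    def test_five_ad_months_per_mph_month(self):
        props, _, _, _ = month_proportions([("A", 1, 5)])
        assert props[0].ad_share * 100 == pytest.approx(83.33, abs=0.01)

    def test_single_type_patient(self):
        props, _, _, _ = month_proportions([("A", 12, 0)])
        assert props[0].mph_share == 1.0 and props[0].ad_share == 0.0

    def test_zero_month_patient_excluded(self):
        props, mean_mph, mean_ad, n_excluded = month_proportions([("A", 0, 0), ("B", 3, 1)])
        assert n_excluded == 1 and len(props) == 1

    @given(st.lists(st.tuples(st.integers(0, 40), st.integers(0, 40)), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_shares_sum_to_one_and_means_bounded(self, pairs):
        rows = [(f"P{i}", m, a) for i, (m, a) in enumerate(pairs)]
        props, mean_mph, mean_ad, _ = month_proportions(rows)
        for p in props:
            assert p.mph_share + p.ad_share == pytest.approx(1.0)
        if props:
            shares = [p.mph_share for p in props]
            assert min(shares) - 1e-12 <= mean_mph <= max(shares) + 1e-12
            assert mean_mph + mean_ad == pytest.approx(1.0)
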