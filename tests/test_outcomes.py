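"""Survival estimation, rank/exact tests, FGA, summary tables, risk rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecmil.outcomes import (
    cohort_summary,
    count_changes,
    cox_ph,
    fisher_exact,
    fraction_genome_altered,
    km_at,
    km_estimate,
    logrank_test,
    mann_whitney_u,
    reassign_risk_group,
)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survivor(self, rng):
        times = rng.exponential(2.0, size=50)
        curve = km_estimate(times, np.ones(50, dtype=int))
        for t in curve.times:
            assert km_at(curve, t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_half_events_gives_half_survival(self):
        # 10 subjects, 5 events by t=5, no censoring
        times = [1, 2, 3, 4, 5, 10, 11, 12, 13, 14]
        curve = km_estimate(times, [1] * 10)
        assert km_at(curve, 5.0) == pytest.approx(0.5)

    def test_all_censored_is_flat_one(self):
        curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert all(km_at(curve, t) == 1.0 for t in (0.5, 2.0, 10.0))

    def test_product_limit_hand_computation(self):
        # times 1, 2+, 3: S(3) = (1 - 1/3)(1 - 1/1) = 0
        curve = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert km_at(curve, 0.5) == 1.0
        assert km_at(curve, 1.0) == pytest.approx(2 / 3)
        assert km_at(curve, 3.0) == pytest.approx(0.0)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            km_estimate([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_zero_statistic(self):
        t, e = [1.0, 2.0, 3.0], [1, 0, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_event_closed_form(self):
        # one event time, equal at-risk (2 vs 2), single event in A:
        # O - E = 1 - 1/2; V = hypergeometric variance = (1*2*2*3)/(4^2*3)=1/4
        chi2, _ = logrank_test([1.0, 5.0], [1, 0], [5.0, 5.0], [0, 0])
        o_minus_e = 1 - 2 / 4
        v = (1 * (4 - 1) * 2 * 2) / (4**2 * (4 - 1))
        assert chi2 == pytest.approx(o_minus_e**2 / v)

    def test_label_exchangeability(self, rng):
        ta, tb = rng.exponential(1, 20), rng.exponential(2, 25)
        ea, eb = np.ones(20, int), np.ones(25, int)
        assert logrank_test(ta, ea, tb, eb)[0] == pytest.approx(
            logrank_test(tb, eb, ta, ea)[0])

    def test_time_rescaling_invariance(self, rng):
        ta, tb = rng.exponential(1, 15), rng.exponential(3, 15)
        ea = rng.integers(0, 2, 15)
        eb = np.ones(15, int)
        c1 = logrank_test(ta, ea, tb, eb)
        c2 = logrank_test(ta * 365.25, ea, tb * 365.25, eb)
        assert c1[0] == pytest.approx(c2[0], rel=1e-9)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_test([1.0], [0], [2.0], [0])


class TestCox:
    def test_recovers_known_hazard_ratio(self):
        rng = np.random.default_rng(0)
        n = 1000
        x = rng.integers(0, 2, n)
        lam = 0.1 * np.exp(np.log(2.0) * x)
        df = pd.DataFrame({
            "time": rng.exponential(1 / lam), "event": 1, "x": x,
        })
        out = cox_ph(df, "time", "event", ["x"])
        assert 1.7 <= out.loc["x", "hazard_ratio"] <= 2.35

    def test_sign_flip_gives_reciprocal_hr(self):
        rng = np.random.default_rng(1)
        n = 300
        x = rng.integers(0, 2, n)
        df = pd.DataFrame({
            "time": rng.exponential(1 / (0.1 * np.exp(0.7 * x))),
            "event": 1, "x": x, "xr": 1 - x,
        })
        hr = cox_ph(df, "time", "event", ["x"]).loc["x", "hazard_ratio"]
        hr_r = cox_ph(df, "time", "event", ["xr"]).loc["xr", "hazard_ratio"]
        assert hr == pytest.approx(1 / hr_r, rel=1e-6)

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1], "x": [1, 1]})
        with pytest.raises(ValueError, match="constant"):
            cox_ph(df, "time", "event", ["x"])


class TestExactTests:
    def test_fisher_balanced_table(self):
        odds, p = fisher_exact([[5, 5], [5, 5]])
        assert odds == 1.0 and p == 1.0

    def test_fisher_diagonal_matches_enumeration(self):
        from math import comb
        _, p = fisher_exact([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-12)

    def test_fisher_transpose_invariant(self):
        t = [[7, 2], [3, 9]]
        assert fisher_exact(t)[1] == pytest.approx(
            fisher_exact(np.transpose(t))[1])

    def test_fisher_negative_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [0, 2]])

    def test_mwu_exact_enumeration(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)  # 2 of 6 rank assignments as extreme

    def test_mwu_identical_samples(self):
        u, p = mann_whitney_u([1, 2, 2, 3], [1, 2, 2, 3])
        assert p == pytest.approx(1.0)

    def test_mwu_swap_symmetry(self, rng):
        x, y = rng.normal(size=12), rng.normal(1, 1, size=9)
        ux, px = mann_whitney_u(x, y)
        uy, py = mann_whitney_u(y, x)
        assert ux + uy == pytest.approx(12 * 9)
        assert px == pytest.approx(py)


class TestFGA:
    def _seg(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                           "log2ratio", "altered_flag"])

    def test_trivial_fractions(self):
        neutral = self._seg([("chr1", 0, 100, 0.0, 0), ("chr1", 100, 200, 0.0, 0)])
        assert fraction_genome_altered(neutral) == 0.0
        flagged = neutral.assign(altered_flag=1)
        assert fraction_genome_altered(flagged) == 1.0
        half = self._seg([("chr1", 0, 100, 0.5, 1), ("chr1", 100, 200, 0.0, 0)])
        assert fraction_genome_altered(half) == 0.5

    def test_threshold_on_log2ratio(self):
        seg = self._seg([("chr1", 0, 100, 0.21, 0), ("chr1", 100, 200, 0.19, 0)])
        assert fraction_genome_altered(seg, threshold=0.2) == 0.5

    @given(split=st.integers(1, 99))
    @settings(max_examples=25, deadline=None)
    def test_split_invariance(self, split):
        whole = self._seg([("chr1", 0, 100, 0.5, 1), ("chr1", 100, 200, 0.0, 0)])
        parts = self._seg([
            ("chr1", 0, split, 0.5, 1), ("chr1", split, 100, 0.5, 1),
            ("chr1", 100, 200, 0.0, 0),
        ])
        assert fraction_genome_altered(parts) == pytest.approx(
            fraction_genome_altered(whole))

    def test_empty_and_overlapping_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fraction_genome_altered(self._seg([]))
        overlap = self._seg([("chr1", 0, 100, 0.0, 0), ("chr1", 50, 150, 0.0, 0)])
        with pytest.raises(ValueError, match="overlap"):
            fraction_genome_altered(overlap)


class TestCohortSummary:
    def test_single_class_full_percentage(self):
        df = pd.DataFrame({"subtype": ["NSMP"] * 3, "grade": ["G3"] * 3})
        out = cohort_summary(df, ["grade"])
        cell = out[(out.variable == "grade") & (out.level == "G3")]["NSMP"].iloc[0]
        assert cell == "3 (100.00%)"

    def test_column_percentages_sum_to_100(self, rng):
        df = pd.DataFrame({
            "subtype": rng.choice(["NSMP", "p53abn"], 200),
            "grade": rng.choice(["G1-2", "G3"], 200),
            "stage": rng.choice(["I-II", "III-IV", None], 200),
        })
        out = cohort_summary(df, ["grade", "stage"])
        for col in ("NSMP", "p53abn", "Total"):
            for var in ("grade", "stage"):
                cells = out[out.variable == var][col]
                total = sum(float(c.split("(")[1].rstrip("%)")) for c in cells)
                assert total == pytest.approx(100.0, abs=0.02)

    def test_absent_variable_rejected(self):
        df = pd.DataFrame({"subtype": ["NSMP"]})
        with pytest.raises(ValueError, match="absent"):
            cohort_summary(df, ["grade"])

    def test_unknown_level_included_in_totals(self):
        df = pd.DataFrame({"subtype": ["NSMP", "NSMP", "p53abn"],
                           "stage": ["I-II", None, "I-II"]})
        out = cohort_summary(df, ["stage"])
        unk = out[(out.variable == "stage") & (out.level == "Unknown")]
        assert unk["NSMP"].iloc[0] == "1 (50.00%)"


class TestRiskReassignment:
    @pytest.mark.parametrize("current, refined, expected", [
        ("Low", "p53abn-like NSMP", ("High", True)),
        ("Intermediate", "p53abn-like NSMP", ("High", True)),
        ("High-intermediate", "p53abn-like NSMP", ("High", True)),
        ("High", "p53abn-like NSMP", ("High", False)),
        ("Advanced metastatic", "p53abn-like NSMP", ("Advanced metastatic", False)),
        ("Intermediate", "NSMP", ("Intermediate", False)),
        ("Low", "p53abn", ("Low", False)),
    ])
    def test_rules(self, current, refined, expected):
        assert reassign_risk_group(current, refined) == expected

    def test_non_myoinvasive_not_upstaged(self):
        assert reassign_risk_group("Intermediate", "p53abn-like NSMP",
                                   myoinvasive=False) == ("Intermediate", False)

    def test_unknown_risk_group_rejected(self):
        with pytest.raises(ValueError, match="unknown risk group"):
            reassign_risk_group("Medium", "p53abn-like NSMP")

    def test_count_changes_sums_flags(self):
        cases = [("Low", "p53abn-like NSMP"), ("High", "p53abn-like NSMP"),
                 ("Intermediate", "NSMP")]
        assert count_changes(cases) == 1
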