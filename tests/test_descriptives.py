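"""Univariate testing machinery against independent oracles: closed-form
brute force for t and chi-square, full enumeration for Fisher and the
rank-sum, and the published summary statistics it must reproduce."""

import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from xyyphen.descriptives import (
    ClassificationRule,
    DegenerateInputError,
    classify_delays_and_sld,
    fisher_exact,
    gated_group_contrast,
    iq_band,
    one_sample_t,
    pearson_chi_square,
    summarize_variable,
    two_sample_t,
    wilcoxon_rank_sum,
)


# ---------------------------------------------------------------- oracles
def fisher_p_enumeration(table) -> float:
    """Two-sided Fisher p by brute-force enumeration of all 2x2 tables
    with the observed margins, summing hypergeometric probabilities no
    larger than the observed table's."""
    t = np.asarray(table, dtype=int)
    r0, r1 = t.sum(axis=1)
    c0 = t[:, 0].sum()
    n = t.sum()
    p_obs = stats.hypergeom.pmf(t[0, 0], n, r0, c0)
    total = 0.0
    for a in range(max(0, c0 - r1), min(r0, c0) + 1):
        p = stats.hypergeom.pmf(a, n, r0, c0)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def rank_sum_p_enumeration(a, b) -> float:
    """Exact two-sided rank-sum p over every group assignment."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    s_obs = ranks[:n_a].sum()
    sums = [sum(ranks[list(c)]) for c in combinations(range(len(pooled)), n_a)]
    sums = np.array(sums)
    p_lo = np.mean(sums <= s_obs + 1e-12)
    p_hi = np.mean(sums >= s_obs - 1e-12)
    return min(1.0, 2 * min(p_lo, p_hi))


# ---------------------------------------------------------- summarization
class TestSummarize:
    def test_all_missing_raises(self):
        with pytest.raises(DegenerateInputError):
            summarize_variable([np.nan, np.nan, np.nan])

    def test_constant_column_raises(self):
        with pytest.raises(DegenerateInputError):
            summarize_variable([4.0, 4.0, 4.0, 4.0])

    def test_nominal_false_positive_rate_on_normal_data(self, rng):
        flags = [summarize_variable(rng.normal(100, 15, 64)).is_normal for _ in range(200)]
        assert np.mean(flags) > 0.90  # about 95% should pass the gate

    def test_high_power_against_lognormal_milestones(self, rng):
        flags = [
            summarize_variable(np.exp(rng.normal(np.log(24), 0.51, 64))).is_normal
            for _ in range(500)
        ]
        assert np.mean(flags) < 0.10


# -------------------------------------------------------------- t tests
class TestOneSampleT:
    @pytest.mark.parametrize(
        "mean, sd, n, mu0, t_expected, df_expected",
        [
            (76.22, 12.95, 64, 100, 14.69, 63),  # adaptive-behavior composite
            (91.81, 15.56, 64, 100, 4.21, 63),   # nonverbal IQ
            (85.89, 14.18, 63, 100, 7.90, 62),   # verbal IQ
            (66.21, 7.86, 62, 50, 16.24, 61),    # SRS-2 total T vs 50
        ],
    )
    def test_reproduces_published_cohort_statistics(self, mean, sd, n, mu0,
                                                    t_expected, df_expected):
        res = one_sample_t(mean, sd, n, mu0)
        assert round(abs(res.statistic), 2) == t_expected
        assert res.df == df_expected

    def test_null_gives_t_zero_p_one(self):
        res = one_sample_t(50.0, 5.0, 30, 50.0)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            one_sample_t(1.0, 0.0, 10, 0.0)
        with pytest.raises(DegenerateInputError):
            one_sample_t(1.0, 1.0, 1, 0.0)


class TestTwoSampleT:
    def test_identical_groups(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = two_sample_t(x, x)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_matches_independent_welch_oracle(self, rng):
        for _ in range(50):
            a = rng.normal(0, 1, rng.integers(3, 30))
            b = rng.normal(0.5, 2, rng.integers(3, 30))
            res = two_sample_t(a, b, variance_rule="welch")
            t_ref, p_ref = stats.ttest_ind(a, b, equal_var=False)
            assert abs(res.statistic - t_ref) < 1e-10
            assert abs(res.p - p_ref) < 1e-10

    def test_matches_independent_pooled_oracle(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 18)
        res = two_sample_t(a, b, variance_rule="pooled")
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert abs(res.statistic - t_ref) < 1e-10
        assert res.df == len(a) + len(b) - 2

    def test_satterthwaite_df_below_pooled_under_unequal_variance(self, rng):
        a = rng.normal(0, 10, 20)
        b = rng.normal(0, 1, 20)
        res = two_sample_t(a, b, variance_rule="welch")
        assert res.df < len(a) + len(b) - 2
        assert res.df != int(res.df)  # fractional, as reported in tables

    def test_folded_f_switches_to_satterthwaite(self, rng):
        a = rng.normal(0, 10, 25)
        b = rng.normal(0, 1, 25)
        assert two_sample_t(a, b).method == "Satterthwaite t"
        c = rng.normal(0, 1, 25)
        assert two_sample_t(b, c).method == "pooled t"

    def test_zero_variance_group_raises_under_folded_f(self):
        with pytest.raises(DegenerateInputError, match="variance"):
            two_sample_t([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# -------------------------------------------------------------- Wilcoxon
class TestWilcoxon:
    def test_tiny_exact_enumeration(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert abs(res.p - 2 / 6) < 1e-12
        assert "exact" in res.method

    def test_identical_groups_z_zero(self):
        res = wilcoxon_rank_sum([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])
        assert res.statistic == 0.0

    def test_all_tied_warns(self):
        with pytest.warns(UserWarning, match="tied"):
            res = wilcoxon_rank_sum([2, 2, 2], [2, 2, 2])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            a = rng.normal(size=rng.integers(2, 6))
            b = rng.normal(size=rng.integers(2, 6))
            res = wilcoxon_rank_sum(a, b)
            assert abs(res.p - rank_sum_p_enumeration(a, b)) < 1e-10

    def test_exact_and_normal_paths_agree_at_small_n(self, rng):
        for _ in range(200):
            a, b = rng.normal(size=5), rng.normal(rng.normal(), 1, 5)
            p_exact = wilcoxon_rank_sum(a, b).p
            p_normal = wilcoxon_rank_sum(a, b, exact_max_n=0).p
            assert abs(p_exact - p_normal) < 0.02

    def test_agrees_with_permutation_oracle_at_study_sizes(self, rng):
        a = rng.normal(0.0, 1, 25)
        b = rng.normal(0.5, 1, 39)
        res = wilcoxon_rank_sum(a, b)
        ranks = stats.rankdata(np.concatenate([a, b]))
        e = 25 * 65 / 2
        s_obs = ranks[:25].sum()
        n_perm = 10_000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(64)
            count += abs(ranks[perm[:25]].sum() - e) >= abs(s_obs - e) - 1e-9
        p_perm = count / n_perm
        se = math.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res.p - p_perm) < 0.01 + 3 * se


# ---------------------------------------------------- categorical tests
class TestChiSquare:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[7, 18], [15, 24]], 0.74),   # prior community ASD diagnosis
            ([[10, 15], [12, 27]], 0.58),  # early intervention
            ([[14, 11], [30, 9]], 3.10),   # speech therapy
        ],
    )
    def test_reproduces_published_contingency_statistics(self, table, expected):
        res = pearson_chi_square(table)
        assert round(res.statistic, 2) == expected
        assert res.df == 1.0

    def test_identical_row_proportions_give_zero(self):
        assert pearson_chi_square([[10, 20], [20, 40]]).statistic < 1e-12

    def test_zero_margin_directs_to_fisher(self):
        with pytest.raises(DegenerateInputError, match="fisher"):
            pearson_chi_square([[0, 5], [0, 7]])

    @given(
        a=st.integers(1, 30), b=st.integers(1, 30),
        c=st.integers(1, 30), d=st.integers(1, 30),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_label_swaps(self, a, b, c, d):
        t = [[a, b], [c, d]]
        base = pearson_chi_square(t).statistic
        assert abs(pearson_chi_square([[c, d], [a, b]]).statistic - base) < 1e-10
        assert abs(pearson_chi_square([[b, a], [d, c]]).statistic - base) < 1e-10

    def test_matches_textbook_formula(self, rng):
        for _ in range(30):
            t = rng.integers(1, 40, (2, 2))
            n = t.sum()
            expected = np.outer(t.sum(1), t.sum(0)) / n
            chi2_ref = ((t - expected) ** 2 / expected).sum()
            assert abs(pearson_chi_square(t).statistic - chi2_ref) < 1e-10


class TestFisher:
    def test_reproduces_published_diagnosis_contrast(self):
        # DSM-5 ASD by diagnosis timing: 2/25 prenatal vs 7/38 assessed later
        assert round(fisher_exact([[2, 23], [7, 31]]).p, 2) == 0.30

    def test_symmetric_table_p_one(self):
        assert fisher_exact([[1, 1], [1, 1]]).p == 1.0

    def test_transposition_invariance(self, rng):
        for _ in range(20):
            t = rng.integers(0, 10, (2, 2))
            if t.sum() == 0:
                continue
            assert abs(fisher_exact(t).p - fisher_exact(t.T).p) < 1e-12

    def test_matches_enumeration_oracle_small_tables(self, rng):
        for _ in range(60):
            t = rng.integers(0, 5, (2, 2))
            if t.sum() == 0 or t.sum() > 12:
                continue
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            assert abs(fisher_exact(t).p - fisher_p_enumeration(t)) < 1e-10


# ----------------------------------------------------------------- gate
class TestGate:
    def test_normal_variable_takes_t_path(self, rng):
        hits = 0
        for _ in range(100):
            x = rng.normal(100, 15, 64)
            res, _ = gated_group_contrast(x[:25], x[25:])
            hits += "t" in res.method and "Wilcoxon" not in res.method
        assert hits > 80

    def test_lognormal_variable_takes_wilcoxon_path(self, rng):
        hits = 0
        for _ in range(200):
            x = np.exp(rng.normal(3, 0.6, 64))
            res, _ = gated_group_contrast(x[:25], x[25:])
            hits += "Wilcoxon" in res.method
        assert hits > 150

    def test_dispatch_transparency(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 25)
        res, summary = gated_group_contrast(a, b)
        direct = (
            two_sample_t(a, b) if summary.is_normal else wilcoxon_rank_sum(a, b)
        )
        assert res == direct


# ----------------------------------------------------- classification
class TestClassification:
    def test_sld_rule(self):
        df = pd.DataFrame(
            {
                "wj_reading": [77.0, 80.0, 77.0],
                "wj_math": [90.0, 90.0, 90.0],
                "wj_writing": [85.0, 85.0, 85.0],
                "fsiq": [85.0, 85.0, 65.0],
            }
        )
        flags, rates = classify_delays_and_sld(df)
        assert flags["sld"].tolist() == [True, False, False]
        assert rates["sld"] == "1/3 (33%)"

    def test_sld_missing_fsiq_is_missing_not_false(self):
        df = pd.DataFrame({"wj_reading": [70.0], "wj_math": [np.nan],
                           "wj_writing": [np.nan], "fsiq": [np.nan]})
        flags, _ = classify_delays_and_sld(df)
        assert flags["sld"].isna().all()

    def test_milestone_boundary_is_strict(self):
        df = pd.DataFrame({"age_first_words": [24.0, 24.01, 23.0]})
        flags, rates = classify_delays_and_sld(df)
        assert flags["age_first_words_delayed"].tolist() == [False, True, False]
        assert rates["age_first_words_delayed"] == "1/3 (33%)"

    def test_denominators_exclude_missing(self):
        df = pd.DataFrame({"age_phrases": [30.0, np.nan, 20.0, 40.0]})
        _, rates = classify_delays_and_sld(df)
        assert rates["age_phrases_delayed"] == "2/3 (67%)"

    @pytest.mark.parametrize(
        "fsiq, band",
        [(112, "average"), (85, "average"), (84.9, "borderline"), (70, "borderline"),
         (69, "mild"), (55, "mild"), (54, "moderate"), (39, "severe")],
    )
    def test_iq_bands(self, fsiq, band):
        assert iq_band(fsiq) == band

    def test_invalid_rule_rejected(self):
        with pytest.raises(ValueError):
            ClassificationRule(milestone_threshold=0.0)


def test_statistics_match_brute_force_on_random_inputs(rng):
    """Cross-cutting 1e-10 oracle check: t statistic and chi-square match
    direct formula evaluation for random instances."""
    for _ in range(100):
        n = int(rng.integers(5, 50))
        x = rng.normal(0, 1, n)
        mu0 = float(rng.normal())
        res = one_sample_t(float(np.mean(x)), float(np.std(x, ddof=1)), n, mu0)
        ref = (np.mean(x) - mu0) / (np.std(x, ddof=1) / np.sqrt(n))
        assert abs(res.statistic - ref) < 1e-10
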