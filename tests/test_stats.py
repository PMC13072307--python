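"""Tests for the reliability and group-comparison statistics.

The ICC implementation is cross-checked against two independent routes:
pingouin's ICC(A,1)/ICC(A,k) on identical tables, and simulation from the
generating variance components.  Exact Mann-Whitney p-values are checked
against a brute-force enumeration oracle.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from octquant.stats import (
    GroupComparison,
    LongitudinalSeries,
    coefficient_of_variation,
    compare_groups_kw_dunn,
    filter_eligible,
    icc_two_way_random_absolute,
    interpret_icc,
    mann_whitney,
    sample_size,
    spearman_brown,
    weekly_change,
)
from octquant.synthetic import RatingSpec, generate_rating_table
from octquant.volio import RatingTable


class TestIcc:
    def test_identical_columns_perfect_agreement(self):
        vals = np.column_stack([np.arange(1.0, 13.0)] * 2)
        res = icc_two_way_random_absolute(RatingTable(values=vals))
        assert res.icc_single == pytest.approx(1.0)
        assert res.icc_average == pytest.approx(1.0)

    def test_simulation_recovers_true_icc(self):
        # subject_sd=3, rater_sd=1, error_sd=1 -> true ICC(A,1) = 9/11.
        # With k=2 each table realizes a single rater-pair draw, so the
        # estimate only converges to the population value averaged over
        # tables, not within one table however large n is.
        ests = [
            icc_two_way_random_absolute(
                generate_rating_table(
                    RatingSpec(
                        n_subjects=500, subject_sd=3.0, rater_sd=1.0,
                        error_sd=1.0, seed=500 + s,
                    )
                )
            ).icc_single
            for s in range(50)
        ]
        assert np.mean(ests) == pytest.approx(9.0 / 11.0, abs=0.03)

    def test_zero_subject_variance_near_zero_icc(self):
        spec = RatingSpec(
            n_subjects=800, subject_sd=0.0, rater_sd=1.0, error_sd=1.0,
            grand_mean=50.0, seed=6,
        )
        res = icc_two_way_random_absolute(generate_rating_table(spec))
        assert abs(res.icc_single) < 0.1

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_pingouin(self, seed, k):
        pg = pytest.importorskip("pingouin")
        tab = generate_rating_table(RatingSpec(n_subjects=20, n_raters=k, seed=seed))
        res = icc_two_way_random_absolute(tab)
        n = tab.n_subjects
        df = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "y": tab.values.ravel(),
            }
        )
        ref = pg.intraclass_corr(
            df, targets="subj", raters="rater", ratings="y"
        ).set_index("Type")
        assert res.icc_single == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-10)
        assert res.icc_average == pytest.approx(ref.loc["ICC(A,k)", "ICC"], abs=1e-10)
        assert res.f_value == pytest.approx(ref.loc["ICC(A,1)", "F"], rel=1e-9)
        assert res.p_value == pytest.approx(ref.loc["ICC(A,1)", "pval"], abs=1e-12)
        np.testing.assert_allclose(
            res.ci95_single, ref.loc["ICC(A,1)", "CI95"], atol=5e-3
        )

    def test_average_equals_spearman_brown_to_10_digits(self):
        for seed in range(10):
            tab = generate_rating_table(RatingSpec(n_subjects=15, seed=seed))
            res = icc_two_way_random_absolute(tab)
            sb = spearman_brown(res.icc_single, tab.n_raters)
            assert res.icc_average == pytest.approx(sb, rel=1e-10)

    def test_average_at_least_single_when_positive(self):
        for seed in range(10):
            tab = generate_rating_table(RatingSpec(n_subjects=12, seed=100 + seed))
            res = icc_two_way_random_absolute(tab)
            if res.icc_single >= 0:
                assert res.icc_average >= res.icc_single - 1e-12

    def test_df_for_12_subjects_2_raters(self):
        tab = generate_rating_table(RatingSpec(n_subjects=12, n_raters=2, seed=0))
        res = icc_two_way_random_absolute(tab)
        assert (res.df1, res.df2) == (11, 11)

    def test_degenerate_table_undefined(self):
        vals = np.full((5, 2), 7.0)
        with pytest.raises(ValueError, match="undefined"):
            icc_two_way_random_absolute(RatingTable(values=vals))

    def test_ci_brackets_estimate(self):
        tab = generate_rating_table(RatingSpec(n_subjects=12, seed=4))
        res = icc_two_way_random_absolute(tab)
        lo, hi = res.ci95_single
        assert lo <= res.icc_single <= hi

    def test_ci_coverage_simulation(self):
        # nominal 95% CI should cover the true ICC in >=90% of simulations.
        # Rater variance kept moderate (sd 0.5): with k=2 the rater component
        # has 1 df, and the standard F-interval (ours matches pingouin's
        # exactly) genuinely undercovers (~87%) when rater and error
        # variances are comparable.
        true = 9.0 / (9.0 + 0.25 + 1.0)
        covered = 0
        reps = 500
        for seed in range(reps):
            tab = generate_rating_table(
                RatingSpec(
                    n_subjects=30, subject_sd=3.0, rater_sd=0.5, error_sd=1.0,
                    seed=20_000 + seed,
                )
            )
            lo, hi = icc_two_way_random_absolute(tab).ci95_single
            covered += lo <= true <= hi
        assert covered / reps >= 0.90


class TestSpearmanBrown:
    @pytest.mark.parametrize(
        "single,k,expected,decimals",
        [
            (0.998, 2, 0.999, 3),
            (0.994, 2, 0.997, 3),
            (1.000, 2, 1.00, 2),
        ],
    )
    def test_published_table_consistency(self, single, k, expected, decimals):
        assert round(spearman_brown(single, k), decimals) == expected

    def test_identity_at_k1(self):
        assert spearman_brown(0.37, 1) == pytest.approx(0.37)

    @given(hst.floats(min_value=0.0, max_value=1.0), hst.integers(2, 10))
    @settings(max_examples=50, deadline=None)
    def test_aggregation_never_decreases(self, r, k):
        assert spearman_brown(r, k) >= r - 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            spearman_brown(-1.0, 2)


class TestInterpretIcc:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.999, "excellent"),
            (0.91, "excellent"),
            (0.9, "good"),
            (0.75, "good"),
            (0.74, "fair"),
            (0.5, "fair"),
            (0.49, "poor"),
            (-0.2, "poor"),
        ],
    )
    def test_cutpoints(self, value, expected):
        assert interpret_icc(value) == expected


class TestCov:
    def test_constant_vector_zero(self):
        assert coefficient_of_variation([4.2, 4.2, 4.2]) == 0.0

    def test_one_two_three_is_fifty(self):
        assert coefficient_of_variation([1, 2, 3]) == pytest.approx(50.0)

    @given(
        hst.lists(hst.floats(min_value=1.0, max_value=100.0), min_size=2, max_size=20),
        hst.floats(min_value=0.1, max_value=10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, values, c):
        base = coefficient_of_variation(values)
        scaled = coefficient_of_variation([c * v for v in values])
        assert scaled == pytest.approx(base, abs=1e-8)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            coefficient_of_variation([-1.0, -2.0])


class TestWeeklyChange:
    def test_simple_arithmetic(self):
        s = LongitudinalSeries("e", [1, 2, 3], [10.0, 9.0, 8.0])
        assert weekly_change(s) == pytest.approx([-10.0, -100.0 / 9.0])

    def test_constant_series_zero(self):
        s = LongitudinalSeries("e", [1, 2, 3], [5.0, 5.0, 5.0])
        assert weekly_change(s) == [0.0, 0.0]

    def test_geometric_series_recovers_rate(self):
        rate = 9.7
        percents = [10.0 * (1 + rate / 100.0) ** i for i in range(5)]
        s = LongitudinalSeries("e", list(range(5)), percents)
        changes = weekly_change(s)
        assert np.mean(changes) == pytest.approx(rate)
        assert all(c == pytest.approx(rate) for c in changes)

    def test_zero_baseline_errors(self):
        s = LongitudinalSeries("e", [1, 2], [0.0, 5.0])
        with pytest.raises(ValueError, match="zero baseline"):
            weekly_change(s)

    def test_unsorted_timepoints_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            LongitudinalSeries("e", [2, 1], [1.0, 2.0])


class TestFilterEligible:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["eye_id", "timepoint", "percent_opacity"])

    def test_strict_boundary(self):
        df = self._df(
            [
                ("a", "baseline", 1.0), ("a", "pre", 6.0),   # delta 5.0: excluded
                ("b", "baseline", 1.0), ("b", "pre", 6.1),   # delta 5.1: included
            ]
        )
        out = filter_eligible(df, min_percent=5.0)
        assert set(out["eye_id"]) == {"b"}

    def test_missing_baseline_warns_and_excludes(self):
        df = self._df([("a", "pre", 30.0), ("b", "baseline", 0.5), ("b", "pre", 9.0)])
        with pytest.warns(UserWarning, match="'a'"):
            out = filter_eligible(df)
        assert set(out["eye_id"]) == {"b"}

    def test_all_naive_empty(self):
        df = self._df(
            [("a", "baseline", 0.4), ("a", "pre", 0.5),
             ("b", "baseline", 0.3), ("b", "pre", 0.6)]
        )
        assert len(filter_eligible(df)) == 0


class TestMannWhitney:
    @staticmethod
    def _enumerate_p(a, b):
        """Exact two-sided p by enumerating all group assignments."""
        pooled = sorted(a) + sorted(b)
        na = len(a)
        u_obs = sum(x > y for x in a for y in b)
        mean_u = na * len(b) / 2.0
        more_extreme = total = 0
        for idx in itertools.combinations(range(len(pooled)), na):
            ga = [pooled[i] for i in idx]
            gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
            u = sum(x > y for x in ga for y in gb)
            total += 1
            if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
                more_extreme += 1
        return more_extreme / total

    def test_textbook_case(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.100, abs=1e-9)
        assert p == pytest.approx(self._enumerate_p([1, 2, 3], [4, 5, 6]))

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = list(rng.permutation(np.arange(40.0))[:5])
        b = list(rng.permutation(np.arange(40.0, 80.0))[:4])
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(self._enumerate_p(a, b), abs=1e-9)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1.0, 1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_swap_symmetry(self):
        a, b = [1.0, 5.0, 7.0], [2.0, 3.0, 9.0, 11.0]
        u_ab, p_ab = mann_whitney(a, b)
        u_ba, p_ba = mann_whitney(b, a)
        assert u_ab + u_ba == len(a) * len(b)
        assert p_ab == pytest.approx(p_ba)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([], [1.0])


class TestKruskalDunn:
    def test_identical_groups_h_zero_p_one(self):
        g = {"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]}
        res = compare_groups_kw_dunn(g)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        g = {
            "a": list(range(1, 6)),
            "b": list(range(11, 16)),
            "c": list(range(21, 26)),
        }
        res = compare_groups_kw_dunn(g)
        assert res.p_value < 0.01
        assert all(row["p_adj"] <= 1.0 for row in res.pairwise)

    def test_monotone_transform_invariance(self):
        g = {"a": [1.0, 2.0, 5.0], "b": [3.0, 8.0, 9.0], "c": [4.0, 6.0, 7.0]}
        res1 = compare_groups_kw_dunn(g)
        res2 = compare_groups_kw_dunn(
            {k: [math.exp(v) for v in vals] for k, vals in g.items()}
        )
        assert res1.statistic == pytest.approx(res2.statistic)
        assert res1.p_value == pytest.approx(res2.p_value)

    def test_two_groups_delegate_to_mann_whitney(self):
        res = compare_groups_kw_dunn({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert res.method == "mann-whitney"
        assert res.p_value == pytest.approx(0.100, abs=1e-9)

    def test_pairwise_count(self):
        g = {f"g{i}": [float(i), i + 0.5, i + 1.0] for i in range(5)}
        res = compare_groups_kw_dunn(g)
        assert len(res.pairwise) == 10  # C(5, 2)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n=1"):
            compare_groups_kw_dunn({"a": [1.0], "b": [1, 2], "c": [1, 2]})

    def test_dunn_z_signs(self):
        g = {"low": [1, 2, 3], "high": [10, 11, 12], "mid": [5, 6, 7]}
        res = compare_groups_kw_dunn(g)
        zs = {(r["group_a"], r["group_b"]): r["z"] for r in res.pairwise}
        assert zs[("low", "high")] < 0
        assert zs[("high", "mid")] > 0

    def test_p_value_range_enforced(self):
        with pytest.raises(ValueError):
            GroupComparison(statistic=1.0, p_value=2.0, method="x")


class TestSampleSize:
    def test_equal_s_and_d(self):
        # 1 + 2 * 10.51 = 22.02 -> 23
        assert sample_size(1.0, 1.0) == 23

    def test_published_inputs(self):
        # s=20, d=30, C=10.51 -> ceil(10.34) = 11
        assert sample_size(30.0, 20.0, C=10.51) == 11

    def test_zero_sd_limit(self):
        assert sample_size(10.0, 0.0) == 1

    def test_invalid_effect(self):
        with pytest.raises(ValueError, match="d must be"):
            sample_size(0.0, 1.0)
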