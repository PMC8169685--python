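"""Hypothesis tests: oracle equivalences, invariances, calibration smoke checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vmrscreen import (
    anova_pairwise_fdr,
    hd_two_sample_test,
    hotelling_t2,
    pearson_chi2_2x2,
    welch_t,
)
from vmrscreen.exceptions import (
    DegenerateTableError,
    DimensionError,
    DomainError,
    InsufficientSampleError,
    SingularCovarianceError,
    UndefinedStatisticError,
)


def brute_force_t2(a, b):
    """Independent oracle: explicit pooled covariance inverse, no shortcuts."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    n1, n2 = a.shape[0], b.shape[0]
    d = a.mean(0) - b.mean(0)
    s = ((n1 - 1) * np.cov(a.T, ddof=1) + (n2 - 1) * np.cov(b.T, ddof=1)) / (
        n1 + n2 - 2
    )
    s = np.atleast_2d(s)
    return float(n1 * n2 / (n1 + n2) * d @ np.linalg.inv(s) @ d)


class TestHotelling:
    def test_identical_samples_give_zero_statistic_and_p_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(10, 4))
        res = hotelling_t2(a, a.copy())
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_univariate_case_equals_squared_pooled_t_by_hand(self):
        res = hotelling_t2(np.array([0.0, 2.0]), np.array([1.0, 3.0]))
        assert res.statistic == pytest.approx(0.5, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_instance(self):
        rng = np.random.default_rng(42)
        a = rng.normal(size=(24, 30))
        b = rng.normal(size=(24, 30)) + 0.1
        res = hotelling_t2(a, b)
        assert res.statistic == pytest.approx(brute_force_t2(a, b), abs=1e-10)
        assert res.df1 == 30
        assert res.df2 == 24 + 24 - 30 - 1

    def test_univariate_equals_squared_pooled_t_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.normal(size=rng.integers(3, 12))
            b = rng.normal(size=rng.integers(3, 12)) + rng.normal()
            t, _ = stats.ttest_ind(a, b, equal_var=True)
            assert hotelling_t2(a, b).statistic == pytest.approx(t**2, rel=1e-10)

    def test_affine_invariance_under_common_linear_transform(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(15, 3))
        b = rng.normal(size=(12, 3)) + 0.3
        base = hotelling_t2(a, b).statistic
        for _ in range(5):
            m = rng.normal(size=(3, 3)) + np.eye(3)
            shift = rng.normal(size=3)
            res = hotelling_t2(a @ m + shift, b @ m + shift)
            assert res.statistic == pytest.approx(base, rel=1e-8)

    def test_agrees_with_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        a = rng.normal(size=(20, 4))
        b = rng.normal(size=(18, 4)) + 0.2
        ours = hotelling_t2(a, b)
        ref = pingouin.multivariate_ttest(a, b)
        assert ours.info["F"] == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert ours.p_value == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-9)

    def test_dimension_error_points_to_hd_test(self):
        rng = np.random.default_rng(1)
        with pytest.raises(DimensionError, match="hd_two_sample_test"):
            hotelling_t2(rng.normal(size=(5, 30)), rng.normal(size=(5, 30)))

    def test_singular_covariance_raises_and_ridge_recovers(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        a[:, 2] = a[:, 0]  # duplicated coordinate in one group only is fine;
        b[:, 2] = b[:, 0]  # duplicated in both makes the pooled covariance singular
        with pytest.raises(SingularCovarianceError):
            hotelling_t2(a, b)
        res = hotelling_t2(a, b, ridge=1e-6)
        assert res.info["ridge"] == 1e-6
        assert 0 <= res.p_value <= 1


class TestHDTwoSample:
    def test_identical_samples_give_zero_statistic_and_p_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(8, 40))
        res = hd_two_sample_test(a, a.copy(), n_boot=300, seed=1)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_bitwise_reproducible_given_seed(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=(12, 30)), rng.normal(size=(12, 30))
        r1 = hd_two_sample_test(a, b, n_boot=500, seed=77)
        r2 = hd_two_sample_test(a, b, n_boot=500, seed=77)
        assert (r1.statistic, r1.p_value) == (r2.statistic, r2.p_value)

    def test_works_in_p_greater_than_n_regime(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(10, 50)), rng.normal(size=(10, 50))
        res = hd_two_sample_test(a, b, n_boot=300, seed=2)
        assert 0 < res.p_value <= 1

    def test_detects_sparse_strong_shift(self):
        rng = np.random.default_rng(11)
        rejected = 0
        for i in range(20):
            a = rng.normal(size=(24, 30))
            b = rng.normal(size=(24, 30))
            b[:, :5] += 3.0
            res = hd_two_sample_test(a, b, n_boot=400, seed=1000 + i)
            rejected += res.p_value < 0.05
        assert rejected == 20

    def test_null_p_values_are_roughly_uniform(self):
        rng = np.random.default_rng(15)
        ps = [
            hd_two_sample_test(
                rng.normal(size=(12, 20)),
                rng.normal(size=(12, 20)),
                n_boot=300,
                seed=int(rng.integers(2**31)),
            ).p_value
            for _ in range(200)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_multiplier_variant_runs_and_differs_in_tag(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=(12, 30)), rng.normal(size=(12, 30))
        res = hd_two_sample_test(a, b, n_boot=300, seed=3, method="multiplier")
        assert res.info["resampling"] == "multiplier"

    def test_too_few_bootstrap_draws_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(DomainError):
            hd_two_sample_test(
                rng.normal(size=(5, 3)), rng.normal(size=(5, 3)), n_boot=50, seed=1
            )

    def test_single_observation_group_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(InsufficientSampleError):
            hd_two_sample_test(
                rng.normal(size=(1, 3)), rng.normal(size=(5, 3)), n_boot=300, seed=1
            )


class TestWelch:
    def test_hand_computed_example(self):
        res = welch_t([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-3.6742346, abs=1e-6)
        assert res.df1 == pytest.approx(4.0, abs=1e-9)

    def test_identical_samples(self):
        res = welch_t([1.0, 2.0, 4.0], [1.0, 2.0, 4.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_antisymmetric_in_group_order(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=10), rng.normal(size=13) + 0.4
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_zero_variance_both_groups_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            welch_t([2.0, 2.0, 2.0], [2.0, 2.0])


class TestChi2:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[9, 15], [16, 8]], 4.09),
            ([[8, 16], [16, 8]], 5.33),
        ],
    )
    def test_rod_distribution_tables_reproduce_published_statistics(
        self, table, expected
    ):
        res = pearson_chi2_2x2(table)
        assert round(res.statistic, 2) == expected
        assert res.df1 == 1
        assert res.p_value < 0.05

    def test_independent_table_gives_zero(self):
        res = pearson_chi2_2x2([[5, 5], [5, 5]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @given(
        a=st.integers(1, 40), b=st.integers(1, 40),
        c=st.integers(1, 40), d=st.integers(1, 40),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_to_transpose_and_swaps(self, a, b, c, d):
        t = np.array([[a, b], [c, d]])
        base = pearson_chi2_2x2(t).statistic
        assert pearson_chi2_2x2(t.T).statistic == pytest.approx(base)
        assert pearson_chi2_2x2(t[::-1]).statistic == pytest.approx(base)
        assert pearson_chi2_2x2(t[:, ::-1]).statistic == pytest.approx(base)

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi2_2x2([[0, 0], [5, 3]])

    def test_non_integer_counts_rejected(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi2_2x2([[1.5, 2], [3, 4]])


class TestAnovaPairwiseFDR:
    def test_bh_adjustment_matches_step_up_by_hand(self):
        # groups engineered so exact raw p's don't matter; check the BH rule
        from statsmodels.stats.multitest import multipletests

        raw = [0.01, 0.02, 0.03]
        adj = multipletests(raw, method="fdr_bh")[1]
        assert list(np.round(adj, 10)) == [0.03, 0.03, 0.03]

    def test_planted_group_offsets_are_detected(self):
        rng = np.random.default_rng(21)
        detected = 0
        for _ in range(20):
            groups = {
                "g0": rng.normal(0.0, 0.5, 10),
                "g1": rng.normal(1.0, 0.5, 10),
                "g2": rng.normal(2.0, 0.5, 10),
            }
            res = anova_pairwise_fdr(groups)
            detected += res["anova"].p_value < 0.001
        assert detected >= 19

    def test_pairwise_results_carry_adjusted_and_raw_p(self):
        rng = np.random.default_rng(22)
        groups = {"a": rng.normal(size=8), "b": rng.normal(size=8) + 1.5,
                  "c": rng.normal(size=8)}
        res = anova_pairwise_fdr(groups)
        assert len(res["pairwise"]) == 3
        for pw in res["pairwise"]:
            assert 0 <= pw.p_value <= 1
            assert pw.p_value >= pw.info["p_raw"] - 1e-12

    def test_identical_constants_are_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            anova_pairwise_fdr({"a": [1.0, 1.0], "b": [1.0, 1.0]})

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientSampleError):
            anova_pairwise_fdr({"a": [1.0], "b": [1.0, 2.0]})
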