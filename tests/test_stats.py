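"""Agreement statistics: ICC, CV, SEM, Bland–Altman, rank tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cmjagree import (
    bland_altman,
    between_tool_cv,
    friedman_with_posthoc,
    icc_absolute_single,
    interpret_icc,
    interpret_r,
    kruskal_wallis,
    loa_from_bias_sd,
    mann_whitney_with_r,
    sem_between_tools,
)


def _pair_table(a, b, participants=None):
    df = pd.DataFrame({"a": a, "b": b})
    if participants is not None:
        df["participant_id"] = participants
    return df


def _icc_oracle(x):
    """ICC(A,1) from an independently fitted two-way ANOVA (statsmodels)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    n, k = x.shape
    df = pd.DataFrame({
        "y": x.ravel(),
        "subject": np.repeat([f"s{i}" for i in range(n)], k),
        "rater": np.tile([f"r{j}" for j in range(k)], n),
    })
    tab = sm.stats.anova_lm(ols("y ~ C(subject) + C(rater)", data=df).fit())
    msr = tab.loc["C(subject)", "mean_sq"]
    msc = tab.loc["C(rater)", "mean_sq"]
    mse = tab.loc["Residual", "mean_sq"]
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestICC:
    def test_identical_columns_give_one(self):
        icc, lo, hi, p = icc_absolute_single(
            np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]]))
        assert icc == 1.0

    def test_hand_computed_4x2_matrix(self):
        # mean squares by hand: MSR = 40/3, MSC = 2, MSE = 0 -> ICC = 40/43
        icc, *_ = icc_absolute_single(np.array([[1, 2], [3, 4], [5, 6], [7, 8]], float))
        assert icc == pytest.approx(40 / 43, rel=1e-12)

    def test_matches_anova_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(2, 4))
            x = rng.normal(10, 3, (n, k)) + rng.normal(0, 2, (n, 1))
            icc, *_ = icc_absolute_single(x)
            assert icc == pytest.approx(_icc_oracle(x), abs=1e-10)

    def test_matches_pingouin_point_and_ci(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        n, k = 12, 3
        x = rng.normal(15, 4, (n, k)) + rng.normal(0, 2, (n, 1))
        icc, lo, hi, p = icc_absolute_single(x)
        df = pd.DataFrame({"t": np.repeat(np.arange(n), k),
                           "r": np.tile(np.arange(k), n), "y": x.ravel()})
        row = pg.intraclass_corr(df, targets="t", raters="r", ratings="y")
        row = row[row.Type == "ICC(A,1)"].iloc[0]
        assert icc == pytest.approx(row.ICC, abs=1e-10)
        assert p == pytest.approx(row.pval, abs=1e-10)
        # pingouin rounds its CI to 2 decimals
        assert lo == pytest.approx(row.CI95[0], abs=5e-3)
        assert hi == pytest.approx(row.CI95[1], abs=5e-3)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(11)
        icc, *_ = icc_absolute_single(rng.normal(0, 1, (10_000, 2)))
        assert abs(icc) < 0.05

    def test_zero_variance_is_an_error_not_one(self):
        with pytest.raises(ValueError, match="undefined"):
            icc_absolute_single(np.full((5, 2), 3.0))

    @pytest.mark.parametrize("icc, label", [
        (0.955, "excellent"), (0.49, "poor"), (0.75, "good"),
        (0.9, "good"), (0.6, "moderate"), (-0.2, "poor"),
    ])
    def test_interpretation_bands(self, icc, label):
        assert interpret_icc(icc) == label


class TestCV:
    def test_identical_columns_zero(self):
        tab = _pair_table([10.0, 12.0, 14.0], [10.0, 12.0, 14.0])
        assert between_tool_cv(tab, ("a", "b")) == 0.0

    def test_single_pair_hand_value(self):
        # (14, 16): SD = 2/sqrt(2), mean = 15 -> 9.43%
        tab = _pair_table([14.0], [16.0])
        assert between_tool_cv(tab, ("a", "b")) == pytest.approx(9.4281, abs=1e-3)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(10, 20, 30)
        b = a + rng.normal(0, 1, 30)
        cv1 = between_tool_cv(_pair_table(a, b), ("a", "b"))
        cv2 = between_tool_cv(_pair_table(2 * a, 2 * b), ("a", "b"))
        assert cv1 == pytest.approx(cv2, rel=1e-12)

    def test_zero_mean_pairs_excluded_with_warning(self):
        tab = _pair_table([14.0, 1.0], [16.0, -1.0])
        with pytest.warns(UserWarning, match="zero pair mean"):
            cv = between_tool_cv(tab, ("a", "b"))
        assert cv == pytest.approx(9.4281, abs=1e-3)


class TestSEM:
    def test_equal_differences_give_zero(self):
        tab = _pair_table([10.0, 12.0, 14.0], [9.0, 11.0, 13.0])
        assert sem_between_tools(tab, ("a", "b")) == 0.0

    @pytest.mark.parametrize("sd, reported", [(1.62, 1.1), (0.41, 0.3)])
    def test_sd_diff_over_root_two(self, sd, reported):
        from cmjagree import round_half_up

        assert round_half_up(sd / math.sqrt(2), 1) == reported

    def test_pooled_equals_bland_altman_sd_over_root_two(self):
        rng = np.random.default_rng(4)
        tab = _pair_table(rng.uniform(10, 20, 40), rng.uniform(10, 20, 40))
        sem = sem_between_tools(tab, ("a", "b"))
        _, sd, _, _ = bland_altman(tab, ("a", "b"))
        assert sem == pytest.approx(sd / math.sqrt(2), rel=1e-12)

    def test_per_participant_mode(self):
        tab = _pair_table([10.0, 12.0, 20.0, 23.0], [9.0, 12.0, 20.0, 20.0],
                          participants=["p1", "p1", "p2", "p2"])
        # p1 diffs (1, 0) -> SD 1/sqrt(2); p2 diffs (0, 3) -> SD 3/sqrt(2)...
        expected = np.mean([np.std([1, 0], ddof=1), np.std([0, 3], ddof=1)]) / math.sqrt(2)
        got = sem_between_tools(tab, ("a", "b"), mode="per_participant_mean")
        assert got == pytest.approx(expected, rel=1e-12)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            sem_between_tools(_pair_table([1.0], [2.0]), ("a", "b"))


class TestBlandAltman:
    @pytest.mark.parametrize("bias, sd, lo, hi", [
        (1.33, 1.62, -1.85, 4.51),
        (-0.36, 1.61, -3.52, 2.80),
        (0.07, 0.31, -0.54, 0.68),
    ])
    def test_limits_from_summary_statistics(self, bias, sd, lo, hi):
        from cmjagree import round_half_up

        got_lo, got_hi = loa_from_bias_sd(bias, sd)
        assert round_half_up(got_lo, 2) == lo
        assert round_half_up(got_hi, 2) == hi

    def test_all_zero_differences(self):
        tab = _pair_table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        bias, sd, lo, hi = bland_altman(tab, ("a", "b"))
        assert (bias, sd, lo, hi) == (0.0, 0.0, 0.0, 0.0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(_pair_table([1.0], [2.0]), ("a", "b"))

    @given(st.floats(-10, 10), st.floats(0, 5))
    def test_limits_symmetric_about_bias(self, bias, sd):
        lo, hi = loa_from_bias_sd(bias, sd)
        assert (lo + hi) / 2 == pytest.approx(bias, abs=1e-12)


class TestRankTests:
    TOY = pd.DataFrame({
        "m1": [1.0, 1.0, 2.0, 1.0, 2.0, 1.0],
        "m2": [2.0, 3.0, 1.0, 2.0, 1.0, 2.0],
        "m3": [3.0, 2.0, 3.0, 3.0, 3.0, 3.0],
    })

    def test_identical_columns_friedman_null(self):
        tab = pd.DataFrame({m: [1.0, 2.0, 3.0, 4.0, 5.0] for m in ("m1", "m2", "m3")})
        omni, pairwise, dropped = friedman_with_posthoc(tab, ("m1", "m2", "m3"))
        assert omni.statistic == 0.0
        assert omni.p_value == 1.0
        assert pairwise == {}

    def test_toy_matrix_matches_hand_rank_arithmetic(self):
        # rank sums 8, 11, 17 -> chi2 = 12/(6*3*4)*(64+121+289) - 3*6*4 = 7.0
        omni, _, _ = friedman_with_posthoc(self.TOY, ("m1", "m2", "m3"))
        assert omni.statistic == pytest.approx(7.0)
        assert omni.p_value == pytest.approx(math.exp(-3.5), rel=1e-6)

    def test_posthoc_p_is_bonferroni_multiplied(self):
        from scipy.stats import wilcoxon

        omni, pairwise, _ = friedman_with_posthoc(self.TOY, ("m1", "m2", "m3"))
        assert omni.p_value < 0.05
        raw = wilcoxon(self.TOY["m1"], self.TOY["m3"], method="approx").pvalue
        assert pairwise[("m1", "m3")].p_value == pytest.approx(min(1.0, raw * 3))

    def test_kruskal_alternative_runs(self):
        res = kruskal_wallis(self.TOY, ("m1", "m2", "m3"))
        assert 0 <= res.p_value <= 1

    def test_incomplete_rows_dropped_and_counted(self):
        tab = self.TOY.copy()
        tab.loc[0, "m2"] = np.nan
        _, _, dropped = friedman_with_posthoc(tab, ("m1", "m2", "m3"))
        assert dropped == 1

    def test_mann_whitney_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = mann_whitney_with_r(a, a.copy())
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert res.interpretation == "trivial"

    def test_mann_whitney_toy_matches_enumeration(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        res = mann_whitney_with_r(a, b)
        # exhaustive U over all C(6,3)=20 label assignments of the pooled ranks
        pooled = np.concatenate([a, b])
        u_values = []
        for idx in itertools.combinations(range(6), 3):
            ga = pooled[list(idx)]
            gb = pooled[[i for i in range(6) if i not in idx]]
            u_values.append(sum((x > y) + 0.5 * (x == y) for x in ga for y in gb))
        assert res.statistic == min(u_values)  # observed split is the extreme one
        assert res.p_value == pytest.approx(2 / 20)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_with_r(np.array([]), np.array([1.0]))

    @pytest.mark.parametrize("r, label", [
        (0.09, "trivial"), (0.15, "small"), (0.35, "medium"), (0.55, "large"),
        (0.1, "trivial"), (-0.4, "medium"),
    ])
    def test_effect_size_bands(self, r, label):
        assert interpret_r(r) == label
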