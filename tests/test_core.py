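"""Unit and property tests for the slope-comparison tests themselves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from welchslopes import (
    GroupSample,
    GroupSummary,
    pooled_slope_test,
    read_two_group_csv,
    summarize_group,
    welch_df,
    welch_statistic,
    welch_test,
)
from conftest import random_two_groups


class TestSummarizeGroup:
    @pytest.mark.parametrize(
        "x, y, slope, intercept, sse, ssx",
        [
            ((0, 1, 2), (1, 3, 5), 2.0, 1.0, 0.0, 2.0),  # exact line
            ((0, 1, 2, 3), (0, 0, 0, 0), 0.0, 0.0, 0.0, 5.0),  # flat response
        ],
    )
    def test_closed_form_cases(self, x, y, slope, intercept, sse, ssx):
        s = summarize_group(GroupSample(1, np.array(x, float), np.array(y, float)))
        assert s.slope_hat == pytest.approx(slope)
        assert s.intercept_hat == pytest.approx(intercept)
        assert s.sse == pytest.approx(sse, abs=1e-12)
        assert s.ssx == pytest.approx(ssx)

    def test_matches_normal_equations_oracle(self, rng):
        """OLS summaries agree with an independent normal-equations solve."""
        x = rng.normal(2.0, 3.0, 25)
        y = 1.5 - 0.7 * x + rng.normal(0, 2.0, 25)
        s = summarize_group(GroupSample(1, x, y))
        design = np.column_stack([np.ones_like(x), x])
        coef = np.linalg.solve(design.T @ design, design.T @ y)
        resid = y - design @ coef
        assert s.intercept_hat == pytest.approx(coef[0], rel=1e-10)
        assert s.slope_hat == pytest.approx(coef[1], rel=1e-10)
        assert s.sse == pytest.approx(float(resid @ resid), rel=1e-10)
        assert s.sigma2_hat == pytest.approx(float(resid @ resid) / 23, rel=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="SSX"):
            summarize_group(GroupSample(1, np.array([2.0, 2.0, 2.0]), np.array([1.0, 2.0, 3.0])))
        with pytest.raises(ValueError, match="at least 3"):
            GroupSample(1, np.array([0.0, 1.0]), np.array([0.0, 1.0]))


class TestWelchStatistic:
    def test_mice_worked_example(self, mice):
        diff, se, t_star = welch_statistic(*mice)
        assert diff == pytest.approx(15.9286 - 3.8398)
        assert t_star == pytest.approx(1.6073, abs=5e-5)

    def test_zero_when_slopes_equal(self):
        s = GroupSummary.from_moments(10, 1.3, 2.0, ssx=5.0)
        t = GroupSummary.from_moments(14, 1.3, 0.7, ssx=9.0)
        assert welch_statistic(s, t)[2] == 0.0

    def test_antisymmetric_in_group_order(self, two_groups):
        s1, s2 = two_groups
        _, _, t12 = welch_statistic(s1, s2)
        _, _, t21 = welch_statistic(s2, s1)
        assert t21 == pytest.approx(-t12, rel=1e-12)
        assert welch_df(s1, s2) == pytest.approx(welch_df(s2, s1), rel=1e-12)


class TestWelchDf:
    def test_mice_worked_example(self, mice):
        assert welch_df(*mice) == pytest.approx(12.9349, abs=5e-5)

    def test_equal_weights_give_twice_residual_df(self):
        s = GroupSummary.from_moments(12, 0.0, 3.0, ssx=6.0)
        t = GroupSummary.from_moments(12, 1.0, 3.0, ssx=6.0)
        assert welch_df(s, t) == pytest.approx(2 * 10, rel=1e-12)

    def test_single_group_limit(self):
        # vanishing variance term in group 2 concentrates all df in group 1
        s = GroupSummary.from_moments(9, 1.0, 4.0, ssx=2.0)
        t = GroupSummary.from_moments(30, 0.0, 0.0, ssx=50.0)
        assert welch_df(s, t) == pytest.approx(s.c, rel=1e-12)

    @given(
        n1=st.integers(4, 60),
        n2=st.integers(4, 60),
        a1=st.floats(1e-3, 1e3),
        a2=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_between_min_c_and_sum_c(self, n1, n2, a1, a2):
        """Satterthwaite df always lies in [min(c1,c2), c1+c2]."""
        s1 = GroupSummary.from_moments(n1, 0.0, a1, ssx=1.0)
        s2 = GroupSummary.from_moments(n2, 0.0, a2, ssx=1.0)
        nu = welch_df(s1, s2)
        assert min(s1.c, s2.c) - 1e-9 <= nu <= s1.c + s2.c + 1e-9


class TestWelchTest:
    def test_mice_worked_example(self, mice):
        res = welch_test(*mice, alpha=0.05)
        assert res.p_value == pytest.approx(0.1321, abs=5e-5)
        assert not res.reject

    def test_null_statistic_gives_p_one(self):
        s = GroupSummary.from_moments(10, 2.0, 1.0, ssx=4.0)
        t = GroupSummary.from_moments(12, 2.0, 2.0, ssx=7.0)
        assert welch_test(s, t).p_value == pytest.approx(1.0)

    def test_p_value_against_quadrature_oracle(self, mice):
        """Two-sided p matches direct numeric integration of the t density."""
        res = welch_test(*mice)
        tail, _ = integrate.quad(
            lambda u: stats.t.pdf(u, res.nu_hat), abs(res.t_star), np.inf
        )
        assert res.p_value == pytest.approx(2 * tail, abs=1e-9)

    def test_decision_consistency(self, two_groups):
        s1, s2 = two_groups
        for alpha in (0.01, 0.05, 0.2):
            res = welch_test(s1, s2, alpha=alpha)
            assert res.reject == (res.p_value < alpha)
            assert res.reject == (abs(res.t_star) > res.crit)


class TestPooledTest:
    def test_mice_worked_example(self, mice):
        res = pooled_slope_test(*mice)
        assert res.nu_hat == 30
        # statistic recomputed from the rounded published summaries; the
        # printed value carries rounding error of those summaries
        assert res.t_star == pytest.approx(1.6492, abs=0.01)
        assert res.p_value == pytest.approx(0.1098, abs=0.005)

    def test_coincides_with_welch_under_homogeneity(self):
        # equal sigma2_hat and equal ssx make both statistics identical
        s = GroupSummary.from_moments(15, 2.0, 3.0, ssx=8.0)
        t = GroupSummary.from_moments(15, 0.5, 3.0, ssx=8.0)
        assert pooled_slope_test(s, t).t_star == pytest.approx(
            welch_statistic(s, t)[2], rel=1e-12
        )


class TestInvariance:
    """T*, df and p are invariant to location shifts and scale changes."""

    @pytest.mark.parametrize("shift_field", ["x", "y"])
    def test_location_shift_of_one_group(self, rng, shift_field):
        g1, g2 = random_two_groups(rng)
        base = welch_test(summarize_group(g1), summarize_group(g2))
        shifted = GroupSample(
            1,
            g1.x + (37.5 if shift_field == "x" else 0.0),
            g1.y + (-12.25 if shift_field == "y" else 0.0),
        )
        res = welch_test(summarize_group(shifted), summarize_group(g2))
        assert res.t_star == pytest.approx(base.t_star, rel=1e-9)
        assert res.nu_hat == pytest.approx(base.nu_hat, rel=1e-9)
        assert res.p_value == pytest.approx(base.p_value, rel=1e-9)

    @pytest.mark.parametrize("k", [0.25, 7.0])
    @pytest.mark.parametrize("axis", ["x", "y"])
    def test_common_rescaling_of_both_groups(self, rng, k, axis):
        g1, g2 = random_two_groups(rng)
        base = welch_test(summarize_group(g1), summarize_group(g2))
        if axis == "y":
            h1 = GroupSample(1, g1.x, k * g1.y)
            h2 = GroupSample(2, g2.x, k * g2.y)
        else:
            h1 = GroupSample(1, k * g1.x, g1.y)
            h2 = GroupSample(2, k * g2.x, g2.y)
        res = welch_test(summarize_group(h1), summarize_group(h2))
        assert res.t_star == pytest.approx(base.t_star, rel=1e-9)
        assert res.p_value == pytest.approx(base.p_value, rel=1e-9)


class TestCsvInput:
    def test_round_trip(self, tmp_path, rng):
        g1, g2 = random_two_groups(rng)
        path = tmp_path / "data.csv"
        lines = ["group,x,y"]
        for g in (g1, g2):
            lines += [f"{g.label},{float(x)!r},{float(y)!r}" for x, y in zip(g.x, g.y)]
        path.write_text("\n".join(lines) + "\n")
        r1, r2 = read_two_group_csv(path)
        np.testing.assert_allclose(r1.x, g1.x)
        np.testing.assert_allclose(r2.y, g2.y)

    def test_parse_errors_report_line_numbers(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("group,x,y\n1,1.0,2.0\n1,oops,3.0\n2,2.0,4.0\n")
        with pytest.raises(ValueError, match="line.*3"):
            read_two_group_csv(path)

    def test_bad_group_label_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("group,x,y\n1,1.0,2.0\n3,2.0,3.0\n")
        with pytest.raises(ValueError, match="group must be 1 or 2"):
            read_two_group_csv(path)
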