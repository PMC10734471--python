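"""Differential-expression statistics against hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from proteoalloc.de import (
    adjust_bh,
    anova_multi,
    call_regulation,
    differential_expression,
    overlap_counts,
    presence_call,
    two_group_ttest,
)
from proteoalloc.model import SampleDesign


def frame(rows, design):
    return pd.DataFrame(
        rows, index=[f"p{i}" for i in range(len(rows))], columns=design.sample_ids
    )


class TestTwoGroupTTest:
    def test_textbook_pooled_t(self, two_by_three_design):
        # groups (1,2,3) vs (3,4,5): pooled t = 2/(1*sqrt(2/3)) = 2.449, df=4
        m = frame([[1.0, 2.0, 3.0, 3.0, 4.0, 5.0]], two_by_three_design)
        res = two_group_ttest(m, two_by_three_design, "A", "B")
        assert res.loc["p0", "log2fc"] == pytest.approx(2.0)
        assert res.loc["p0", "t"] == pytest.approx(2.449, abs=1e-3)
        expected_p = 2 * stats.t.sf(2.0 / np.sqrt(2.0 / 3.0), 4)
        assert res.loc["p0", "p_value"] == pytest.approx(expected_p, rel=1e-12)
        assert expected_p == pytest.approx(0.0705, abs=2e-4)

    def test_identical_groups_give_p_one(self, two_by_three_design):
        m = frame([[5.0] * 6, [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], two_by_three_design)
        res = two_group_ttest(m, two_by_three_design, "A", "B")
        assert res.loc["p0", "p_value"] == 1.0 and res.loc["p0", "log2fc"] == 0.0
        assert res.loc["p1", "p_value"] == 1.0

    def test_zero_variance_nonzero_difference_warns_p_zero(self, two_by_three_design):
        m = frame([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0]], two_by_three_design)
        with pytest.warns(UserWarning, match="zero pooled variance"):
            res = two_group_ttest(m, two_by_three_design, "A", "B")
        assert res.loc["p0", "p_value"] == 0.0

    def test_agrees_with_scipy_on_random_data(self, two_by_three_design):
        rng = np.random.default_rng(1)
        m = frame(rng.normal(20, 1, size=(50, 6)), two_by_three_design)
        res = two_group_ttest(m, two_by_three_design, "A", "B")
        ref = stats.ttest_ind(
            m.iloc[:, 3:], m.iloc[:, :3], axis=1, equal_var=True
        )
        np.testing.assert_allclose(res["p_value"], ref.pvalue, rtol=1e-10)
        np.testing.assert_allclose(res["t"], ref.statistic, rtol=1e-10)

    def test_unknown_group_and_missing_values_rejected(self, two_by_three_design):
        m = frame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], two_by_three_design)
        with pytest.raises(KeyError):
            two_group_ttest(m, two_by_three_design, "A", "Z")
        m.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            two_group_ttest(m, two_by_three_design, "A", "B")


class TestAnova:
    @pytest.fixture
    def design3(self):
        return SampleDesign(
            pd.DataFrame(
                {
                    "sample_id": [f"{c}{r}" for c in "ABC" for r in (1, 2, 3)],
                    "condition": [c for c in "ABC" for _ in range(3)],
                    "replicate": [1, 2, 3] * 3,
                }
            )
        )

    def test_identical_groups_give_p_one(self, design3):
        m = frame([[7.0] * 9], design3)
        p = anova_multi(m, design3, ["A", "B", "C"])
        assert p.iloc[0] == 1.0

    def test_separated_group_gives_tiny_p(self, design3):
        m = frame([[0, 0.01, -0.01, 0, 0.01, -0.01, 10, 10.01, 9.99]], design3)
        p = anova_multi(m, design3, ["A", "B", "C"])
        assert p.iloc[0] < 1e-6

    def test_agrees_with_scipy_f_oneway(self, design3):
        rng = np.random.default_rng(2)
        m = frame(rng.normal(0, 1, size=(40, 9)), design3)
        p = anova_multi(m, design3, ["A", "B", "C"])
        ref = stats.f_oneway(
            m.iloc[:, 0:3], m.iloc[:, 3:6], m.iloc[:, 6:9], axis=1
        )
        np.testing.assert_allclose(p, ref.pvalue, rtol=1e-10)

    def test_needs_three_groups(self, two_by_three_design, small_matrix):
        logm = np.log2(small_matrix)
        with pytest.raises(ValueError, match=">= 3 groups"):
            anova_multi(logm, two_by_three_design, ["A", "B"])


def bh_brute_force(p):
    """BH step-up from the definition: q_(i) = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running_min = np.inf
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * n / rank)
        q[idx] = min(running_min, 1.0)
    return q


class TestAdjustBH:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.03], [0.03]),
            ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
            ([0.01, 0.02, 0.03, 0.5], [0.04, 0.04, 0.04, 0.5]),
        ],
    )
    def test_known_vectors(self, p, expected):
        np.testing.assert_allclose(adjust_bh(p), expected, rtol=1e-12)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(adjust_bh(p), bh_brute_force(p), rtol=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_monotone_in_p_rank(self, p):
        q = adjust_bh(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all((q >= 0) & (q <= 1))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])


class TestRegulationCalls:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [
            (6.09, 0.0005, "UP"),  # a ~68-fold induction
            (1.0, 0.001, "NS"),  # threshold is strict
            (-2.0, 0.04, "DOWN"),
            (-1.0, 0.001, "NS"),
            (2.0, 0.05, "NS"),  # p threshold is strict too
            (0.5, 0.001, "NS"),
        ],
    )
    def test_threshold_logic(self, fc, p, expected):
        res = pd.DataFrame({"log2fc": [fc], "p_value": [p]})
        assert call_regulation(res)[0] == expected


class TestPresence:
    def test_uniqueness_labels_and_threshold(self, two_by_three_design):
        m = frame(
            [
                [1, 1, 1, np.nan, np.nan, np.nan],  # unique to A
                [1, 1, 1, 1, 1, 1],  # shared
                [1, np.nan, np.nan, np.nan, np.nan, np.nan],  # 1/3 < 70%: absent
            ],
            two_by_three_design,
        )
        tab = presence_call(m, two_by_three_design)
        assert tab.loc["p0", "uniqueness"] == "unique:A"
        assert tab.loc["p1", "uniqueness"] == "shared"
        assert not tab.loc["p2", "detected_A"]
        assert tab.loc["p2", "uniqueness"] == "absent"
        assert tab.loc["p2", "valid_fraction_A"] == pytest.approx(1 / 3)


class TestOverlap:
    def test_intersection_counts(self):
        a = pd.Series(["UP", "UP", "NS", "DOWN"], index=list("wxyz"))
        b = pd.Series(["NS", "UP", "UP", "DOWN"], index=list("wxyz"))
        ov = overlap_counts(a, b)
        assert (ov.n_common_up, ov.n_common_down) == (1, 1)
        assert (ov.n_up_a, ov.n_up_b) == (2, 2)

    def test_identity_and_disjoint(self):
        a = pd.Series(["UP", "DOWN", "NS"], index=list("xyz"))
        same = overlap_counts(a, a)
        assert same.n_common_up == same.n_up_a == 1
        b = pd.Series(["NS", "NS", "UP"], index=list("xyz"))
        assert overlap_counts(a, b).n_common_up == 0

    def test_mismatched_universe_rejected(self):
        a = pd.Series(["UP"], index=["x"])
        b = pd.Series(["UP"], index=["y"])
        with pytest.raises(ValueError, match="universe"):
            overlap_counts(a, b)


class TestDifferentialExpression:
    def test_q_values_and_calls_attached(self, two_by_three_design):
        rng = np.random.default_rng(3)
        m = frame(rng.normal(20, 0.3, size=(30, 6)), two_by_three_design)
        m.iloc[:5, 3:] += 3.0  # strong induction in B
        res = differential_expression(m, two_by_three_design, "A", "B")
        assert set(res.columns) >= {"log2fc", "p_value", "q_value", "call"}
        assert (res["call"].iloc[:5] == "UP").all()
        np.testing.assert_allclose(
            res["q_value"], bh_brute_force(res["p_value"]), rtol=1e-12
        )
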