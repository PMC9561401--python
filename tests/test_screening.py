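"""Logical-attribute screening: thresholds, odds ratios, Fisher inference."""

from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss
from hypothesis import given, settings, strategies as st

import talentscreen as ts
from talentscreen.screening import (
    BRANCH_DEGENERATE,
    BRANCH_FALLBACK,
    N_GRID,
    optimize_parameter,
    parameter_vector,
)

from conftest import published_counts


def fisher_brute_force(a, b, c, d, alternative="two-sided"):
    """Independent oracle: explicit enumeration of all fixed-margin tables."""
    m, nh, nl = a + b, a + c, b + d
    denom = comb(nh + nl, m)
    support = range(max(0, m - nl), min(nh, m) + 1)
    probs = {k: comb(nh, k) * comb(nl, m - k) / denom for k in support}
    if alternative == "greater":
        return sum(p for k, p in probs.items() if k >= a)
    if alternative == "less":
        return sum(p for k, p in probs.items() if k <= a)
    return sum(p for p in probs.values() if p <= probs[a] * (1 + 1e-7))


def _labels(high_mask, index=None):
    idx = index if index is not None else pd.Index([f"a{i}" for i in range(len(high_mask))])
    return ts.GroupLabels.from_series(pd.Series(np.where(high_mask, "high", "low"), index=idx))


class TestParameterVector:
    def test_unit_spacing_over_0_99(self):
        vec = parameter_vector(pd.Series(np.arange(100.0)))
        assert np.allclose(vec.thresholds, np.arange(100.0))

    def test_constant_column_flagged_degenerate(self):
        vec = parameter_vector(pd.Series([5.0] * 8))
        assert vec.degenerate
        assert np.all(vec.thresholds == 5.0)

    def test_fully_missing_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            parameter_vector(pd.Series([np.nan, np.nan]))

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=40))
    @settings(max_examples=50, derandomize=True)
    def test_grid_geometry(self, values):
        vec = parameter_vector(pd.Series(values))
        x = np.asarray(values)
        assert len(vec) == N_GRID
        assert vec.thresholds[0] == x.min() and vec.thresholds[-1] == x.max()
        spacing = np.diff(vec.thresholds)
        assert np.allclose(spacing, (x.max() - x.min()) / (N_GRID - 1), atol=1e-9)


class TestBinarize:
    def test_worked_example_sports_sampled_over_2_5(self):
        out = ts.binarize(pd.Series([1.0, 2.0, 3.0]), 2.5)
        assert list(out.indicator) == [0.0, 0.0, 1.0]

    def test_theta_below_minimum_all_one(self):
        out = ts.binarize(pd.Series([1.0, 2.0, 3.0]), 0.5)
        assert out.n_exposed == 3

    def test_missing_propagates(self):
        out = ts.binarize(pd.Series([1.0, np.nan]), 0.0)
        assert np.isnan(out.indicator.iloc[1])

    def test_ties_code_zero_by_default_one_on_request(self):
        vals = pd.Series([2.0, 3.0])
        assert ts.binarize(vals, 2.0).indicator.iloc[0] == 0.0
        assert ts.binarize(vals, 2.0, ties="one").indicator.iloc[0] == 1.0

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=30), st.floats(-50, 50))
    @settings(max_examples=60, derandomize=True)
    def test_count_matches_brute_force(self, values, theta):
        out = ts.binarize(pd.Series(values), theta)
        assert out.n_exposed == sum(1 for v in values if v > theta)


class TestContingency:
    def test_published_cell_pattern(self):
        ind = pd.Series([1.0] * 4 + [0.0] * 2 + [1.0] * 1 + [0.0] * 22)
        high = np.zeros(29, bool)
        high[:6] = True
        counts, _ = ts.contingency(
            ts.LogicalAttribute("x", 0.0, ind), _labels(high, ind.index)
        )
        assert (counts.a, counts.b, counts.c, counts.d) == (4, 1, 2, 22)

    def test_nobody_exposed(self):
        ind = pd.Series([0.0] * 10)
        counts, _ = ts.contingency(ts.LogicalAttribute("x", 0.0, ind), _labels([True] * 3 + [False] * 7, ind.index))
        assert (counts.a, counts.b, counts.c, counts.d) == (0, 0, 3, 7)

    def test_missing_excluded_and_tallied(self):
        ind = pd.Series([1.0, np.nan, 0.0, 1.0, np.nan, 0.0])
        counts, n_excl = ts.contingency(
            ts.LogicalAttribute("x", 0.0, ind), _labels([True, True, True, False, False, False], ind.index)
        )
        assert n_excl == 2
        assert counts.n == 4

    @given(st.integers(2, 8), st.integers(2, 12), st.integers(0, 10**6))
    @settings(max_examples=40, derandomize=True)
    def test_margins_reproduce_group_sizes(self, n_high, n_low, seed):
        rng = np.random.default_rng(seed)
        n = n_high + n_low
        ind = pd.Series(rng.integers(0, 2, n).astype(float))
        counts, _ = ts.contingency(
            ts.LogicalAttribute("x", 0.0, ind), _labels([True] * n_high + [False] * n_low, ind.index)
        )
        assert counts.n_high == n_high and counts.n_low == n_low


class TestOddsRatioSmall:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (published_counts(4, 1), 88 / 6),  # 14.67
            (published_counts(2, 0), 46 / 5),  # 9.2
            ((ts.ContingencyCounts(0, 5, 3, 9)), 0.0),
        ],
    )
    def test_examples(self, counts, expected):
        assert ts.odds_ratio_small(counts) == pytest.approx(expected)

    def test_finite_for_zero_cells(self):
        for counts in (ts.ContingencyCounts(3, 0, 0, 5), ts.ContingencyCounts(0, 0, 4, 4)):
            assert np.isfinite(ts.odds_ratio_small(counts))


class TestFisher:
    def test_balanced_table_p_one(self):
        assert ts.fisher_exact(ts.ContingencyCounts(3, 3, 3, 3)) == pytest.approx(1.0)

    def test_published_discriminator_is_significant(self):
        assert ts.fisher_exact(published_counts(4, 1)) < 0.05

    def test_matches_scipy_and_enumeration(self, rng):
        for _ in range(80):
            n = int(rng.integers(4, 31))
            a, b, c = (int(v) for v in rng.multinomial(n, [0.25] * 4)[:3])
            d = n - a - b - c
            counts = ts.ContingencyCounts(a, b, c, d)
            for alt in ("two-sided", "greater", "less"):
                mine = ts.fisher_exact(counts, alt)
                assert mine == pytest.approx(fisher_brute_force(a, b, c, d, alt), abs=1e-12)
                alt_scipy = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[alt]
                assert mine == pytest.approx(
                    ss.fisher_exact([[a, b], [c, d]], alternative=alt_scipy).pvalue, abs=1e-9
                )

    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8))
    @settings(max_examples=60, derandomize=True)
    def test_transposition_symmetry(self, a, b, c, d):
        """Swapping groups and exposure together leaves the two-sided p unchanged."""
        if (a + c == 0) or (b + d == 0) or (a + b + c + d == 0):
            return
        p1 = ts.fisher_exact(ts.ContingencyCounts(a, b, c, d))
        p2 = ts.fisher_exact(ts.ContingencyCounts(d, c, b, a))
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestFisherCI:
    def test_zero_numerator_lower_bound_zero(self):
        lo, hi = ts.fisher_ci(ts.ContingencyCounts(0, 5, 4, 9))
        assert lo == 0.0

    def test_zero_cell_upper_bound_open(self):
        lo, hi = ts.fisher_ci(ts.ContingencyCounts(4, 0, 2, 23))
        assert hi == np.inf

    def test_brackets_conditional_mle_for_random_tables(self, rng):
        for _ in range(20):
            a, b, c, d = (int(v) for v in rng.integers(1, 9, 4))
            lo, hi = ts.fisher_ci(ts.ContingencyCounts(a, b, c, d))
            cmle = ss.contingency.odds_ratio([[a, b], [c, d]], kind="conditional").statistic
            assert lo <= cmle <= hi

    def test_contains_published_point_estimate(self):
        lo, hi = ts.fisher_ci(published_counts(4, 1))
        assert lo < 14.67 < hi


class TestTruePositiveRate:
    def test_examples(self):
        assert ts.true_positive_rate(published_counts(4, 1)) == pytest.approx(4 / 6)
        assert ts.true_positive_rate(published_counts(6, 10)) == 1.0
        assert ts.true_positive_rate(ts.ContingencyCounts(0, 3, 5, 4)) == 0.0

    def test_empty_high_group_rejected(self):
        with pytest.raises(ValueError):
            ts.true_positive_rate(ts.ContingencyCounts(0, 3, 0, 4))


class TestOptimizeParameter:
    def test_null_attribute_falls_back_to_range_minimum(self, rng):
        values = pd.Series(rng.normal(size=29), index=[f"a{i}" for i in range(29)])
        high = np.zeros(29, bool)
        high[rng.choice(29, 6, replace=False)] = True
        labels = _labels(high, values.index)
        # at a vanishing alpha no threshold can be significant: branch 3 fires
        opt = optimize_parameter(values, labels, alpha=1e-9)
        assert opt.branch == BRANCH_FALLBACK
        assert opt.theta == values.min()

    def test_theta_always_grid_member(self, rng):
        for _ in range(10):
            values = pd.Series(rng.normal(size=20), index=[f"a{i}" for i in range(20)])
            high = np.zeros(20, bool)
            high[rng.choice(20, 5, replace=False)] = True
            labels = _labels(high, values.index)
            vec = parameter_vector(values)
            opt = optimize_parameter(values, labels, vec)
            assert np.isclose(vec.thresholds, opt.theta).any()

    def test_perfect_separation_matches_exhaustive_oracle(self, rng):
        low_vals = rng.uniform(0, 10, 23)
        high_vals = rng.uniform(12, 20, 6)
        values = pd.Series(np.concatenate([high_vals, low_vals]), index=[f"a{i}" for i in range(29)])
        labels = _labels([True] * 6 + [False] * 23, values.index)
        vec = parameter_vector(values)
        opt = optimize_parameter(values, labels, vec)

        # exhaustive oracle: scan the grid with scipy's Fisher test
        oracle_idx = None
        for i, theta in enumerate(vec.thresholds):
            a = int((high_vals > theta).sum())
            b = int((low_vals > theta).sum())
            p = ss.fisher_exact([[a, b], [6 - a, 23 - b]], alternative="greater").pvalue
            if p < 0.05:
                oracle_idx = i
                break
        assert oracle_idx is not None
        assert opt.index == oracle_idx
        assert opt.theta == pytest.approx(vec.thresholds[oracle_idx])

    def test_protective_attribute_selectable_via_single_direction(self):
        # rule prevalent among low performers only: protective direction
        values = pd.Series([0.0] * 6 + [1.0] * 22 + [0.0], index=[f"a{i}" for i in range(29)])
        labels = _labels([True] * 6 + [False] * 23, values.index)
        opt = optimize_parameter(values, labels)
        counts, _ = ts.contingency(ts.binarize(values, opt.theta), labels)
        assert ts.fisher_exact(counts) < 0.05
        assert ts.odds_ratio_small(counts) < 1

    def test_degenerate_attribute_status(self):
        values = pd.Series([2.0] * 10, index=[f"a{i}" for i in range(10)])
        labels = _labels([True] * 3 + [False] * 7, values.index)
        opt = optimize_parameter(values, labels)
        assert opt.branch == BRANCH_DEGENERATE and opt.theta == 2.0

    def test_exposure_count_monotone_in_theta(self, rng):
        values = pd.Series(rng.normal(size=15))
        vec = parameter_vector(values)
        exposed = [ts.binarize(values, t).n_exposed for t in vec.thresholds]
        assert all(x >= y for x, y in zip(exposed, exposed[1:]))


class TestImportance:
    def test_fig_style_calibration_pair(self):
        # OR 14.67 at TPR 66.7% within the published distribution grades High
        assert ts.grade_importance(14.67, 4 / 6, True) == "high"

    def test_moderate_example(self):
        assert ts.grade_importance(9.2, 2 / 6, True) == "moderate"

    def test_not_significant_dominates(self):
        assert ts.grade_importance(100.0, 1.0, False) == "not_significant"

    def test_zero_tpr_without_counts_is_lowest_grade(self):
        assert ts.grade_importance(0.0, 0.0, True) == "low"

    def test_protective_with_low_rate_grades_high(self):
        # mastery-avoidance style: OR 0.04, prevalent in 21/23 low performers
        assert ts.grade_importance(0.04, 2 / 6, True, low_rate=21 / 23) == "high"

    def test_percentile_anchor_mode_available(self):
        scales = ts.ImportanceScales.from_distribution([5.0, 8.0, 9.0, 12.0, 17.0, 31.0])
        assert scales.or_anchors[0] == 5.0 and scales.or_anchors[-1] == 31.0


class TestCommonalities:
    def _screen_frame(self, tpr, low_rate, p):
        return pd.DataFrame(
            {"theta": [0.0], "tpr": [tpr], "low_rate": [low_rate], "p_value": [p]},
            index=pd.Index(["attr"], name="attribute"),
        )

    def test_prevalent_non_discriminator_flagged(self):
        out = ts.find_commonalities(self._screen_frame(0.9, 0.9, 0.5))
        assert list(out.index) == ["attr"]
        assert out["review_theoretical_relevance"].all()

    def test_discriminator_contrast_not_flagged(self):
        assert len(ts.find_commonalities(self._screen_frame(0.9, 0.1, 0.001))) == 0

    def test_flags_match_brute_force_on_random_screens(self, rng):
        n = 50
        frame = pd.DataFrame(
            {
                "theta": np.zeros(n),
                "tpr": rng.uniform(0, 1, n),
                "low_rate": rng.uniform(0, 1, n),
                "p_value": rng.uniform(0, 1, n),
            },
            index=pd.Index([f"x{i}" for i in range(n)], name="attribute"),
        )
        flagged = set(ts.find_commonalities(frame).index)
        expected = {
            i
            for i in frame.index
            if frame.loc[i, "p_value"] >= 0.05
            and frame.loc[i, "tpr"] >= 0.6
            and frame.loc[i, "low_rate"] >= 0.6
        }
        assert flagged == expected


class TestScreenDriver:
    def test_deterministic_and_complete(self, small_cohort):
        screen1 = ts.screen_attributes(small_cohort.features, small_cohort.labels, compute_ci=False)
        screen2 = ts.screen_attributes(small_cohort.features, small_cohort.labels, compute_ci=False)
        pd.testing.assert_frame_equal(screen1, screen2)
        assert len(screen1) == small_cohort.features.n_attributes

    def test_planted_prevalence_effect_detected(self, small_cohort):
        row = ts.screen_attributes(
            small_cohort.features, small_cohort.labels, compute_ci=False
        ).loc["planted_prev"]
        assert row["significant"]
        assert row["or_small"] > 1
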