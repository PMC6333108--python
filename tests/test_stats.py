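"""Cohort statistics: agreement, discrimination, clustered contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octapcd.errors import UndefinedStatisticError, ValidationError
from octapcd.stats import (
    bland_altman,
    compare_groups,
    format_p,
    quality_disagreement_correlation,
    roc_from_values,
)
from octapcd.synthetic import CohortSpec, generate_cohort


def brute_force_auc(pos, neg):
    """Mann-Whitney U / (n1*n2) by direct pair enumeration (ties count 1/2)."""
    wins = sum(1.0 * (p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestBlandAltman:
    def test_identical_pairs_have_zero_bias_and_width(self):
        res = bland_altman([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert res.bias == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_constant_offset_pairs(self):
        """Pairs {(10,20),(20,30),(30,40)}: bias 10, SD 0, LoA (10, 10)."""
        res = bland_altman([10.0, 20.0, 30.0], [20.0, 30.0, 40.0])
        assert res.bias == 10.0
        assert res.sd_diff == 0.0
        assert (res.loa_low, res.loa_high) == (10.0, 10.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0, 2.0], [2.0, 3.0])

    def test_proportional_bias_sign(self):
        """When the gap shrinks as the magnitude grows, the bias-magnitude
        correlation is negative (the direction reported for both slabs)."""
        rng = np.random.default_rng(0)
        custom = rng.uniform(10, 50, 200)
        commercial = custom + (40 - 0.5 * custom) + rng.normal(0, 2, 200)
        res = bland_altman(custom, commercial)
        assert res.r_bias_vs_magnitude < -0.5
        assert res.r_p < 0.001

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(0, 100), st.floats(0, 100)),
            min_size=3,
            max_size=40,
        )
    )
    def test_midpoint_identity_always_holds(self, pairs):
        custom = [a for a, _ in pairs]
        commercial = [b for _, b in pairs]
        res = bland_altman(custom, commercial)
        assert (res.loa_low + res.loa_high) / 2.0 == pytest.approx(res.bias, abs=1e-12)


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        res = roc_from_values([5.0, 6.0, 7.0], [1.0, 2.0, 3.0], direction="higher")
        assert res.auc == 1.0

    def test_auc_equals_mann_whitney_on_toy_set(self):
        pos = [3.0, 5.0, 6.0]
        neg = [1.0, 2.0, 5.0]
        res = roc_from_values(pos, neg, direction="higher")
        assert res.auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    def test_ties_counted_half(self):
        res = roc_from_values([1.0, 2.0], [1.0, 2.0])
        assert res.auc == 0.5

    def test_direction_lower_flips_orientation(self):
        pos = [1.0, 2.0, 3.0]
        neg = [5.0, 6.0, 7.0]
        assert roc_from_values(pos, neg, direction="lower").auc == 1.0
        assert roc_from_values(pos, neg, direction="higher").auc == 0.0

    def test_cutoff_sensitivity_specificity(self):
        """'Below cutoff' positives: sensitivity counts positives strictly
        below, specificity counts negatives at or above."""
        pos = [10.0, 20.0, 30.0]  # low values = diseased
        neg = [20.0, 35.0, 45.0]
        res = roc_from_values(pos, neg, direction="lower", cutoffs=[22.6])
        (point,) = res.cutoff_points
        assert point.sensitivity == pytest.approx(2 / 3)
        assert point.specificity == pytest.approx(2 / 3)

    def test_degenerate_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_from_values([], [1.0])

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(1.0, 1.0, 15)
        neg = rng.normal(0.0, 1.0, 12)
        base = roc_from_values(pos, neg).auc
        for f in (np.exp, lambda x: x**3, lambda x: 5 * x - 2):
            assert roc_from_values(f(pos), f(neg)).auc == pytest.approx(base, abs=1e-12)

    def test_delong_ci_brackets_auc_and_shrinks(self):
        rng = np.random.default_rng(1)
        small = roc_from_values(rng.normal(1, 1, 20), rng.normal(0, 1, 20))
        large = roc_from_values(rng.normal(1, 1, 400), rng.normal(0, 1, 400))
        assert small.auc_ci[0] <= small.auc <= small.auc_ci[1]
        assert (large.auc_ci[1] - large.auc_ci[0]) < (small.auc_ci[1] - small.auc_ci[0])


class TestCompareGroups:
    @staticmethod
    def cohort(mean_a, mean_b, sd=5.0, n_subjects=20, seed=0):
        spec = CohortSpec(
            groups=[("a", n_subjects, 2 * n_subjects), ("b", n_subjects, 2 * n_subjects)],
            metric_params={"m": {"a": (mean_a, sd), "b": (mean_b, sd)}},
            subject_sd=sd / np.sqrt(2),
            seed=seed,
        )
        return generate_cohort(spec)

    def test_detects_large_difference(self):
        table = self.cohort(150.1, 101.7)
        res = compare_groups(table, "m")
        c = res.contrast("a", "b")
        assert c.p_adjusted < 0.001
        assert c.p_display == "<0.001"

    def test_null_difference_not_significant_typically(self):
        hits = 0
        for seed in range(20):
            res = compare_groups(self.cohort(10.0, 10.0, sd=2.0, seed=seed), "m")
            if res.contrast("a", "b").p_adjusted < 0.05:
                hits += 1
        assert hits <= 3

    def test_single_group_rejected(self):
        spec = CohortSpec(
            groups=[("a", 5, 5)],
            metric_params={"m": {"a": (1.0, 1.0)}},
            seed=0,
        )
        with pytest.raises(ValidationError):
            compare_groups(generate_cohort(spec), "m")

    def test_missing_metric_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups(self.cohort(1.0, 1.0), "absent")

    def test_one_eye_per_subject_falls_back_to_ols(self):
        spec = CohortSpec(
            groups=[("a", 15, 15), ("b", 15, 15)],
            metric_params={"m": {"a": (10.0, 2.0), "b": (12.0, 2.0)}},
            subject_sd=0.0,
            seed=0,
        )
        res = compare_groups(generate_cohort(spec), "m")
        assert res.contrast("a", "b").method == "ols"
        assert res.notes

    def test_bonferroni_scales_with_pairs(self):
        spec = CohortSpec(
            groups=[("a", 10, 20), ("b", 10, 20), ("c", 10, 20)],
            metric_params={"m": {g: (10.0, 2.0) for g in "abc"}},
            subject_sd=1.0,
            seed=2,
        )
        res = compare_groups(generate_cohort(spec), "m")
        assert res.n_pairs == 3
        for c in res.contrasts:
            assert c.p_adjusted == pytest.approx(min(1.0, c.p_raw * 3))


class TestQualityCorrelation:
    def test_null_correlation_small(self):
        rng = np.random.default_rng(3)
        r, _ = quality_disagreement_correlation(
            rng.normal(25, 5, 500), rng.normal(65, 6, 500)
        )
        assert abs(r) < 0.1

    def test_induced_negative_correlation_detected(self):
        rng = np.random.default_rng(4)
        ssi = rng.normal(65, 6, 300)
        diff = 60 - 0.5 * ssi + rng.normal(0, 2, 300)
        r, p = quality_disagreement_correlation(diff, ssi)
        assert r < -0.5
        assert p < 0.001

    def test_too_few_eyes_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            quality_disagreement_correlation([1.0, 2.0], [50.0, 60.0])

    def test_constant_ssi_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            quality_disagreement_correlation([1.0, 2.0, 3.0], [60.0, 60.0, 60.0])


def test_p_value_display_conventions():
    assert format_p(0.0005) == "<0.001"
    assert format_p(0.995) == ">0.99"
    assert format_p(0.43) == "0.43"
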