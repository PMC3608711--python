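"""ROC curves, DeLong comparison, cutoffs and operating points."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from darklung import (
    delong_compare,
    optimal_cutoff,
    roc_curve,
    sensitivity_at_specificity,
)
from darklung.roc import RocError

from conftest import pair_count_auc


class TestRocCurve:
    def test_small_example_auc(self):
        scores = np.array([3.0, 5.0, 1.0, 4.0])
        labels = np.array([True, True, False, False])
        c = roc_curve(scores, labels, "greater_is_diseased")
        assert c.auc == pytest.approx(0.75)
        assert c.n_pos == 2 and c.n_neg == 2

    def test_perfect_separation(self):
        scores = np.array([10.0, 11.0, 1.0, 2.0])
        labels = np.array([True, True, False, False])
        assert roc_curve(scores, labels, "greater_is_diseased").auc == 1.0

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=4000)
        labels = rng.random(4000) < 0.5
        c = roc_curve(scores, labels, "greater_is_diseased")
        assert c.auc == pytest.approx(0.5, abs=0.03)

    def test_monotone_operating_points(self):
        rng = np.random.default_rng(1)
        scores = np.round(rng.normal(size=500), 1)  # plenty of ties
        labels = rng.random(500) < 0.4
        c = roc_curve(scores, labels, "greater_is_diseased")
        assert (np.diff(c.sensitivity) <= 1e-12).all()
        assert (np.diff(c.specificity) >= -1e-12).all()

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.integers(0, 8), min_size=1, max_size=40),
        st.lists(st.integers(0, 8), min_size=1, max_size=40),
    )
    def test_auc_equals_pair_counting_mann_whitney(self, pos, neg):
        """Trapezoidal AUC == tie-aware concordant-pair fraction, to
        1e-12, on arbitrary integer scores (heavy ties included)."""
        scores = np.array(pos + neg, dtype=float)
        labels = np.array([True] * len(pos) + [False] * len(neg))
        c = roc_curve(scores, labels, "greater_is_diseased")
        assert abs(c.auc - pair_count_auc(scores, labels)) < 1e-12

    def test_orientation_flip_mirrors_auc(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=300) + np.repeat([0.0, 1.0], 150)
        labels = np.repeat([False, True], 150)
        a = roc_curve(scores, labels, "greater_is_diseased").auc
        b = roc_curve(scores, labels, "less_is_diseased").auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(RocError, match="both classes"):
            roc_curve(np.arange(5.0), np.ones(5, bool), "greater_is_diseased")


class TestDelong:
    def test_self_comparison_is_null(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.5
        with pytest.warns(UserWarning, match="degenerate"):
            r = delong_compare(scores, scores, labels)
        assert r.z == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_variance_matches_stratified_bootstrap(self):
        """On a 30-unit paired set the DeLong variance of the AUC
        difference agrees with a 10^4-replicate stratified bootstrap
        within 10%."""
        rng = np.random.default_rng(4)
        n = 15
        labels = np.repeat([True, False], n)
        latent = rng.normal(size=2 * n)
        scores_a = latent + np.where(labels, 1.0, 0.0) + rng.normal(0, 0.5, 2 * n)
        scores_b = latent + np.where(labels, 0.6, 0.0) + rng.normal(0, 0.8, 2 * n)
        r = delong_compare(scores_a, scores_b, labels)

        reps = 10_000
        pos_idx = rng.integers(0, n, (reps, n))
        neg_idx = n + rng.integers(0, n, (reps, n))

        def auc(scores, pi, ni):
            x = scores[pi][:, :, None]
            y = scores[ni][:, None, :]
            return ((x > y) + 0.5 * (x == y)).mean(axis=(1, 2))

        diff = auc(scores_a, pos_idx, neg_idx) - auc(scores_b, pos_idx, neg_idx)
        var_boot = diff.var(ddof=1)
        var_delong = (
            r.covariance[0, 0] + r.covariance[1, 1] - 2 * r.covariance[0, 1]
        )
        assert var_delong == pytest.approx(var_boot, rel=0.10)

    def test_large_separation_significant(self):
        rng = np.random.default_rng(5)
        labels = np.repeat([True, False], 400)
        good = np.where(labels, 2.0, 0.0) + rng.normal(0, 1, 800)
        weak = rng.normal(0, 1, 800)
        r = delong_compare(good, weak, labels)
        assert r.auc_a > r.auc_b
        assert r.p < 1e-6

    def test_degenerate_variance_warns_p_one(self):
        scores = np.array([1.0, 1.0, 0.0, 0.0])
        labels = np.array([True, True, False, False])
        with pytest.warns(UserWarning, match="degenerate"):
            r = delong_compare(scores, scores, labels)
        assert r.p == 1.0


class TestCutoff:
    def test_separated_classes_midpoint_of_gap(self):
        scores = np.array([3.0, 5.0, 1.0, 2.0])
        labels = np.array([True, True, False, False])
        c = roc_curve(scores, labels, "greater_is_diseased")
        assert optimal_cutoff(c) == pytest.approx(2.5)

    def test_youden_example_with_overlap(self):
        """pos {3,5}, neg {1,4}: J peaks at 0.5 with the chosen cutoff
        in (4, 5] (tie broken toward higher specificity)."""
        scores = np.array([3.0, 5.0, 1.0, 4.0])
        labels = np.array([True, True, False, False])
        c = roc_curve(scores, labels, "greater_is_diseased")
        cut = optimal_cutoff(c)
        assert 4.0 < cut <= 5.0
        j = c.sensitivity + c.specificity - 1.0
        assert j.max() == pytest.approx(0.5)

    def test_less_is_diseased_cutoff_in_score_scale(self):
        scores = np.array([1.0, 2.0, 8.0, 9.0])
        labels = np.array([True, True, False, False])
        c = roc_curve(scores, labels, "less_is_diseased")
        assert c.auc == 1.0
        assert optimal_cutoff(c) == pytest.approx(5.0)


class TestSensitivityAtSpecificity:
    def test_perfect_separation_gives_one(self):
        scores = np.array([3.0, 5.0, 1.0, 2.0])
        labels = np.array([True, True, False, False])
        c = roc_curve(scores, labels, "greater_is_diseased")
        for level in (0.25, 0.5, 0.9):
            assert sensitivity_at_specificity(c, level) == 1.0

    def test_overlap_example(self):
        scores = np.array([3.0, 5.0, 1.0, 4.0])
        labels = np.array([True, True, False, False])
        c = roc_curve(scores, labels, "greater_is_diseased")
        assert sensitivity_at_specificity(c, 0.75) == pytest.approx(0.5)

    def test_level_out_of_range_rejected(self):
        scores = np.array([3.0, 5.0, 1.0, 4.0])
        labels = np.array([True, True, False, False])
        c = roc_curve(scores, labels, "greater_is_diseased")
        with pytest.raises(ValueError):
            sensitivity_at_specificity(c, 1.5)
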