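"""Threshold optimization, ROC/AUC and performance reports."""

import itertools

import numpy as np
import pytest

from msisig.errors import ValidationError
from msisig.evaluation import (
    optimize_primary_threshold,
    optimize_secondary_threshold,
    performance_report,
    roc_auc,
)


def brute_force_best_sum(indices, labels):
    """Exhaustive sens+spec maximum over every possible decision boundary."""
    indices = np.asarray(indices, dtype=float)
    labels = np.asarray(labels)
    best = -np.inf
    for thr in np.concatenate((indices - 1e-9, indices + 1e-9, [indices.min() - 1, indices.max() + 1])):
        pos = indices >= thr
        sens = np.sum(pos & (labels == 1)) / np.sum(labels == 1)
        spec = np.sum(~pos & (labels == 0)) / np.sum(labels == 0)
        best = max(best, sens + spec)
    return best


def sens_spec(indices, labels, thr):
    pos = np.asarray(indices) >= thr
    labels = np.asarray(labels)
    return (
        np.sum(pos & (labels == 1)) / np.sum(labels == 1),
        np.sum(~pos & (labels == 0)) / np.sum(labels == 0),
    )


class TestPrimaryThreshold:
    def test_perfect_separation_picks_gap(self):
        idx = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        thr = optimize_primary_threshold(idx, labels)
        assert 0.2 < thr < 0.8
        assert sens_spec(idx, labels, thr) == (1.0, 1.0)

    def test_interleaved_case_matches_enumeration(self):
        idx = np.array([0.1, 0.2, 0.3, 0.4])
        labels = np.array([0, 1, 0, 1])
        thr = optimize_primary_threshold(idx, labels)
        s, p = sens_spec(idx, labels, thr)
        assert s + p == pytest.approx(1.5)
        assert thr < 0.2  # lowest optimal boundary, favoring sensitivity

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 60))
            idx = np.round(rng.normal(size=n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            thr = optimize_primary_threshold(idx, labels)
            s, p = sens_spec(idx, labels, thr)
            assert s + p == pytest.approx(brute_force_best_sum(idx, labels), abs=1e-12)

    def test_sensitivity_floor_rule(self, rng):
        idx = np.concatenate((rng.normal(1, 1, 30), rng.normal(-1, 1, 70)))
        labels = np.array([1] * 30 + [0] * 70)
        thr = optimize_primary_threshold(idx, labels, rule="max_sens_plus_spec_with_floor", sens_floor=0.9)
        s, _ = sens_spec(idx, labels, thr)
        assert s >= 0.9

    def test_unattainable_floor_reports_max_sensitivity(self):
        idx = np.array([0.0, 1.0])
        labels = np.array([1, 0])
        with pytest.raises(ValidationError, match="unattainable"):
            # sensitivity 1 requires calling the higher-index MSS sample
            # positive too; a floor above 1 can never be met
            optimize_primary_threshold(idx, labels, rule="max_sens_plus_spec_with_floor", sens_floor=1.1)

    def test_null_data_sum_near_one(self, rng):
        idx = rng.normal(size=300)
        labels = rng.integers(0, 2, 300)
        thr = optimize_primary_threshold(idx, labels)
        s, p = sens_spec(idx, labels, thr)
        assert s + p <= 1.25


class TestSecondaryThreshold:
    def test_separated_hospital_classes_split_in_gap(self):
        idx = np.array([0.2, 0.25, 0.6, 0.7])
        hosp = np.array([0, 0, 1, 1])
        thr = optimize_secondary_threshold(idx, hosp)
        assert 0.25 < thr < 0.6

    def test_single_class_positives_rejected(self):
        with pytest.raises(ValidationError, match="single"):
            optimize_secondary_threshold([0.3, 0.4], [1, 1])

    def test_agrees_with_enumeration(self, rng):
        idx = rng.normal(0.5, 0.3, 40)
        hosp = (idx + rng.normal(0, 0.2, 40) > 0.5).astype(int)
        if 0 < hosp.sum() < 40:
            thr = optimize_secondary_threshold(idx, hosp)
            s, p = sens_spec(idx, hosp, thr)
            assert s + p == pytest.approx(brute_force_best_sum(idx, hosp), abs=1e-12)


class TestRocAuc:
    def test_perfect_separation_is_one(self):
        auc, _ = roc_auc([1, 2, 3, 4], [0, 0, 1, 1], n_boot=10, seed=0)
        assert auc == 1.0

    def test_interleaved_pairwise_count(self):
        auc, _ = roc_auc([1, 2, 3, 4], [0, 1, 0, 1], n_boot=10, seed=0)
        assert auc == pytest.approx(0.75)

    def test_matches_pairwise_comparison_oracle(self, rng):
        idx = np.round(rng.normal(size=80), 1)
        labels = rng.integers(0, 2, 80)
        auc, _ = roc_auc(idx, labels, n_boot=10, seed=0)
        pos, neg = idx[labels == 1], idx[labels == 0]
        wins = sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a, b in itertools.product(pos, neg)
        )
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        idx = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        a1, _ = roc_auc(idx, labels, n_boot=10, seed=0)
        a2, _ = roc_auc(np.exp(3 * idx), labels, n_boot=10, seed=0)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_bootstrap_ci_brackets_auc(self, rng):
        idx = np.concatenate((rng.normal(1, 1, 40), rng.normal(0, 1, 60)))
        labels = np.array([1] * 40 + [0] * 60)
        auc, (lo, hi) = roc_auc(idx, labels, n_boot=200, seed=1)
        assert lo <= auc <= hi

    def test_delong_ci_brackets_auc(self, rng):
        idx = np.concatenate((rng.normal(1, 1, 40), rng.normal(0, 1, 60)))
        labels = np.array([1] * 40 + [0] * 60)
        auc, (lo, hi) = roc_auc(idx, labels, ci_method="delong")
        assert lo <= auc <= hi and hi - lo < 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1.0, 2.0], [1, 1])


class TestPerformanceReport:
    def test_confusion_arithmetic(self):
        # 29 true MSI of which 27 called positive; 247 true MSS of which 217
        # called negative: sensitivity 0.931, specificity 0.879
        idx = np.array([1.0] * 27 + [-1.0] * 2 + [1.0] * 30 + [-1.0] * 217)
        labels = np.array([1] * 27 + [1] * 2 + [0] * 30 + [0] * 217)
        rep = performance_report(idx, labels, 0.0)
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (27, 2, 30, 217)
        assert rep.sensitivity == pytest.approx(0.931, abs=5e-4)
        assert rep.specificity == pytest.approx(0.879, abs=5e-4)
        assert rep.overall_accuracy == pytest.approx((27 + 217) / 276, abs=1e-12)

    def test_all_correct(self):
        rep = performance_report([1.0, 1.0, -1.0], [1, 1, 0], 0.0)
        assert rep.sensitivity == rep.specificity == rep.overall_accuracy == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            performance_report([], [], 0.0)

    def test_report_at_optimized_threshold_achieves_claimed_sum(self, rng):
        idx = np.concatenate((rng.normal(1, 1, 30), rng.normal(0, 1, 70)))
        labels = np.array([1] * 30 + [0] * 70)
        thr = optimize_primary_threshold(idx, labels)
        rep = performance_report(idx, labels, thr)
        assert rep.sensitivity + rep.specificity == pytest.approx(
            brute_force_best_sum(idx, labels), abs=1e-12
        )
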