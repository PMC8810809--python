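"""Tests of the clinical evaluation statistics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nirglucose.evaluation import (
    ConfusionMatrix,
    bland_altman,
    ceg_report,
    ceg_zone,
    ceg_zones,
    confusion_metrics,
    evaluate_predictions,
    feature_importance_by_exclusion,
    iso15197_check,
    roc_curve,
)


class TestConfusionMetrics:
    # the three cohort-level matrices read with rows as predictions, and the
    # study percentages they reproduce
    @pytest.mark.parametrize(
        "cm, expected",
        [
            (ConfusionMatrix(102, 2, 4, 293), (98.5, 98.0, 96.2, 99.3)),
            (ConfusionMatrix(44, 4, 4, 182), (96.6, 91.7, 91.7, 97.8)),
            (ConfusionMatrix(146, 6, 8, 475), (97.8, 96.0, 94.8, 98.7)),
        ],
    )
    def test_reproduces_printed_cohort_percentages(self, cm, expected):
        m = confusion_metrics(cm)
        got = (m.accuracy, m.precision, m.sensitivity, m.specificity)
        for value, printed in zip(got, expected):
            assert abs(100 * value - printed) <= 0.11

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionMatrix(10, 0, 0, 10))
        assert m.accuracy == m.precision == m.sensitivity == m.specificity == 1.0

    def test_always_wrong_classifier(self):
        m = confusion_metrics(ConfusionMatrix(0, 5, 5, 0))
        assert m.accuracy == 0.0 and m.sensitivity == 0.0 and m.specificity == 0.0

    def test_zero_denominator_reported_as_nan_with_warning(self):
        with pytest.warns(UserWarning, match="precision"):
            m = confusion_metrics(ConfusionMatrix(0, 0, 3, 7))
        assert math.isnan(m.precision)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 1)


class TestClarkeErrorGrid:
    @pytest.mark.parametrize(
        "ref, pred, zone",
        [
            (100.0, 100.0, "A"),   # prediction equals reference
            (50.0, 250.0, "E"),    # hypoglycemia read as severe hyperglycemia
            (250.0, 120.0, "D"),   # missed high value
            (150.0, 270.0, "C"),   # overcorrection range
            (65.0, 65.0, "A"),     # both below 70
            (200.0, 165.0, "A"),   # within 20%
        ],
    )
    def test_reference_points(self, ref, pred, zone):
        assert ceg_zone(ref, pred) == zone

    def test_every_point_gets_exactly_one_zone(self, rng):
        ref = rng.uniform(1.0, 500.0, size=3000)
        pred = rng.uniform(0.0, 500.0, size=3000)
        zones = ceg_zones(ref, pred)
        assert set(np.unique(zones)) <= set("ABCDE")
        rep = ceg_report(ref, pred)
        assert sum(rep.zone_counts.values()) == 3000

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            ceg_zone(math.nan, 100.0)
        with pytest.raises(ValueError):
            ceg_zone(0.0, 100.0)


class TestBlandAltman:
    def test_identical_series_have_zero_bias_and_zero_limits(self):
        r = np.array([80.0, 120.0, 200.0])
        rep = bland_altman(r, r, mode="absolute")
        assert rep.bias == rep.loa_low == rep.loa_high == 0.0

    def test_hand_computed_four_point_case(self):
        ref = np.array([100.0, 100.0, 100.0, 100.0])
        pred = ref + np.array([-10.0, 10.0, -10.0, 10.0])
        rep = bland_altman(ref, pred, mode="absolute")
        assert rep.bias == 0.0
        assert rep.sd == pytest.approx(11.547005, abs=1e-6)   # sample SD, n-1
        assert rep.loa_high == pytest.approx(22.632130, abs=1e-5)
        assert rep.loa_low == pytest.approx(-22.632130, abs=1e-5)

    def test_symmetry_invariant(self, rng):
        ref = rng.uniform(60, 400, size=50)
        pred = ref * rng.uniform(0.9, 1.1, size=50)
        rep = bland_altman(ref, pred)
        assert rep.loa_high - rep.bias == pytest.approx(rep.bias - rep.loa_low, abs=1e-9)

    def test_percent_mode_scales_by_reference(self):
        ref = np.array([100.0, 200.0])
        pred = np.array([110.0, 220.0])
        rep = bland_altman(ref, pred, mode="percent")
        assert rep.bias == pytest.approx(10.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([100.0], [100.0])

    def test_percent_mode_with_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([0.0, 100.0], [10.0, 100.0], mode="percent")


def auc_by_pair_counting(scores, labels):
    """Independent oracle: normalized count of positive/negative score pairs
    ordered correctly, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)


class TestRoc:
    def test_perfect_separation_gives_unit_auc(self):
        *_, auc = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_all_tied_scores_give_half(self):
        *_, auc = roc_curve([1.0] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == 0.5

    @pytest.mark.parametrize(
        "scores, expected", [([1, 2, 3, 4], 1.0), ([1, 3, 2, 4], 0.75)]
    )
    def test_small_exact_cases(self, scores, expected):
        *_, auc = roc_curve(scores, [0, 0, 1, 1])
        assert auc == pytest.approx(expected, abs=1e-12)

    def test_matches_pair_counting_on_random_sets(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 13))
            scores = rng.integers(0, 5, size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            *_, auc = roc_curve(scores, labels)
            assert auc == pytest.approx(auc_by_pair_counting(scores, labels), abs=1e-12)

    def test_matches_reference_implementation(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        for _ in range(25):
            scores = rng.normal(size=40)
            labels = rng.integers(0, 2, size=40)
            if labels.min() == labels.max():
                continue
            *_, auc = roc_curve(scores, labels)
            assert auc == pytest.approx(
                sklearn_metrics.roc_auc_score(labels, scores), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [1, 1])


class TestIso15197:
    def test_exact_predictions_pass_both_criteria(self):
        r = np.linspace(60, 400, 20)
        rep = iso15197_check(r, r)
        assert rep.overall_pass and rep.frac_within == 1.0

    def test_one_outlier_in_ten_fails_criterion_one(self):
        ref = np.full(10, 150.0)
        pred = ref.copy()
        ref[0], pred[0] = 200.0, 232.0   # 16% high
        rep = iso15197_check(ref, pred)
        assert rep.frac_within == pytest.approx(0.9)
        assert not rep.criterion1_pass

    @pytest.mark.parametrize(
        "ref, pred, ok",
        [
            (90.0, 104.0, True),    # +14 mg/dL, inside the 15 mg/dL band
            (90.0, 106.0, False),   # +16 mg/dL, outside
            (90.0, 105.0, True),    # boundary inclusive
            (200.0, 230.0, True),   # exactly +15%
            (200.0, 231.0, False),
        ],
    )
    def test_reference_dependent_limit(self, ref, pred, ok):
        rep = iso15197_check(np.array([ref]), np.array([pred]))
        assert (rep.frac_within == 1.0) is ok

    def test_zone_ab_criterion(self):
        # one point deep in zone E among 200 accurate ones -> 99.5% in A+B
        ref = np.linspace(80, 350, 201)
        pred = ref.copy()
        ref[0], pred[0] = 50.0, 250.0
        rep = iso15197_check(ref, pred)
        assert rep.frac_zone_ab == pytest.approx(200 / 201)
        assert rep.criterion2_pass

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            iso15197_check([0.0], [10.0])


class TestFeatureImportance:
    def evaluator_factory(self, informative):
        def evaluator(features):
            return 1.0 if any(f in features for f in informative) else 0.5

        return evaluator

    def test_exclusion_of_irrelevant_group_costs_nothing(self):
        groups = {"g1": ["a", "b"], "g2": ["c"]}
        rep = feature_importance_by_exclusion(groups, self.evaluator_factory(["a"]))
        assert rep.normalized == {"g1": 1.0, "g2": 0.0}

    def test_importances_sum_to_one_and_are_nonnegative(self):
        def evaluator(features):
            return 0.4 + 0.1 * len(features)

        rep = feature_importance_by_exclusion({"g1": ["a"], "g2": ["b", "c"]}, evaluator)
        assert sum(rep.normalized.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in rep.normalized.values())

    def test_invariant_to_group_ordering(self):
        def ev(features):
            return 0.5 + 0.3 * ("a" in features) + 0.1 * ("c" in features)

        r1 = feature_importance_by_exclusion({"g1": ["a"], "g2": ["c"]}, ev)
        r2 = feature_importance_by_exclusion({"g2": ["c"], "g1": ["a"]}, ev)
        assert r1.normalized == dict(r2.normalized)
        assert r1.normalized == pytest.approx({"g1": 0.75, "g2": 0.25})

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            feature_importance_by_exclusion({"all": ["a", "b"]}, lambda f: 1.0)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            feature_importance_by_exclusion(
                {"g1": ["a", "b"], "g2": ["b"]}, lambda f: 1.0
            )


class TestEvaluateBundle:
    def test_report_internally_consistent(self, rng):
        ref = rng.uniform(60, 400, size=120)
        pred = ref * rng.uniform(0.92, 1.08, size=120)
        rep = evaluate_predictions(ref, pred)
        assert rep.confusion.total == 120
        assert sum(rep.ceg.zone_counts.values()) == 120
        frame = rep.to_frame()
        assert set(frame.columns) == {"metric", "value"}
        assert "accuracy" in frame.metric.values
        assert "ISO 15197" in rep.summary()
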