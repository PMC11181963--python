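"""Counting, cost, agreement, multi-threshold and calibration metrics."""

import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from valimet.classification import (
    CalibrationSet,
    CostMatrix,
    KappaWeights,
    auroc,
    counting_metric,
    expected_calibration_error,
    expected_cost,
    net_benefit,
    weighted_cohens_kappa,
)
from valimet.core import ConfusionCounts, InputError, Level, MetricParams, multiclass_confusion


def C(tp, fp, fn, tn):
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, level=Level.IMAGE)


class TestCountingMetrics:
    def test_sensitivity_undefined_without_positives(self):
        r = counting_metric(C(0, 2, 0, 0), "sensitivity")
        assert math.isnan(r.value) and r.flags["nan_reason"]

    def test_perfect_prediction_accuracy(self):
        assert counting_metric(C(3, 0, 0, 5), "accuracy").value == 1.0

    def test_mcc_perfect_anticorrelation(self):
        assert counting_metric(C(0, 2, 2, 0), "mcc").value == -1.0

    def test_f1_direct_evaluation(self):
        assert counting_metric(C(1, 1, 1, 0), "f_beta", MetricParams(beta=1.0)).value == 0.5

    @pytest.mark.parametrize("metric", ["accuracy", "balanced_accuracy", "sensitivity",
                                        "specificity", "ppv", "npv", "f_beta"])
    def test_unit_interval_range(self, metric, rng):
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(0, 10, 4)
            v = counting_metric(C(tp, fp, fn, tn), metric).value
            assert math.isnan(v) or 0.0 <= v <= 1.0

    def test_balanced_accuracy_is_mean_of_sens_and_spec(self, rng):
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(1, 10, 4)  # all denominators positive
            c = C(tp, fp, fn, tn)
            sens = counting_metric(c, "sensitivity").value
            spec = counting_metric(c, "specificity").value
            ba = counting_metric(c, "balanced_accuracy").value
            assert ba == pytest.approx((sens + spec) / 2, abs=1e-15)

    def test_mcc_magnitude_invariant_to_positive_class_swap(self, rng):
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(0, 10, 4)
            a = counting_metric(C(tp, fp, fn, tn), "mcc").value
            b = counting_metric(C(tn, fn, fp, tp), "mcc").value  # swapped designation
            if math.isnan(a) or math.isnan(b):
                continue
            assert abs(a) == pytest.approx(abs(b), abs=1e-12)

    def test_object_level_counts_reject_tn_requiring_metrics(self):
        obj = ConfusionCounts(tp=1, fp=1, fn=1, level=Level.OBJECT)
        with pytest.raises(InputError):
            counting_metric(obj, "accuracy")
        assert counting_metric(obj, "sensitivity").value == 0.5

    def test_unknown_metric_raises(self):
        with pytest.raises(InputError):
            counting_metric(C(1, 1, 1, 1), "f2_score")


class TestExpectedCost:
    def test_diagonal_confusion_costs_nothing(self):
        cm = multiclass_confusion([0, 1, 2], [0, 1, 2], (0, 1, 2))
        assert expected_cost(cm, CostMatrix.zero_one((0, 1, 2))).value == 0.0

    def test_zero_one_costs_equal_error_rate(self, rng):
        ref = rng.integers(0, 3, 60).tolist()
        pred = rng.integers(0, 3, 60).tolist()
        cm = multiclass_confusion(ref, pred, (0, 1, 2))
        ec = expected_cost(cm, CostMatrix.zero_one((0, 1, 2))).value
        acc = np.trace(cm.counts) / cm.total
        assert ec == pytest.approx(1.0 - acc, abs=1e-12)

    def test_ordinal_penalty_asymmetry(self):
        classes = ("mild", "moderate", "severe")
        costs = np.zeros((3, 3))
        costs[2, 0], costs[0, 2] = 10.0, 1.0
        cm_a = multiclass_confusion(["mild", "moderate", "severe"],
                                    ["mild", "moderate", "mild"], classes)
        cm_b = multiclass_confusion(["mild", "moderate", "severe"],
                                    ["severe", "moderate", "severe"], classes)
        ec_a = expected_cost(cm_a, CostMatrix(classes, costs)).value
        ec_b = expected_cost(cm_b, CostMatrix(classes, costs)).value
        # hand evaluation: EC(A) = 1/3 * 10, EC(B) = 1/3 * 1
        assert ec_a == pytest.approx(10.0 / 3.0, abs=1e-12)
        assert ec_b == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert ec_a == pytest.approx(10.0 * ec_b, abs=1e-12)

    def test_binary_zero_one_uniform_priors_is_one_minus_ba(self, rng):
        ref = rng.integers(0, 2, 40).tolist() + [0, 1]
        pred = rng.integers(0, 2, 42).tolist()
        cm = multiclass_confusion(ref, pred, (0, 1))
        ec = expected_cost(cm, CostMatrix.zero_one((0, 1)), priors=(0.5, 0.5)).value
        tp = cm.counts[1, 1]; fn = cm.counts[1, 0]
        tn = cm.counts[0, 0]; fp = cm.counts[0, 1]
        ba = ((tp / (tp + fn)) + (tn / (tn + fp))) / 2
        assert ec == pytest.approx(1.0 - ba, abs=1e-12)

    def test_zero_support_with_nonzero_prior_is_undefined(self):
        cm = multiclass_confusion([0, 0], [0, 1], (0, 1))
        assert math.isnan(expected_cost(cm, CostMatrix.zero_one((0, 1)),
                                        priors=(0.5, 0.5)).value)


class TestWeightedKappa:
    def test_perfect_agreement(self):
        cm = multiclass_confusion([0, 1, 2] * 3, [0, 1, 2] * 3, (0, 1, 2))
        assert weighted_cohens_kappa(cm, KappaWeights("quadratic")).value == 1.0

    def test_margin_product_table_scores_zero(self):
        # observed table equal to the outer product of its own margins
        from valimet.core import ConfusionMatrix
        counts = np.outer([2, 3], [4, 1])  # total 25, margins (10,15)x(20,5)/25... construct directly
        cm = ConfusionMatrix((0, 1), counts)
        # margins: rows (10, 15)?? -> recompute: rows sums (2+3)*... keep it simple:
        # counts[i,j] = r_i * c_j ensures O = E exactly after normalization
        assert weighted_cohens_kappa(cm, KappaWeights("linear")).value == pytest.approx(0.0, abs=1e-12)

    def test_three_class_quadratic_hand_value(self):
        from valimet.core import ConfusionMatrix
        counts = np.array([[5, 2, 0], [1, 6, 1], [0, 2, 7]])
        cm = ConfusionMatrix((0, 1, 2), counts)
        # independent direct evaluation of 1 - sum(wO)/sum(wE)
        w = np.array([[(i - j) ** 2 for j in range(3)] for i in range(3)], dtype=float)
        total = counts.sum()
        expected = np.outer(counts.sum(1), counts.sum(0)) / total
        hand = 1.0 - (w * counts).sum() / (w * expected).sum()
        assert weighted_cohens_kappa(cm, KappaWeights("quadratic")).value == pytest.approx(hand, abs=1e-12)

    def test_single_cell_table_has_undefined_kappa(self):
        from valimet.core import ConfusionMatrix
        cm = ConfusionMatrix((0, 1), np.array([[5, 0], [0, 0]]))
        assert math.isnan(weighted_cohens_kappa(cm, KappaWeights("linear")).value)


class TestNetBenefit:
    def test_no_predicted_positives(self):
        assert net_benefit(C(0, 0, 3, 7), 0.3, 10).value == 0.0

    def test_weights_cancel_at_half_threshold(self):
        assert net_benefit(C(4, 4, 1, 1), 0.5, 10).value == 0.0

    def test_direct_formula_evaluation(self):
        v = net_benefit(C(3, 2, 2, 3), 0.25, 10).value
        assert v == pytest.approx(3 / 10 - (2 / 10) * (0.25 / 0.75), abs=1e-15)

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            net_benefit(C(1, 1, 1, 1), 0.5, 0)
        with pytest.raises(InputError):
            net_benefit(C(1, 1, 1, 1), 1.5, 10)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).value == 1.0

    def test_all_ties_give_half(self):
        assert auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]).value == 0.5

    def test_single_class_is_undefined(self):
        assert math.isnan(auroc([0.1, 0.9], [1, 1]).value)

    def test_matches_pairwise_enumeration_and_sklearn(self, rng):
        scores = np.round(rng.random(20), 2)  # rounding forces some ties
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        v = auroc(scores, labels).value
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert v == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)
        assert v == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_to_monotone_rescoring(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        a = auroc(scores, labels).value
        b = auroc(np.exp(5 * scores) - 2, labels).value
        assert a == pytest.approx(b, abs=1e-12)


class TestCalibration:
    def test_single_bin_perfectly_matched(self):
        conf = np.full(10, 0.7)
        out = np.array([1] * 7 + [0] * 3)
        cal = CalibrationSet(conf, out, bins=1)
        assert expected_calibration_error(cal).value == pytest.approx(0.0, abs=1e-12)

    def test_single_sample_direct_value(self):
        cal = CalibrationSet([0.7], [1], bins=10)
        assert expected_calibration_error(cal).value == pytest.approx(0.3, abs=1e-12)

    def test_confidence_one_falls_in_last_bin(self):
        cal = CalibrationSet([1.0, 1.0], [1, 1], bins=10)
        assert expected_calibration_error(cal).value == 0.0

    def test_small_sample_bias_of_calibrated_model(self, rng):
        # perfectly calibrated generator: ECE shrinks with n in expectation
        def mean_ece(n, reps=100):
            vals = []
            for _ in range(reps):
                conf = rng.uniform(0, 1, n)
                out = (rng.uniform(0, 1, n) < conf).astype(int)
                vals.append(expected_calibration_error(CalibrationSet(conf, out)).value)
            return np.mean(vals)

        assert mean_ece(10) > mean_ece(2000)

    def test_validation(self):
        with pytest.raises(InputError):
            CalibrationSet([1.2], [1])
        with pytest.raises(InputError):
            CalibrationSet([0.5], [1], bins=0)
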