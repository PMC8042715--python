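"""Decision rule, confusion counts and the metrics suite vs independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn import metrics as skm

from batchfocus.metrics import (
    ConfusionMatrix,
    DecisionConfig,
    confusion,
    metrics,
    pr_auc,
    predict,
    roc_curve,
    score_report,
    sweep_threshold,
)


# ---------------------------------------------------------------------------
# independent definitional oracles
# ---------------------------------------------------------------------------

def oracle_metrics(tp, fp, tn, fn):
    """Textbook formulas coded independently, pure python floats."""
    def div(a, b):
        return a / b if b else math.nan

    n = tp + fp + tn + fn
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "sensitivity": div(tp, tp + fn),
        "specificity": div(tn, tn + fp),
        "accuracy": div(tp + tn, n),
        "f1": div(2 * tp, 2 * tp + fp + fn),
        "mcc": div(tp * tn - fp * fn, mcc_den),
    }


def oracle_concordant_pair_auc(scores, labels):
    """Mann-Whitney statistic: fraction of concordant pos/neg pairs, ties 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def oracle_pr_auc(scores, labels):
    """Average precision by explicit threshold enumeration."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    n_pos = y.sum()
    thresholds = sorted(set(s), reverse=True)
    area, prev_recall = 0.0, 0.0
    for t in thresholds:
        pred = s >= t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


# ---------------------------------------------------------------------------
# decision rule
# ---------------------------------------------------------------------------

class TestPredict:
    @pytest.mark.parametrize(
        "score,delta,expected",
        [
            (0.4, 0.0, 0),
            (0.4, 0.15, 1),   # 0.4 > 0.35
            (0.26, 0.25, 1),  # effective threshold 0.25
            (0.25, 0.25, 0),  # strict inequality, tie -> negative
            (0.6, -0.2, 0),   # negative shift raises the bar to 0.7
        ],
    )
    def test_shifted_rule(self, score, delta, expected):
        assert predict([score], DecisionConfig(delta=delta))[0] == expected

    def test_tie_rule_positive(self):
        assert predict([0.25], DecisionConfig(delta=0.25, tie_rule="positive"))[0] == 1

    def test_threshold_must_stay_a_probability(self):
        with pytest.raises(ValueError):
            DecisionConfig(delta=0.75)
        with pytest.raises(ValueError):
            DecisionConfig(delta=-0.75)


class TestConfusion:
    def test_all_correct(self):
        cm = confusion([1, 0, 1], [1, 0, 1])
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (2, 0, 1, 0)

    def test_external_validation_narrative(self):
        """11 positives of which 9 predicted positive -> tp=9, fn=2."""
        labels = [1] * 11 + [0] * 120
        preds = [1] * 9 + [0] * 2 + [0] * 120
        cm = confusion(preds, labels)
        assert cm.tp == 9 and cm.fn == 2

    def test_internal_validation_narrative(self):
        """10 positives, 7 correctly identified -> tp=7, fn=3."""
        labels = [1] * 10 + [0] * 94
        preds = [1] * 7 + [0] * 3 + [0] * 94
        cm = confusion(preds, labels)
        assert cm.tp == 7 and cm.fn == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1], [1, 0])


class TestMetrics:
    def test_sensitivity_worked_examples(self):
        assert metrics(ConfusionMatrix(7, 0, 94, 3)).sensitivity == pytest.approx(0.70)
        assert metrics(ConfusionMatrix(9, 0, 120, 2)).sensitivity == pytest.approx(
            0.818, abs=5e-4
        )

    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(1000):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 50, size=4))
            got = metrics(ConfusionMatrix(tp, fp, tn, fn))
            want = oracle_metrics(tp, fp, tn, fn)
            for key, expected in want.items():
                actual = getattr(got, key)
                if math.isnan(expected):
                    assert math.isnan(actual)
                else:
                    assert actual == pytest.approx(expected, abs=1e-12)

    def test_mcc_symmetric_under_class_swap(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 40, size=4))
            a = metrics(ConfusionMatrix(tp, fp, tn, fn)).mcc
            b = metrics(ConfusionMatrix(tn, fn, tp, fp)).mcc
            assert a == pytest.approx(b, abs=1e-12)

    def test_undefined_denominator_reported_as_nan(self):
        rep = metrics(ConfusionMatrix(0, 0, 10, 0))
        assert math.isnan(rep.sensitivity)
        assert rep.specificity == 1.0


class TestRoc:
    def test_perfect_separation(self):
        *_, auc = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_constant_scores_are_chance(self):
        *_, auc = roc_curve([0.5] * 10, [1, 0] * 5)
        assert auc == pytest.approx(0.5)

    def test_trapezoid_equals_concordant_pairs(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 40))
            scores = np.round(rng.random(n), 2)  # force some ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            *_, auc = roc_curve(scores, labels)
            assert auc == pytest.approx(
                oracle_concordant_pair_auc(scores, labels), abs=1e-12
            )

    def test_agrees_with_sklearn(self, rng):
        scores = rng.random(200)
        labels = rng.integers(0, 2, size=200)
        *_, auc = roc_curve(scores, labels)
        assert auc == pytest.approx(skm.roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(50)
        labels = (rng.random(50) < 0.3).astype(int)
        *_, a = roc_curve(scores, labels)
        *_, b = roc_curve(np.exp(3 * scores) - 0.5, labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.9], [1, 1])


class TestPrAuc:
    def test_perfect_ranking(self):
        assert pr_auc([0.9, 0.8, 0.1], [1, 1, 0]) == pytest.approx(1.0)

    def test_constant_scores_equal_prevalence(self):
        labels = [1, 0, 0, 0, 1, 0, 0, 0, 0, 0]
        assert pr_auc([0.4] * 10, labels) == pytest.approx(0.2)

    def test_matches_threshold_enumeration_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 40))
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                continue
            assert pr_auc(scores, labels) == pytest.approx(
                oracle_pr_auc(scores, labels), abs=1e-9
            )

    def test_agrees_with_sklearn_average_precision(self, rng):
        scores = rng.random(300)
        labels = rng.integers(0, 2, size=300)
        assert pr_auc(scores, labels) == pytest.approx(
            skm.average_precision_score(labels, scores), abs=1e-12
        )

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_auc([0.2, 0.4], [0, 0])


class TestThresholdSweep:
    def test_study_grid_accepted_and_monotone(self, rng):
        scores = rng.random(150)
        labels = rng.integers(0, 2, size=150)
        deltas = np.round(np.arange(-0.20, 0.2500001, 0.01), 4)
        sweep = sweep_threshold(scores, labels, deltas)
        sens = [r.sensitivity for r in sweep.reports]
        spec = [r.specificity for r in sweep.reports]
        assert all(b >= a for a, b in zip(sens, sens[1:]))
        assert all(b <= a for a, b in zip(spec, spec[1:]))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_raising_delta_never_loses_tp_nor_gains_tn(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        sweep = sweep_threshold(scores, labels, [-0.1, 0.0, 0.1, 0.2])
        tps = [m.tp for m in sweep.matrices]
        tns = [m.tn for m in sweep.matrices]
        assert all(b >= a for a, b in zip(tps, tps[1:]))
        assert all(b <= a for a, b in zip(tns, tns[1:]))

    def test_huge_shift_predicts_everyone_positive(self):
        sweep = sweep_threshold([0.2, 0.3, 0.9], [0, 1, 1], [0.5])
        assert sweep.reports[0].sensitivity == 1.0

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_threshold([0.5], [1], [0.1, 0.1])

    def test_curve_table_columns(self, rng):
        scores = rng.random(20)
        labels = rng.integers(0, 2, size=20)
        df = sweep_threshold(scores, labels, [0.0, 0.1]).to_dataframe()
        assert list(df.columns) == [
            "delta", "tp", "fp", "tn", "fn",
            "sensitivity", "specificity", "accuracy", "f1", "mcc",
        ]


class TestScoreReport:
    def test_curves_filled_when_both_classes_present(self, rng):
        scores = rng.random(60)
        labels = rng.integers(0, 2, size=60)
        rep = score_report(scores, labels, DecisionConfig(0.1))
        assert 0.0 <= rep.roc_auc <= 1.0
        assert 0.0 <= rep.pr_auc <= 1.0

    def test_single_class_leaves_curves_nan(self):
        rep = score_report([0.2, 0.4], [0, 0], DecisionConfig())
        assert math.isnan(rep.roc_auc)
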