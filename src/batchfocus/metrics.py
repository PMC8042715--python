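"""Threshold-shifted prediction and the imbalanced-classification metrics suite.

The network emits a positive-class score o1 in [0, 1]. In the default
decision rule a positive is predicted iff o1 > 0.5. Because minorities
are hard to score confidently, the cut-off can be shifted by Δ: a
positive is predicted iff o1 > 0.5 − Δ (strict inequality; a tie is
negative by default). Raising Δ trades specificity for sensitivity.

All metrics are computed from first principles (the confusion-matrix
formulas, trapezoid ROC-AUC over all distinct score thresholds, and
step-interpolated PR-AUC); scikit-learn is used only as an independent
cross-check in the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("batchfocus")

METRIC_FIELDS = ("sensitivity", "specificity", "accuracy", "f1", "mcc")


@dataclass(frozen=True)
class DecisionConfig:
    """Threshold shift Δ for the rule: positive iff o1 > 0.5 − Δ."""

    delta: float = 0.0
    tie_rule: str = "negative"

    def __post_init__(self) -> None:
        if not 0.0 <= 0.5 - self.delta <= 1.0:
            raise ValueError(
                f"effective threshold 0.5 - delta = {0.5 - self.delta} "
                "must stay within [0, 1]"
            )
        if self.tie_rule not in ("positive", "negative"):
            raise ValueError("tie_rule must be 'positive' or 'negative'")

    @property
    def threshold(self) -> float:
        return 0.5 - self.delta


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    mcc: float
    roc_auc: float = math.nan
    pr_auc: float = math.nan

    def to_dict(self) -> dict[str, float]:
        return dict(vars(self))


def predict(scores: Sequence[float], decision: DecisionConfig = DecisionConfig()) -> np.ndarray:
    """Apply the shifted decision rule to positive-class scores.

    Returns 0/1 predictions; a score exactly at the threshold follows
    ``tie_rule`` (default negative, preserving the strict inequality).
    """
    s = np.asarray(scores, dtype=float)
    thr = decision.threshold
    if decision.tie_rule == "positive":
        return (s >= thr).astype(int)
    return (s > thr).astype(int)


def confusion(predictions: Sequence[int], labels: Sequence[int]) -> ConfusionMatrix:
    """Exact confusion counts; labels and predictions are 0/1 with 1 = positive."""
    p = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    if p.size == 0:
        raise ValueError("empty inputs")
    return ConfusionMatrix(
        tp=int(np.sum((p == 1) & (y == 1))),
        fp=int(np.sum((p == 1) & (y == 0))),
        tn=int(np.sum((p == 0) & (y == 0))),
        fn=int(np.sum((p == 0) & (y == 1))),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reported as NaN", name)
        return math.nan
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Curve-free metrics from a confusion matrix.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/N, F1 = 2TP/(2TP+FP+FN), and MCC via its
    determinant formula. A metric with a zero denominator is NaN.
    """
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    sens = _safe_div(tp, tp + fn, "sensitivity")
    spec = _safe_div(tn, tn + fp, "specificity")
    acc = _safe_div(tp + tn, cm.total, "accuracy")
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn, "f1")
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(float(tp) * tn - float(fp) * fn, mcc_den, "mcc")
    return MetricReport(sens, spec, acc, f1, mcc)


def roc_curve(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points and trapezoid AUC by sweeping all distinct score thresholds.

    The AUC equals the Mann-Whitney concordant-pair statistic (ties
    counted half). Requires both classes present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # collapse tied scores: take cumulative counts at the last index of each tie
    distinct = np.where(np.diff(s_sorted))[0]
    idx = np.r_[distinct, s_sorted.size - 1]
    tps = np.cumsum(y_sorted == 1)[idx]
    fps = np.cumsum(y_sorted == 0)[idx]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve, step-wise interpolation.

    Computed as sum over thresholds of (recall step) x precision, i.e.
    the average-precision summary. Requires at least one positive.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    if n_pos == 0:
        raise ValueError("PR-AUC requires at least one positive")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    distinct = np.where(np.diff(s_sorted))[0]
    idx = np.r_[distinct, s_sorted.size - 1]
    tps = np.cumsum(y_sorted == 1)[idx].astype(float)
    fps = np.cumsum(y_sorted == 0)[idx].astype(float)
    precision = tps / (tps + fps)
    recall = tps / n_pos
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - recall_prev) * precision))


def score_report(
    scores: Sequence[float],
    labels: Sequence[int],
    decision: DecisionConfig = DecisionConfig(),
    curves: bool = True,
) -> MetricReport:
    """Full metric report for scores + labels at a decision threshold.

    ROC-AUC and PR-AUC are threshold-free; they are filled in when
    ``curves`` is set and both classes are present.
    """
    cm = confusion(predict(scores, decision), labels)
    base = metrics(cm)
    if not curves:
        return base
    y = np.asarray(labels, dtype=int)
    roc = math.nan
    pr = math.nan
    if 0 < y.sum() < y.size:
        roc = roc_curve(scores, labels)[2]
        pr = pr_auc(scores, labels)
    return MetricReport(
        base.sensitivity, base.specificity, base.accuracy, base.f1, base.mcc, roc, pr
    )


@dataclass
class ThresholdSweep:
    """Per-Δ confusion counts and metrics over a strictly increasing grid."""

    deltas: list[float]
    matrices: list[ConfusionMatrix]
    reports: list[MetricReport]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for d, cm, rep in zip(self.deltas, self.matrices, self.reports):
            rows.append(
                {
                    "delta": d,
                    "tp": cm.tp,
                    "fp": cm.fp,
                    "tn": cm.tn,
                    "fn": cm.fn,
                    **rep.to_dict(),
                }
            )
        df = pd.DataFrame(rows)
        return df.drop(columns=["roc_auc", "pr_auc"])


def sweep_threshold(
    scores: Sequence[float], labels: Sequence[int], deltas: Sequence[float]
) -> ThresholdSweep:
    """Evaluate the shifted decision rule over a grid of Δ values."""
    ds = [float(d) for d in deltas]
    if any(b <= a for a, b in zip(ds, ds[1:])):
        raise ValueError("deltas must be strictly increasing")
    matrices, reports = [], []
    for d in ds:
        cm = confusion(predict(scores, DecisionConfig(delta=d)), labels)
        matrices.append(cm)
        reports.append(metrics(cm))
    return ThresholdSweep(ds, matrices, reports)
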