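"""Cost-sensitive training for imbalanced cohorts.

Two training modes share one SGD loop:

* ``batch_adaptive`` — the training set is shuffled into fixed-size
  mini-batches each epoch; every batch's mean gradient is applied with
  a learning rate that grows linearly with the number of minority
  (positive) samples in that batch::

      lr(i) = lr0 + n(i) * delta_lr

  so batches containing rare fetal-loss cases take larger steps and the
  minority's features are not drowned out by the majority.

* ``per_sample_baseline`` — the classical cost-sensitive rule: samples
  are applied one at a time with rate ``lr0`` for the majority and
  ``lr0 + delta_lr_baseline`` for the minority. With ``delta_lr = 0``
  and ``batch_size = 1`` the adaptive mode collapses to this baseline at
  ``delta_lr_baseline = 0`` exactly (same shuffles, same updates).

Training stops early when the validation sum-squared error has risen for
``patience`` consecutive epochs, and the weights of the best-validation
epoch are restored. Restarts that never improve, diverge, or produce
degenerate validation predictions are flagged for exclusion; the
multi-restart protocol averages metrics over the retained networks and
keeps the most sensitive one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, split_cohort, normalize_cohort
from .metrics import DecisionConfig, MetricReport, score_report
from .network import (
    NetworkConfig,
    NetworkWeights,
    backprop_batch,
    forward_batch,
    init_weights,
    labels_to_onehot,
    loss_sse,
    sgd_step_,
)

logger = logging.getLogger("batchfocus")

MAX_SEED = 2**31 - 1


class AllNetworksExcludedError(RuntimeError):
    """Every restart in an ensemble was excluded; diagnostics attached."""

    def __init__(self, reasons: list[str]):
        super().__init__(
            f"all {len(reasons)} restarts were excluded "
            f"(reasons: {sorted(set(reasons))})"
        )
        self.reasons = reasons


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the cost-sensitive SGD loop.

    ``lr0`` is the base learning rate (default 1); ``delta_lr`` the
    per-minority-sample increment of the batch-adaptive rule;
    ``delta_lr_baseline`` the positive-class increment of the per-sample
    baseline.
    """

    mode: str = "batch_adaptive"
    lr0: float = 1.0
    delta_lr: float = 0.2
    delta_lr_baseline: float = 0.2
    batch_size: int = 13
    max_epochs: int = 500
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("batch_adaptive", "per_sample_baseline"):
            raise ValueError(f"unknown training mode {self.mode!r}")
        if self.delta_lr < 0 or self.delta_lr_baseline < 0:
            raise ValueError("learning-rate increments must be non-negative")
        if self.batch_size < 1 or self.lr0 <= 0:
            raise ValueError("batch_size must be >= 1 and lr0 > 0")


@dataclass
class BatchPlan:
    """One epoch's partition of the training set into equal batches."""

    batches: list[np.ndarray]  # positional index arrays
    minority_counts: list[int]


@dataclass
class TrainingTrace:
    train_sse: list[float] = field(default_factory=list)
    validation_sse: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    converged: bool = True
    exclusion_reason: str | None = None


def batch_learning_rate(lr0: float, delta_lr: float, n_i: int) -> float:
    """Batch-adaptive rate: lr0 + n_i * delta_lr for n_i minority samples."""
    if n_i < 0:
        raise ValueError("minority count must be >= 0")
    return lr0 + n_i * delta_lr


def per_sample_learning_rate(lr0: float, delta_lr_baseline: float, label: int) -> float:
    """Per-sample cost-sensitive rate: lr0 + delta_lr_baseline for positives."""
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    return lr0 + (delta_lr_baseline if label == 1 else 0.0)


def make_batches(
    train_ids: Sequence, labels: Sequence[int], batch_size: int, seed: int
) -> BatchPlan:
    """Shuffle ids (seeded) and partition into consecutive equal batches.

    ``minority_counts[i]`` is the number of positive labels in batch i;
    their sum always equals the total positive count.
    """
    n = len(train_ids)
    if n % batch_size != 0:
        raise ValueError(f"{n} ids not divisible by batch size {batch_size}")
    y = np.asarray(labels, dtype=int)
    perm = np.random.default_rng(seed).permutation(n)
    batches = [perm[i : i + batch_size] for i in range(0, n, batch_size)]
    counts = [int(y[b].sum()) for b in batches]
    return BatchPlan(batches=batches, minority_counts=counts)


def _epoch_seed(base_seed: int, epoch: int) -> int:
    return int(np.random.SeedSequence([base_seed, epoch]).generate_state(1)[0] % MAX_SEED)


def train(
    network_config: NetworkConfig,
    training_config: TrainingConfig,
    train_cohort: Cohort,
    validation_cohort: Cohort,
) -> tuple[NetworkWeights, TrainingTrace]:
    """Train one network with early stopping on validation SSE.

    Both cohorts must be normalized with shared statistics. Batches are
    re-shuffled every epoch (seeded). Returns the weights of the epoch
    with minimum validation SSE and a full per-epoch trace; a run whose
    loss goes non-finite or whose validation SSE never improves on the
    initial weights is marked non-convergent with an exclusion reason.
    """
    if train_cohort.n == 0 or validation_cohort.n == 0:
        raise ValueError("train and validation cohorts must be non-empty")
    if train_cohort.normalization_state is None or validation_cohort.normalization_state is None:
        logger.warning("training on un-normalized cohorts; divergence is likely")

    cfg = training_config
    Xtr = train_cohort.X
    ytr = train_cohort.y
    Ytr = labels_to_onehot(ytr)
    Xval = validation_cohort.X
    Yval = labels_to_onehot(validation_cohort.y)
    batch_size = 1 if cfg.mode == "per_sample_baseline" else cfg.batch_size
    if Xtr.shape[0] % batch_size != 0:
        raise ValueError(
            f"training size {Xtr.shape[0]} not divisible by batch size {batch_size}"
        )

    weights = init_weights(network_config)
    trace = TrainingTrace()

    O0, _ = forward_batch(weights, Xval)
    initial_val = loss_sse(O0, Yval)
    best_val = math.inf
    best_weights = weights.copy()
    best_epoch = 0
    rises = 0
    prev_val = initial_val

    for epoch in range(1, cfg.max_epochs + 1):
        plan = make_batches(
            train_cohort.ids, ytr, batch_size, _epoch_seed(cfg.seed, epoch)
        )
        for b, n_i in zip(plan.batches, plan.minority_counts):
            grad = backprop_batch(weights, Xtr[b], Ytr[b])
            if cfg.mode == "batch_adaptive":
                # lr(i) multiplies the mean batch gradient, so lr0 = 1 keeps
                # the same step scale as the per-sample baseline regardless
                # of batch size (and stays stable on the SSE loss).
                lr = batch_learning_rate(cfg.lr0, cfg.delta_lr, n_i) / batch_size
            else:
                lr = per_sample_learning_rate(
                    cfg.lr0, cfg.delta_lr_baseline, int(ytr[b[0]])
                )
            sgd_step_(weights, grad, lr)

        if not weights.is_finite():
            trace.converged = False
            trace.exclusion_reason = "non_finite_loss"
            trace.stopped_epoch = epoch
            return best_weights, trace

        Otr, _ = forward_batch(weights, Xtr)
        Oval, _ = forward_batch(weights, Xval)
        tr_sse = loss_sse(Otr, Ytr)
        val_sse = loss_sse(Oval, Yval)
        trace.train_sse.append(tr_sse)
        trace.validation_sse.append(val_sse)
        if not (math.isfinite(tr_sse) and math.isfinite(val_sse)):
            trace.converged = False
            trace.exclusion_reason = "non_finite_loss"
            trace.stopped_epoch = epoch
            return best_weights, trace

        if val_sse < best_val:
            best_val = val_sse
            best_weights = weights.copy()
            best_epoch = epoch
        rises = rises + 1 if val_sse > prev_val else 0
        prev_val = val_sse
        trace.stopped_epoch = epoch
        if rises >= cfg.patience:
            break

    if best_val >= initial_val:
        trace.converged = False
        trace.exclusion_reason = "no_improvement"
    logger.debug(
        "training stopped at epoch %d (best epoch %d, val SSE %.4f)",
        trace.stopped_epoch, best_epoch, best_val,
    )
    return best_weights, trace


# ---------------------------------------------------------------------------
# Multi-restart protocol
# ---------------------------------------------------------------------------

@dataclass
class RestartResult:
    seed: int
    weights: NetworkWeights
    trace: TrainingTrace
    report: MetricReport
    normalization_state: list | None
    excluded: bool
    exclusion_reason: str | None
    validation_scores: np.ndarray
    validation_labels: np.ndarray


@dataclass
class EnsembleResult:
    """Aggregate of a multi-restart run: per-metric means/stds over the
    retained networks and the single most sensitive network."""

    n_trained: int
    n_excluded: int
    metric_means: dict[str, float]
    metric_stds: dict[str, float]
    best: RestartResult
    restarts: list[RestartResult]

    @property
    def n_retained(self) -> int:
        return self.n_trained - self.n_excluded


def exclusion_reason(
    trace: TrainingTrace, report: MetricReport, majority_rate: float
) -> str | None:
    """Why a trained network should be dropped from the ensemble average.

    Non-convergent runs (non-finite loss, no validation improvement) are
    excluded, as are networks whose validation behaviour is totally
    wrong: every prediction incorrect (sensitivity and specificity both
    zero) or accuracy more than 10 points below the trivial
    majority-class rate.
    """
    if not trace.converged:
        return trace.exclusion_reason or "not_convergent"
    if report.sensitivity == 0.0 and report.specificity == 0.0:
        return "all_predictions_wrong"
    if not math.isnan(report.accuracy) and report.accuracy < majority_rate - 0.10:
        return "accuracy_below_majority_rate"
    return None


def restart_seeds_for(seed: int, n_restarts: int) -> list[int]:
    """Deterministic per-restart seeds derived from one base seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s % MAX_SEED) for s in ss.generate_state(n_restarts, dtype=np.uint64)]


def train_ensemble(
    network_config: NetworkConfig,
    training_config: TrainingConfig,
    cohort: Cohort,
    n_restarts: int = 120,
    train_fraction: float = 0.7,
    decision: DecisionConfig = DecisionConfig(),
    restart_seeds: Sequence[int] | None = None,
) -> EnsembleResult:
    """Train many networks with fresh splits and initializations.

    Each restart re-splits the raw cohort, re-computes normalization on
    its training part, re-initializes weights, trains with early
    stopping, and is scored on its held-out validation part under the
    given decision threshold. Excluded restarts (see
    :func:`exclusion_reason`) do not enter the metric averages. The best
    network is the retained one with the highest sensitivity, ties
    broken by MCC then accuracy.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if restart_seeds is None:
        restart_seeds = restart_seeds_for(training_config.seed, n_restarts)
    elif len(restart_seeds) != n_restarts:
        raise ValueError("restart_seeds length must equal n_restarts")

    restarts: list[RestartResult] = []
    for s in restart_seeds:
        plan = split_cohort(
            cohort, train_fraction, training_config.batch_size, seed=s
        )
        train_raw = cohort.subset(plan.train_ids)
        val_raw = cohort.subset(plan.validation_ids)
        train_norm = normalize_cohort(train_raw)
        val_norm = normalize_cohort(val_raw, state=train_norm.normalization_state)
        net_cfg = replace(network_config, seed=s)
        tr_cfg = replace(training_config, seed=s)
        weights, trace = train(net_cfg, tr_cfg, train_norm, val_norm)
        O, _ = forward_batch(weights, val_norm.X)
        scores = O[:, 0]
        report = score_report(scores, val_norm.y, decision)
        majority = max(val_raw.n_positive, val_raw.n_negative) / val_raw.n
        base_report = score_report(scores, val_norm.y, DecisionConfig())
        reason = exclusion_reason(trace, base_report, majority)
        restarts.append(
            RestartResult(
                seed=s,
                weights=weights,
                trace=trace,
                report=report,
                normalization_state=train_norm.normalization_state,
                excluded=reason is not None,
                exclusion_reason=reason,
                validation_scores=scores,
                validation_labels=val_norm.y.copy(),
            )
        )

    retained = [r for r in restarts if not r.excluded]
    if not retained:
        raise AllNetworksExcludedError([r.exclusion_reason or "?" for r in restarts])

    fields = ("sensitivity", "specificity", "accuracy", "f1", "mcc", "roc_auc", "pr_auc")
    values = {f: np.asarray([getattr(r.report, f) for r in retained]) for f in fields}
    means = {f: float(np.nanmean(v)) for f, v in values.items()}
    stds = {f: float(np.nanstd(v)) for f, v in values.items()}

    def rank(r: RestartResult) -> tuple:
        rep = r.report
        key = lambda x: -math.inf if math.isnan(x) else x
        return (key(rep.sensitivity), key(rep.mcc), key(rep.accuracy))

    best = max(retained, key=rank)
    return EnsembleResult(
        n_trained=len(restarts),
        n_excluded=len(restarts) - len(retained),
        metric_means=means,
        metric_stds=stds,
        best=best,
        restarts=restarts,
    )


# ---------------------------------------------------------------------------
# Hyperparameter sweeps (shared restart seeds across grid points)
# ---------------------------------------------------------------------------

def sweep_delta_lr(
    values: Sequence[float],
    network_config: NetworkConfig,
    training_config: TrainingConfig,
    cohort: Cohort,
    n_restarts: int = 120,
    train_fraction: float = 0.7,
    decision: DecisionConfig = DecisionConfig(),
) -> pd.DataFrame:
    """Mean/std sensitivity versus the learning-rate increment.

    In ``batch_adaptive`` mode the grid varies ``delta_lr``; in
    ``per_sample_baseline`` mode it varies ``delta_lr_baseline``. All
    grid points share the same restart seeds so the comparison is
    paired.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("empty sweep grid")
    if any(not math.isfinite(v) or v < 0 for v in vals):
        raise ValueError("sweep values must be finite and >= 0")
    seeds = restart_seeds_for(training_config.seed, n_restarts)
    rows = []
    for v in vals:
        if training_config.mode == "per_sample_baseline":
            cfg = replace(training_config, delta_lr_baseline=v)
        else:
            cfg = replace(training_config, delta_lr=v)
        res = train_ensemble(
            network_config, cfg, cohort, n_restarts, train_fraction,
            decision, restart_seeds=seeds,
        )
        rows.append(
            {
                "delta_lr": v,
                "mean_sensitivity": res.metric_means["sensitivity"],
                "std_sensitivity": res.metric_stds["sensitivity"],
                "mean_specificity": res.metric_means["specificity"],
                "mean_accuracy": res.metric_means["accuracy"],
                "n_retained": res.n_retained,
            }
        )
    return pd.DataFrame(rows)


def sweep_hidden_neurons(
    values: Sequence[int],
    network_config: NetworkConfig,
    training_config: TrainingConfig,
    cohort: Cohort,
    n_restarts: int = 120,
    train_fraction: float = 0.7,
    decision: DecisionConfig = DecisionConfig(),
) -> pd.DataFrame:
    """Mean/std sensitivity versus hidden-layer width, sorted ascending,
    with the arg-max width flagged in the ``optimal`` column."""
    vals = sorted(int(v) for v in values)
    if not vals:
        raise ValueError("empty sweep grid")
    if any(v < 1 for v in vals):
        raise ValueError("hidden-layer sizes must be >= 1")
    seeds = restart_seeds_for(training_config.seed, n_restarts)
    rows = []
    for v in vals:
        res = train_ensemble(
            replace(network_config, n_hidden=v), training_config, cohort,
            n_restarts, train_fraction, decision, restart_seeds=seeds,
        )
        rows.append(
            {
                "n_hidden": v,
                "mean_sensitivity": res.metric_means["sensitivity"],
                "std_sensitivity": res.metric_stds["sensitivity"],
                "n_retained": res.n_retained,
            }
        )
    df = pd.DataFrame(rows)
    df["optimal"] = df["mean_sensitivity"] == df["mean_sensitivity"].max()
    return df
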