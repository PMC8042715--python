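# batchfocus

Cost-sensitive neural-network learning for **imbalanced clinical tabular
data**, built around two ideas:

1. **Batch-adaptive learning rate.** A small feed-forward network
   (default 29-14-2) is trained by mini-batch SGD in which the learning
   rate of the *i*-th batch grows with the number of minority-class
   samples it contains:

   ```
   lr(i) = lr0 + n(i) · Δlr
   ```

   so the rare class is emphasised exactly when its examples are
   present, instead of being drowned out by the majority. The classical
   per-sample cost-sensitive baseline (`lr = lr0` for the majority,
   `lr0 + δlr` for the minority) is included for comparison.

2. **Decision-threshold shifting.** The two output units satisfy
   `o1 + o2 = 1`; a positive is predicted iff `o1 > 0.5 − Δ`. Raising Δ
   trades specificity for sensitivity, which is the right trade in
   screening settings where a missed positive is costly.

The motivating application is predicting fetal loss in pregnancies of
patients with systemic lupus erythematosus (SLE) from 29 routine
clinical indices with ~10% positive prevalence, but nothing in the
package is tied to that dataset: a synthetic cohort generator with the
same statistical shape (mixed binary/count/continuous features, a
three-way one-hot disease-status group, zero-inflated proteinuria,
configurable class signal) makes every experiment reproducible from
code alone.

The package is aimed at biostatisticians and ML practitioners who need
an imbalanced-classification workbench with exact, inspectable
internals: hand-derived backpropagation, a definitional metrics suite
(sensitivity, specificity, accuracy, F1, MCC, ROC-AUC, PR-AUC), early
stopping on validation sum-squared error, a multi-restart
selection protocol with divergence exclusion, and hyperparameter sweeps.

## Worked example

```python
import batchfocus as bf

# a 338-patient development pool and a 131-patient later "external" pool
pool, external = bf.reference_cohort()

# multi-restart training: every restart re-splits 234/104 (batch size 13),
# re-initializes the 29-14-2 network, and early-stops on validation SSE
result = bf.train_ensemble(
    bf.NetworkConfig(),
    bf.TrainingConfig(delta_lr=0.2, seed=1),
    pool,
    n_restarts=120,
)
print(f"retained {result.n_retained}/120 networks")
print(f"mean validation sensitivity {result.metric_means['sensitivity']:.3f}")

# shift the decision threshold by 25% and re-score the best network
best = result.best
ext = bf.normalize_cohort(external, state=best.normalization_state)
scores = bf.forward_batch(best.weights, ext.X)[0][:, 0]
report = bf.score_report(scores, ext.y, bf.DecisionConfig(delta=0.25))
print(f"external sensitivity {report.sensitivity:.3f} "
      f"specificity {report.specificity:.3f} ROC-AUC {report.roc_auc:.3f}")
```

Output:

```
retained 120/120 networks
mean validation sensitivity 0.431
external sensitivity 0.727 specificity 0.883 ROC-AUC 0.942
```

Reading: averaged over 120 restarts the batch-adaptive rule lifts
validation sensitivity to 0.431 (plain mini-batch SGD at `Δlr = 0`
gives 0.401 on the same restart seeds). Shifting the threshold by 25%
raises the selected network's external sensitivity to 0.727 (8 of the
11 held-out positives) at 0.883 specificity, and its external ranking
quality is ROC-AUC 0.942.

The same workflows are available from the shell:

```bash
batchfocus simulate --n 469 --seed 7 --out cohort.csv
batchfocus train cohort.csv --delta-lr 0.2 --batch-size 13 --out-model model.json
batchfocus evaluate model.json cohort.csv --delta 25% --sweep -0.20:0.25:0.01 --out report.json
batchfocus sweep cohort.csv --param delta_lr --grid 0:1:0.2 --restarts 120 --out sweep.csv
```

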