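# sensitab

Drug-sensitivity prediction from gene-expression tables, built for the
venetoclax / T-ALL setting but applicable to any drug with IC50-annotated
transcriptomic cohorts.  The package covers the full workflow: data
preparation with leak-free normalization and class rebalancing, a
semi-supervised gated tabular network, hyperparameter-search orchestration
scored by NegLog2RMSL, a 13-metric evaluation harness with repeated
cross-validation, cohort-level sensitive/resistant calling, and the
dose-response / Bliss-synergy mathematics used to validate predicted
resistance partners (e.g. PLK1 inhibition alongside BCL2 inhibition).

## What it computes

**Labels.** A sample is *sensitive* iff its IC50 for the target drug is
strictly below a threshold (default 500 nM), otherwise *resistant*.

**Model.** A feed-forward network for tabular data with an instance-wise
soft feature-attention gate g(x) ∈ (0,1)ᵖ multiplying the input before the
hidden stack, trained with an L1 sparsity penalty on the gate so the model
attends to few genes.  The same encoder is first pretrained
self-supervised (random feature masking, linear reconstruction head,
masked-MSE loss) on unlabeled expression data, then fine-tuned with a
logistic head on the labeled training split, early-stopping on validation
NegLog2RMSL.

**Model selection.** Candidates are scored by

```
NegLog2RMSL = −log₂( max(RMSL, 10⁻⁶) ),   RMSL = √(mean((pᵢ − yᵢ)²))
```

with y ∈ {0,1} — an uninformative constant-0.5 predictor scores exactly
1.0 and each halving of the root-mean-square loss adds 1.  Four search
strategies (hardcoded, grid, Gaussian-process/EI, TPE) share one surface,
and a *superior* mode runs all four and keeps the winner.  Final scoring
additionally uses the combined Cohen–MCC statistic, (κ + MCC)/2.

**Synergy.** Viability curves are fitted with the four-parameter logistic
on the inhibitory-effect scale, effect(x) = bottom + (top −
bottom)/(1 + (EC50/x)^hill), giving EC50 and closed-form EC-f (e.g. EC33).
Combination grids are scored by Bliss independence: excess = observed −
(e₁ + e₂ − e₁·e₂), positive meaning synergy.

## Worked example

Everything runs on synthetic data with known ground truth (no downloads).
The generator plants a configurable number of informative genes whose
log-expression is shifted between classes, and draws IC50s so that the
500 nM rule reproduces the intended labels exactly.

```python
from sensitab import (make_pharmacogenomic, minmax_normalize, split_train_test,
                      HyperParams, fit, pretrain, evaluate_holdout, predict_cohort)
from sensitab.data import make_labeled

annotated, responses, unlabeled, truth = make_pharmacogenomic(
    n_sensitive=140, n_resistant=191, n_genes=200, n_informative=10,
    effect_size=1.5, n_unlabeled=264, seed=1)

norm, stats = minmax_normalize(annotated)
dataset = make_labeled(norm, responses, "venetoclax")   # IC50 < 500 nM -> sensitive
train, test = split_train_test(dataset, test_fraction=0.2, seed=1)

unlabeled_norm, _ = minmax_normalize(unlabeled, stats)  # train-fitted stats, clipped
hp = HyperParams(max_epochs=40, seed=1)
encoder = pretrain(unlabeled_norm, hp, masking_fraction=0.5)

inner_train, inner_val = split_train_test(train, 0.2, seed=2)
model = fit(inner_train, hp, encoder=encoder, validation=inner_val)

report = evaluate_holdout(model, test)
print(f"AUC={report.auc:.3f}  accuracy={report.accuracy:.3f}  "
      f"MCC={report.mcc:.3f}  NegLog2RMSL={report.neglog2rmsl:.2f}")
print("confusion:", report.confusion.to_dict())

calls = predict_cohort(model, unlabeled_norm)
print("cohort calls:", calls.counts)
```

Output:

```
AUC=0.927  accuracy=0.806  MCC=0.618  NegLog2RMSL=1.39
confusion: {'tp': 24, 'fp': 9, 'tn': 30, 'fn': 4}
cohort calls: {'sensitive': 119, 'resistant': 145}
```

At a moderate 1.5-sigma effect the held-out AUC is 0.93; of the 67 test
samples, 9 resistant and 4 sensitive ones are miscalled.  The 264
unlabeled samples split into 119 predicted sensitive and 145 predicted
resistant, close to the generator's 42% sensitive mixing proportion.
At the default 3-sigma benchmark effect the same pipeline separates the
classes essentially perfectly.

The same workflow runs from a shell:

```bash
sensitab simulate -o simdir --seed 1
sensitab run -c config.yaml            # load -> select -> normalize -> label ->
                                       # split -> resample -> pretrain -> search ->
                                       # fit -> evaluate -> predict-cohort
sensitab synergy fit4pl viability.csv --ec 50 --ec 33
sensitab synergy bliss combination_grid.csv
```

`run` writes `metrics.json`, optional CV tables, `cohort_predictions.csv`,
a model directory and a `manifest.json` recording every seed and artifact
digest, so any reported number can be regenerated.

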