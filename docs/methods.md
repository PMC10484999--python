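# Methods

## Problem setting

Given a samples × genes expression matrix and per-sample IC50 values for a
drug, the pipeline learns a binary classifier of drug sensitivity and
applies it to unlabeled cohorts.  The label rule is strict: sensitive iff
IC50 < 500 nM (the boundary value itself is resistant).  The positive
class throughout is *sensitive*.

## Data preparation

* **Orientation.** Matrices are samples × genes internally; the loader
  accepts either orientation and transposes as declared.  Duplicate
  identifiers and non-numeric or non-finite cells are rejected with the
  offending name/coordinates (no silent imputation).
* **Feature selection** keeps the k genes with largest per-gene variance
  (population variance, ties broken lexicographically on gene id for
  determinism).  Default k = 1000; on synthetic data the generator's gene
  count is usually smaller and all genes are kept.
* **Min-max normalization** maps each gene to [0, 1].  Stats are fitted on
  the training split only and applied with clipping to validation, test
  and unlabeled data; a `global` mode fitting on the full annotated matrix
  exists for comparison.  A gene constant in the fitting data maps to 0
  (not NaN) so matrices stay finite.
* **Tripartite sampling.** Training data (never test data — the API takes
  only the training split) can be left unaltered, oversampled (minority
  duplicated with replacement up to the majority count; duplicates get
  suffixed ids so they remain identifiable) or undersampled (majority
  randomly reduced to the minority count).  Random duplication rather than
  interpolation keeps class counts and feature distributions exact.

## The learner

A compact feed-forward network for tabular data with an instance-wise
feature-attention gate, written in numpy with hand-derived backpropagation
(verified against central finite differences in the test suite) and Adam:

```
z₁ = leaky(x·U₁ + c₁)                 # gate subnetwork, width = attention_width
g  = σ(γ · (z₁·U₂ + c₂))              # per-feature gate in (0,1)
h₀ = x ⊙ g
hₗ = leaky(hₗ₋₁·Wₗ + bₗ)              # n_decision_steps layers, width = decision_width
p  = σ(h·w + b)                       # logistic head
loss = BCE(p, y) + λ·mean(g)
```

γ (`relaxation_gamma` ≥ 1) sharpens the gate toward hard feature
selection; λ (`sparsity_coefficient`) is an L1 penalty on mean gate
activation encouraging the model to attend to few genes.  Activations are
leaky ReLU (slope 0.01): with hard ReLU the reconstruction objective below
can park the whole hidden stack in an all-negative (dead) configuration
from which no gradient escapes, and the leak keeps fine-tuning able to
recover such units.  Hidden biases start at +0.01 for the same reason.

**Self-supervised pretraining.** A random fraction of entries (default
0.5) is zeroed per presentation and a linear decoder reconstructs the
original values; the loss is the MSE over masked entries only.  The gate
sparsity penalty is disabled during pretraining: under a reconstruction
objective it drives the gates into a degenerate all-closed optimum where
the decoder bias alone predicts column means.  The encoder weights (gate +
hidden stack) then initialize supervised training; the heads are always
fresh.

**Supervised training** minimizes cross-entropy with mini-batch Adam
(default batch 32, learning rate 0.02).  With a validation set, training
early-stops on validation NegLog2RMSL (AUC selectable) with patience 20
and restores the best epoch's weights.

Defaults (decision width 16, attention width 8, 2 hidden layers, γ = 1.5,
λ = 10⁻⁴, 100 epochs) were chosen as a small-capacity configuration
appropriate for cohorts of a few hundred samples; they are the `hardcoded`
search strategy's configuration and the base the other strategies perturb.

Everything is seeded through `numpy.random.Generator`, so pretraining,
fitting and prediction are bit-reproducible per BLAS build; weight
fingerprints (SHA-256 of the weight bytes) make identity checkable.

## Model-selection metric

NegLog2RMSL = −log₂(max(RMSL, 10⁻⁶)) with RMSL the root-mean-square
difference between predicted probabilities and 0/1 labels.  The score is
strictly decreasing in RMSL until the ε-clamp; the clamp bounds the score
at ≈ 19.93 for perfect probabilities.  RMSL is computed in probability
space.  The combined Cohen–MCC score is the arithmetic mean of Cohen's κ
and the Matthews correlation coefficient (a `min` combination is
available); degenerate 2×2 tables (a zero marginal) define the affected
statistic as 0 with a flag rather than NaN.

## Hyperparameter search

All strategies evaluate candidates by inner-validation NegLog2RMSL
computed entirely inside the training split (stratified 3-fold by default,
holdout selectable), and record every sample id seen in an audit log that
callers can intersect with their held-out ids.

* `hardcoded` scores the predefined configuration once.
* `grid` enumerates the Cartesian product of the enumerable dimensions; a
  continuous range in a pure grid spec is an error, while under `superior`
  continuous dimensions stay at their hardcoded values.
* `bayes` fits a Gaussian-process surrogate (Matérn 5/2, inputs encoded to
  [0,1]ᴰ, log-scaled where declared) after an initial random third of the
  budget, and picks candidates by expected improvement over 64 random
  proposals per step.
* `tpe` splits past trials into the top quarter and the rest, models each
  group with per-dimension kernel densities (Laplace-smoothed frequencies
  for categorical dimensions), and picks the candidate maximizing the
  good/bad density ratio among 24 proposals.

`superior` runs all four with independently derived seeds; the winner is
the argmax of inner-validation score, ties broken by fewer model
parameters, then by method order hardcoded → grid → bayes → tpe
(simplicity first).  A failing sub-method is recorded as a failure row and
excluded from the argmax; only all four failing is fatal.  Default spaces
(widths {8,16,32}, steps {3,5}, learning rate log-uniform on
[10⁻³, 2·10⁻²], budget 20) are pragmatic defaults, not a claim about any
particular study's search ranges.

## Evaluation

The 13-metric report — accuracy, AUC, average precision, Cohen's κ, Brier
score, F1, Jaccard, MCC, NPV, precision, sensitivity, specificity,
NegLog2RMSL — derives all thresholded metrics from exact confusion counts;
probability ties at the decision threshold classify positive.  Jaccard is
reported both for the positive class and macro-averaged over both classes,
because the two variants differ materially on imbalanced data; both fields
are always emitted.  Single-class label vectors flag AUC and average
precision as undefined (0 with a flag) and compute the rest.

Repeated stratified k-fold cross-validation (default 5 × 20) re-runs the
full recipe — resampling, optional search, fitting with an early-stopping
split carved from the fold's training portion — inside each fold and
scores the untouched fold test portion; the result carries one record per
fold (k·repeats total), per-metric mean/sd/min/max, and a per-fold audit
of train/test ids.  Within-CV search defaults to the hardcoded
configuration for tractability, with the full search available by config.
In the CLI's CV stage, normalization for the pooled matrix is computed
once on the full annotated data rather than per fold — a small,
documented, conservative-against-the-model simplification.

Cohort prediction applies the trained model (after normalizing the cohort
with the *training* stats) and emits per-sample probabilities, calls at a
threshold (ties sensitive), counts, and probability-ranked class lists
suitable for downstream enrichment tools.

## Dose-response and synergy

4PL fitting works on the inhibitory-effect scale (effect = 1 − viability,
clipped to [0,1]), fitting all replicate points jointly by bounded
trust-region least squares with EC50 and Hill slope log-parameterized.
Initialization is an exhaustive multi-start over Hill ∈ {0.5, 1, 2, 4} ×
four log-spaced EC50 guesses spanning the dose range; the lowest-SSE
solution wins, making the fit deterministic given the data.  A fitted span
(top − bottom) below 0.1 flags the curve degenerate — a flat curve carries
no dose information and its EC50 must not be trusted; EC-f extraction
refuses degenerate fits.  EC-f uses the closed form EC_f = EC50 ·
(p/(1−p))^(1/hill), p = f/100 on the bottom→top span, so EC50 is recovered
exactly at f = 50 regardless of slope.

Bliss scoring takes inhibitory-effect *fractions* in [0,1] (percentages
convert at the I/O boundary): excess = observed − (e₁ + e₂ − e₁e₂).  The
expected effect is algebraically guaranteed to stay in [0,1].  Grid
scoring applies the formula elementwise and summarizes by mean excess.
The kinase-screen filter keeps inhibitors whose viability reduction meets
the cutoff (default 10%, inclusive), sorted descending.

## Synthetic data

The generator is the package's test bed and defines its study conditions:

* **Expression**: log-expression per gene is baseline N(1, 0.5) plus, for
  the informative genes in sensitive samples, a shift of
  effect_size × noise_sd, plus N(0, noise_sd) noise; expression is its
  exponential (lognormal — positive and right-skewed like real expression
  measurements).  Defaults mirror a mid-size annotated cohort: 140
  sensitive / 191 resistant, 200 genes of which 10 informative, 3-sigma
  effect, 264-sample unlabeled pool drawn from the same mixture.
* **IC50s**: lognormal, sensitive centred at 100 nM truncated below the
  threshold, resistant at 2000 nM truncated above it, so binarization
  reproduces the intended labels with zero error — a deliberate
  simplification versus real pharmacology that makes label-dependent
  invariants exactly testable.
* **Dose-response**: viability = 1 − 4PL(dose) + Gaussian noise, clipped
  to [0, 1.5]; **combination grids**: Bliss expectation + injected excess
  + noise, clipped to [0,1] with clipping recorded.

What the generator does *not* emulate: gene–gene covariance structure,
batch effects, dropout, platform differences, or any relationship between
expression and IC50 beyond the class labels.  Passing tests therefore
demonstrate correctness of the machinery and learnability under the stated
mixture model, not clinical-grade performance on real cohorts.

## Problem sizes used in tests and the acceptance script

The separable benchmark runs at n = 300 samples (150/150), 200 genes, 10
informative, 3-sigma effect, 40 training epochs, medians over 10 seeds;
the repeated-CV checks use 120 samples × 50 genes at 12 epochs; the
leakage audit uses 20 seeds of 60 × 30 data at 8 epochs.  These sizes give
stable statistics while keeping the whole suite fast on a single CPU.

## Known limitations

* The learner is a compact gated network, not a multi-step
  sequential-attention architecture; capacity is deliberately small and
  geared to cohorts of hundreds, not tens of thousands, of samples.
* Bitwise reproducibility holds per BLAS/hardware class; cross-platform
  comparisons should use the 1e-6 tolerance the tests use.
* Combination-index scoring is not implemented (no standard closed form
  was adopted); Bliss independence is the sole synergy model, and
  Loewe/ZIP/HSA are out of scope.
* The pipeline performs no probe-to-gene mapping, batch correction or
  cohort download; inputs are assumed to be clean expression tables.
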