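# Methods

## Model

`attnrisk` implements an attention-gated feed-forward classifier for binary
clinical outcomes on tabular patient data. For a patient with feature vector
x ∈ R^m the model computes

    alpha = softmax(W x + b),        W ∈ R^{m×m}, b ∈ R^m
    g     = alpha ⊙ x                (element-wise gating)
    p     = sigmoid(MLP(g))          (ReLU hidden layers, one sigmoid unit)

and predicts the positive class when p is strictly greater than the decision
threshold (default 0.5; a probability exactly at the threshold maps to the
negative class, so a degenerate constant-0.5 output never predicts events).
Because alpha lies on the probability simplex, its entries serve as a
per-patient decomposition of which features the prediction relied on. The
attention is magnitude-only: it cannot express the direction of a feature's
effect, which is why the interpretation module pairs attention rankings with
signed logistic-regression coefficients.

Training minimizes

    L(Θ) = −(1/n) Σ_i [ y_i log p_i + (1−y_i) log(1−p_i) ] + λ ‖Θ‖²₂

by mini-batch Adam. Probabilities are clipped to [ε, 1−ε] with ε = 1e-7
inside the logs, and the gradient respects the clipping (it is exactly zero
where the clip is active), so analytic gradients match finite differences to
better than 1e-5 relative error even at saturated outputs.

**Penalty membership.** Θ comprises the attention parameters (both W and b)
and the MLP weight matrices; MLP biases are not penalized. Penalizing the
attention *bias* alongside its weights is a deliberate choice: the bias
directly parametrizes the attention distribution, and with a scale-invariant
optimizer like Adam an unpenalized bias can drift while the weights decay,
leaving the attention pinned at an arbitrary distribution. With the bias in
Θ, a dominant penalty provably collapses attention to uniform — the
behaviour one expects of "regularize toward no feature preference", and a
property the test suite checks at λ = 10⁶.

## Defaults and why

| parameter | default | rationale |
|---|---|---|
| learning rate | 0.001 | stable Adam rate for tiny tabular nets |
| λ (L2) | 0.001 | mild shrinkage; the sweep grid explores depth, not λ |
| hidden layers | 1 (grid 1–5) | small cohorts favour shallow nets |
| hidden width | 64 | common default; exposed in `ModelConfig` |
| activation | ReLU | standard; gradient-checked subgradient at 0 is 0 |
| batch size | 32 | a few dozen steps per epoch at n ≈ 600 training rows |
| epochs / patience | 300 / 20 | early stopping on a 10% stratified validation split (unpenalized cross-entropy); best parameters restored |
| init | Glorot-uniform weights, zero biases | lets attention break symmetry at step one (zero-init W would also work but starts exactly uniform) |
| threshold | 0.5, strict `>` | ties map to the negative class |

All randomness flows from a single integer seed through
`numpy.random.default_rng`; fits are bit-reproducible given (data, config).

## Baselines

- **Logistic regression**: penalized Bernoulli MLE, objective
  (1/n)·NLL + l2·‖w‖² (intercept unpenalized), backed by scikit-learn's
  lbfgs solver (C = 1/(2·n·l2); `penalty=None` when l2 = 0). Default
  l2 = 1e-4 for numerical stability; l2 = 0 gives the pure MLE, with a
  warning when the coefficient norm suggests perfect separation.
- **Plain MLP**: the identical training engine with the attention layer
  removed. With zero attention parameters the gated model is numerically
  identical (to 1e-12) to the plain MLP applied to x/m.
- **SDAE**: greedy layerwise denoising-autoencoder pretraining (ReLU
  encoder, linear decoder, masking corruption at rate 0.2, squared-error
  reconstruction of the *clean* input), then a sigmoid head fine-tuned
  end-to-end with cross-entropy. Defaults: two coder layers of widths
  [64, 32], Adam 0.001 in both phases. The classification head uses the
  encoder stack only; decoders are discarded after pretraining. Corruption
  type/rate and widths are conventional choices, all exposed in
  `SDAEConfig`.

## Preprocessing

- Features missing in **strictly more than 30%** of patients are dropped
  (a feature at exactly 30% is retained — the rule is "more than").
- Remaining missing cells are filled with the per-feature median computed
  over **all rows** by default, i.e. imputation happens once at the dataset
  level before any splitting. This mirrors a common (if leak-prone)
  clinical-study workflow; the leak-free alternative — medians from the
  training split applied to held-out data — is available by preprocessing
  each split separately (`filter_missing_features`/`impute_median` operate
  on any `RawTable`, and the report's `imputation_medians` can be re-applied).
- Features are z-scored with training-split statistics (sample sd, ddof=1),
  applied unchanged to test data. Scaling is essential here, not cosmetic:
  the gating multiplies attention into raw feature values, so without a
  common scale the attention magnitudes of different features would not be
  comparable. Zero-variance features are centered but left unscaled.
- Missing-value markers default to the empty cell, `NA` and `NaN`;
  configurable.

## Evaluation protocol

Per repetition r (seed = base_seed + r): a **stratified** 80/20 split is
drawn fresh — redrawing per repetition is what gives the mean ± std
summaries their spread; a fixed split with a deterministic pipeline would
have zero variance. On the 80%: each model with a depth grid selects the
number of hidden layers by mean five-fold CV AUC (stratified folds, ties to
the shallower net), then refits on the full 80% and scores the untouched
20%. Test rows never influence imputation or standardization statistics,
training, or depth selection.

Metrics: accuracy, precision, recall, F1, AUC. AUC is the Mann–Whitney
concordance (ties count 1/2), computed via the rank-sum identity so it
agrees *exactly* with brute-force pair enumeration. Precision with zero
predicted positives is defined as 0 with a warning (F1 likewise).

Model comparison uses the paired-samples t-test on the pooled per-patient
predicted labels across repetitions (t = mean(d)/(sd(d)/√n), sample sd,
two-sided p from Student t(n−1); d ≡ 0 gives t = 0, p = 1; constant nonzero
d gives infinite t, p = 0, flagged degenerate). A t-test on paired binary
outcomes is statistically questionable — McNemar's exact test on discordant
correctness is the textbook tool and is provided as `mcnemar_test` — but
the t-test is the harness default for comparability. A per-repetition
t-test mode is also exposed (`ttest_mode="per_repetition"`, reporting the
median-p repetition).

## Synthetic cohorts

The generator emulates a numeric clinical feature table: features are
standard Gaussians with optional equicorrelation ρ (one-factor
construction), the outcome follows a sparse logistic model over a designated
informative set, and missingness can be injected completely at random
(labels are never masked). An optional flag dichotomizes chosen features at
0 to mimic comorbidity indicators. The `study_shaped_spec` preset produces a
cohort shaped like a small heart-failure readmission study — 736 patients,
105 features, target prevalence 461/736 ≈ 0.626 via bisection on the
Monte-Carlo expectation of the sigmoid, 10 informative features with
alternating-sign log-odds ±0.8.

What the generator does **not** emulate: mixed feature types and coding
conventions of real EHR tables, informative (MNAR) missingness, visit
structure, label noise from imperfect follow-up, and correlated blocks
beyond equicorrelation. Passing tests on these cohorts therefore show that
the machinery is correct and that attention recovers planted signal under
clean conditions; they do not certify performance on real clinical data.

The equicorrelation knob exists precisely to observe a known failure mode:
with correlated features, attention can smear credit across a correlated
block rather than isolating the causal column.

## Attention-faithfulness check

The headline validation: on a cohort with n = 2000, m = 20, three
informative features (|β| = 2, ρ = 0), across 10 training seeds the mean
attention on informative features must exceed the mean on noise features in
at least 9 of 10 runs, and all three informative features must appear in the
global top-5 frequency ranking (top-10 per patient) in at least 8 of 10
runs. Both checks pass 10/10 at the defaults used in the test suite.

## Numerical choices

- Softmax is max-subtracted; any finite logits are safe. Mathematically
  attention entries lie in (0, 1), but a saturated softmax can round an
  entry to exactly 1.0 in float64; the container accepts that.
- Cross-entropy clipping ε = 1e-7.
- Ranking ties (attention, frequency counts, |coefficients|) break by
  original feature order, via stable sorts.
- The heat-map transform is the natural log of attention weights
  (configurable base), over a seeded random subset of 50 patients by
  default; all entries are ≤ 0 since weights are ≤ 1.
- Model serialization is a single JSON file; doubles round-trip exactly, so
  a reloaded model reproduces forward outputs bit-for-bit.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` exercise the full protocol on a
study-shaped cohort (n = 736, m = 105) with demonstration-scale training
budgets — hidden width 32 and a few tens of epochs per fit — chosen so the
complete 10-repetition, five-fold, depth-1–5 pipeline runs in minutes on a
single CPU while leaving every structural property (counts, summaries,
t-test matrix, oracle behaviour) intact. The attention-recovery check runs
at its full stated size (n = 2000, 10 refits).

## Known limitations

- No autodiff dependency: gradients are hand-derived (and verified against
  central finite differences); extending the architecture requires
  extending the backward pass.
- The attention layer has m² parameters — for very wide tables (m in the
  thousands) it dominates the parameter count and will overfit small n.
- Attention explains the model, not the world: rankings are descriptive of
  the fitted network and carry no causal claim about risk factors.
- Single binary outcome only; no sequence/visit-level attention.
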