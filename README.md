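# attnrisk

Interpretable clinical risk prediction with input-feature attention.

Clinical prediction models are only useful to clinicians if they can say
*why* a patient was flagged. `attnrisk` implements a small neural
architecture for binary outcomes on tabular patient data (the motivating
task is one-year hospital-readmission prediction for heart-failure
patients) in which every prediction comes with a per-feature contribution
profile. An attention layer

    α = softmax(W x + b),    g = α ⊙ x,    ŷ = σ(MLP(g))

maps each patient's feature vector x ∈ ℝ^m to a probability vector α on the
simplex, gates the input element-wise, and classifies the gated
representation with a ReLU MLP and sigmoid output. Training minimizes the
L2-penalized cross-entropy

    L = −(1/n) Σᵢ [ yᵢ log ŷᵢ + (1−yᵢ) log(1−ŷᵢ) ] + λ‖Θ‖²₂.

Because α sums to one, its entries read directly as the relative weight the
model placed on each feature for that patient — per-patient risk-factor
profiles, global frequency rankings, and log-attention heat maps all fall
out of it.

The package also provides:

- **Preprocessing** for clinical feature tables: drop features with more
  than 30% missing values, median-impute the rest, z-score with
  training-split statistics, stratified holdout splitting.
- **Baselines**: logistic regression, a plain MLP (same training engine,
  no attention), and a stacked denoising autoencoder classifier.
- **An evaluation protocol**: repeated stratified 80/20 holdout with
  five-fold cross-validated depth tuning, five metrics reported
  mean ± std, hidden-layer sweeps, and paired t-tests (plus McNemar's
  test) between models.
- **A synthetic cohort generator** with known informative features, so
  that both prediction and attention faithfulness are testable against
  ground truth — including a preset shaped like a small readmission study
  (n = 736, m = 105, prevalence ≈ 0.63).

The networks are pure numpy with hand-derived gradients, verified against
central finite differences in the test suite.

## Worked example

```python
from attnrisk import (
    SyntheticSpec, generate_cohort, split_holdout, standardize_features,
    ModelConfig, fit_attention_model, compute_metrics,
    extract_attention, global_frequency_ranking,
)

sc = generate_cohort(SyntheticSpec(
    n=1000, m=12, informative_idx=[0, 1, 2], beta=[2.0, -2.0, 1.5], seed=4))
train, test = split_holdout(sc.cohort, seed=0)
train, stats = standardize_features(train)
test, _ = standardize_features(test, stats=stats)

model = fit_attention_model(train, ModelConfig(n_hidden_layers=1, epochs=100, seed=0))
pred = model.predict(test.X)
print(compute_metrics(test.Y, pred.labels, pred.probs))

alpha = extract_attention(model, test.X)
for feat, count in global_frequency_ranking(alpha, test.feature_names, k=5, top=5).entries:
    print(feat, int(count))
```

prints (see `examples/03_train_and_explain.py`):

```
{'accuracy': 0.805, 'precision': 0.854, 'recall': 0.745, 'f1': 0.796, 'auc': 0.901}
f1 194
f2 192
f3 167
f9 77
f10 71
```

The held-out metrics show the model discriminates well (AUC 0.90), and the
global ranking — how many of the 200 test patients have each feature in
their attention top-5 — puts the three truly informative features (`f1`,
`f2`, `f3`) clearly ahead of the noise features.

More narrative scripts live in `examples/`: cohort generation,
preprocessing, model comparison, and the hidden-layer depth sweep.

## Command line

A thin CLI wraps the library for reproducible runs; every command writes a
manifest (resolved config, seeds, input digests) next to its outputs:

```bash
attnrisk simulate --preset study-shaped --seed 7 -o out/sim
attnrisk preprocess --data out/sim/cohort.csv -o out/prep
attnrisk evaluate --data out/prep/cohort.csv --models attn,mlp,lr,sdae \
    --repeats 10 -o out/eval
attnrisk sweep --data out/prep/cohort.csv --grid 1,2,3,4,5 -o out/sweep
attnrisk train --data out/prep/cohort.csv -o out/model
attnrisk interpret --data out/prep/cohort.csv --model out/model/model.json -o out/interp
```

## Layout

```
src/attnrisk/
  data_io.py          table parsing, missingness filter, imputation, scaling, splits
  synthetic.py        ground-truth cohort generator
  attention_model.py  the attention-gated classifier (model, loss, training)
  baselines.py        logistic regression, plain MLP, SDAE
  evaluation.py       metrics, AUC, t-tests, repeated-holdout protocol, sweeps
  interpretation.py   attention extraction, rankings, heat-map matrices
  cli.py              thin click CLI
docs/methods.md       model, defaults, protocol and limitations in detail
examples/             one narrative script per capability
tests/                pytest suite (unit, property and end-to-end checks)
```
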