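"""Train the attention-gated classifier and read off feature contributions.

Each patient gets an attention vector alpha = softmax(Wx + b) on the
probability simplex: large entries mark the features that drove that
patient's prediction. Globally, counting how often a feature lands in
patients' top-k gives a population-level risk-factor ranking.
"""

from attnrisk import (
    ModelConfig,
    SyntheticSpec,
    explanation_sheet,
    extract_attention,
    fit_attention_model,
    generate_cohort,
    global_frequency_ranking,
    split_holdout,
    standardize_features,
    compute_metrics,
)

sc = generate_cohort(
    SyntheticSpec(n=1000, m=12, informative_idx=[0, 1, 2], beta=[2.0, -2.0, 1.5], seed=4)
)
train, test = split_holdout(sc.cohort, seed=0)
train, stats = standardize_features(train)
test, _ = standardize_features(test, stats=stats)

model = fit_attention_model(train, ModelConfig(n_hidden_layers=1, epochs=100, seed=0))
pred = model.predict(test.X)
metrics = compute_metrics(test.Y, pred.labels, pred.probs)
print("held-out metrics:", {k: round(v, 3) for k, v in metrics.items()})

alpha = extract_attention(model, test.X)
ranking = global_frequency_ranking(alpha, test.feature_names, k=5, top=5)
print("\nglobal ranking (times in a patient's top-5 of", test.n, "patients):")
for feature, count in ranking.entries:
    truth = "informative" if feature in ("f1", "f2", "f3") else "noise"
    print(f"  {feature}: {count:.0f}  [{truth}]")

sheet = explanation_sheet(model, test.X, test.feature_names, patient_index=0, k=3)
print(f"\npatient 0: p(event) = {sheet['probability']:.3f}, top features:")
for e in sheet["top_features"]:
    print(f"  {e['feature']}: attention {e['attention']:.3f}")
# attention is magnitude-only: it says WHICH features mattered, not the
# direction of their effect — pair with signed LR coefficients for that.
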