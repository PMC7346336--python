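"""Clinical-table preprocessing: missingness filter and median imputation.

Features missing in more than 30% of patients are dropped outright; the
remaining missing cells are filled with the per-feature median.
"""

from attnrisk import SyntheticSpec, generate_cohort, inject_missingness, preprocess

sc = generate_cohort(SyntheticSpec(n=300, m=8, seed=2))
raw = inject_missingness(sc.cohort, missing_rate=0.15, seed=3)
# push two features over the 30% threshold
raw.values[:150, 0] = float("nan")
raw.values[:120, 1] = float("nan")

cohort, report = preprocess(raw, max_missing_fraction=0.30)
print(f"features before/after: {report.n_cols_before} -> {report.n_cols_after}")
for name, frac in report.dropped_features:
    print(f"  dropped {name}: {frac:.0%} missing (> 30%)")
print(f"imputed features: {sorted(report.imputation_medians)}")
print(f"any missing left: {bool((cohort.X != cohort.X).any())}")
# the cohort is now a complete numeric matrix ready for modelling
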