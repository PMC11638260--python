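# reliattn

**How measurement noise in behavioural phenotypes limits brain–behaviour
prediction.**

Predictive modelling studies regress behavioural phenotypes (cognition,
grip strength, symptoms, age) on functional-connectivity features. When a
prediction target has imperfect test–retest reliability, part of its
variance is unlearnable measurement noise, and out-of-sample accuracy is
attenuated — often drastically. `reliattn` provides, for methodologists and
cohort analysts, a tested pipeline to quantify this attenuation: a
correlated-noise surrogate generator, ICC(2,1) reliability estimation,
nested cross-validated ridge prediction, reliability × sample-size learning
curves, and a synthetic cohort generator so every stage runs without
restricted data.

## The model in brief

*Surrogates.* Given an observed target Y, draw X with Y's moments, take the
least-squares residuals Y⊥ of X on Y, and form

```
X_Yρ = ρ·σ(Y⊥)·Y + √(1−ρ²)·σ(Y)·Y⊥
```

so that corr(X_Yρ, Y) = ρ **exactly**. X_Yρ behaves like a noisier
re-measurement of Y; under classical test theory its effective reliability
is ρ²·ICC_Y ("adjusted reliability").

*Reliability.* ICC(2,1): two-way random-effects ANOVA, absolute agreement,
single measurement, with F-based 95% confidence intervals.

*Prediction.* Ridge regression, nested CV (10 folds × 5 repeats, or
family-grouped splits), fold-safe z-scoring and confound removal, and exact
closed-form leave-one-out selection of the penalty α. Accuracy is the
coefficient of determination R² = 1 − SS_res/SS_tot (not the squared
correlation; negative out-of-sample values are possible), plus MAE and
Pearson r.

*Attenuation summary.* Mean R² within reliability bands of width 0.2
anchored at 1.0, and the mean relative R² drop between consecutive bands.

*Spearman's 1910 attenuation law* anchors the expectations: the observed
brain–behaviour correlation scales as √reliability, so R² scales roughly in
proportion to reliability — and training on noisy targets costs extra on
top.

## Worked example

```python
import numpy as np
from reliattn import CohortSpec, CVScheme, NoiseGrid, batch_simulate, icc_2_1
from reliattn.cohort import generate_cohort
from reliattn.experiments import predict_target

spec = CohortSpec(n_participants=500, n_parcels=16, n_sessions=2,
                  effect_r=0.75, target_icc=0.8, seed=42)
cohort = generate_cohort(spec)

est = icc_2_1(cohort.session_table(), name="target")
print(f"ICC(2,1) = {est.icc:.3f}  (95% CI {est.ci_lower:.3f}-{est.ci_upper:.3f})")

clean = predict_target(cohort.features, cohort.target, CVScheme(seed=42))
print(f"clean target: R2 = {clean.r2_mean:.3f} +/- {clean.r2_sd:.3f}")

for rho in (0.9, 0.7, 0.5):
    surs = batch_simulate(cohort.target, NoiseGrid((rho,), n_repeats=10, seed=42),
                          icc_source=est.icc)
    r2s = [predict_target(cohort.features, s.as_phenotype(),
                          CVScheme(seed=42)).r2_mean for s in surs]
    print(f"rho = {rho:.1f}  (adjusted reliability "
          f"{surs[0].adjusted_reliability:.2f}):  mean R2 = {np.mean(r2s):.3f}")
```

Output:

```
ICC(2,1) = 0.776  (95% CI 0.739-0.809)
clean target: R2 = 0.290 +/- 0.123
rho = 0.9  (adjusted reliability 0.63):  mean R2 = 0.233
rho = 0.7  (adjusted reliability 0.38):  mean R2 = 0.123
rho = 0.5  (adjusted reliability 0.19):  mean R2 = 0.035
```

Reading it: a target measured with ICC ≈ 0.78 is predicted at R² = 0.29;
re-measuring it with 10% extra noise (ρ = 0.9, effective reliability 0.63)
already costs a fifth of the accuracy, and at ρ = 0.5 — reliability levels
not uncommon for single behavioural assessments — prediction nearly fails.

## Command line

The `reliattn` umbrella command exposes each stage:
`simulate-cohort`, `inject-noise`, `icc`, `predict`, `learning-curve`, and
`report --config experiment.toml` (recipes: `attenuation`,
`reliability_accuracy`, `reliability_size`). All commands take `--seed` and
write CSV/JSON plus a manifest echoing the full configuration.

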