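# Methods

`reliattn` studies a single question end to end: how does the test–retest
reliability of a behavioural prediction target limit the out-of-sample
accuracy with which it can be predicted from brain connectivity features?
This note documents the models, the numerical choices, and what the
synthetic data do and do not show about real cohorts.

## The correlated-noise surrogate generator

The core primitive manufactures a "noisier re-measurement" of an observed
phenotype Y. A random vector X is drawn with Y's mean and SD (from a normal,
or from a Gaussian KDE of Y for visibly non-normal phenotypes such as age);
the residuals Y⊥ of a least-squares regression of X on Y (with intercept)
are exactly orthogonal to centred Y; and the surrogate is

    X_Yρ = ρ·σ(Y⊥)·Y + √(1−ρ²)·σ(Y)·Y⊥ .

Because of the orthogonality, the sample Pearson correlation of X_Yρ with Y
equals ρ *exactly* (floating point aside), not merely in expectation. An
exact affine moment match then restores Y's mean and SD, which leaves
correlations untouched. Numerical notes:

- The regression includes an intercept; without it the achieved correlation
  would be exact only for centred Y.
- σ(·) is the sample SD with n−1 denominator. The choice only scales the
  pre-matching output; the achieved correlation is unaffected.
- Moment matching is exact rather than approximate: strictly stronger, and
  it makes the invariant testable at 1e−9.
- The KDE uses a Gaussian kernel with Silverman bandwidth.
- Negative ρ is rejected; reliability manipulation only lowers correlations
  toward 0.
- Grids are seeded per (level, repeat) cell by spawning children of a single
  `SeedSequence`, so cells are independent and individually reproducible.

Under classical test theory a surrogate built at level ρ from a source with
test–retest reliability ICC₀ has true-score variance fraction ρ²·ICC₀ — its
**adjusted reliability**. The package adopts ρ²·ICC₀ as the reliability
attributed to surrogates throughout (verified by Monte Carlo: a surrogate
retest pair built from two source sessions has sample ICC(2,1) ≈ ρ²·ICC₀).

A caution that the tests encode: the attenuation identity
corr(ŷ, X_Yρ) = ρ·corr(ŷ, Y) is exact only for ŷ in span{1, Y}. An
arbitrary fixed vector (e.g. a trained model's predictions) has an
O(n^−1/2) chance overlap with the surrogate's residual direction, so for
such vectors the identity holds in expectation over surrogate draws.

## Reliability estimation

ICC(2,1) — two-way random effects, absolute agreement, single measurement —
is computed from the ANOVA mean squares, with the F-based McGraw–Wong 95%
confidence interval (Satterthwaite degrees of freedom for the session term).
Negative estimates are reported as computed rather than truncated at zero;
truncation would bias averages of estimates and hide degenerate designs.
The implementation is cross-checked in the tests against both a brute-force
sums-of-squares oracle and `pingouin.intraclass_corr`.

Phenotype preprocessing mirrors common practice for linear models: targets
whose sample skewness exceeds 1 (configurable, or forced) are natural-log
transformed — a strictly per-participant operation, so no information leaks
across participants — and participants more than 3 SD from the sample mean
are removed in one non-iterative pass before prediction.

## Prediction pipeline

Ridge regression inside a nested cross-validation: 10 outer folds × 5
repeats (default), or, for cohorts with related participants, 5 repeated
leave-30%-of-families-out splits in which family members never straddle a
fold boundary. Per outer fold:

1. features are z-scored column-wise with training-fold statistics
   (zero-variance columns get SD 1: no information, no crash);
2. confounds, if any, are regressed out of every feature with betas fit on
   training rows only and applied to the held-out rows;
3. the ridge penalty α is chosen on the training fold by *exact* closed-form
   leave-one-out CV: with the thin SVD of the centred design, the LOO
   residual of observation i is (yᵢ−ŷᵢ)/(1−hᵢᵢ), reproducing n refits at
   the cost of one decomposition. The decomposition itself runs through
   `eigh` on the smaller Gram matrix (≈2× faster than LAPACK SVD at these
   shapes, identical results to ~1e−12);
4. the fitted model predicts the held-out fold; R² (the coefficient of
   determination, 1 − SS_res/SS_tot — negative values possible and
   meaningful), MAE and Pearson r are recorded per fold and averaged over
   folds × repeats. Pooled-prediction R² is not the default.

The α grid is 17 log-spaced values 10⁻³…10⁵ (configurable). Exact ties in
LOO MSE break toward the larger α. Under a pure-noise target the criterion
drives α into the top of the grid in ≈all seeds, though not always to the
single largest grid point — roughly 40% of noise datasets have a shallow
interior LOO minimum, which is a property of cross-validation noise, not a
defect of the shortcut.

Row-wise (within-participant) z-scoring of the whole feature matrix is
applied before splitting by default; being row-local it cannot leak
information across participants.

A linear-kernel SVR control path replaces steps 3–4 with
C = 1 / mean_i √(G[i,i]), G = XXᵀ (inverse mean row norm), non-nested.

## Synthetic cohorts

Each participant has a latent trait s ~ N(0,1). Behavioural sessions follow
the classical true-score model y⁽ᵏ⁾ = √ICC·s + √(1−ICC)·e⁽ᵏ⁾ with unit
normal errors, so the population ICC(2,1) of the sessions equals the
requested `target_icc` exactly; optional confound effects (age-like normal,
sex-like Bernoulli, weights on standardised values) are added, and an
optional right-skew transform exp(c·y/σ(y)) with c = 0.5513 produces sample
skewness ≈ 2 — chosen so the natural-log preprocessing inverts it exactly
(up to an affine map). Family sizes are 1 + Poisson(mean−1), assigned in
blocks.

Features emulate Fisher-z connectivity edge vectors at configurable parcel
count p, with m = p(p−1)/2 edges. Ten percent of edges (the "informative
network") carry the signal γ·s; γ is set in closed form so that the
population correlation between the best linear read-out (the informative-
edge sum) and s equals `effect_r`, and this calibration is verified by
Monte Carlo in the tests.

The edge noise is structured, not i.i.d.:

- non-informative edges draw 30% of their variance from 30 shared
  "network" factors (block equicorrelation) and 70% i.i.d.;
- informative edges share one common factor carrying 20% of their noise
  variance, so the informative network coheres and the predictive signal
  rides a dominant direction of the feature covariance.

Both choices mirror real connectivity data, where a modest number of
network-level components carries a large share of edge variance and
predictive signal concentrates on dominant components. They matter
quantitatively: with fully i.i.d. edge noise the signal direction of a
moderately predictable phenotype sits inside the Marchenko–Pastur bulk at
the sample sizes studied here (n in the hundreds, p ≈ 500), making ridge
attenuation far steeper than observed attenuation rates in empirical
cohorts; the factor structure reproduces the empirically observed regime in
which strongly predicted targets attenuate nearly in proportion to
reliability while weakly predicted targets sit near the estimability
threshold and lose extra accuracy to training noise. What the generator
does *not* model: parcel-geometry (spatial) autocorrelation, haemodynamics,
motion artefacts, non-Gaussian edge distributions, and site effects — so
passing tests certify the statistical mechanics of
reliability-vs-prediction, not fidelity to any particular scanner or
cohort.

Optionally, parcel × time series can be generated per participant from a
covariance Σᵢ = 0.7·Rᵢ + 0.3·I, where Rᵢ has a base off-diagonal 0.05 and an
informative-edge strength increasing in s through a sigmoid; the convex
shrinkage toward the identity guarantees positive-definiteness by
construction, and the Pearson-edge extractor recovers a monotone
trait-connectivity relation.

## Experiments

- **Attenuation**: one highly reliable phenotype; surrogates at the 11-level
  grid (0.99…0.5) or the 5-level grid (0.9…0.5); each surrogate is
  outlier-trimmed and predicted; mean R² is summarised in reliability bands
  of width 0.2 anchored at 1.0 (band edges belong to the higher band), with
  the percent drop between consecutive bands and their mean. Whether "mean
  drop" averages over bands, phenotypes or repeats is a genuine ambiguity;
  the band-pair mean is adopted here.
- **Reliability vs accuracy**: a battery of phenotypes with ICCs spread over
  a range, each in its own cohort; ICC(2,1) estimated on a retest subsample,
  R² from the full sample; Pearson correlation of ICC with R², two-tailed
  t-test with df = k−2, Fisher-z 95% CI, no multiple-comparison correction.
  Variants use the ICC confidence bounds or restrict to positive R².
- **Reliability × sample size**: fixed-test-set learning curves (10% test
  fraction) over geometrically spaced training sizes — floor of the
  geometric progression with exact endpoints; the canonical series from 250
  to 4450 in 7 steps is (250, 403, 652, 1054, 1704, 2753, 4450). Within a
  repetition, smaller training subsets are nested inside larger ones, which
  matches fixed-test-set learning-curve semantics and lowers variance.

Where a target clean-signal accuracy is required (e.g. a cohort whose
clean-target CV R² should be ≈0.23), `calibrate_effect_to_clean_r2` measures
CV R² at two probe effect sizes on the same cohort seed and inverts the
(nearly affine) relation between CV R² and effect_r² — two pipeline runs,
no iteration.

Problem sizes in the shipped tests and in `scripts/acceptance.py` (n = 550
and 650 participants, 32 parcels / 496 edges, 20–50 surrogate repeats per
level) were chosen so the full suites complete comfortably on a single CPU
while keeping Monte-Carlo error inside the stated tolerances.

## Known limitations

- The adjusted-reliability formula ρ²·ICC is a classical-test-theory
  interpretation; other corrections (e.g. using retest correlations
  directly) would shift the reliability axis but not the qualitative
  attenuation pattern.
- ICC confidence intervals assume normal errors; coverage is verified by
  simulation at the design points used, not in general.
- The SVR path exists as an algorithmic control, not a tuned competitor.
- Learning curves are reported as measured; no parametric extrapolation is
  fitted.
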