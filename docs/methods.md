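# Methods

## The problem

In relapsing and progressive multiple sclerosis, cognition is assessed at
irregular clinic visits with a battery of standardized tests, normalized to
z-scores against population norms. Two questions drive the package: how do
global cognition and its domains (verbal memory, visual memory,
attention/information-processing speed, semantic fluency) change over the
disease course, and which baseline demographic, clinical and MRI measures
predict who will be cognitively impaired at the latest follow-up. Since no
patient-level data ship with the package, a simulator generates cohorts with
the full statistical structure both analyses assume, including every latent
parameter, so recovery can be verified exactly.

## Impairment scoring

A test is *failed* when its z-score lies strictly below −1.5 (the boundary
value −1.5 itself is not a failure; the threshold is configurable). A domain
is impaired when at least one of its tests is failed; global impairment
requires at least two failed tests, counted across all domains, so two
failures within one domain suffice. Fixture panels use two tests per domain;
the rules are driven by an explicit test-to-domain map and work for any
battery composition.

## Trajectory model

For outcome z (one of the five z-scores) at time t years since disease
onset:

    z_ij = β0 + Σ_k β_k B_k(t_ij) + γ' w_i + u_i (+ v_i t_ij) + ε_ij

with truncated-power basis B(t) = (t, (t−5)+, (t−15)+), covariates w =
(centred age at onset, education level 1–4 coded ordinally, female
indicator), random intercept u_i ~ N(0, τ²), optional random slope v_i, and
residual ε ~ N(0, σ²). The spline mean is continuous at the knots for any
coefficients. Reported quantities are per-period slopes, the cumulative sums
of the basis coefficients, with standard errors by the delta method on the
linear contrasts and Wald z CIs/p-values (the inferential method is a
package choice; likelihood-ratio or Satterthwaite alternatives would differ
little at cohort sizes of ~200 subjects).

Estimation uses statsmodels `MixedLM`. REML is the default for reported
fits; knot selection refits every candidate by ML so AIC values are
comparable across fixed-effect structures, with AIC = 2k − 2·logLik counting
fixed effects, random-effect (co)variances and the residual variance.
Candidates that fail to converge are flagged and excluded rather than
aborting the comparison; exact ties go to the first candidate and are
reported. Noise-free data make the profiled likelihood singular; the fit
then falls back to OLS, the mixed-model limit with all variance components
at zero, flagged as singular.

Subjects whose visits all share one timestamp are rejected at validation —
a trajectory cannot be identified from them.

## Batch harmonization

Regional volumes acquired under two protocols are harmonized with a
parametric empirical-Bayes location/scale adjustment (the canonical ComBat
formulation): standardize each feature on a covariate regression (age and
sex protected by default) with a pooled variance; estimate per-batch,
per-feature locations and scales; shrink them across features via a normal
prior on locations and an inverse-gamma prior on scales, iterating the
conditional updates to 1e-6 (max 500 iterations); adjust and back-transform.
The implementation matches R `sva::ComBat` to 1e-13 on shared fixtures (a
cross-check test runs `Rscript` when available). With a single feature, or
zero across-feature variance, no prior can be estimated and the direct
per-batch estimates are used unchanged.

Two behaviours of the canonical estimator are worth knowing. First, EB
shrinkage treats a batch effect confined to one feature among many null ones
partly as noise, so such an offset is only partially removed; a
protocol-wide offset (what the simulator generates, and what scanner
differences produce in practice) is pooled into the prior mean and removed
essentially completely. The `eb=False` mode applies the raw moment estimates
and removes any per-feature offset exactly. Second, the adjustment is noisy
at small n: the location estimates carry sampling error of order
1/√(batch size), so the null-data round trip approaches identity only as
batches grow (max absolute deviation ≈0.1 SD at 250 per batch, <0.05 SD at
2000 per batch). Tests are sized accordingly.

In the pipeline, harmonization is fitted on the full baseline sample before
prediction modelling, mirroring the usual preprocessing order; it requires
complete feature values, which the pipeline guarantees by confining default
missingness to clinical columns (MRI-derived features exist for every
included subject, and age/sex — the protected covariates — are never
missing in practice).

## Impairment-prediction ensemble

Baseline predictors (~85: sex, age, education, disease duration, disease
type, EDSS, DMT use, relapse count, lesion volume, 76 regional volumes) feed
L1-penalized logistic models of each binary impairment label. Disease type
is coded ordinally by clinical severity CIS < RRMS < SPMS < PPMS (one-hot
coding is available); education is ordinal 1–4.

For each of `n_imputations` (default 200) stochastic imputations and each of
`n_folds` (default 10) stratified outer folds, all fitted on the training
part only and applied to the held-out fold:

- **Imputation**: each incomplete column is regressed on the remaining
  columns (mean-completed) over its observed training rows; missing cells
  are drawn from the fitted conditional — normal with fitted mean and
  residual SD for continuous columns, multinomial-logistic category
  probabilities for categorical ones. Observed cells are never altered. The
  per-fold model fit is deterministic, so it is computed once per fold and
  reused across imputations (only the draws differ).
- **Age residualization**: the 76 volumes are replaced by their residuals
  from per-feature regressions on age; age itself stays in the predictor
  set.
- **Lasso**: features are z-scored on training statistics; the penalty is
  chosen on an adaptive 12-point path spanning 1.5 decades above the
  smallest penalty admitting any feature, by 5-fold inner CV minimizing
  held-out binomial deviance with the one-standard-error rule (the sparsest
  model within one SE of the minimum). The 1-SE rule, rather than the CV
  minimum, is deliberate: at these n/p ratios the CV minimum keeps dozens of
  chance-correlated features in every model, destroying the interpretability
  of selection rates. Coefficients are reported on the standardized scale.

Outputs: per-feature selection frequency and percentage over all
`n_imputations × n_folds` models; the representative model, maximizing mean
Dice overlap `2|A∩B|/(|A|+|B|)` of its support with all other supports (two
empty supports count as identical, Dice 1; ties go to the earliest model);
and pooled out-of-fold predictions — each subject's mean predicted
probability across imputations — thresholded at 0.5 and summarized as
sensitivity, specificity, PPV, NPV (Wilson 95% CIs) and balanced accuracy
(their arithmetic mean). Metrics with empty denominators are reported as
undefined, never as zero.

One caveat is inherent to finite cohorts: a null feature whose in-cohort
chance correlation with the label is large (the expected maximum over ~80
nulls at n=400 is |r|≈0.15) genuinely improves held-out-fold prediction
within that cohort and will be selected by any deviance-based rule in
essentially every model. Selection rates therefore separate truth from noise
up to ties at the top, not strictly, in a minority of cohorts.

## Synthetic cohorts

Defaults emulate a single-centre MS cohort of 212 subjects: 68% female, age
41 ± 9.5 (18–65), education levels with probabilities (0.08, 0.40, 0.35,
0.17), disease duration log-normal with median 8.2 years clipped to 0.1–29,
disease types (CIS, RRMS, SPMS, PPMS) with probabilities (0.09, 0.83, 0.06,
0.02), EDSS a half-point-rounded gamma with median ≈2, 52% on
disease-modifying therapy, relapse count Poisson(3), lesion volume
log-normal with median 5.16 cm³, and 76 regional volumes as independent
Gaussians (mean 10, SD 1 in normalized units) — region-to-region covariance
is deliberately not modelled. Visits: 2–5 per subject, the first at the
baseline disease duration, later ones at uniform gaps scaled to a total
follow-up drawn from 0.9–7.9 years.

Longitudinal outcomes follow the spline mean with knots (5, 15) and
per-period slopes per outcome — global cognition (0.080, −0.029, −0.031)
z/year, verbal memory (0.083, −0.041, −0.055), visual memory (0, −0.041, 0),
attention-IPS (0.107, 0, −0.035), fluency (0, 0, 0) — plus small covariate
effects, a random intercept (SD 0.55), optional random slope (SD 0.02),
and residual noise (SD 0.35). These magnitudes sit in the range reported
for MS cognition studies; with them, a 212-subject cohort yields CI coverage
near nominal and the (+, −, −) sign pattern in most replicates.

Impairment labels are drawn once per subject from sparse logistic models on
standardized baseline features (education, EDSS, lesion volume and limbic /
cingulate volumes with log-odds of magnitude 0.4–0.8 per SD by default),
with the intercept solved numerically so the expected prevalence matches the
targets (36/27/24/18/20% for global and the four domains). The per-test
score panel is constructed to reproduce the latent domain labels exactly;
the scored global label is then the honest application of the ≥2-failures
rule to that panel, which can disagree with the latent global label in rare
configurations (e.g. two singly-impaired domains and latent global 0), so
scored prevalences can deviate slightly from the targets.

Missingness is MCAR at a configurable rate (default 5%), never touching
subject identifiers or batch labels, and in the pipeline confined to
clinical columns (see harmonization above). Protocol B volumes are shifted
(+0.25) and variance-scaled (×1.2) about their batch mean.

What the simulator does *not* emulate: correlated regional atrophy patterns,
informative (MNAR) missingness, practice effects and alternate test forms,
visit-frequency dependence on disease severity, and any coupling between
the trajectory noise and the impairment labels. Passing tests therefore
demonstrate correct recovery of the assumed generative structure, not
robustness to these real-data features.

## Problem sizes and numerical choices

Test and demonstration runs use scaled problem sizes chosen to exercise the
statistics they check: 100 replicates at the 212-subject cohort scale for CI
coverage; 50 replicates at 1000 subjects for AIC knot selection (knot
discrimination needs large n; at 500 subjects the 5-vs-8-year contrast is
frequently won by neighbouring candidates); 20 seeded runs of a reduced
20-imputation × 10-fold ensemble at n=400 for support recovery; 4000
subjects for harmonization round trips. The acceptance script runs a
10 × 10 ensemble. Seeds are explicit everywhere; liblinear and fold
assignment are seeded, so every result is bit-reproducible given the seed.

Other numerical choices: the logistic-intercept calibration solves by Brent
bracketing on ±40 log-odds; lasso coefficients below 1e-12 count as zero;
penalty ties in the inner CV go to the sparser model; zero-variance features
standardize to zero rather than dividing by zero; Wilson intervals come from
statsmodels `proportion_confint`.

## Known limitations

- The trajectory model assumes Gaussian residuals and linear-within-period
  means; floor effects of severely impaired patients are not modelled.
- Harmonization assumes the batch effect is location/scale within feature;
  nonparametric and longitudinal ComBat variants are out of scope.
- The imputer regresses on mean-completed covariates (a single-pass
  approximation to chained equations) and is not intended for high
  missingness rates.
- Rubin's-rules pooled inference over imputations is not implemented; the
  ensemble pools predictions, not coefficient uncertainty.
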