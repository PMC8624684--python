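# mscog

Cognitive trajectories and impairment prediction in multiple sclerosis (MS),
built as a tested, simulation-driven pipeline over tabular cohort data.

Cognitive impairment affects 40–70% of people with MS, yet how it evolves
over decades of disease, and which baseline clinical and MRI measures
foreshadow it, are hard questions: cohorts are assessed at irregular visits,
impairment is a thresholded composite of many tests, and MRI features carry
scanner-protocol artefacts. `mscog` implements the two analytic engines such
a study needs, plus everything around them:

1. **Trajectory modelling.** Mixed-effects linear-spline models of cognitive
   z-scores over disease duration. With knots at 5 and 15 years the disease
   course splits into three periods, and the model reports one slope
   (z-score/year) per period,

   `z_ij = β0 + β1 t_ij + β2 (t_ij − 5)+ + β3 (t_ij − 15)+ + γ'w_i + u_i + ε_ij`,

   with subject random intercept `u_i` (optionally a random slope), covariates
   `w_i` (age at onset, education, sex), and per-period slopes
   `(s1, s2, s3) = (β1, β1+β2, β1+β2+β3)` with delta-method CIs. Knot placement
   is compared by AIC under ML fitting.

2. **Impairment prediction.** A multiple-imputation × cross-validation
   logistic-Lasso ensemble: for each stochastic imputation of missing baseline
   entries and each stratified outer fold, an imputer, an age-residualizer for
   the 76 regional brain volumes, a standardizer and an L1-penalized logistic
   model (penalty by inner CV with the one-standard-error rule) are fitted on
   the training part only. The ensemble reports per-feature selection rates,
   a representative model (highest mean Dice overlap of predictor supports),
   and pooled out-of-fold sensitivity/specificity/PPV/NPV/balanced accuracy
   with Wilson 95% CIs.

Supporting modules: impairment scoring rules (a test is failed at z < −1.5;
a domain is impaired by ≥1 failure; global impairment needs ≥2 failed tests),
ComBat-style empirical-Bayes batch harmonization of MRI volumes (validated
against R `sva::ComBat` to 1e-13), and a synthetic-cohort simulator with full
ground truth (piecewise-linear trajectories, random effects, sparse logistic
impairment models, MCAR missingness, two acquisition protocols).

## Worked example

```python
from mscog import SimulationConfig, simulate_dataset, score_panel, fit_mixed_spline
from mscog import EnsembleConfig, ImpairmentLassoEnsemble

data = simulate_dataset(SimulationConfig(n_subjects=212, seed=9))
labels = score_panel(data["test_scores"])

fit = fit_mixed_spline(data["visits"], data["baseline"], "z_global")
print(fit.period_slopes.round(4))

result = ImpairmentLassoEnsemble(
    data["baseline"], labels, "ci_global",
    EnsembleConfig(n_folds=10, n_imputations=5, seed=1),
).fit()
print(result.performance().summary())
```

prints (numbers from this exact run):

```
         slope      se  ci_low  ci_high  p_value
period
0-5 y   0.0628  0.0280  0.0080   0.1177   0.0248
5-15 y -0.0252  0.0082 -0.0413  -0.0092   0.0021
>15 y  -0.0255  0.0106 -0.0464  -0.0047   0.0164

n = 212  (TP 59, FP 33, FN 45, TN 75)
Balanced accuracy   63.1%
Sensitivity         56.7% (95% CI 47.1-65.8)
Specificity         69.4% (95% CI 60.2-77.3)
PPV                 64.1% (95% CI 53.9-73.2)
NPV                 62.5% (95% CI 53.6-70.6)
```

The cohort was generated with period slopes (0.080, −0.029, −0.031)
z-score/year for global cognition: an early post-onset improvement followed
by steady decline. The fitted slopes recover that pattern within their CIs;
the prediction block shows the ensemble's pooled out-of-fold accuracy for
global impairment on this 212-subject cohort.

A command-line interface mirrors the stages
(`mscog simulate | score | harmonize | trajectory | predict | run-all | report`);
`mscog run-all --out run/ --seed 7` executes the whole pipeline and
`mscog report --run-dir run/` renders a Markdown summary.

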