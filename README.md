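# gfrtraj

Predicting individual kidney-function trajectories in type 2 diabetes with
chronic kidney disease (CKD), from routinely collected baseline data.

CKD progression is tracked by the estimated glomerular filtration rate
(eGFR, mL/min/1.73 m²). Rather than dichotomizing decline or estimating
per-patient slopes from sparse visits, `gfrtraj` models the whole sequence of
eGFR measurements — **including the baseline value as part of the outcome
vector** — with a linear mixed-effects model, and then personalizes
predictions for a new patient from a *single* baseline eGFR by
empirical-Bayes updating of their random intercept and slope. It is written
for biostatisticians and nephrology researchers who want a tested,
reproducible implementation of this modelling strategy, exercised end to end
on synthetic multi-country cohorts.

## Model

For visit *j* of subject *i* in country *c(i)*:

```
y_ij = x_i'β + β_t·t_ij + (x_i·t_ij)'γ + u_c(i) + b0_i + b1_i·t_ij + ε_ij

u_c ~ N(0, τ²),   (b0_i, b1_i) ~ N(0, G) (unstructured 2×2),   ε_ij ~ N(0, σ²)
```

* `x_i`: 12 baseline predictors — age, sex, BMI, ever-smoking, HbA1c,
  hemoglobin, serum cholesterol, mean arterial pressure, log₂(UACR), and
  glucose-/blood-pressure-/lipid-lowering medication — each with a main
  effect and a time interaction (26 fixed effects with intercept and time).
* Individual random intercepts are nested within countries via the
  country-level random intercept `u_c`, which absorbs between-country eGFR
  level differences (e.g. creatinine assay offsets).
* Estimation is profiled REML (ML optional) with `G` parameterized through
  its Cholesky factor; the fit matches reference mixed-model software to
  ~1e-10 in log-likelihood on test fixtures.

For a new patient, Gaussian conditioning on the single baseline eGFR gives
the posterior of `(b0, b1)`; the trajectory derivative `β_t + x'γ + b1` then
yields an individual slope distribution, and
`P(slope < −3 mL/min/1.73 m²/yr) = Φ((−3 − mean)/sd)` is reported as the
probability of rapid progression. Validation is internal-external: leave one
country out, refit, update held-out subjects from baseline only, and score
predicted R², concordance (C statistic) and calibration slope per follow-up
year with cluster-bootstrap 95% CIs.

## Worked example

The `analysis/` scripts run the study end to end on synthetic data
(three countries, distinct eGFR levels and visit schedules):

```bash
python analysis/01_simulate_cohorts.py --seed 0   # simulate + inclusion filters
python analysis/02_fit_mixed_model.py             # REML fit + coefficients
python analysis/03_validate_loco.py               # leave-one-country-out
python analysis/04_risk_profiles.py               # per-patient risk
```

Output of the fitting step (seed 0):

```
Fitted 1450 subjects / 6734 visits (REML, loglik -24711.8)
Random effects: intercept SD 12.9, slope SD 2.02 (corr -0.27); country SD 18.5; residual SD 6.15
Marginal R2 0.080 | conditional R2 0.937
Largest standardized main effects: log2_uacr (-3.64), age (-3.06), hemoglobin (+2.45)
```

The between-subject intercept SD (12.9) and slope SD (2.0 per year) dominate
the fixed effects, which is why the conditional R² (0.937, random effects
included) towers over the marginal R² (0.080): most predictable variation is
individual, and is exactly what baseline-eGFR updating recovers. The risk
step shows what that buys:

```
country_B-00120: baseline 76 -> year-5 prediction 71.6; slope -1.21 +/- 1.96; P(rapid) = 0.181
Follow-up RMSE across 5284 visits: 10.58 with updating vs 14.53 without (27% lower)
```

Each patient gets a five-year predicted trajectory with predictive
intervals, an annual-slope distribution (here −1.21 ± 1.96 mL/min/1.73 m²/yr)
and the probability that their decline is steeper than −3 (here 0.181).

A `gfrtraj` CLI wraps the same steps (`simulate`, `fit`, `predict`,
`validate`, `run-all`); see `gfrtraj --help`.

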