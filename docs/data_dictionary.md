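# Data dictionary

## baseline.csv — one row per subject

| column | unit / coding | description |
|---|---|---|
| subject_id | string | unique subject identifier |
| country | string | cohort/country label |
| age | years | age at baseline (18–75) |
| sex | 0 female / 1 male | sex |
| bmi | kg/m² | body mass index |
| smoking_ever | 0/1 | ever smoked |
| hba1c | mmol/mol | hemoglobin A1c |
| hemoglobin | g/dL | blood hemoglobin |
| cholesterol | mg/dL | serum cholesterol |
| map | mm Hg | mean arterial pressure |
| uacr | mg/g | urinary albumin-creatinine ratio (> 0) |
| log2_uacr | log₂(mg/g) | log₂-transformed UACR (derived if absent) |
| med_glucose | 0/1 | glucose-lowering medication |
| med_bp | 0/1 | blood-pressure-lowering medication |
| med_lipid | 0/1 | lipid-lowering medication |
| baseline_egfr | mL/min/1.73 m² | eGFR at the baseline visit (derived from visits.csv at t=0 if absent) |

## visits.csv — long format, one row per eGFR measurement

| column | unit | description |
|---|---|---|
| subject_id | string | must exist in baseline.csv |
| country | string | cohort/country label |
| time_years | years ≥ 0 | time since baseline; every subject has a row at 0 |
| egfr | mL/min/1.73 m² | measured eGFR (CKD-EPI 2021) |

Duplicate (subject_id, time_years) pairs are rejected.

## truth.csv — simulation ground truth (never consumed by fitting code)

| column | description |
|---|---|
| country_effect | realized country intercept u_c (eGFR units) |
| b0, b1 | realized individual random intercept (eGFR) and slope (eGFR/yr) |
| fixed_intercept, fixed_slope | x'β and β_t + x'γ for the subject |
| true_slope | fixed_slope + b1 |

## model.json — persisted fit (schema_version 1)

Fixed-effect names and values (column order: intercept, 12 predictors, time,
12 predictor:time products), their covariance, G (2×2), tau2, sigma2,
posterior country effects, training covariate SDs, log-likelihood,
convergence flag, and the model spec. Loading a file with a different
schema_version fails loudly.

## report.json — validation report

One record per follow-up year: n_pairs, r2, c_statistic, calibration_slope,
each with percentile-bootstrap `_lo`/`_hi` 95% bounds (missing cells are
null, not zero); plus per-split fit summaries, n_boot and seed.
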