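# Methods

## The model

Repeated eGFR measurements are modelled jointly — baseline and follow-up
values alike — by a linear mixed-effects model:

    y_ij = x_i'β + β_t t_ij + (x_i t_ij)'γ + u_c(i) + b0_i + b1_i t_ij + ε_ij

with country random intercepts u_c ~ N(0, τ²), individual random intercepts
and slopes (b0, b1) ~ N(0, G) with unstructured 2×2 covariance, and residual
noise ε ~ N(0, σ²). Putting baseline eGFR in the outcome vector (rather than
using it as a covariate) lets the model treat baseline and follow-up values
as equally noisy realizations of the same latent trajectory, which is what
makes principled single-measurement updating possible later.

Assumptions worth stating plainly: trajectories are linear in time at the
individual level; residuals are homoscedastic Gaussian and independent
across visits; covariate effects are linear and constant over countries;
dropout is unrelated to the trajectory.

## Estimation

The (restricted) likelihood is maximized over four unconstrained parameters:
the Cholesky factor of G/σ² (three entries, so G is positive semi-definite by
construction) and √(τ²/σ²). β and σ² are profiled out exactly. The
per-country marginal covariance is never formed densely: per-subject 2×2
Woodbury identities plus a rank-one update for the country intercept give
criterion evaluations costing O(subjects), so a 3000-subject fit takes
seconds. Optimization is L-BFGS-B followed by a Nelder-Mead polish
(xatol 1e-8, fatol 1e-11, one perturbed restart on failure; `converged=False`
is reported rather than raising). The REML log-likelihood includes all
constants of the (n−p)-dimensional contrast likelihood, so values are
directly comparable with standard mixed-model software; tests pin agreement
to ~1e-10 on fixtures. With a single country τ² is fixed at 0 with a
warning. Rank-deficient designs fail loudly, naming the suspect columns
found by pivoted QR.

REML is the default (ML is available for likelihood-ratio work). Predictors
enter untransformed except UACR, which is log₂-transformed; standardization
is reporting-only (continuous terms scaled by the training-sample SD, binary
terms left raw), so the fitted model is invariant to it.

## Updating from a single baseline eGFR

For a new subject with baseline value y₀ and fixed-effect level a = x'β̂
(+ country effect û if their country was in the training data), the residual
r = y₀ − a − û updates the random effects by Gaussian conditioning with
z = (1, 0):

    mean = G z r / (G₀₀ + s²),   cov = G − G z z'G / (G₀₀ + s²),   s² = σ̂²

**Unseen countries.** When the subject's country was not in the training
data, the unknown country effect u is *part of what must be predicted
forward*: u persists at that subject's follow-up visits exactly like b0
does. The update therefore conditions on (u + b0, b1), i.e. τ̂² is added to
the prior intercept variance G₀₀ rather than to the observation noise s².
Treating u as transient noise instead would shrink the baseline residual by
G₀₀/(G₀₀+σ²+τ²) rather than (G₀₀+τ²)/(G₀₀+σ²+τ²), systematically
under-attributing it and producing observed-on-predicted calibration slopes
above 1 on held-out countries; the joint-conditioning form keeps
leave-one-country-out predictions calibrated, which is also the behaviour
one wants from an externally deployed model.

Only the baseline measurement updates the posterior — follow-up values are
never fed back (no dynamic updating). Predictive variance at time t is
(1,t) cov (1,t)' + σ̂²; the fixed-effect estimation term x(t)'V̂(β̂)x(t) is
available behind an opt-in flag and excluded by default, since it is
negligible at training sizes of interest and its inclusion convention is a
deployment choice.

## Slope distribution and rapid-progression risk

The trajectory is linear in t, so its derivative is β̂_t + x'γ̂ + b1. With the
posterior of b1 this gives a normal slope distribution; default variance is
the posterior random-slope variance (same opt-in flag adds fixed-effect
uncertainty). The probability of rapid progression is the CDF at the
threshold, Φ((−3 − mean)/sd), degenerating to an indicator when sd = 0. The
−3 mL/min/1.73 m²/yr threshold is a conventional boundary between stable and
rapid decline and is a parameter everywhere it appears.

## Validation design

Internal-external validation holds out each country in turn (countries are
nonrandom, structurally distinct units), refits, updates every held-out
subject from baseline only, and predicts all follow-up visits. Visits are
bucketed into follow-up years by t ∈ (y−0.5, y+0.5]; baseline is excluded.
Held-out pairs are pooled across splits before computing, per year:

* predicted R² = 1 − SSE/SST (can be negative);
* C statistic: concordance probability across subject pairs with different
  observed values, prediction ties credited 0.5 — computed by exhaustive
  enumeration up to 400 pairs and via Kendall's τ-b above that (identical to
  enumeration to 1e-10 in tests; invariant to monotone transforms);
* calibration slope: OLS slope of observed on predicted.

Degenerate cells (no pairs, zero variance) are reported as missing, never
as zero.

**Bootstrap.** CIs are percentile, 95%, resampling subjects as whole
clusters so within-subject correlation across years is respected. For the
pooled leave-one-country-out report the bootstrap is two-stage — countries
with replacement, then subjects within each drawn country — because the
pooled estimate varies with the few realized country effects as well as with
subjects; a subject-only bootstrap demonstrably undercovers there (its CIs
miss the known truth about half the time on well-specified simulations,
since even the true-parameter predictor shows ±2–3% pooled calibration-slope
excursions driven purely by the three realized country draws). External
validation of a single cohort keeps the subject-level bootstrap: with one
cohort there is no country-level replication to resample. B defaults to 1000
(analysis scripts use 200 to keep runs short).

## The synthetic cohort generator

Because the development and validation cohorts of interest are not public,
the generator emulates their structure: three countries with distinct
baseline eGFR levels (means calibrated to 52.4 / 89.6 / 81.2 mL/min/1.73 m²)
and distinct schedules (biennial; yearly; no year-1 visit), ~5 years of
follow-up, covariates drawn from marginals typical of European diabetic-CKD
cohorts (age truncated-normal 63.5 ± 9.1 within 18–75; UACR log₂-normal
4.0 ± 2.5; binary prevalences 0.5–0.9), Gaussian visit-time jitter
(SD 0.1 yr, a free default — real visit irregularity statistics are not
published), and per-visit missed-completely-at-random dropout (default
0.10). Inclusion filters mirror the study criteria: ≥3 eGFR readings, ≥2
years of follow-up, baseline eGFR ≥ 30.

Generating parameters (natural units): G = [[180, −8], [−8, 4]] (intercept
SD 13.4 eGFR, slope SD 2 eGFR/yr, correlation −0.30), σ² = 36 (within-person
noise SD 6), and a mean slope of −1.45 eGFR/yr — values a practitioner would
call representative of moderate diabetic CKD. Two presets exist:
`three_cohort_config` uses fixed country offsets (τ²=0) so the per-country means
are calibrated exactly, and is the demo/default; `well_specified_config`
draws u_c ~ N(0, 25) with no offsets, making the fitted model exactly
correctly specified — recovery, calibration and risk studies use it, because
fixed offsets would confound intercept recovery. Offset calibration refers
to the generated population; the eGFR ≥ 30 filter raises the low-eGFR
cohort's *included* mean by ~2 units. A truth table records each subject's
realized (u, b0, b1) and true slope for recovery tests; fitting code never
reads it. The CKD-EPI 2021 race-free creatinine equation (and its closed-form
inverse) lets the simulator emit serum creatinine consistent with each eGFR.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: correlated covariates, informative dropout,
nonlinear or treatment-modified trajectories, assay drift over time, and
heavy-tailed eGFR noise. Tests on this generator verify the estimator and
the validation machinery, not clinical transportability.

## Problem sizes and numerical conventions

The test suite exercises recovery at ~2000 subjects × 3 countries × yearly
visits (with the bias check averaged over four replicate cohorts at fixed
seeds, so a real bias of two standard errors still fails while the
multiplicity of 26 simultaneous coefficient checks does not dominate),
leave-one-country-out at 3000 subjects with B=200, and risk calibration on
~2100 fresh subjects; the analysis scripts default to 500 subjects per
country. Ties in the C statistic get half credit; year buckets use the
half-open convention above; posterior updates guard G₀₀ + s² = 0 by
returning the prior; probabilities are reported to 3 decimals; predictions
beyond the 5-year horizon are produced but flagged as extrapolation (the
training follow-up does not support more).

## Known limitations

Country effects are exchangeable random intercepts — systematic assay
differences are absorbed but not modelled; with 3 countries τ̂² is weakly
identified, which widens (correctly) unseen-country predictions. The model
carries no treatment dynamics (medication status is frozen at baseline), no
survival endpoints, and assumes linear individual trajectories over the
5-year horizon. The slope-variance convention excludes fixed-effect
uncertainty by default; both variants are implemented.
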