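"""Individualized prediction: empirical-Bayes updating from baseline eGFR.

A new individual contributes a single eGFR measurement (at baseline, t=0).
Conditioning the population model on that one value yields the posterior
(BLUP) distribution of the individual's random intercept and slope, which in
turn gives personalized trajectory predictions, an individual slope
distribution, and the probability that the individual is a rapid progressor
(annual eGFR decline steeper than -3 mL/min/1.73 m2 per year).

Repeated follow-up measurements are deliberately not used for updating: only
the first available (baseline) eGFR enters the posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import FittedModel

#: Annual eGFR change separating stable from rapid progression (mL/min/1.73 m2/yr).
RAPID_PROGRESSION_THRESHOLD = -3.0

#: Prediction horizon (years) beyond which predictions are flagged as
#: extrapolation.
DEFAULT_HORIZON = 5.0


@dataclass
class PosteriorEffects:
    """Conditional N(mean, cov) of (b0, b1) given the baseline eGFR."""

    mean: np.ndarray  # (2,) eGFR, eGFR/yr
    cov: np.ndarray  # (2, 2)
    country_effect: float
    country_known: bool


@dataclass
class SlopeDistribution:
    """Normal distribution of an individual's annual eGFR slope."""

    mean: float  # eGFR/yr
    sd: float
    fixed_part: float  # beta_t + x' gamma
    random_part: float  # posterior mean of b1


def posterior_from_residual(
    G: np.ndarray, s2: float, residual: float
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian conditioning of (b0, b1) ~ N(0, G) on y0 = b0 + e,
    e ~ N(0, s2), observed residual ``y0 - fixed part``.

    Returns (mean, cov): mean = G z r / (z'Gz + s2), cov = G - G z z' G /
    (z'Gz + s2) with z = (1, 0).  If both G[0,0] and s2 are zero the baseline
    carries no signal and the prior is returned unchanged.
    """
    G = np.asarray(G, dtype=float)
    gz = G[:, 0]
    denom = G[0, 0] + s2
    if denom <= 0:
        return np.zeros(2), G.copy()
    mean = gz * (residual / denom)
    cov = G - np.outer(gz, gz) / denom
    return mean, cov


def _subject_row(subject) -> pd.Series:
    if isinstance(subject, pd.DataFrame):
        if len(subject) != 1:
            raise ValueError("expected a single-row subject table")
        return subject.iloc[0]
    if isinstance(subject, dict):
        return pd.Series(subject)
    return subject


def fixed_components(model: FittedModel, subject) -> tuple[float, float]:
    """(level, slope) of the fixed part of the trajectory for one subject:
    level = intercept + x'beta, slope = beta_t + x'gamma."""
    row = _subject_row(subject)
    beta = model.beta
    level = float(beta["intercept"])
    slope = float(beta[model.spec.time_name])
    for p in model.predictors:
        x = float(row[p])
        level += float(beta[p]) * x
        key = f"{p}:{model.spec.time_name}"
        if key in beta.index:
            slope += float(beta[key]) * x
    return level, slope


def update_random_effects(model: FittedModel, subject) -> PosteriorEffects:
    """Posterior random effects of a new individual given baseline eGFR.

    For a country seen in training, the posterior mean country effect is
    subtracted from the baseline residual and the conditioning noise is the
    residual variance sigma2.  For an unseen country the unknown country
    effect u is absorbed into the intercept being predicted: the update
    conditions on (u + b0, b1) with prior covariance G + tau2 on the
    intercept entry, because u persists at this subject's follow-up visits
    just like b0 does.
    """
    row = _subject_row(subject)
    if "baseline_egfr" not in row or pd.isna(row["baseline_egfr"]):
        raise ValueError("subject must carry a baseline_egfr value")
    level, _ = fixed_components(model, row)
    country = row.get("country", None)
    known = country in model.country_effects.index
    u = float(model.country_effects.get(country, 0.0)) if known else 0.0
    if not known:
        warnings.warn(
            f"country {country!r} not seen in training: using zero country "
            "effect with widened intercept variance",
            UserWarning,
            stacklevel=2,
        )
    prior = np.asarray(model.G, dtype=float).copy()
    if not known:
        prior[0, 0] += model.tau2
    residual = float(row["baseline_egfr"]) - level - u
    mean, cov = posterior_from_residual(prior, model.sigma2, residual)
    return PosteriorEffects(mean=mean, cov=cov, country_effect=u, country_known=known)


def predict_trajectory(
    model: FittedModel,
    subject,
    posterior: PosteriorEffects,
    times,
    include_fixed_uncertainty: bool = False,
    horizon: float = DEFAULT_HORIZON,
) -> pd.DataFrame:
    """Point predictions and predictive SDs of eGFR at the given times.

    yhat(t) = fixed level + slope*t + country effect + posterior (b0 + b1 t);
    predictive variance = d'(t) cov d(t) + sigma2 with d(t) = (1, t) (for an
    unseen country the extra tau2 uncertainty is already inside cov),
    optionally plus the fixed-effect estimation term x(t)' beta_cov x(t).
    Times beyond ``horizon`` are predicted but flagged (with a warning) as
    extrapolation.
    """
    row = _subject_row(subject)
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("prediction times must be >= 0")
    extrapolated = t > horizon
    if extrapolated.any():
        warnings.warn(
            f"{int(extrapolated.sum())} prediction times beyond the {horizon}-year "
            "horizon: flagged as extrapolation",
            UserWarning,
            stacklevel=2,
        )
    level, slope = fixed_components(model, row)
    b0, b1 = posterior.mean
    pred = level + posterior.country_effect + b0 + (slope + b1) * t

    cov = posterior.cov
    var = cov[0, 0] + 2.0 * cov[0, 1] * t + cov[1, 1] * t * t + model.sigma2
    if include_fixed_uncertainty:
        x_const, x_slope = _design_vectors(model, row)
        for i, ti in enumerate(t):
            xt = x_const + ti * x_slope
            var[i] += float(xt @ model.beta_cov @ xt)
    return pd.DataFrame(
        {
            "time_years": t,
            "egfr_pred": pred,
            "pred_sd": np.sqrt(np.maximum(var, 0.0)),
            "extrapolated": extrapolated,
        }
    )


def _design_vectors(model: FittedModel, row) -> tuple[np.ndarray, np.ndarray]:
    """Split x(t) into time-constant and time-proportional design vectors."""
    cols = list(model.beta.index)
    x_const = np.zeros(len(cols))
    x_slope = np.zeros(len(cols))
    tname = model.spec.time_name
    for i, c in enumerate(cols):
        if c == "intercept":
            x_const[i] = 1.0
        elif c == tname:
            x_slope[i] = 1.0
        elif c.endswith(f":{tname}"):
            x_slope[i] = float(row[c.split(":")[0]])
        else:
            x_const[i] = float(row[c])
    return x_const, x_slope


def slope_distribution(
    model: FittedModel,
    subject,
    posterior: PosteriorEffects,
    include_fixed_uncertainty: bool = False,
) -> SlopeDistribution:
    """Distribution of the individual's annual eGFR slope: the derivative of
    the trajectory with respect to time, with baseline eGFR information
    already absorbed into the posterior.

    mean = beta_t + x'gamma + E[b1 | baseline]; variance defaults to the
    posterior random-slope variance, optionally adding the fixed-effect
    estimation variance of the time block.
    """
    row = _subject_row(subject)
    _, slope_fixed = fixed_components(model, row)
    mean = slope_fixed + float(posterior.mean[1])
    var = float(posterior.cov[1, 1])
    if include_fixed_uncertainty:
        _, x_slope = _design_vectors(model, row)
        var += float(x_slope @ model.beta_cov @ x_slope)
    return SlopeDistribution(
        mean=mean,
        sd=float(np.sqrt(max(var, 0.0))),
        fixed_part=slope_fixed,
        random_part=float(posterior.mean[1]),
    )


def prob_rapid_progression(
    slope: SlopeDistribution, threshold: float = RAPID_PROGRESSION_THRESHOLD
) -> float:
    """P(annual slope < threshold) under the slope's normal distribution.

    With zero SD this degenerates to the indicator of mean < threshold.
    """
    if slope.sd < 0:
        raise ValueError("slope sd must be >= 0")
    if slope.sd == 0:
        return float(slope.mean < threshold)
    return float(norm.cdf((threshold - slope.mean) / slope.sd))


def batch_predict(
    model: FittedModel,
    baselines: pd.DataFrame,
    visits: pd.DataFrame,
    update: bool = True,
) -> pd.DataFrame:
    """Vectorized trajectory predictions for every visit of many subjects.

    Returns one row per visit with ``observed``, ``predicted`` (posterior-
    updated from baseline eGFR) and ``predicted_no_update`` (fixed effects and
    country effect only).  Subjects are treated independently, so results do
    not depend on row order.
    """
    b = baselines.reset_index(drop=True)
    beta = model.beta
    P = b[list(model.predictors)].to_numpy(dtype=float)
    beta_mains = np.array([beta[p] for p in model.predictors])
    gammas = np.array(
        [beta.get(f"{p}:{model.spec.time_name}", 0.0) for p in model.predictors]
    )
    level = float(beta["intercept"]) + P @ beta_mains
    slope = float(beta[model.spec.time_name]) + P @ gammas

    known = b["country"].isin(model.country_effects.index).to_numpy()
    u = np.where(known, model.country_effects.reindex(b["country"]).fillna(0.0), 0.0)
    # unseen country: the country effect is part of the intercept being
    # predicted, so tau2 widens the prior intercept variance
    g00 = model.G[0, 0] + np.where(known, 0.0, model.tau2)

    if "baseline_egfr" in b.columns:
        y0 = b["baseline_egfr"].to_numpy(dtype=float)
    else:
        base = visits.loc[visits["time_years"] == 0.0].set_index("subject_id")["egfr"]
        y0 = base.reindex(b["subject_id"]).to_numpy(dtype=float)

    denom = g00 + model.sigma2
    r = y0 - level - u
    b0_hat = np.where(denom > 0, g00 * r / denom, 0.0)
    b1_hat = np.where(denom > 0, model.G[1, 0] * r / denom, 0.0)

    per_subject = pd.DataFrame(
        {
            "subject_id": b["subject_id"],
            "level": level + u,
            "slope": slope,
            "b0_hat": b0_hat,
            "b1_hat": b1_hat,
        }
    )
    merged = visits.merge(per_subject, on="subject_id", how="inner")
    t = merged["time_years"].to_numpy(dtype=float)
    no_update = merged["level"].to_numpy() + merged["slope"].to_numpy() * t
    updated = (
        merged["level"].to_numpy()
        + merged["b0_hat"].to_numpy()
        + (merged["slope"].to_numpy() + merged["b1_hat"].to_numpy()) * t
    )
    out = pd.DataFrame(
        {
            "subject_id": merged["subject_id"],
            "country": merged["country"],
            "time_years": t,
            "observed": merged["egfr"].to_numpy(dtype=float),
            "predicted": updated if update else no_update,
            "predicted_no_update": no_update,
        }
    )
    return out
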