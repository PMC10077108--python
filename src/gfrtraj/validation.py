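"""Internal-external (leave-one-country-out) and external validation.

Predictive performance is assessed per follow-up year on held-out subjects
whose random effects were updated from their single baseline eGFR:

* predicted R2 = 1 - SSE/SST against the held-out observations,
* C statistic = concordance probability that the ordering of two subjects'
  predictions matches the ordering of their observed values (prediction ties
  get half credit),
* calibration slope = OLS slope of observed on predicted (1 = neither over-
  nor under-dispersed predictions).

Confidence intervals come from a cluster bootstrap that resamples subjects
(not visits) so within-subject correlation across years is respected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NumericalError
from .model import DesignBundle, FittedModel, ModelSpec, build_design, fit_lmm, r2_nakagawa
from .prediction import batch_predict

DEFAULT_YEARS = (1, 2, 3, 4, 5)


def assign_year(times) -> np.ndarray:
    """Bucket visit times into integer follow-up years: a visit at time t
    belongs to year y when t is in (y-0.5, y+0.5].  Baseline (t <= 0.5)
    gets year 0 and is excluded from evaluation buckets."""
    t = np.asarray(times, dtype=float)
    return np.ceil(t - 0.5).astype(int)


def predicted_r2(observed, predicted) -> float:
    """1 - SSE/SST; may be negative for worse-than-mean predictions.
    Undefined (NaN) with fewer than 2 pairs or zero observed variance."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size < 2:
        return float("nan")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        return float("nan")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst


def _c_statistic_exact(obs: np.ndarray, pred: np.ndarray) -> float:
    do = np.sign(obs[:, None] - obs[None, :])
    dp = np.sign(pred[:, None] - pred[None, :])
    iu = np.triu_indices(obs.size, k=1)
    do, dp = do[iu], dp[iu]
    comparable = do != 0
    n_comp = int(comparable.sum())
    if n_comp == 0:
        return float("nan")
    agree = (do[comparable] * dp[comparable] > 0).sum()
    ties = (dp[comparable] == 0).sum()
    return float((agree + 0.5 * ties) / n_comp)


def _tie_pairs(x: np.ndarray) -> float:
    _, counts = np.unique(x, return_counts=True)
    return float(np.sum(counts * (counts - 1) / 2.0))


def _c_statistic_fast(obs: np.ndarray, pred: np.ndarray) -> float:
    """O(n log n) concordance via Kendall's tau-b: C = ((nc-nd)/comparable+1)/2
    where comparable excludes pairs tied on the observation."""
    n = obs.size
    n0 = n * (n - 1) / 2.0
    t_obs = _tie_pairs(obs)
    t_pred = _tie_pairs(pred)
    comparable = n0 - t_obs
    if comparable == 0:
        return float("nan")
    if n0 - t_pred == 0:  # all predictions tied: every pair gets half credit
        return 0.5
    tau = stats.kendalltau(obs, pred).statistic
    ncd = tau * math.sqrt((n0 - t_pred) * (n0 - t_obs))
    return float(0.5 * (ncd / comparable + 1.0))


def c_statistic(observed, predicted, method: str = "auto") -> float:
    """Concordance probability for a continuous outcome.

    Over all subject pairs with different observed values, the fraction whose
    predictions are ordered the same way; prediction ties count 0.5.
    Invariant to strictly increasing transforms of the predictions.  The
    ``exact`` path enumerates all pairs; ``fast`` uses Kendall's tau;
    ``auto`` switches to ``fast`` above 400 pairs.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size < 2:
        return float("nan")
    if method == "exact" or (method == "auto" and obs.size <= 400):
        return _c_statistic_exact(obs, pred)
    return _c_statistic_fast(obs, pred)


def calibration_slope(observed, predicted) -> float:
    """OLS slope of observed on predicted eGFR.  NaN with fewer than 3 pairs
    or zero prediction variance."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size < 3 or np.var(pred) == 0:
        return float("nan")
    return float(stats.linregress(pred, obs).slope)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Per-year performance with bootstrap CIs plus the pooled pair table."""

    table: pd.DataFrame  # rows per year: metrics and CI bounds
    pairs: pd.DataFrame  # pooled (subject, year, observed, predicted, ...)
    splits: dict = field(default_factory=dict)
    n_boot: int = 0
    seed: int = 0

    def to_json(self, path) -> None:
        payload = {
            "years": self.table.reset_index().to_dict(orient="records"),
            "splits": self.splits,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _year_metrics(pairs: pd.DataFrame, years, c_method: str = "auto") -> dict:
    out = {}
    yr = pairs["year"].to_numpy()
    obs = pairs["observed"].to_numpy()
    pred = pairs["predicted"].to_numpy()
    for y in years:
        mask = yr == y
        o, p = obs[mask], pred[mask]
        out[y] = {
            "n_pairs": int(mask.sum()),
            "r2": predicted_r2(o, p),
            "c_statistic": c_statistic(o, p, method=c_method),
            "calibration_slope": calibration_slope(o, p),
        }
    return out


def _bootstrap_table(
    pairs: pd.DataFrame, years, n_boot: int, seed: int, by_country: bool = False
) -> pd.DataFrame:
    """Cluster bootstrap with percentile 95% CIs per year/metric.

    Subjects are always resampled as whole clusters (all their visits move
    together).  With ``by_country`` the bootstrap is two-stage: countries are
    resampled with replacement first, then subjects within each drawn
    country — required for pooled leave-one-country-out estimates, whose
    sampling variance includes a country-level component that subject-only
    resampling misses.
    """
    point = _year_metrics(pairs, years)
    rng = np.random.default_rng(seed)
    subjects, subj_codes = np.unique(pairs["subject_id"].to_numpy(), return_inverse=True)
    order = np.argsort(subj_codes, kind="stable")
    sorted_codes = subj_codes[order]
    bounds = np.searchsorted(sorted_codes, np.arange(subjects.size + 1))
    idx_by_subject = [order[bounds[i] : bounds[i + 1]] for i in range(subjects.size)]

    subj_country = (
        pairs.groupby("subject_id")["country"].first().reindex(subjects).to_numpy()
    )
    country_levels = np.unique(subj_country)
    subj_of_country = [
        np.where(subj_country == c)[0] for c in country_levels
    ]

    yr = pairs["year"].to_numpy()
    obs = pairs["observed"].to_numpy()
    pred = pairs["predicted"].to_numpy()
    metrics = {y: {"r2": [], "c_statistic": [], "calibration_slope": []} for y in years}
    for _ in range(n_boot):
        if by_country and country_levels.size > 1:
            draw_parts = []
            for k in rng.integers(0, country_levels.size, size=country_levels.size):
                pool = subj_of_country[k]
                draw_parts.append(pool[rng.integers(0, pool.size, size=pool.size)])
            draw = np.concatenate(draw_parts)
        else:
            draw = rng.integers(0, subjects.size, size=subjects.size)
        rows = np.concatenate([idx_by_subject[s] for s in draw])
        yr_b, obs_b, pred_b = yr[rows], obs[rows], pred[rows]
        for y in years:
            m = yr_b == y
            o, p = obs_b[m], pred_b[m]
            metrics[y]["r2"].append(predicted_r2(o, p))
            metrics[y]["c_statistic"].append(c_statistic(o, p, method="fast"))
            metrics[y]["calibration_slope"].append(calibration_slope(o, p))

    rows_out = []
    for y in years:
        rec = {"year": y, "n_pairs": point[y]["n_pairs"]}
        for name in ("r2", "c_statistic", "calibration_slope"):
            rec[name] = point[y][name]
            draws = np.asarray(metrics[y][name], dtype=float)
            valid = draws[np.isfinite(draws)]
            if valid.size:
                rec[f"{name}_lo"] = float(np.percentile(valid, 2.5))
                rec[f"{name}_hi"] = float(np.percentile(valid, 97.5))
            else:
                rec[f"{name}_lo"] = rec[f"{name}_hi"] = float("nan")
        rows_out.append(rec)
    return pd.DataFrame(rows_out).set_index("year")


def internal_external_cv(
    baselines: pd.DataFrame,
    visits: pd.DataFrame,
    spec: ModelSpec | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    years=DEFAULT_YEARS,
) -> ValidationReport:
    """Leave-one-country-out validation.

    Each country is held out in turn; the model is refitted on the remaining
    countries, the held-out subjects' random effects are updated from their
    baseline eGFR (country treated as unseen), and all follow-up visits are
    predicted.  Held-out pairs from all splits are pooled before computing
    per-year metrics; 95% CIs come from a two-stage cluster bootstrap
    (countries, then subjects within country) because the pooled estimate
    varies with the realized country effects as well as with subjects.
    Requires at least two countries.
    """
    spec = spec or ModelSpec()
    countries = sorted(baselines["country"].unique())
    if len(countries) < 2:
        raise NumericalError("leave-one-country-out requires >= 2 countries")
    all_pairs = []
    splits = {}
    for held_out in countries:
        train_b = baselines[baselines["country"] != held_out]
        train_v = visits[visits["country"] != held_out]
        design = build_design(train_b, train_v, spec)
        model = fit_lmm(design)
        marg, cond = r2_nakagawa(model, design)
        splits[held_out] = {
            "n_train_subjects": model.n_subjects,
            "loglik": model.loglik,
            "converged": model.converged,
            "marginal_r2": marg,
            "conditional_r2": cond,
            "sigma2": model.sigma2,
            "tau2": model.tau2,
        }
        test_b = baselines[baselines["country"] == held_out]
        test_v = visits[visits["country"] == held_out]
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", UserWarning)  # unseen country is intended here
            pred = batch_predict(model, test_b, test_v)
        pred["year"] = assign_year(pred["time_years"])
        pred["split"] = held_out
        all_pairs.append(pred[pred["year"] > 0])
    pairs = pd.concat(all_pairs, ignore_index=True)
    table = _bootstrap_table(pairs, years, n_boot, seed, by_country=True)
    return ValidationReport(table=table, pairs=pairs, splits=splits, n_boot=n_boot, seed=seed)


def external_validate(
    model: FittedModel,
    baselines: pd.DataFrame,
    visits: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    years=DEFAULT_YEARS,
) -> ValidationReport:
    """Validate a single frozen model on an external cohort.

    Countries not present in the training data are handled with the unseen-
    country rule (zero country effect, widened variance).  A year without any
    visit (e.g. a cohort with no year-1 examination) is reported as missing,
    not zero.
    """
    for col in ("subject_id", "country"):
        if col not in baselines.columns:
            raise NumericalError(f"baseline table lacks column {col!r}")
    missing = [p for p in model.predictors if p not in baselines.columns]
    if missing:
        from .errors import SchemaError

        raise SchemaError(f"external cohort lacks predictor columns: {missing}")
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", UserWarning)
        pred = batch_predict(model, baselines, visits)
    pred["year"] = assign_year(pred["time_years"])
    pairs = pred[pred["year"] > 0].copy()
    table = _bootstrap_table(pairs, years, n_boot, seed)
    return ValidationReport(table=table, pairs=pairs, splits={}, n_boot=n_boot, seed=seed)


def calibration_plot(pairs: pd.DataFrame, path, years=DEFAULT_YEARS):
    """Observed-vs-predicted calibration scatter, before and after updating.

    Two panels share axes: left uses ``predicted_no_update``, right uses
    ``predicted``.  The 45-degree line marks perfect agreement; later years
    are drawn lighter.  Returns the written path.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    years = [y for y in years if (pairs["year"] == y).any()]
    cmap = plt.get_cmap("viridis")
    fig, axes = plt.subplots(1, 2, figsize=(10, 5), sharex=True, sharey=True)
    lims = (
        min(pairs["observed"].min(), pairs["predicted"].min(), 0.0),
        max(pairs["observed"].max(), pairs["predicted"].max()),
    )
    for ax, col, title in zip(
        axes,
        ("predicted_no_update", "predicted"),
        ("Before updating", "After updating by baseline eGFR"),
    ):
        for i, y in enumerate(years):
            sub = pairs[pairs["year"] == y]
            ax.scatter(
                sub[col],
                sub["observed"],
                s=6,
                alpha=0.4,
                color=cmap(0.15 + 0.7 * i / max(len(years) - 1, 1)),
                label=f"year {y}",
            )
        ax.plot(lims, lims, color="black", lw=1)
        ax.set_xlabel("predicted eGFR (mL/min/1.73 m$^2$)")
        ax.set_title(title)
    axes[0].set_ylabel("observed eGFR (mL/min/1.73 m$^2$)")
    axes[1].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": "gfrtraj"})
    plt.close(fig)
    return Path(path)
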