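"""Synthetic multi-country longitudinal cohorts of eGFR trajectories.

The generator emulates the data structure of multinational prospective
type-2-diabetes / CKD cohorts: several countries with distinct baseline
kidney-function levels and visit schedules, repeated eGFR measurements over
roughly five years, and a panel of routinely collected baseline predictors.
Each subject's eGFR follows a linear mixed-effects law::

    y_ij = x_i' beta + beta_t * t_ij + (x_i * t_ij)' gamma
           + u_{c(i)} + b0_i + b1_i * t_ij + eps_ij

with a country intercept ``u ~ N(0, tau2)`` (optionally shifted by a fixed
per-country offset), individual random intercept/slope ``(b0, b1) ~ N(0, G)``
with unstructured 2x2 covariance ``G``, and measurement noise
``eps ~ N(0, sigma2)``.  The realized random effects are returned in a truth
table so that recovery and calibration of downstream estimators can be tested;
fitting code never reads the truth table.

Also provided: the race-free 2021 CKD-EPI creatinine equation (and its
inverse, so the simulator can emit serum creatinine instead of eGFR) and the
cohort inclusion filters (>=3 eGFR readings, >=2 years of follow-up, baseline
eGFR >= 30 mL/min/1.73 m2, age 18-75 at generation time).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ParameterizationError

logger = logging.getLogger(__name__)

#: Baseline predictors entering the model, in canonical column order.
#: UACR enters the design as log2(UACR); both columns are carried in tables.
PREDICTORS = (
    "age",
    "sex",
    "bmi",
    "smoking_ever",
    "hba1c",
    "hemoglobin",
    "cholesterol",
    "map",
    "log2_uacr",
    "med_glucose",
    "med_bp",
    "med_lipid",
)

#: Predictors that are binary indicators (left unstandardized in reports).
BINARY_PREDICTORS = frozenset(
    {"sex", "smoking_ever", "med_glucose", "med_bp", "med_lipid"}
)

#: Marginal generating laws for the baseline predictors, loosely calibrated to
#: pooled descriptives of large European diabetic-CKD cohorts.  Units: age in
#: years, BMI kg/m2, HbA1c mmol/mol, hemoglobin g/dL, cholesterol mg/dL, MAP
#: mm Hg, UACR mg/g (log2-normal).  Predictors are drawn independently.
DEFAULT_COVARIATES: dict[str, dict] = {
    "age": {"dist": "truncnormal", "mean": 63.5, "sd": 9.1, "low": 18.0, "high": 75.0},
    "sex": {"dist": "bernoulli", "p": 0.578},
    "bmi": {"dist": "normal", "mean": 31.2, "sd": 5.4},
    "smoking_ever": {"dist": "bernoulli", "p": 0.513},
    "hba1c": {"dist": "normal", "mean": 52.8, "sd": 12.0},
    "hemoglobin": {"dist": "normal", "mean": 13.9, "sd": 1.5},
    "cholesterol": {"dist": "normal", "mean": 192.0, "sd": 46.0},
    "map": {"dist": "normal", "mean": 98.5, "sd": 11.0},
    "uacr": {"dist": "log2normal", "mean": 4.0, "sd": 2.5},
    "med_glucose": {"dist": "bernoulli", "p": 0.87},
    "med_bp": {"dist": "bernoulli", "p": 0.84},
    "med_lipid": {"dist": "bernoulli", "p": 0.58},
}

#: Generating fixed effects in natural units (eGFR per unit of predictor for
#: main effects; eGFR per unit per year for time interactions).  The intercept
#: and the time main effect are set by the presets so that population means
#: hit their targets.
TRUE_MAIN_EFFECTS: dict[str, float] = {
    "age": -0.40,
    "sex": 2.0,
    "bmi": -0.15,
    "smoking_ever": -1.0,
    "hba1c": -0.05,
    "hemoglobin": 1.5,
    "cholesterol": -0.01,
    "map": -0.05,
    "log2_uacr": -1.6,
    "med_glucose": -1.0,
    "med_bp": -2.0,
    "med_lipid": 0.5,
}

TRUE_INTERACTION_EFFECTS: dict[str, float] = {
    "age": -0.012,
    "sex": -0.10,
    "bmi": -0.004,
    "smoking_ever": -0.08,
    "hba1c": -0.008,
    "hemoglobin": 0.04,
    "cholesterol": -0.0004,
    "map": -0.004,
    "log2_uacr": -0.12,
    "med_glucose": -0.04,
    "med_bp": -0.04,
    "med_lipid": 0.02,
}

#: Default individual random-effect covariance ((eGFR)^2, eGFR*eGFR/yr,
#: (eGFR/yr)^2): intercept SD ~13.4, slope SD 2, correlation ~ -0.30.
DEFAULT_G = np.array([[180.0, -8.0], [-8.0, 4.0]])
DEFAULT_SIGMA2 = 36.0  # within-subject eGFR measurement noise, SD 6


@dataclass(frozen=True)
class CountrySpec:
    """One country/cohort: label, fixed eGFR intercept offset, visit schedule.

    ``visit_times`` are the nominal years since baseline; the first entry must
    be 0 (baseline is always observed).
    """

    name: str
    intercept_offset: float = 0.0
    visit_times: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the synthetic cohort generator."""

    n_subjects_per_country: int
    countries: tuple[CountrySpec, ...]
    fixed_effects: dict[str, float]
    G: np.ndarray = field(default_factory=lambda: DEFAULT_G.copy())
    tau2: float = 0.0
    sigma2: float = DEFAULT_SIGMA2
    covariates: dict[str, dict] = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    visit_jitter_sd: float = 0.1
    dropout_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_per_country <= 0:
            raise ConfigurationError("n_subjects_per_country must be positive")
        if not self.countries:
            raise ConfigurationError("at least one country is required")
        for c in self.countries:
            if not c.visit_times or c.visit_times[0] != 0.0:
                raise ConfigurationError(
                    f"country {c.name!r}: visit schedule must start at time 0"
                )
        G = np.asarray(self.G, dtype=float)
        if G.shape != (2, 2) or not np.allclose(G, G.T):
            raise ParameterizationError("G must be a symmetric 2x2 matrix")
        eigvals = np.linalg.eigvalsh(G)
        if eigvals.min() < -1e-10 * max(1.0, eigvals.max()):
            raise ParameterizationError("G must be positive semi-definite")
        if self.tau2 < 0:
            raise ParameterizationError("tau2 must be >= 0")
        if self.sigma2 < 0:
            raise ParameterizationError("sigma2 must be >= 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.visit_jitter_sd < 0:
            raise ConfigurationError("visit_jitter_sd must be >= 0")
        for name in PREDICTORS:
            key = "uacr" if name == "log2_uacr" else name
            if key not in self.covariates:
                raise ConfigurationError(f"missing covariate distribution for {key!r}")


def _expected_covariate_mean(spec: dict) -> float:
    """Population mean of one covariate under its generating law."""
    dist = spec["dist"]
    if dist == "normal" or dist == "log2normal":
        return float(spec["mean"])
    if dist == "bernoulli":
        return float(spec["p"])
    if dist == "truncnormal":
        a = (spec["low"] - spec["mean"]) / spec["sd"]
        b = (spec["high"] - spec["mean"]) / spec["sd"]
        return float(stats.truncnorm.mean(a, b, loc=spec["mean"], scale=spec["sd"]))
    raise ConfigurationError(f"unknown covariate distribution {dist!r}")


def expected_design_means(covariates: dict[str, dict]) -> dict[str, float]:
    """Expected value of each design predictor (log2_uacr from the uacr law)."""
    out = {}
    for name in PREDICTORS:
        key = "uacr" if name == "log2_uacr" else name
        out[name] = _expected_covariate_mean(covariates[key])
    return out


def _build_fixed_effects(
    covariates: dict[str, dict],
    target_mean_egfr: float,
    target_mean_slope: float,
) -> dict[str, float]:
    """Assemble the generating coefficient map, solving for the intercept and
    the time main effect so that a zero-offset country has the requested
    population mean baseline eGFR and mean annual slope."""
    means = expected_design_means(covariates)
    xb = sum(TRUE_MAIN_EFFECTS[p] * means[p] for p in PREDICTORS)
    xg = sum(TRUE_INTERACTION_EFFECTS[p] * means[p] for p in PREDICTORS)
    eff: dict[str, float] = {"intercept": target_mean_egfr - xb}
    eff.update(TRUE_MAIN_EFFECTS)
    eff["time"] = target_mean_slope - xg
    eff.update({f"{p}:time": v for p, v in TRUE_INTERACTION_EFFECTS.items()})
    return eff


def three_cohort_config(n_per_country: int = 500, seed: int = 0, **overrides) -> SimulationConfig:
    """Three-cohort preset with country mean baseline eGFR calibrated to
    52.4 / 89.6 / 81.2 mL/min/1.73 m2 via fixed intercept offsets.

    country_A: biennial visits, low eGFR (CKD-enriched cohort);
    country_B: yearly visits, preserved eGFR;
    country_C: no year-1 visit, intermediate eGFR.

    tau2 is 0 here so the offset calibration is exact in expectation; the
    offsets play the role of realized country effects.  Calibration refers to
    the generated population, before inclusion filtering (the eGFR>=30 filter
    raises the low-eGFR cohort's included mean by ~2 units).
    """
    covariates = dict(DEFAULT_COVARIATES)
    eff = _build_fixed_effects(covariates, target_mean_egfr=81.2, target_mean_slope=-1.45)
    countries = (
        CountrySpec("country_A", 52.4 - 81.2, (0.0, 2.0, 4.0, 6.0)),
        CountrySpec("country_B", 89.6 - 81.2, (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)),
        CountrySpec("country_C", 0.0, (0.0, 2.0, 3.0, 4.0, 5.0)),
    )
    cfg = SimulationConfig(
        n_subjects_per_country=n_per_country,
        countries=countries,
        fixed_effects=eff,
        tau2=0.0,
        seed=seed,
        covariates=covariates,
    )
    return replace(cfg, **overrides) if overrides else cfg


def well_specified_config(
    n_per_country: int = 700, seed: int = 0, tau2: float = 25.0, **overrides
) -> SimulationConfig:
    """Model-consistent preset: three countries with random intercepts drawn
    from N(0, tau2), no fixed offsets, yearly visits over five years.

    Used for recovery and validation studies where the fitted model should be
    exactly well specified.
    """
    covariates = dict(DEFAULT_COVARIATES)
    eff = _build_fixed_effects(covariates, target_mean_egfr=80.0, target_mean_slope=-1.45)
    yearly = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
    countries = (
        CountrySpec("country_A", 0.0, yearly),
        CountrySpec("country_B", 0.0, yearly),
        CountrySpec("country_C", 0.0, yearly),
    )
    cfg = SimulationConfig(
        n_subjects_per_country=n_per_country,
        countries=countries,
        fixed_effects=eff,
        tau2=tau2,
        seed=seed,
        covariates=covariates,
    )
    return replace(cfg, **overrides) if overrides else cfg


def _draw_covariates(rng: np.random.Generator, spec: dict, n: int) -> np.ndarray:
    dist = spec["dist"]
    if dist == "normal":
        return rng.normal(spec["mean"], spec["sd"], size=n)
    if dist == "bernoulli":
        return (rng.random(n) < spec["p"]).astype(float)
    if dist == "log2normal":
        return rng.normal(spec["mean"], spec["sd"], size=n)  # on the log2 scale
    if dist == "truncnormal":
        a = (spec["low"] - spec["mean"]) / spec["sd"]
        b = (spec["high"] - spec["mean"]) / spec["sd"]
        return stats.truncnorm.rvs(
            a, b, loc=spec["mean"], scale=spec["sd"], size=n, random_state=rng
        )
    raise ConfigurationError(f"unknown covariate distribution {dist!r}")


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate baselines, long-format visit table, and the truth record.

    Returns
    -------
    baselines : DataFrame
        One row per subject: ``subject_id``, ``country``, the predictors of
        :data:`PREDICTORS` (plus raw ``uacr``), and ``baseline_egfr``.
    visits : DataFrame
        Long format: ``subject_id``, ``country``, ``time_years``, ``egfr``.
        Every subject has a row at time 0.
    truth : DataFrame
        Per-subject realized random effects and true slope — for testing
        recovery only, never consumed by fitting code.

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    eff = config.fixed_effects
    G = np.asarray(config.G, dtype=float)
    beta_mains = np.array([eff[p] for p in PREDICTORS])
    gammas = np.array([eff.get(f"{p}:time", 0.0) for p in PREDICTORS])

    base_rows, visit_rows, truth_rows = [], [], []
    for country in config.countries:
        n = config.n_subjects_per_country
        cov: dict[str, np.ndarray] = {}
        for key, spec in config.covariates.items():
            cov[key] = _draw_covariates(rng, spec, n)
        log2_uacr = cov["uacr"]  # drawn on the log2 scale
        uacr = np.exp2(log2_uacr)

        u_c = country.intercept_offset
        if config.tau2 > 0:
            u_c += rng.normal(0.0, math.sqrt(config.tau2))

        if np.any(G):
            b = rng.multivariate_normal(np.zeros(2), G, size=n, method="svd")
        else:
            b = np.zeros((n, 2))

        X = np.column_stack(
            [cov[p] if p != "log2_uacr" else log2_uacr for p in PREDICTORS]
        )
        fixed_intercept = eff["intercept"] + X @ beta_mains
        fixed_slope = eff["time"] + X @ gammas

        for i in range(n):
            sid = f"{country.name}-{i:05d}"
            times = np.asarray(country.visit_times, dtype=float).copy()
            if config.visit_jitter_sd > 0 and times.size > 1:
                jit = rng.normal(0.0, config.visit_jitter_sd, size=times.size - 1)
                times[1:] = np.maximum(times[1:] + jit, 0.05)
            keep = np.ones(times.size, dtype=bool)
            if config.dropout_rate > 0 and times.size > 1:
                keep[1:] = rng.random(times.size - 1) >= config.dropout_rate
            eps = rng.normal(0.0, math.sqrt(config.sigma2), size=times.size)
            y = (
                fixed_intercept[i]
                + u_c
                + b[i, 0]
                + (fixed_slope[i] + b[i, 1]) * times
                + eps
            )
            for t_j, y_j, k in zip(times, y, keep):
                if k:
                    visit_rows.append((sid, country.name, float(t_j), float(y_j)))
            row = {"subject_id": sid, "country": country.name}
            for p in PREDICTORS:
                row[p] = float(X[i, PREDICTORS.index(p)])
            row["uacr"] = float(uacr[i])
            row["baseline_egfr"] = float(y[0])
            base_rows.append(row)
            truth_rows.append(
                {
                    "subject_id": sid,
                    "country": country.name,
                    "country_effect": float(u_c),
                    "b0": float(b[i, 0]),
                    "b1": float(b[i, 1]),
                    "fixed_intercept": float(fixed_intercept[i]),
                    "fixed_slope": float(fixed_slope[i]),
                    "true_slope": float(fixed_slope[i] + b[i, 1]),
                }
            )

    baselines = pd.DataFrame(base_rows)
    visits = pd.DataFrame(
        visit_rows, columns=["subject_id", "country", "time_years", "egfr"]
    )
    truth = pd.DataFrame(truth_rows)
    return baselines, visits, truth


def apply_inclusion_filters(
    baselines: pd.DataFrame,
    visits: pd.DataFrame,
    min_readings: int = 3,
    min_span_years: float = 2.0,
    min_baseline_egfr: float = 30.0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Apply the cohort inclusion criteria and report exclusion counts.

    Criteria: at least ``min_readings`` eGFR readings, follow-up spanning at
    least ``min_span_years``, and baseline eGFR >= ``min_baseline_egfr``.
    A subject can fail several criteria; counts are reported per criterion, so
    they may sum to more than the number excluded.  Idempotent.
    """
    grp = visits.groupby("subject_id")
    n_read = grp.size()
    span = grp["time_years"].max()
    base = visits.loc[visits["time_years"] == 0.0].set_index("subject_id")["egfr"]

    subjects = pd.Index(baselines["subject_id"])
    fail_read = n_read.reindex(subjects).fillna(0) < min_readings
    fail_span = span.reindex(subjects).fillna(0.0) < min_span_years
    base_aligned = base.reindex(subjects)
    fail_nobase = base_aligned.isna()
    fail_egfr = (base_aligned < min_baseline_egfr).fillna(False)

    excluded = fail_read | fail_span | fail_egfr | fail_nobase
    counts = {
        "readings<3": int(fail_read.sum()),
        "followup<2y": int(fail_span.sum()),
        "baseline eGFR<30": int(fail_egfr.sum()),
        "no baseline visit": int(fail_nobase.sum()),
        "n_excluded": int(excluded.sum()),
        "n_retained": int((~excluded).sum()),
    }
    keep_ids = set(subjects[~excluded.to_numpy()])
    baselines_f = baselines[baselines["subject_id"].isin(keep_ids)].reset_index(drop=True)
    visits_f = visits[visits["subject_id"].isin(keep_ids)].reset_index(drop=True)
    return baselines_f, visits_f, counts


# ---------------------------------------------------------------------------
# CKD-EPI 2021 creatinine equation (race free)
# ---------------------------------------------------------------------------

_CKD_EPI_A = 142.0
_CKD_EPI_AGE = 0.9938
_CKD_EPI_FEMALE = 1.012


def ckd_epi_2021(serum_creatinine, age, sex):
    """Race-free 2021 CKD-EPI creatinine eGFR (mL/min/1.73 m2).

    Parameters: serum creatinine in mg/dL, age in years, sex coded 0 = female,
    1 = male.  Vectorized; raises ``ValueError`` on non-positive creatinine or
    age.
    """
    scr = np.asarray(serum_creatinine, dtype=float)
    age_a = np.asarray(age, dtype=float)
    sex_a = np.asarray(sex)
    if np.any(scr <= 0) or np.any(age_a <= 0):
        raise ValueError("serum creatinine and age must be positive")
    male = sex_a == 1
    kappa = np.where(male, 0.9, 0.7)
    alpha = np.where(male, -0.302, -0.241)
    ratio = scr / kappa
    egfr = (
        _CKD_EPI_A
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.200
        * _CKD_EPI_AGE**age_a
        * np.where(male, 1.0, _CKD_EPI_FEMALE)
    )
    return egfr if egfr.ndim else float(egfr)


def creatinine_for_egfr(egfr, age, sex):
    """Invert :func:`ckd_epi_2021`: serum creatinine (mg/dL) producing the
    given eGFR at the given age/sex.  The equation is strictly decreasing in
    creatinine, so the inverse is unique (closed-form, piecewise)."""
    e = np.asarray(egfr, dtype=float)
    age_a = np.asarray(age, dtype=float)
    sex_a = np.asarray(sex)
    if np.any(e <= 0) or np.any(age_a <= 0):
        raise ValueError("egfr and age must be positive")
    male = sex_a == 1
    kappa = np.where(male, 0.9, 0.7)
    alpha = np.where(male, -0.302, -0.241)
    scale = _CKD_EPI_A * _CKD_EPI_AGE**age_a * np.where(male, 1.0, _CKD_EPI_FEMALE)
    ratio_target = e / scale  # value of the piecewise power term
    low_branch = ratio_target >= 1.0  # scr <= kappa
    scr = np.where(
        low_branch,
        kappa * ratio_target ** (1.0 / alpha),
        kappa * ratio_target ** (-1.0 / 1.200),
    )
    return scr if scr.ndim else float(scr)


def attach_creatinine(visits: pd.DataFrame, baselines: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``visits`` with a ``creatinine`` column consistent with
    each eGFR value under CKD-EPI 2021 (age fixed at baseline age)."""
    demo = baselines.set_index("subject_id")[["age", "sex"]]
    merged = visits.merge(demo, left_on="subject_id", right_index=True, how="left")
    out = visits.copy()
    out["creatinine"] = creatinine_for_egfr(
        merged["egfr"].to_numpy(), merged["age"].to_numpy(), merged["sex"].to_numpy()
    )
    return out
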