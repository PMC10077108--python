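"""Linear mixed-effects model for repeated eGFR measurements.

Model
-----
For visit ``j`` of subject ``i`` in country ``c(i)``::

    y_ij = x_i' beta + beta_t t_ij + (x_i t_ij)' gamma
           + u_{c(i)} + b0_i + b1_i t_ij + eps_ij

* ``x_i``: baseline predictors (UACR as log2), each with a main effect and a
  time-interaction coefficient;
* ``(b0_i, b1_i) ~ N(0, G)``: individual random intercept and slope with
  unstructured 2x2 covariance (individual intercepts are nested within
  countries);
* ``u_c ~ N(0, tau2)``: country-level random intercept, which absorbs
  country-specific eGFR level differences (e.g. creatinine assay offsets);
* ``eps_ij ~ N(0, sigma2)``: residual measurement noise.

Estimation maximizes the (restricted) marginal Gaussian likelihood with
``G`` parameterized through its Cholesky factor (so PSD by construction) and
``tau2`` through a square root, both scaled by ``sigma2`` so that ``beta`` and
``sigma2`` are profiled out analytically.  The per-country marginal covariance
is handled with a Woodbury identity on the 2x2 per-subject blocks plus a
rank-one update for the country intercept, so a criterion evaluation costs
O(number of subjects).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .cohort import BINARY_PREDICTORS, PREDICTORS
from .errors import (
    DegeneratePredictorError,
    IntegrityError,
    NumericalError,
    SingularDesignError,
)

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)
MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ModelSpec:
    """Which predictors enter the fixed part, and how the model is fitted.

    ``predictors`` get one main effect each; every predictor listed in
    ``interactions`` additionally gets a predictor-by-time product term.  The
    fixed-effect dimension is ``2 + len(predictors) + len(interactions)``
    (intercept and time main effect included).
    """

    predictors: tuple[str, ...] = PREDICTORS
    interactions: tuple[str, ...] | None = None  # None -> all predictors
    time_name: str = "time"
    fit_method: str = "reml"  # or "ml"

    @property
    def interaction_terms(self) -> tuple[str, ...]:
        return self.predictors if self.interactions is None else self.interactions

    @property
    def columns(self) -> list[str]:
        return (
            ["intercept"]
            + list(self.predictors)
            + [self.time_name]
            + [f"{p}:{self.time_name}" for p in self.interaction_terms]
        )

    @property
    def n_fixed(self) -> int:
        return 2 + len(self.predictors) + len(self.interaction_terms)


@dataclass
class DesignBundle:
    """Design matrices and grouping structure for one analysis data set."""

    X: np.ndarray  # (n_obs, p) fixed-effect design
    y: np.ndarray  # (n_obs,) eGFR
    time: np.ndarray  # (n_obs,) years since baseline
    columns: list[str]
    subject_index: np.ndarray  # (n_obs,) int codes 0..S-1
    subject_ids: list  # id per code
    subject_country: np.ndarray  # (S,) int codes 0..K-1
    countries: list[str]
    predictor_sds: dict[str, float]  # training-sample SD per predictor
    spec: ModelSpec
    n_dropped_incomplete: int = 0

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def p(self) -> int:
        return self.X.shape[1]


def build_design(
    baselines: pd.DataFrame, visits: pd.DataFrame, spec: ModelSpec | None = None
) -> DesignBundle:
    """Assemble the fixed-effect design from baseline and visit tables.

    Rows follow the visit table order (after complete-case removal).  Column
    order is ``intercept, <predictors>, time, <predictor:time products>``.
    Subjects with any missing predictor are dropped (complete-case policy)
    with the count logged; a visit whose subject is absent from the baseline
    table raises :class:`IntegrityError`.
    """
    spec = spec or ModelSpec()
    missing_cols = [p for p in spec.predictors if p not in baselines.columns]
    if missing_cols:
        raise IntegrityError(f"baseline table lacks predictor columns: {missing_cols}")

    unknown = set(visits["subject_id"]) - set(baselines["subject_id"])
    if unknown:
        raise IntegrityError(
            f"{len(unknown)} visit subjects missing from baseline table "
            f"(e.g. {sorted(unknown)[:3]})"
        )

    pred_block = baselines[list(spec.predictors)]
    complete = pred_block.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("complete-case filter dropped %d subjects", n_dropped)
    base_cc = baselines.loc[complete].reset_index(drop=True)

    keep = visits["subject_id"].isin(set(base_cc["subject_id"]))
    v = visits.loc[keep].reset_index(drop=True)

    merged = v.merge(
        base_cc[["subject_id", "country", *spec.predictors]],
        on="subject_id",
        how="left",
        suffixes=("", "_base"),
    )

    t = merged["time_years"].to_numpy(dtype=float)
    P = merged[list(spec.predictors)].to_numpy(dtype=float)
    inter_idx = [spec.predictors.index(p) for p in spec.interaction_terms]
    X = np.column_stack(
        [np.ones(len(merged)), P, t, P[:, inter_idx] * t[:, None]]
    )

    subj_codes, subj_ids = pd.factorize(merged["subject_id"], sort=False)
    country_per_subject = (
        merged.groupby(subj_codes)["country"].first().sort_index().to_numpy()
    )
    country_codes, countries = pd.factorize(country_per_subject, sort=True)

    sds = {
        p: float(base_cc[p].std(ddof=1)) for p in spec.predictors
    }

    return DesignBundle(
        X=X,
        y=merged["egfr"].to_numpy(dtype=float),
        time=t,
        columns=spec.columns,
        subject_index=subj_codes.astype(np.int64),
        subject_ids=list(subj_ids),
        subject_country=country_codes.astype(np.int64),
        countries=list(countries),
        predictor_sds=sds,
        spec=spec,
        n_dropped_incomplete=n_dropped,
    )


# ---------------------------------------------------------------------------
# Profiled (RE)ML machinery
# ---------------------------------------------------------------------------


class _Precomp:
    """Sufficient statistics reused across criterion evaluations.

    With M = [X, y, 1] and Z_i = [1, t] per subject, stores C_i = Z_i'M_i,
    T_i = Z_i'Z_i, and per-country sums of M_i'M_i.
    """

    def __init__(self, design: DesignBundle):
        X, y, t = design.X, design.y, design.time
        n, p = X.shape
        S = design.n_subjects
        K = len(design.countries)
        subj = design.subject_index
        M = np.column_stack([X, y, np.ones(n)])
        m = p + 2
        C = np.zeros((S, 2, m))
        for j in range(m):
            C[:, 0, j] = np.bincount(subj, weights=M[:, j], minlength=S)
            C[:, 1, j] = np.bincount(subj, weights=M[:, j] * t, minlength=S)
        T = np.zeros((S, 2, 2))
        T[:, 0, 0] = np.bincount(subj, minlength=S)
        T[:, 0, 1] = T[:, 1, 0] = np.bincount(subj, weights=t, minlength=S)
        T[:, 1, 1] = np.bincount(subj, weights=t * t, minlength=S)
        MtM_country = np.zeros((K, m, m))
        row_country = design.subject_country[subj]
        for k in range(K):
            Mk = M[row_country == k]
            MtM_country[k] = Mk.T @ Mk
        self.C, self.T, self.MtM_country = C, T, MtM_country
        self.subj_country = design.subject_country
        self.n, self.p, self.S, self.K, self.m = n, p, S, K, m


def _whole_matrices(pre: _Precomp, Gs: np.ndarray, ts2: float):
    """Per-country M'V0^-1 M and log|V0| for V0 = I + Z Gs Z' + ts2 on the
    country block (everything scaled by sigma2)."""
    C, T = pre.C, pre.T
    GsT = np.einsum("ab,sbc->sac", Gs, T)
    B = GsT.copy()
    B[:, 0, 0] += 1.0
    B[:, 1, 1] += 1.0
    detB = B[:, 0, 0] * B[:, 1, 1] - B[:, 0, 1] * B[:, 1, 0]
    if np.any(detB <= 0) or not np.all(np.isfinite(detB)):
        return None, None
    Binv = np.empty_like(B)
    Binv[:, 0, 0] = B[:, 1, 1]
    Binv[:, 1, 1] = B[:, 0, 0]
    Binv[:, 0, 1] = -B[:, 0, 1]
    Binv[:, 1, 0] = -B[:, 1, 0]
    Binv /= detB[:, None, None]
    W = np.einsum("sab,bc->sac", Binv, Gs)  # (I + Gs T)^-1 Gs, symmetric
    WC = np.einsum("sab,sbm->sam", W, C)
    corr = np.einsum("sam,san->smn", C, WC)  # C' W C per subject

    K, m = pre.K, pre.m
    S_c = pre.MtM_country.copy()
    logdet_c = np.bincount(pre.subj_country, weights=np.log(detB), minlength=K)
    for k in range(K):
        S_c[k] -= corr[pre.subj_country == k].sum(axis=0)
        u = S_c[k][:, -1].copy()  # M' A^-1 1
        alpha = u[-1]
        denom = 1.0 + ts2 * alpha
        S_c[k] -= (ts2 / denom) * np.outer(u, u)
        logdet_c[k] += math.log(denom)
    return S_c, logdet_c


def _criterion_parts(pre: _Precomp, Gs: np.ndarray, ts2: float, method: str):
    out = _whole_matrices(pre, Gs, ts2)
    if out[0] is None:
        return None
    S_c, logdet_c = out
    S_V = S_c.sum(axis=0)
    logdetV0 = float(logdet_c.sum())
    p, n = pre.p, pre.n
    Sxx = S_V[:p, :p]
    Sxy = S_V[:p, p]
    Syy = S_V[p, p]
    try:
        cf = linalg.cho_factor(Sxx, lower=False, check_finite=False)
    except linalg.LinAlgError:
        return None
    beta = linalg.cho_solve(cf, Sxy, check_finite=False)
    rss = Syy - Sxy @ beta
    if not np.isfinite(rss) or rss <= 0:
        return None
    ld_Sxx = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    if method == "reml":
        dof = n - p
        sigma2 = rss / dof
        loglik = -0.5 * (dof * (_LOG2PI + 1.0 + math.log(sigma2)) + logdetV0 + ld_Sxx)
    else:
        sigma2 = rss / n
        loglik = -0.5 * (n * (_LOG2PI + 1.0 + math.log(sigma2)) + logdetV0)
    return {
        "loglik": loglik,
        "beta": beta,
        "sigma2": sigma2,
        "S_c": S_c,
        "cho": cf,
        "logdetV0": logdetV0,
    }


def _theta_to_varparams(theta: np.ndarray, fit_tau: bool):
    a, b, c = theta[0], theta[1], theta[2]
    L = np.array([[a, 0.0], [b, c]])
    Gs = L @ L.T
    ts2 = float(theta[3] ** 2) if fit_tau else 0.0
    return Gs, ts2


def _start_values(design: DesignBundle, fit_tau: bool) -> np.ndarray:
    """Moment-based starting point for the scaled variance parameters."""
    X, y = design.X, design.y
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    s2 = max(float(resid.var()), 1e-8)
    subj = design.subject_index
    S = design.n_subjects
    mean_r = np.bincount(subj, weights=resid, minlength=S) / np.bincount(
        subj, minlength=S
    )
    between = float(np.var(mean_r))
    g00 = min(max(between / s2, 1e-2), 50.0)
    g11 = max(g00 / 30.0, 1e-3)
    theta = [math.sqrt(g00), 0.0, math.sqrt(g11)]
    if fit_tau:
        cm = np.array(
            [mean_r[design.subject_country == k].mean() for k in range(len(design.countries))]
        )
        t2 = min(max(float(np.var(cm)) / s2, 1e-3), 50.0)
        theta.append(math.sqrt(t2))
    return np.asarray(theta)


def _check_full_rank(design: DesignBundle) -> None:
    X = design.X
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = d.max() * max(X.shape) * np.finfo(float).eps * 10
    bad = d < tol
    if bad.any():
        names = [design.columns[piv[i]] for i in np.where(bad)[0]]
        raise SingularDesignError(f"design matrix is rank deficient; suspect columns: {names}")


@dataclass
class FittedModel:
    """Estimated population parameters of the eGFR trajectory model."""

    beta: pd.Series  # fixed effects, indexed by design column name
    beta_cov: np.ndarray  # (p, p) covariance of the fixed-effect estimates
    G: np.ndarray  # 2x2 individual (intercept, slope) covariance
    tau2: float  # country intercept variance
    sigma2: float  # residual variance
    country_effects: pd.Series  # posterior mean country deviations
    loglik: float
    converged: bool
    fit_method: str
    n_subjects: int
    n_obs: int
    predictor_sds: dict[str, float]
    spec: ModelSpec = field(default_factory=ModelSpec)

    @property
    def predictors(self) -> tuple[str, ...]:
        return self.spec.predictors

    def save(self, path) -> None:
        """Persist to a versioned JSON file (re-loadable without refitting)."""
        payload = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "columns": list(self.beta.index),
            "beta": self.beta.to_list(),
            "beta_cov": np.asarray(self.beta_cov).tolist(),
            "G": np.asarray(self.G).tolist(),
            "tau2": self.tau2,
            "sigma2": self.sigma2,
            "country_effects": self.country_effects.to_dict(),
            "loglik": self.loglik,
            "converged": bool(self.converged),
            "fit_method": self.fit_method,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "predictor_sds": self.predictor_sds,
            "spec": {
                "predictors": list(self.spec.predictors),
                "interactions": list(self.spec.interaction_terms),
                "time_name": self.spec.time_name,
                "fit_method": self.spec.fit_method,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path) -> "FittedModel":
        payload = json.loads(Path(path).read_text())
        version = payload.get("schema_version")
        if version != MODEL_SCHEMA_VERSION:
            raise NumericalError(
                f"model file schema version {version!r} != {MODEL_SCHEMA_VERSION}"
            )
        spec = ModelSpec(
            predictors=tuple(payload["spec"]["predictors"]),
            interactions=tuple(payload["spec"]["interactions"]),
            time_name=payload["spec"]["time_name"],
            fit_method=payload["spec"]["fit_method"],
        )
        return cls(
            beta=pd.Series(payload["beta"], index=payload["columns"]),
            beta_cov=np.asarray(payload["beta_cov"]),
            G=np.asarray(payload["G"]),
            tau2=float(payload["tau2"]),
            sigma2=float(payload["sigma2"]),
            country_effects=pd.Series(payload["country_effects"], dtype=float),
            loglik=float(payload["loglik"]),
            converged=bool(payload["converged"]),
            fit_method=payload["fit_method"],
            n_subjects=int(payload["n_subjects"]),
            n_obs=int(payload["n_obs"]),
            predictor_sds={k: float(v) for k, v in payload["predictor_sds"].items()},
            spec=spec,
        )


def fit_lmm(design: DesignBundle, method: str | None = None) -> FittedModel:
    """Fit the mixed model by profiled (restricted) maximum likelihood.

    The optimizer works on four unconstrained parameters: the Cholesky factor
    of ``G/sigma2`` and the square root of ``tau2/sigma2``; ``beta`` and
    ``sigma2`` are profiled out exactly.  A quasi-Newton pass is polished by
    Nelder-Mead restarts; on failure the fit is retried once from a perturbed
    start and ``converged=False`` is reported rather than raising.
    """
    method = (method or design.spec.fit_method).lower()
    if method not in {"reml", "ml"}:
        raise ValueError(f"unknown fit method {method!r}")
    _check_full_rank(design)
    K = len(design.countries)
    fit_tau = K >= 2
    if not fit_tau:
        warnings.warn(
            "fewer than 2 countries: tau2 fixed at 0", UserWarning, stacklevel=2
        )
    pre = _Precomp(design)

    def neg(theta: np.ndarray) -> float:
        Gs, ts2 = _theta_to_varparams(theta, fit_tau)
        parts = _criterion_parts(pre, Gs, ts2, method)
        if parts is None:
            return 1e12
        return -parts["loglik"]

    def polish(x0: np.ndarray):
        best = optimize.minimize(
            neg, x0, method="L-BFGS-B", options={"ftol": 1e-15, "gtol": 1e-9}
        )
        res_nm = optimize.minimize(
            neg,
            best.x,
            method="Nelder-Mead",
            options={
                "xatol": 1e-8,
                "fatol": 1e-11,
                "maxfev": 2000,
                "adaptive": True,
            },
        )
        if res_nm.fun <= best.fun:
            best = res_nm
        return best

    x0 = _start_values(design, fit_tau)
    best = polish(x0)
    converged = bool(np.isfinite(best.fun) and best.fun < 1e11)
    if not converged:
        rng = np.random.default_rng(0)
        best2 = polish(x0 * (1.0 + 0.5 * rng.standard_normal(x0.shape)))
        if best2.fun < best.fun:
            best = best2
        converged = bool(np.isfinite(best.fun) and best.fun < 1e11)

    Gs, ts2 = _theta_to_varparams(best.x, fit_tau)
    parts = _criterion_parts(pre, Gs, ts2, method)
    if parts is None:
        raise NumericalError("likelihood evaluation failed at the optimum")
    sigma2 = parts["sigma2"]
    beta = parts["beta"]
    p = design.p
    beta_cov = sigma2 * linalg.cho_solve(parts["cho"], np.eye(p), check_finite=False)

    country_eff = {}
    for k, name in enumerate(design.countries):
        S_k = parts["S_c"][k]
        ones_X = S_k[-1, :p]
        ones_y = S_k[-1, p]
        country_eff[name] = float(ts2 * (ones_y - ones_X @ beta))

    return FittedModel(
        beta=pd.Series(beta, index=design.columns),
        beta_cov=beta_cov,
        G=sigma2 * Gs,
        tau2=sigma2 * ts2,
        sigma2=float(sigma2),
        country_effects=pd.Series(country_eff, dtype=float),
        loglik=float(parts["loglik"]),
        converged=converged,
        fit_method=method,
        n_subjects=design.n_subjects,
        n_obs=design.n_obs,
        predictor_sds=dict(design.predictor_sds),
        spec=design.spec,
    )


def gls_fit(
    design: DesignBundle, G: np.ndarray, tau2: float, sigma2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Generalized least-squares ``beta`` (and its covariance) at fixed
    variance components — the exact solution the fitter must reproduce."""
    if sigma2 <= 0:
        raise NumericalError("sigma2 must be positive")
    pre = _Precomp(design)
    Gs = np.asarray(G, dtype=float) / sigma2
    ts2 = float(tau2) / sigma2
    S_c, _ = _whole_matrices(pre, Gs, ts2)
    if S_c is None:
        raise NumericalError("non-finite marginal covariance")
    S_V = S_c.sum(axis=0)
    p = design.p
    beta = np.linalg.solve(S_V[:p, :p], S_V[:p, p])
    cov = sigma2 * np.linalg.inv(S_V[:p, :p])
    return beta, cov


def loglikelihood(
    design: DesignBundle,
    G: np.ndarray,
    tau2: float,
    sigma2: float,
    method: str = "reml",
) -> float:
    """Marginal (restricted) log-likelihood at the given variance components
    with ``beta`` set to its GLS value.  Matches the convention in which the
    REML criterion uses the n-p dimensional contrast likelihood, including
    all constants."""
    pre = _Precomp(design)
    Gs = np.asarray(G, dtype=float) / sigma2
    ts2 = float(tau2) / sigma2
    S_c, logdet_c = _whole_matrices(pre, Gs, ts2)
    if S_c is None:
        raise NumericalError("non-finite marginal covariance")
    S_V = S_c.sum(axis=0)
    logdetV0 = float(logdet_c.sum())
    n, p = pre.n, pre.p
    Sxx, Sxy, Syy = S_V[:p, :p], S_V[:p, p], S_V[p, p]
    beta = np.linalg.solve(Sxx, Sxy)
    quad = (Syy - Sxy @ beta) / sigma2
    if method == "reml":
        ld_Sxx = float(np.linalg.slogdet(Sxx)[1])
        return -0.5 * (
            (n - p) * _LOG2PI
            + (n - p) * math.log(sigma2)
            + logdetV0
            + ld_Sxx
            + quad
        )
    return -0.5 * (n * _LOG2PI + n * math.log(sigma2) + logdetV0 + quad)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def r2_nakagawa(model: FittedModel, design: DesignBundle) -> tuple[float, float]:
    """Marginal and conditional R2 for the mixed model.

    marginal = var(X beta) / (var(X beta) + RE variance + sigma2), where the
    random-effect contribution uses the design-averaged z G z' term (z=(1,t))
    plus tau2; conditional adds the RE variance to the numerator.  Both lie in
    [0,1] and conditional >= marginal.
    """
    if not model.converged:
        warnings.warn("R2 computed on a non-converged fit", UserWarning, stacklevel=2)
    fitted = design.X @ model.beta.to_numpy()
    var_f = float(np.var(fitted, ddof=1))
    t = design.time
    G = model.G
    var_re = (
        G[0, 0] + 2.0 * G[0, 1] * float(t.mean()) + G[1, 1] * float(np.mean(t * t))
    ) + model.tau2
    total = var_f + var_re + model.sigma2
    if total <= 0:
        raise NumericalError("total variance is zero; R2 undefined")
    return var_f / total, (var_f + var_re) / total


def standardized_coefficients(
    model: FittedModel, design: DesignBundle | None = None
) -> pd.DataFrame:
    """Coefficient report with standardized estimates for continuous terms.

    Continuous predictor mains and their time interactions are multiplied by
    the predictor's training-sample SD (difference in predicted eGFR per 1-SD
    difference); binary terms, the intercept, and the time main effect are
    reported unchanged.  95% CIs are estimate +/- 1.96 SE on the same scale.
    """
    sds = model.predictor_sds
    names = list(model.beta.index)
    se = np.sqrt(np.diag(model.beta_cov))
    rows = []
    for i, name in enumerate(names):
        base = name.split(":")[0]
        est = float(model.beta.iloc[i])
        scale = 1.0
        if base in sds and base not in BINARY_PREDICTORS:
            if sds[base] == 0 or not np.isfinite(sds[base]):
                raise DegeneratePredictorError(f"predictor {base!r} has zero SD")
            scale = sds[base]
        std_est = est * scale
        std_se = float(se[i]) * scale
        rows.append(
            {
                "term": name,
                "estimate": est,
                "se": float(se[i]),
                "standardized_estimate": std_est,
                "ci_low": std_est - 1.96 * std_se,
                "ci_high": std_est + 1.96 * std_se,
                "standardized": scale != 1.0,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def _drop_predictor(design: DesignBundle, predictor: str) -> DesignBundle:
    spec = design.spec
    if predictor not in spec.predictors:
        raise KeyError(f"unknown predictor {predictor!r}")
    new_spec = ModelSpec(
        predictors=tuple(p for p in spec.predictors if p != predictor),
        interactions=tuple(p for p in spec.interaction_terms if p != predictor),
        time_name=spec.time_name,
        fit_method=spec.fit_method,
    )
    keep_idx = [
        i for i, c in enumerate(design.columns) if c.split(":")[0] != predictor
    ]
    return dataclasses.replace(
        design,
        X=design.X[:, keep_idx],
        columns=[design.columns[i] for i in keep_idx],
        predictor_sds={k: v for k, v in design.predictor_sds.items() if k != predictor},
        spec=new_spec,
    )


def drop_one_marginal_r2(
    model: FittedModel, design: DesignBundle, predictor: str
) -> float:
    """Decrease in marginal R2 when refitting without one predictor (its main
    effect and time interaction both removed).  Non-negative up to refit
    noise for nested models evaluated on the training data."""
    reduced = _drop_predictor(design, predictor)
    refit = fit_lmm(reduced, method=model.fit_method)
    full_marg, _ = r2_nakagawa(model, design)
    red_marg, _ = r2_nakagawa(refit, reduced)
    return full_marg - red_marg
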