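"""Design construction, REML fitting, and reporting of the mixed model."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from gfrtraj import (
    CountrySpec,
    ModelSpec,
    build_design,
    drop_one_marginal_r2,
    fit_lmm,
    generate_cohort,
    gls_fit,
    loglikelihood,
    r2_nakagawa,
    standardized_coefficients,
    well_specified_config,
)
from gfrtraj.cohort import PREDICTORS
from gfrtraj.errors import (
    DegeneratePredictorError,
    IntegrityError,
    NumericalError,
    SingularDesignError,
)


def _one_subject_tables():
    baselines = pd.DataFrame(
        {
            "subject_id": ["s1"],
            "country": ["X"],
            "age": [60.0],
            "sex": [1.0],
            "bmi": [30.0],
            "smoking_ever": [0.0],
            "hba1c": [50.0],
            "hemoglobin": [14.0],
            "cholesterol": [190.0],
            "map": [100.0],
            "uacr": [8.0],
            "log2_uacr": [3.0],
            "med_glucose": [1.0],
            "med_bp": [1.0],
            "med_lipid": [0.0],
            "baseline_egfr": [85.0],
        }
    )
    visits = pd.DataFrame(
        {
            "subject_id": ["s1"] * 3,
            "country": ["X"] * 3,
            "time_years": [0.0, 1.0, 2.0],
            "egfr": [85.0, 83.0, 81.0],
        }
    )
    return baselines, visits


class TestBuildDesign:
    def test_dimensions_and_column_order(self):
        baselines, visits = _one_subject_tables()
        d = build_design(baselines, visits)
        # intercept + mains + time + interactions for every predictor
        assert d.X.shape == (3, 2 * len(PREDICTORS) + 2)
        assert d.columns[0] == "intercept"
        assert d.columns[1 + len(PREDICTORS)] == "time"
        assert d.columns[-1] == f"{PREDICTORS[-1]}:time"

    def test_log2_uacr_and_interaction_values(self):
        baselines, visits = _one_subject_tables()
        d = build_design(baselines, visits)
        j = d.columns.index("log2_uacr")
        assert d.X[0, j] == pytest.approx(3.0)  # log2(8)
        k = d.columns.index("age:time")
        assert d.X[2, k] == pytest.approx(120.0)  # age 60 * t 2

    def test_unknown_subject_raises(self):
        baselines, visits = _one_subject_tables()
        bad = visits.copy()
        bad.loc[1, "subject_id"] = "ghost"
        with pytest.raises(IntegrityError):
            build_design(baselines, bad)

    def test_complete_case_drop_counted(self):
        baselines, visits = _one_subject_tables()
        b2 = pd.concat([baselines, baselines.assign(subject_id="s2", bmi=np.nan)])
        v2 = pd.concat([visits, visits.assign(subject_id="s2")])
        d = build_design(b2.reset_index(drop=True), v2.reset_index(drop=True))
        assert d.n_dropped_incomplete == 1
        assert d.n_subjects == 1

    def test_collinear_design_fails_loudly(self, small_cohort):
        baselines, visits, _, _ = small_cohort
        b = baselines.copy()
        b["hba1c"] = b["age"]  # hba1c duplicates age -> rank deficiency
        d = build_design(b, visits, ModelSpec())
        with pytest.raises(SingularDesignError):
            fit_lmm(d)


def _dense_reml_loglik(design, G, tau2, sigma2):
    """Brute-force REML log-likelihood via the dense marginal covariance."""
    X, y, t = design.X, design.y, design.time
    n, p = X.shape
    subj = design.subject_index
    country_row = design.subject_country[subj]
    V = np.zeros((n, n))
    for i in range(design.n_subjects):
        idx = np.where(subj == i)[0]
        Z = np.column_stack([np.ones(idx.size), t[idx]])
        V[np.ix_(idx, idx)] += Z @ G @ Z.T
    for k in range(len(design.countries)):
        idx = np.where(country_row == k)[0]
        V[np.ix_(idx, idx)] += tau2
    V[np.diag_indices(n)] += sigma2
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    A = XtVi @ X
    beta = np.linalg.solve(A, XtVi @ y)
    r = y - X @ beta
    sign, ldV = np.linalg.slogdet(V)
    signA, ldA = np.linalg.slogdet(A)
    return (
        -0.5 * ((n - p) * np.log(2 * np.pi) + ldV + ldA + r @ Vi @ r),
        beta,
    )


@pytest.fixture(scope="module")
def tiny_design():
    cfg = well_specified_config(n_per_country=12, seed=21)
    b, v, _ = generate_cohort(cfg)
    return build_design(b, v)


class TestLikelihoodMachinery:
    def test_gls_matches_dense_weighted_least_squares(self, tiny_design):
        G = np.array([[150.0, -6.0], [-6.0, 3.0]])
        beta, _ = gls_fit(tiny_design, G, tau2=20.0, sigma2=30.0)
        _, beta_dense = _dense_reml_loglik(tiny_design, G, 20.0, 30.0)
        np.testing.assert_allclose(beta, beta_dense, rtol=1e-8)

    def test_loglik_matches_dense_formula(self, tiny_design):
        G = np.array([[150.0, -6.0], [-6.0, 3.0]])
        ll = loglikelihood(tiny_design, G, tau2=20.0, sigma2=30.0, method="reml")
        ll_dense, _ = _dense_reml_loglik(tiny_design, G, 20.0, 30.0)
        assert ll == pytest.approx(ll_dense, abs=1e-7)

    def test_reml_beats_other_variance_components(self, small_design, small_model):
        """The optimizer's solution is a maximum: nearby variance components
        give lower restricted likelihood."""
        m = small_model
        base = loglikelihood(small_design, m.G, m.tau2, m.sigma2, method="reml")
        assert base == pytest.approx(m.loglik, abs=1e-6)
        for fac in (0.8, 1.25):
            ll = loglikelihood(small_design, m.G * fac, m.tau2, m.sigma2 * fac)
            assert ll < base + 1e-8


def test_collapses_to_ols_when_no_random_effects():
    cfg = well_specified_config(
        n_per_country=150,
        seed=31,
        tau2=0.0,
        G=np.zeros((2, 2)),
        countries=(CountrySpec("solo", 0.0, (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)),),
    )
    b, v, _ = generate_cohort(cfg)
    d = build_design(b, v)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = fit_lmm(d)
    beta_ols, *_ = np.linalg.lstsq(d.X, d.y, rcond=None)
    XtX_inv = np.linalg.inv(d.X.T @ d.X)
    resid = d.y - d.X @ beta_ols
    s2 = resid @ resid / (d.n_obs - d.p)
    se_ols = np.sqrt(s2 * np.diag(XtX_inv))
    # boundary variance components: small relative to the noise variance
    assert m.G[0, 0] < 0.15 * cfg.sigma2 and m.G[1, 1] < 0.5
    assert m.tau2 == 0.0  # single country: fixed at zero
    np.testing.assert_array_less(np.abs(m.beta.to_numpy() - beta_ols), 2 * se_ols + 1e-9)


def test_fit_matches_statsmodels_on_single_country():
    """Live oracle: statsmodels MixedLM fits the same likelihood when there
    is no country level (random intercept+slope per subject only)."""
    smf = pytest.importorskip("statsmodels.formula.api")
    cfg = well_specified_config(
        n_per_country=60,
        seed=7,
        tau2=0.0,
        countries=(CountrySpec("solo", 0.0, (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)),),
    )
    b, v, _ = generate_cohort(cfg)
    d = build_design(b, v)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = fit_lmm(d)
    df = v.merge(b.drop(columns=["country"]), on="subject_id")
    df["time"] = df["time_years"]
    preds = list(PREDICTORS)
    rhs = " + ".join(preds + ["time"] + [f"{p}:time" for p in preds])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sm_fit = smf.mixedlm(
            f"egfr ~ {rhs}", df, groups=df["subject_id"], re_formula="~time"
        ).fit(reml=True, method="lbfgs")
    assert m.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
    assert m.sigma2 == pytest.approx(sm_fit.scale, rel=1e-3)
    np.testing.assert_allclose(m.G, sm_fit.cov_re.values, rtol=2e-3)


class TestR2Nakagawa:
    def test_no_random_effects_conditional_equals_marginal(self, small_model, small_design):
        m0 = dataclasses.replace(small_model, G=np.zeros((2, 2)), tau2=0.0)
        marg, cond = r2_nakagawa(m0, small_design)
        assert cond == pytest.approx(marg)

    def test_constant_fixed_prediction_gives_zero_marginal(self, small_model, small_design):
        beta0 = small_model.beta.copy()
        beta0[:] = 0.0
        beta0["intercept"] = 80.0
        m0 = dataclasses.replace(small_model, beta=beta0)
        marg, cond = r2_nakagawa(m0, small_design)
        assert marg == pytest.approx(0.0, abs=1e-12)

    def test_bounds_and_ordering(self, small_model, small_design):
        marg, cond = r2_nakagawa(small_model, small_design)
        assert 0.0 <= marg <= cond <= 1.0
        # sizable random effects: conditional far exceeds marginal
        assert cond > marg + 0.3


class TestStandardizedCoefficients:
    def test_binary_terms_unchanged_continuous_scaled(self, small_model, small_design):
        rep = standardized_coefficients(small_model, small_design)
        assert rep.loc["sex", "standardized_estimate"] == pytest.approx(
            rep.loc["sex", "estimate"]
        )
        sd_age = small_model.predictor_sds["age"]
        assert rep.loc["age", "standardized_estimate"] == pytest.approx(
            rep.loc["age", "estimate"] * sd_age
        )
        assert rep.loc["age:time", "standardized_estimate"] == pytest.approx(
            rep.loc["age:time", "estimate"] * sd_age
        )
        assert (rep["ci_low"] <= rep["standardized_estimate"]).all()
        assert (rep["standardized_estimate"] <= rep["ci_high"]).all()

    def test_zero_sd_predictor_raises(self, small_model, small_design):
        m = dataclasses.replace(
            small_model, predictor_sds={**small_model.predictor_sds, "age": 0.0}
        )
        with pytest.raises(DegeneratePredictorError):
            standardized_coefficients(m, small_design)


@pytest.fixture(scope="module")
def age_dominant_fit():
    """Simulation where age carries by far the largest standardized effect."""
    cfg = well_specified_config(n_per_country=120, seed=41)
    eff = dict(cfg.fixed_effects)
    for p in PREDICTORS:
        eff[p] = 0.0
        eff[f"{p}:time"] = 0.0
    eff["age"] = -1.2
    eff["hemoglobin"] = 0.5
    eff["age:time"] = -0.05
    cfg = dataclasses.replace(cfg, fixed_effects=eff)
    b, v, _ = generate_cohort(cfg)
    d = build_design(b, v)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_lmm(d), d


def test_dominant_predictor_has_largest_standardized_main(age_dominant_fit):
    model, design = age_dominant_fit
    rep = standardized_coefficients(model, design)
    mains = rep.loc[list(PREDICTORS), "standardized_estimate"].abs()
    assert mains.idxmax() == "age"


def test_drop_one_marginal_r2_ranks_dominant_predictor(age_dominant_fit):
    model, design = age_dominant_fit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d_age = drop_one_marginal_r2(model, design, "age")
        d_bmi = drop_one_marginal_r2(model, design, "bmi")
        d_lip = drop_one_marginal_r2(model, design, "med_lipid")
    assert d_age > max(d_bmi, d_lip)
    assert d_age > 0.05
    # null predictors: contribution ~ 0, and never meaningfully negative
    for delta in (d_bmi, d_lip):
        assert abs(delta) < 0.02
        assert delta >= -1e-3

    with pytest.raises(KeyError):
        drop_one_marginal_r2(model, design, "not_a_predictor")


def test_ml_and_reml_both_converge(tiny_design):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m_reml = fit_lmm(tiny_design, method="reml")
        m_ml = fit_lmm(tiny_design, method="ml")
    assert m_reml.converged and m_ml.converged
    # ML absorbs fixed-effect dof: residual variance estimate is smaller
    assert m_ml.sigma2 <= m_reml.sigma2 * 1.05


def test_r2_zero_total_variance_raises(small_model, small_design):
    m = dataclasses.replace(
        small_model,
        G=np.zeros((2, 2)),
        tau2=0.0,
        sigma2=0.0,
        beta=small_model.beta * 0.0,
    )
    with pytest.raises(NumericalError):
        r2_nakagawa(m, small_design)
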