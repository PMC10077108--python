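"""Empirical-Bayes updating, trajectory prediction, slope distributions."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from gfrtraj import (
    FittedModel,
    ModelSpec,
    batch_predict,
    posterior_from_residual,
    predict_trajectory,
    prob_rapid_progression,
    slope_distribution,
    update_random_effects,
)
from gfrtraj.cohort import PREDICTORS
from gfrtraj.prediction import SlopeDistribution


def _toy_model(sigma2=1.0, G=None, tau2=0.0, beta_time=-1.5):
    """Hand-built population model with zero covariate effects."""
    spec = ModelSpec()
    beta = pd.Series(0.0, index=spec.columns)
    beta["intercept"] = 90.0
    beta["time"] = beta_time
    p = len(beta)
    return FittedModel(
        beta=beta,
        beta_cov=np.zeros((p, p)),
        G=np.array([[16.0, -1.0], [-1.0, 1.0]]) if G is None else np.asarray(G),
        tau2=tau2,
        sigma2=sigma2,
        country_effects=pd.Series({"X": 2.0, "Y": -2.0}),
        loglik=0.0,
        converged=True,
        fit_method="reml",
        n_subjects=100,
        n_obs=500,
        predictor_sds={q: 1.0 for q in PREDICTORS},
        spec=spec,
    )


def _toy_subject(baseline_egfr, country="X"):
    row = {p: 0.0 for p in PREDICTORS}
    row.update(
        {"subject_id": "t1", "country": country, "baseline_egfr": baseline_egfr}
    )
    return pd.Series(row)


def _condition_numerically(G, s2, r):
    """Oracle: joint normal of (b0, b1, y0) conditioned on y0 = r."""
    joint = np.zeros((3, 3))
    joint[:2, :2] = G
    joint[:2, 2] = G[:, 0]
    joint[2, :2] = G[0, :]
    joint[2, 2] = G[0, 0] + s2
    mean = joint[:2, 2] * (r / joint[2, 2])
    cov = joint[:2, :2] - np.outer(joint[:2, 2], joint[2, :2]) / joint[2, 2]
    return mean, cov


class TestPosteriorFromResidual:
    def test_worked_example(self):
        """G=[[4,1],[1,.25]], s2=1, r=2 -> mean (1.6, 0.4)."""
        G = np.array([[4.0, 1.0], [1.0, 0.25]])
        mean, cov = posterior_from_residual(G, 1.0, 2.0)
        np.testing.assert_allclose(mean, [1.6, 0.4], rtol=1e-12)
        # conditioning never inflates marginal variances
        assert cov[0, 0] <= G[0, 0] and cov[1, 1] <= G[1, 1]
        # Loewner order: G - cov is PSD
        assert np.linalg.eigvalsh(G - cov).min() >= -1e-12

    def test_zero_residual_gives_prior_centered_posterior(self):
        G = np.array([[4.0, 1.0], [1.0, 0.25]])
        mean, _ = posterior_from_residual(G, 1.0, 0.0)
        np.testing.assert_allclose(mean, [0.0, 0.0])

    def test_uninformative_observation_limit(self):
        G = np.array([[4.0, 1.0], [1.0, 0.25]])
        mean, cov = posterior_from_residual(G, 1e9, 2.0)
        np.testing.assert_allclose(mean, [0.0, 0.0], atol=1e-6)
        np.testing.assert_allclose(cov, G, atol=1e-6)

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(
        a=st.floats(0.1, 20.0),
        c=st.floats(0.0, 5.0),
        rho=st.floats(-0.95, 0.95),
        s2=st.floats(1e-3, 1e3),
        r=st.floats(-50.0, 50.0),
    )
    def test_matches_numeric_gaussian_conditioning(self, a, c, rho, s2, r):
        G = np.array([[a * a, rho * a * c], [rho * a * c, c * c]])
        mean, cov = posterior_from_residual(G, s2, r)
        mean_o, cov_o = _condition_numerically(G, s2, r)
        np.testing.assert_allclose(mean, mean_o, atol=1e-8)
        np.testing.assert_allclose(cov, cov_o, atol=1e-8)

    def test_shrinkage_bound(self):
        G = np.array([[16.0, -1.0], [-1.0, 1.0]])
        for s2, r in [(1.0, 5.0), (4.0, -8.0), (0.5, 0.3)]:
            mean, _ = posterior_from_residual(G, s2, r)
            assert abs(mean[0]) <= abs(r) * G[0, 0] / (G[0, 0] + s2) + 1e-12


class TestUpdateRandomEffects:
    def test_known_country_uses_its_effect(self):
        m = _toy_model()
        post = update_random_effects(m, _toy_subject(94.0, "X"))
        # residual = 94 - 90 - 2 = 2
        expect_mean, _ = posterior_from_residual(m.G, m.sigma2, 2.0)
        np.testing.assert_allclose(post.mean, expect_mean)
        assert post.country_known and post.country_effect == 2.0

    def test_unknown_country_warns_and_widens_intercept_prior(self):
        m = _toy_model(tau2=9.0)
        with pytest.warns(UserWarning, match="not seen in training"):
            post = update_random_effects(m, _toy_subject(94.0, "Z"))
        assert not post.country_known
        prior = m.G.copy()
        prior[0, 0] += 9.0  # the persistent country effect joins the intercept
        expect_mean, expect_cov = posterior_from_residual(prior, m.sigma2, 4.0)
        np.testing.assert_allclose(post.mean, expect_mean)
        np.testing.assert_allclose(post.cov, expect_cov)

    def test_missing_baseline_raises(self):
        m = _toy_model()
        subj = _toy_subject(np.nan)
        with pytest.raises(ValueError, match="baseline_egfr"):
            update_random_effects(m, subj)


class TestPredictTrajectory:
    def test_noiseless_conditioning_reproduces_baseline(self):
        m = _toy_model(sigma2=0.0)
        subj = _toy_subject(97.0, "X")
        post = update_random_effects(m, subj)
        traj = predict_trajectory(m, subj, post, [0.0])
        assert traj["egfr_pred"].iloc[0] == pytest.approx(97.0)

    def test_reduces_to_fixed_line_without_random_effects(self):
        m = _toy_model()
        subj = _toy_subject(92.0, "X")
        post = update_random_effects(m, subj)
        post.mean[:] = 0.0
        traj = predict_trajectory(m, subj, post, [0, 1, 2, 3])
        np.testing.assert_allclose(
            traj["egfr_pred"], 92.0 - 1.5 * np.arange(4.0), rtol=1e-12
        )
        assert not traj["extrapolated"].any()

    def test_predictive_sd_grows_with_horizon(self):
        m = _toy_model()
        subj = _toy_subject(95.0, "X")
        post = update_random_effects(m, subj)
        traj = predict_trajectory(m, subj, post, [1, 3, 5])
        assert traj["pred_sd"].is_monotonic_increasing

    def test_beyond_horizon_flagged_with_warning(self):
        m = _toy_model()
        subj = _toy_subject(95.0, "X")
        post = update_random_effects(m, subj)
        with pytest.warns(UserWarning, match="extrapolation"):
            traj = predict_trajectory(m, subj, post, [4, 6])
        assert list(traj["extrapolated"]) == [False, True]

    def test_fixed_uncertainty_adds_variance(self):
        m = _toy_model()
        m = dataclasses.replace(m, beta_cov=np.eye(len(m.beta)) * 0.01)
        subj = _toy_subject(95.0, "X")
        post = update_random_effects(m, subj)
        plain = predict_trajectory(m, subj, post, [1, 2])
        wide = predict_trajectory(m, subj, post, [1, 2], include_fixed_uncertainty=True)
        assert (wide["pred_sd"] > plain["pred_sd"]).all()


class TestSlopeDistribution:
    def test_reduces_to_time_effect(self):
        m = _toy_model()
        subj = _toy_subject(92.0, "X")
        post = update_random_effects(m, subj)
        post.mean[:] = 0.0
        s = slope_distribution(m, subj, post)
        assert s.mean == pytest.approx(m.beta["time"])

    def test_equals_difference_quotient_of_trajectory(self):
        m = _toy_model()
        subj = _toy_subject(99.0, "Y")
        post = update_random_effects(m, subj)
        s = slope_distribution(m, subj, post)
        traj = predict_trajectory(m, subj, post, [1.0, 3.5])
        dq = (traj["egfr_pred"].iloc[1] - traj["egfr_pred"].iloc[0]) / 2.5
        assert s.mean == pytest.approx(dq, rel=1e-12)

    def test_variance_components_recorded(self):
        m = _toy_model()
        subj = _toy_subject(80.0, "X")
        post = update_random_effects(m, subj)
        s = slope_distribution(m, subj, post)
        assert s.sd == pytest.approx(np.sqrt(post.cov[1, 1]))
        assert s.mean == pytest.approx(s.fixed_part + s.random_part)


class TestProbRapidProgression:
    def test_half_at_threshold(self):
        assert prob_rapid_progression(
            SlopeDistribution(mean=-3.0, sd=1.7, fixed_part=-3.0, random_part=0.0)
        ) == pytest.approx(0.5)

    def test_phi_of_two(self):
        p = prob_rapid_progression(
            SlopeDistribution(mean=-5.0, sd=1.0, fixed_part=-5.0, random_part=0.0)
        )
        assert p == pytest.approx(norm.cdf(2.0), rel=1e-12)

    def test_monotone_decreasing_in_mean(self):
        probs = [
            prob_rapid_progression(
                SlopeDistribution(mean=mu, sd=1.5, fixed_part=mu, random_part=0.0)
            )
            for mu in np.linspace(-6, 0, 13)
        ]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_degenerate_sd_indicator(self):
        mk = lambda mu: SlopeDistribution(mean=mu, sd=0.0, fixed_part=mu, random_part=0.0)
        assert prob_rapid_progression(mk(-4.0)) == 1.0
        assert prob_rapid_progression(mk(-2.0)) == 0.0


class TestBatchPredict:
    def test_matches_single_subject_path(self, small_model, small_cohort):
        baselines, visits, _, _ = small_cohort
        out = batch_predict(small_model, baselines, visits)
        subj = baselines.iloc[3]
        post = update_random_effects(small_model, subj)
        sv = visits[visits["subject_id"] == subj["subject_id"]]
        traj = predict_trajectory(
            small_model, subj, post, sv["time_years"].to_numpy(), horizon=10.0
        )
        got = out[out["subject_id"] == subj["subject_id"]].sort_values("time_years")
        np.testing.assert_allclose(
            got["predicted"].to_numpy(), traj["egfr_pred"].to_numpy(), rtol=1e-10
        )

    def test_invariant_to_row_order_and_unrelated_subjects(self, small_model, small_cohort):
        baselines, visits, _, _ = small_cohort
        out1 = batch_predict(small_model, baselines, visits)
        shuffled = baselines.sample(frac=1.0, random_state=1)
        out2 = batch_predict(small_model, shuffled, visits)
        merged = out1.merge(
            out2, on=["subject_id", "time_years"], suffixes=("_a", "_b")
        )
        assert len(merged) == len(out1)
        np.testing.assert_allclose(merged["predicted_a"], merged["predicted_b"])

    def test_updating_reduces_error(self, small_model, small_cohort):
        baselines, visits, _, _ = small_cohort
        out = batch_predict(small_model, baselines, visits)
        follow = out[out["time_years"] > 0.5]
        rmse_up = np.sqrt(np.mean((follow["observed"] - follow["predicted"]) ** 2))
        rmse_raw = np.sqrt(
            np.mean((follow["observed"] - follow["predicted_no_update"]) ** 2)
        )
        assert rmse_up < rmse_raw
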