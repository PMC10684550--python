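"""Mixed proportional-odds model: likelihood, fitting, ORs, cross-checks."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from noctglu.ordinal import (
    MixedOrdinalRegression,
    cross_check,
    fit_exposure,
    marginal_loglik,
    odds_ratio,
)
from noctglu.simulate import SyntheticConfig, generate_cohort


def simulate_ordinal(n, betas, cutpoints, sigma_u, n_groups, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({
        "x1": rng.normal(size=n),
        "x2": rng.binomial(1, 0.5, size=n).astype(float),
    }).iloc[:, : len(betas)]
    groups = rng.integers(0, n_groups, size=n)
    u = rng.normal(0, sigma_u, size=n_groups)
    eta = X.to_numpy() @ np.asarray(betas) + u[groups]
    cum = expit(np.asarray(cutpoints)[None, :] - eta[:, None])
    y = (rng.random(n)[:, None] > cum).sum(axis=1) + 1
    return X, y, groups


@pytest.fixture(scope="module")
def tiny_fixture():
    """3 groups x 4 observations, all five categories forced to appear."""
    X = pd.DataFrame({"x": [0.2, -1.0, 0.5, 1.4, 0.0, -0.3, 2.0, -2.0, 0.7, 1.0, -0.5, 0.1]})
    y = np.array([1, 2, 3, 4, 5, 3, 2, 4, 1, 5, 3, 2])
    groups = np.repeat([0, 1, 2], 4)
    return X, y, groups


def dense_marginal_loglik(X, y, groups, betas, cutpoints, sigma_u, n_points=10_000):
    """Independent brute-force oracle: trapezoid integration over u."""
    Xa = X.to_numpy(dtype=float)
    y = np.asarray(y)
    cats = np.unique(y)
    codes = np.searchsorted(cats, y)
    khi = np.concatenate([cutpoints, [np.inf]])
    klo = np.concatenate([[-np.inf], cutpoints])
    eta = Xa @ np.asarray(betas)
    u = np.linspace(-10 * sigma_u, 10 * sigma_u, n_points)
    phi = np.exp(-(u**2) / (2 * sigma_u**2)) / (sigma_u * np.sqrt(2 * np.pi))
    total = 0.0
    for g in np.unique(groups):
        sel = np.asarray(groups) == g
        p = expit(khi[codes[sel]][:, None] - eta[sel][:, None] - u[None, :]) - expit(
            klo[codes[sel]][:, None] - eta[sel][:, None] - u[None, :]
        )
        lik = np.prod(p, axis=0) * phi
        total += np.log(np.trapezoid(lik, u))
    return total


class TestLikelihood:
    def test_quadrature_matches_bruteforce_integration(self, tiny_fixture):
        X, y, groups = tiny_fixture
        betas = np.array([0.4])
        cutpoints = np.array([-1.2, -0.3, 0.5, 1.6])
        for sigma in (0.3, 0.8, 1.5):
            ll_q = marginal_loglik(X, y, groups, betas, cutpoints, sigma, n_quad=15)
            ll_d = dense_marginal_loglik(X, y, groups, betas, cutpoints, sigma)
            assert ll_q == pytest.approx(ll_d, rel=1e-6)

    def test_quadrature_refinement_stable(self, default_cohort_table):
        fit = fit_exposure(default_cohort_table, "nh39_presence", n_quad=15)
        X = pd.DataFrame({
            "x": default_cohort_table["nh39_present"].astype(float),
            "age": default_cohort_table["age"].astype(float),
            "sexf": default_cohort_table["sex_female"].astype(float),
        })
        args = (X, default_cohort_table["sleep_score"], default_cohort_table["participant_id"],
                fit.coef_, fit.cutpoints_, fit.sigma_u_)
        ll15 = marginal_loglik(*args, n_quad=15)
        ll30 = marginal_loglik(*args, n_quad=30)
        assert ll30 == pytest.approx(ll15, rel=1e-6)

    def test_probabilities_sum_to_one_and_cumulative_monotone(self, tiny_fixture):
        X, y, groups = tiny_fixture
        m = MixedOrdinalRegression(n_quad=7).fit(X, y, groups)
        probs = m.predict_proba(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-10)
        assert (probs >= 0).all()
        assert np.all(np.diff(np.cumsum(probs, axis=1), axis=1) >= -1e-12)

    def test_location_shift_invariance(self, tiny_fixture):
        # adding c to all cutpoints and a constant covariate with coef c
        # leaves the likelihood unchanged
        X, y, groups = tiny_fixture
        betas = np.array([0.4])
        cutpoints = np.array([-1.2, -0.3, 0.5, 1.6])
        c = 0.9
        X2 = X.assign(const=1.0)
        ll1 = marginal_loglik(X, y, groups, betas, cutpoints, 0.7)
        ll2 = marginal_loglik(X2, y, groups, np.append(betas, c), cutpoints + c, 0.7)
        assert ll2 == pytest.approx(ll1, rel=1e-12)


class TestFitting:
    def test_saturated_intercept_only_matches_empirical_logits(self):
        # sigma_u = 0, no covariates: MLE cutpoints are the empirical
        # cumulative logits
        rng = np.random.default_rng(4)
        y = rng.choice([1, 2, 3, 4, 5], size=2000, p=[0.1, 0.2, 0.35, 0.25, 0.1])
        X = pd.DataFrame(index=range(len(y)))
        m = MixedOrdinalRegression(random_intercept=False, ftol=1e-13, gtol=1e-8).fit(X, y)
        freq = np.bincount(y - 1, minlength=5) / len(y)
        cum = np.cumsum(freq)[:-1]
        expected = np.log(cum / (1 - cum))
        np.testing.assert_allclose(m.cutpoints_, expected, atol=1e-4)

    def test_recovers_betas_at_large_n(self):
        X, y, groups = simulate_ordinal(
            8000, [0.8, -0.5], [-1.5, -0.5, 0.5, 1.5], 0.7, 200, seed=9
        )
        m = MixedOrdinalRegression(n_quad=7).fit(X, y, groups)
        assert m.converged_
        np.testing.assert_allclose(m.coef_, [0.8, -0.5], atol=0.1)
        assert m.sigma_u_ == pytest.approx(0.7, abs=0.12)
        assert np.all(np.diff(m.cutpoints_) > 0)

    def test_standard_errors_match_loglik_curvature_scale(self):
        X, y, groups = simulate_ordinal(
            1500, [0.6], [-1.0, 0.0, 1.0, 2.0], 0.5, 60, seed=2
        )
        m = MixedOrdinalRegression(n_quad=7).fit(X, y, groups)
        assert 0.0 < m.se_coef_[0] < 0.2
        assert np.isfinite(m.se_cutpoints_).all()

    def test_singular_exposure_rejected(self, tiny_fixture):
        X, y, groups = tiny_fixture
        X = X.assign(flat=1.0)
        with pytest.raises(ValueError, match="zero variance"):
            MixedOrdinalRegression().fit(X, y, groups)

    def test_single_category_rejected(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ValueError, match="categories"):
            MixedOrdinalRegression().fit(X, np.ones(10, int), np.arange(10) % 2)

    def test_groups_required_for_random_intercept(self, tiny_fixture):
        X, y, _ = tiny_fixture
        with pytest.raises(ValueError, match="groups"):
            MixedOrdinalRegression().fit(X, y)

    def test_sklearn_param_interface(self):
        m = MixedOrdinalRegression(n_quad=5)
        assert m.get_params()["n_quad"] == 5
        m.set_params(n_quad=9)
        assert m.n_quad == 9


class TestOddsRatio:
    def _fitted_stub(self, beta, se):
        m = MixedOrdinalRegression()
        m.coef_ = np.array([beta])
        m.se_coef_ = np.array([se])
        m.feature_names_in_ = np.array(["x"], dtype=object)
        m.converged_ = True
        return m

    def test_zero_beta_gives_unit_or_with_symmetric_ci(self):
        or_, lo, hi = odds_ratio(self._fitted_stub(0.0, 0.2), "x")
        assert or_ == 1.0
        assert math.log(lo) == pytest.approx(-math.log(hi))

    def test_degenerate_se(self):
        or_, lo, hi = odds_ratio(self._fitted_stub(math.log(0.5), 0.0), "x")
        assert or_ == lo == hi == pytest.approx(0.5)

    def test_duration_scale_arithmetic(self):
        # beta -0.0398 per 15-min step, SE 0.0156 -> OR 0.961 (0.932, 0.990)
        or_, lo, hi = odds_ratio(self._fitted_stub(-0.0398, 0.0156), "x")
        assert or_ == pytest.approx(0.961, abs=5e-4)
        assert lo == pytest.approx(0.932, abs=5e-4)
        assert hi == pytest.approx(0.9908, abs=5e-4)

    def test_unknown_term_raises(self):
        with pytest.raises(KeyError, match="unknown term"):
            odds_ratio(self._fitted_stub(0.0, 0.1), "nope")

    def test_unconverged_fit_refused(self):
        m = self._fitted_stub(0.0, 0.1)
        m.converged_ = False
        with pytest.raises(ValueError, match="converged"):
            odds_ratio(m, "x")


@pytest.fixture(scope="module")
def fitted():
    cfg = SyntheticConfig(n_participants=15, nights_per_participant=20)
    table = generate_cohort(cfg, seed=6, build_traces=False).night_table
    X = pd.DataFrame({
        "nh": table["nh39_present"].astype(float),
        "age": table["age"].astype(float),
        "sexf": table["sex_female"].astype(float),
    })
    y = table["sleep_score"].to_numpy()
    groups = table["participant_id"].to_numpy()
    model = MixedOrdinalRegression(n_quad=15).fit(X, y, groups)
    return model, X, y, groups


class TestCrossCheck:
    def test_agrees_with_independent_implementations(self, fitted):
        model, X, y, groups = fitted
        report = cross_check(model, X, y, groups)
        assert report["fixed_effects"]["max_abs_beta_diff"] < 1e-3
        assert report["fixed_effects"]["max_abs_cutpoint_diff"] < 1e-3
        assert report["integration"]["ok"]
        assert report["passed"]

    def test_perturbed_fit_is_flagged(self, fitted):
        model, X, y, groups = fitted
        bad = MixedOrdinalRegression(n_quad=model.n_quad)
        for attr in ("coef_", "cutpoints_", "sigma_u_", "se_coef_", "converged_",
                     "feature_names_in_", "n_obs_", "n_groups_", "loglik_"):
            setattr(bad, attr, getattr(model, attr))
        bad.coef_ = model.coef_ + np.array([0.5, 0.0, 0.0])
        report = cross_check(bad, X, y, groups)
        assert not report["stationarity"]["ok"]
        assert not report["passed"]
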