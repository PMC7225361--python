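"""Two-stage GRS test: adjustment, penalized weights, score, interaction GLM."""

import numpy as np
import pytest
import statsmodels.api as sm
from sklearn.linear_model import ElasticNet, Ridge

from grsgxe import (CohortTable, DegenerateGRSError,
                    InestimableInteractionError, SingularDesignError,
                    adjust_covariates, build_grs, fit_ols_weights,
                    fit_penalized_weights, run_grs_pipeline)
from grsgxe import test_grs_by_e as grs_by_e  # avoid pytest collecting it
from grsgxe.grs_gxe import PenalizedWeights, _lambda_grid

from conftest import make_panel, make_single_snp_cohort


def _gaussian_cohort(y, e=None, covars=None):
    n = len(y)
    return CohortTable(y=y,
                       exposure=e if e is not None else np.zeros(n),
                       covariates=covars if covars is not None
                       else np.zeros((n, 0)),
                       family="gaussian")


class TestAdjustCovariates:
    def test_intercept_only_gaussian(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        eps = adjust_covariates(_gaussian_cohort(y))
        np.testing.assert_allclose(eps.residuals, y - y.mean(), atol=1e-12)

    def test_intercept_only_binomial(self):
        y = np.array([1.0, 0.0, 0.0, 1.0, 0.0])
        c = CohortTable(y=y, exposure=np.zeros(5),
                        covariates=np.zeros((5, 0)), family="binomial")
        eps = adjust_covariates(c)
        np.testing.assert_allclose(eps.residuals, y - 0.4, atol=1e-8)
        assert np.all(np.abs(eps.residuals) < 1.0)

    def test_residuals_orthogonal_to_covariate(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = 1.0 + 2.0 * x + rng.normal(size=200)
        eps = adjust_covariates(_gaussian_cohort(y, covars=x[:, None]))
        assert abs(eps.residuals @ x) < 1e-8
        assert abs(eps.residuals.sum()) < 1e-8


class TestOLSWeights:
    def test_orthogonal_design_projection(self):
        # orthonormal-ish columns: slope_j = <G_j, eps> / <G_j, G_j>
        d = np.array([[0, 0], [2, 0], [0, 2], [2, 2.0],
                      [0, 0], [2, 0], [0, 2], [2, 2.0]])
        panel = make_panel(d)
        y = np.array([1, 2, 0, 4, 1.0, 2, 0, 4])
        eps = adjust_covariates(_gaussian_cohort(y))
        w = fit_ols_weights(eps, panel)
        X = np.column_stack([np.ones(8), d])
        expect = np.linalg.lstsq(X, eps.residuals, rcond=None)[0]
        np.testing.assert_allclose(w.beta_hat, expect, atol=1e-10)

    def test_duplicated_column_is_singular(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.3, 30).astype(float)
        panel = make_panel(np.column_stack([g, g]))
        eps = adjust_covariates(_gaussian_cohort(rng.normal(size=30)))
        with pytest.raises(SingularDesignError):
            fit_ols_weights(eps, panel)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.4, size=(50, 5)).astype(float)
        panel = make_panel(d)
        y = rng.normal(size=50)
        eps = adjust_covariates(_gaussian_cohort(y))
        w = fit_ols_weights(eps, panel)
        X = np.column_stack([np.ones(50), d])
        beta = np.linalg.solve(X.T @ X, X.T @ eps.residuals)
        np.testing.assert_allclose(w.beta_hat, beta, atol=1e-10)


class TestPenalizedWeights:
    @pytest.fixture(scope="class")
    def design(self, sim_panel, sim_cohort):
        return sim_panel, adjust_covariates(sim_cohort.cohort)

    def test_ridge_closed_form_at_fixed_lambda(self, design):
        panel, eps = design
        G = panel.imputed_dosages()
        Gc = G - G.mean(0)
        yc = eps.residuals - eps.residuals.mean()
        lam = 7.3
        from grsgxe.grs_gxe import _ridge_path
        b = _ridge_path(Gc, yc, np.array([lam]))[:, 0]
        expect = np.linalg.solve(Gc.T @ Gc + lam * np.eye(Gc.shape[1]),
                                 Gc.T @ yc)
        np.testing.assert_allclose(b, expect, atol=1e-6)
        # and against an independent solver on the same objective
        sk = Ridge(alpha=lam, fit_intercept=True).fit(G, eps.residuals).coef_
        np.testing.assert_allclose(b, sk, atol=1e-6)

    def test_ridge_ols_limit(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.4, size=(200, 10)).astype(float)
        panel = make_panel(d)
        y = rng.normal(size=200)
        eps = adjust_covariates(_gaussian_cohort(y))
        ols = fit_ols_weights(eps, panel)
        Gc = d - d.mean(0)
        yc = eps.residuals - eps.residuals.mean()
        from grsgxe.grs_gxe import _ridge_path
        near0 = _ridge_path(Gc, yc, np.array([1e-8]))[:, 0]
        np.testing.assert_allclose(near0, ols.slopes, atol=1e-4)

    def test_large_lambda_collapses_to_intercept(self, design):
        panel, eps = design
        Gc = panel.imputed_dosages() - panel.imputed_dosages().mean(0)
        yc = eps.residuals - eps.residuals.mean()
        from grsgxe.grs_gxe import _ridge_path
        b = _ridge_path(Gc, yc, np.array([1e12]))[:, 0]
        assert np.abs(b).max() < 1e-6

    def test_lasso_lambda_max_nulls_all_slopes(self, design):
        panel, eps = design
        G = panel.imputed_dosages()
        Gc = G - G.mean(0)
        yc = eps.residuals - eps.residuals.mean()
        lmax = _lambda_grid(Gc, yc, "lasso", 1.0)[0]
        m = ElasticNet(alpha=lmax / (2 * G.shape[0]), l1_ratio=1.0,
                       fit_intercept=True).fit(G, eps.residuals)
        assert np.all(m.coef_ == 0.0)
        # just below lambda_max something enters
        m2 = ElasticNet(alpha=0.9 * lmax / (2 * G.shape[0]), l1_ratio=1.0,
                        fit_intercept=True, tol=1e-8).fit(G, eps.residuals)
        assert np.any(m2.coef_ != 0.0)

    def test_cv_lambda_minimizes_path(self, design):
        panel, eps = design
        w = fit_penalized_weights(eps, panel, "ridge", seed=4)
        lams, mses = w.cv_mse_path[:, 0], w.cv_mse_path[:, 1]
        assert w.lambda_ == lams[np.argmin(mses)]

    def test_deterministic_given_seed(self, design):
        panel, eps = design
        a = fit_penalized_weights(eps, panel, "lasso", seed=5)
        b = fit_penalized_weights(eps, panel, "lasso", seed=5)
        np.testing.assert_array_equal(a.beta_hat, b.beta_hat)
        assert a.lambda_ == b.lambda_

    def test_constant_residual_warns_and_zeroes(self, small_panel):
        eps = adjust_covariates(_gaussian_cohort(np.full(5, 2.0)))
        with pytest.warns(UserWarning, match="constant"):
            w = fit_penalized_weights(eps, small_panel, "ridge", folds=5,
                                      seed=0)
        assert np.all(w.slopes == 0.0)

    def test_folds_exceeding_n_error(self, small_panel):
        eps = adjust_covariates(_gaussian_cohort(np.arange(5.0)))
        with pytest.raises(ValueError, match="folds"):
            fit_penalized_weights(eps, small_panel, "ridge", folds=10, seed=0)


class TestGRSAndInteraction:
    def test_single_snp_grs_is_zscored_dosage(self):
        rng = np.random.default_rng(6)
        g = rng.binomial(2, 0.3, 100).astype(float)
        panel = make_panel(g[:, None])
        w = PenalizedWeights(beta_hat=np.array([0.0, 1.0]), method="ols",
                             lambda_=0.0, alpha_mix=0.0)
        grs = build_grs(panel, w)
        np.testing.assert_allclose(
            grs.standardized, (g - g.mean()) / g.std(ddof=1), atol=1e-12)
        assert grs.standardized.mean() == pytest.approx(0.0, abs=1e-8)
        assert grs.standardized.std(ddof=1) == pytest.approx(1.0, abs=1e-8)

    def test_zero_weights_degenerate(self, small_panel):
        w = PenalizedWeights(beta_hat=np.zeros(4), method="lasso",
                             lambda_=1.0, alpha_mix=1.0)
        with pytest.raises(DegenerateGRSError):
            build_grs(small_panel, w)

    def test_interaction_direction_labels(self):
        rng = np.random.default_rng(7)
        n = 2000
        g = rng.binomial(2, 0.3, n).astype(float)
        e = rng.binomial(1, 0.5, n).astype(float)
        y = 0.3 * g + 0.3 * e - 0.4 * g * e + rng.standard_normal(n)
        cohort = _gaussian_cohort(y, e=e)
        panel = make_panel(g[:, None])
        w = PenalizedWeights(beta_hat=np.array([0.0, 1.0]), method="ols",
                             lambda_=0.0, alpha_mix=0.0)
        res = grs_by_e(cohort, build_grs(panel, w))
        assert res.p_value < 0.05
        assert res.gamma_int_hat < 0
        assert res.direction == "attenuation"

    def test_constant_exposure_inestimable(self, sim_panel, sim_cohort):
        c = sim_cohort.cohort
        const = CohortTable(y=c.y, exposure=np.ones(c.n),
                            covariates=c.covariates, family="gaussian")
        w = PenalizedWeights(
            beta_hat=np.ones(sim_panel.n_variants + 1), method="ols",
            lambda_=0.0, alpha_mix=0.0)
        with pytest.raises(InestimableInteractionError):
            grs_by_e(const, build_grs(sim_panel, w))

    def test_matches_statsmodels_wald(self, sim_panel, sim_cohort):
        c = sim_cohort.cohort
        res = run_grs_pipeline(c, sim_panel, "ridge", seed=8)
        eps = adjust_covariates(c)
        w = fit_penalized_weights(eps, sim_panel, "ridge", seed=8)
        z = build_grs(sim_panel, w).standardized
        X = np.column_stack([np.ones(c.n), z, c.exposure, z * c.exposure])
        sm_p = sm.OLS(c.y, X).fit().pvalues[3]
        assert res.p_value == pytest.approx(sm_p, rel=1e-10)


class TestPipelineProperties:
    def test_single_snp_reduces_to_wald_interaction(self):
        cohort, panel = make_single_snp_cohort(seed=9)
        res = run_grs_pipeline(cohort, panel, "ridge", seed=10)
        g, e = panel.dosages[:, 0], cohort.exposure
        X = np.column_stack([np.ones(cohort.n), g, e, g * e])
        expect = sm.OLS(cohort.y, X).fit().pvalues[3]
        assert res.p_value == pytest.approx(expect, rel=1e-8)

    def test_allele_flip_invariance(self, sim_panel, sim_cohort):
        c = sim_cohort.cohort
        base = run_grs_pipeline(c, sim_panel, "ridge", seed=11)
        flipped = sim_panel.dosages.copy()
        flip_cols = [0, 5, 17]
        flipped[:, flip_cols] = 2.0 - flipped[:, flip_cols]
        panel2 = make_panel(flipped)
        other = run_grs_pipeline(c, panel2, "ridge", seed=11)
        assert other.p_value == pytest.approx(base.p_value, abs=1e-6)
        assert other.gamma_int_hat == pytest.approx(base.gamma_int_hat,
                                                    abs=1e-6)

    def test_deterministic_end_to_end(self, sim_panel, sim_cohort):
        c = sim_cohort.cohort
        a = run_grs_pipeline(c, sim_panel, "enet", seed=12)
        b = run_grs_pipeline(c, sim_panel, "enet", seed=12)
        assert (a.p_value, a.gamma_int_hat, a.lambda_) == \
            (b.p_value, b.gamma_int_hat, b.lambda_)

    def test_strong_attenuation_recovered(self):
        # inflate scenario-9-style effects: the label must come out right
        from grsgxe import (GenotypeSimConfig, assign_causal_snps,
                            get_scenario, sample_effects, sample_exposure,
                            simulate_ld_genotypes, simulate_trait)
        panel = simulate_ld_genotypes(GenotypeSimConfig(2000, 48, seed=13))
        causal = assign_causal_snps(panel, 4, seed=14)
        eff = sample_effects(get_scenario(9), "gaussian", seed=15,
                             effect_scale=4.0)
        e = sample_exposure("binary", 2000, 0.5, seed=16)
        sim = simulate_trait(panel, causal, eff, e, seed=17)
        res = run_grs_pipeline(sim.cohort, panel, "ridge", seed=18)
        assert res.direction == "attenuation"
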