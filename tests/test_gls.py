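import numpy as np
import pandas as pd
import pytest
from scipy import stats

from setmean import (build_design, fit_mvlm, gls_bootstrap, gls_fit,
                     gls_permutation, mean_effect, standardize_columns)
from setmean.gls import HetCSParams, _beta_step, hetcs_loglik

from conftest import make_dataset, simple_design


def hetcs_data(rng, n, m, rho, sigma=None, beta=0.25, n_nuisance=1):
    sigma = np.ones(m) if sigma is None else np.asarray(sigma)
    R = np.full((m, m), rho)
    np.fill_diagonal(R, 1.0)
    S = R * np.outer(sigma, sigma)
    cov = pd.DataFrame({f"x{k}": rng.normal(size=n) for k in range(n_nuisance)}
                       | {"foc": rng.normal(size=n)})
    Y = rng.standard_normal((n, m)) @ np.linalg.cholesky(S).T
    if beta:
        Y = Y + beta * cov["foc"].to_numpy()[:, None]
    return Y, build_design(cov, ["foc"])


class TestHetCSParams:
    def test_rho_range_enforced(self):
        with pytest.raises(ValueError):
            HetCSParams(rho=-0.6, sigma=np.ones(3))  # below -1/(m-1)
        p = HetCSParams(rho=0.4, sigma=np.array([1.0, 2.0, 0.5]))
        assert np.linalg.eigvalsh(p.covariance()).min() > 0

    def test_loglik_matches_dense_gaussian(self, rng):
        """Closed-form het-CS likelihood equals the generic multivariate
        normal log-density summed over subjects."""
        E = rng.normal(size=(9, 4))
        params = HetCSParams(rho=0.35, sigma=np.array([0.7, 1.1, 1.6, 0.9]))
        expected = stats.multivariate_normal(
            mean=np.zeros(4), cov=params.covariance()).logpdf(E).sum()
        assert hetcs_loglik(E, params.sigma, params.rho) == pytest.approx(
            expected, rel=1e-12)


class TestGLSFit:
    def test_identity_covariance_beta_step_equals_ols_mean_effect(self, rng):
        """With Sigma = I (homoscedastic exchangeable weights) the stacked
        long-format OLS focal estimate equals the wide-format mean effect
        exactly."""
        Y, design = make_dataset(rng, n=40, m=5, beta=0.3)
        full = design.full_matrix()
        names = design.full_names()
        C = full[:, [j for j in range(full.shape[1]) if names[j] != "intercept"]]
        beta, _, _ = _beta_step(Y, C, np.eye(5))
        betabar = mean_effect(fit_mvlm(Y, design), "eud").betabar
        assert beta[-1] == pytest.approx(betabar, abs=1e-10)

    def test_independent_data_close_to_ols(self, rng):
        Y, design = hetcs_data(rng, n=250, m=5, rho=0.0)
        fit = gls_fit(Y, design)
        betabar = mean_effect(fit_mvlm(Y, design), "foc").betabar
        assert fit.coef("foc") == pytest.approx(betabar, abs=0.02)
        # model SE close to the analytic OLS SE of the mean effect
        assert abs(fit.params.rho) < 0.05

    def test_parameter_recovery_and_monotone_loglik(self, rng):
        sigma = rng.uniform(0.5, 2.0, 6)
        Y, design = hetcs_data(rng, n=300, m=6, rho=0.3, sigma=sigma)
        fit = gls_fit(Y, design)
        assert fit.converged
        assert fit.params.rho == pytest.approx(0.3, abs=0.05)
        np.testing.assert_allclose(fit.params.sigma, sigma, rtol=0.10)
        ll = np.array(fit.loglik_path)
        assert np.all(np.diff(ll) >= -1e-7)

    def test_unstructured_recovers_covariance(self, rng):
        m = 3
        S = np.array([[1.0, 0.5, 0.1], [0.5, 1.2, -0.2], [0.1, -0.2, 0.8]])
        n = 1200
        cov = pd.DataFrame({"foc": rng.normal(size=n)})
        Y = rng.standard_normal((n, m)) @ np.linalg.cholesky(S).T
        design = build_design(cov, ["foc"])
        fit = gls_fit(Y, design, structure="unstructured")
        assert fit.converged
        np.testing.assert_allclose(fit.params, S, atol=0.12)

    def test_unstructured_refuses_m_at_least_n(self, rng):
        Y, design = hetcs_data(rng, n=5, m=6, rho=0.0, n_nuisance=0)
        with pytest.raises(ValueError, match="n > m"):
            gls_fit(Y, design, structure="unstructured")

    def test_model_se_matches_empirical_sd_under_true_hetcs(self, rng):
        """Correct specification: model-based SE tracks the sampling SD;
        misspecified (factor) correlation: model SE understates it."""
        n_rep = 300
        est, ses = [], []
        for _ in range(n_rep):
            Y, design = hetcs_data(rng, n=60, m=5, rho=0.4, beta=0.0)
            fit = gls_fit(Y, design)
            est.append(fit.coef("foc"))
            ses.append(fit.stderr("foc"))
        ratio = np.mean(ses) / np.std(est, ddof=1)
        assert abs(ratio - 1.0) < 0.15

    def test_model_se_understates_sd_under_factor_correlation(self, rng):
        """Non-exchangeable (factor-model) gene covariance at a realistic
        set size: the het-CS model SE runs below the true sampling SD —
        the downward SE bias behind the inflated GLS Type I error."""
        from setmean import SyntheticCovarianceSpec, make_covariances
        _, S = make_covariances(SyntheticCovarianceSpec(m_genes=30), seed=4)
        L = np.linalg.cholesky(S)
        n, n_rep = 80, 250
        est, ses = [], []
        for _ in range(n_rep):
            cov = pd.DataFrame({"foc": rng.normal(size=n)})
            Y = rng.standard_normal((n, 30)) @ L.T
            fit = gls_fit(Y, build_design(cov, ["foc"]))
            est.append(fit.coef("foc"))
            ses.append(fit.stderr("foc"))
        assert np.mean(ses) < 0.92 * np.std(est, ddof=1)


class TestGLSBootstrap:
    def test_deterministic_under_seed(self, rng):
        Y, design = hetcs_data(rng, n=40, m=3, rho=0.2)
        s1 = gls_bootstrap(Y, design, "foc", n_boot=8, seed=123)
        s2 = gls_bootstrap(Y, design, "foc", n_boot=8, seed=123)
        np.testing.assert_array_equal(s1.coefficients, s2.coefficients)
        assert s1.se == s2.se

    def test_iteration_zero_is_observed_fit(self, rng):
        Y, design = hetcs_data(rng, n=40, m=3, rho=0.2)
        s = gls_bootstrap(Y, design, "foc", n_boot=5, seed=0)
        fit = gls_fit(standardize_columns(Y), design)
        assert s.coefficients[0] == pytest.approx(fit.coef("foc"), abs=1e-10)

    def test_independent_data_se_near_analytic_ols_se(self, rng):
        n, m = 150, 4
        Y, design = hetcs_data(rng, n=n, m=m, rho=0.0, beta=0.1)
        s = gls_bootstrap(Y, design, "foc", n_boot=120, seed=7)
        # analytic OLS SE of the mean effect with independent unit-variance
        # genes: sd(mean of m coefficients) = 1/sqrt(n*m) x 1/||z~|| scaling
        fit = fit_mvlm(standardize_columns(Y), design)
        k = design.focal_index("foc")
        per_gene_var = fit.xtx_inv[k, k] * fit.rss / fit.df_resid
        analytic = float(np.sqrt(per_gene_var.mean() / m))
        assert s.se == pytest.approx(analytic, rel=0.20)

    def test_rare_binary_covariate_dropped_not_fatal(self, rng):
        n = 40
        smoke = np.zeros(n)
        smoke[:2] = 1.0  # rare level: some resamples will lack cases
        cov = pd.DataFrame({"smoke": smoke, "foc": rng.normal(size=n)})
        Y = rng.normal(size=(n, 3))
        design = build_design(cov, ["foc"])
        s = gls_bootstrap(Y, design, "foc", n_boot=30, seed=5,
                          drop_rare_binary_threshold=3)
        assert s.failures == 0
        assert "smoke" in s.dropped_covariates


class TestGLSPermutation:
    def test_strong_effect_saturates(self, rng):
        Y, design = hetcs_data(rng, n=50, m=3, rho=0.2, beta=1.5)
        s = gls_permutation(Y, design, "foc", n_perm=60, seed=0)
        assert s.p == pytest.approx(1 / 60)
        assert s.failures == 0

    def test_permutation_calibrated_where_parametric_is_liberal(self, rng):
        """Null factor-correlated data: the parametric GLS z-test rejects
        too often while the Freedman-Lane permutation p stays near
        nominal."""
        lam = np.array([0.9, 0.85, 0.8, -0.75, 0.7])
        S = np.outer(lam, lam)
        np.fill_diagonal(S, 1.0)
        L = np.linalg.cholesky(S)
        n, n_rep = 40, 80
        p_param, p_perm = [], []
        for _ in range(n_rep):
            cov = pd.DataFrame({"foc": rng.normal(size=n)})
            Y = rng.standard_normal((n, 5)) @ L.T
            design = build_design(cov, ["foc"])
            fit = gls_fit(standardize_columns(Y), design)
            p_param.append(fit.wald_p("foc"))
            p_perm.append(gls_permutation(Y, design, "foc", n_perm=40,
                                          seed=rng).p)
        rej_param = np.mean(np.array(p_param) < 0.15)
        rej_perm = np.mean(np.array(p_perm) < 0.15)
        assert rej_param > rej_perm
        assert abs(rej_perm - 0.15) < 0.10
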