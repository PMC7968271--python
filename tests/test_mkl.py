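"""Multi-kernel Gibbs sampler against linear mixed-model oracles."""

import numpy as np
import pytest

from spectrakin import (
    backsolve_snp_effects,
    fit_kernel_model,
    predict_kernel_testset,
)
from spectrakin.mkl import MCMC, KernelFit, _batch_se

SHORT = MCMC(niter=1500, burnin=500, thin=2)


def wishart_kernel(rng, n, m=80):
    x = rng.standard_normal((n, m))
    return x @ x.T / m


def mme_solve(y, x, kernels, variances, s2e):
    """Henderson mixed-model equations at fixed variance components."""
    n = y.size
    blocks = [x] + [np.eye(n) for _ in kernels]
    precisions = [np.linalg.inv(k) / v for k, v in zip(kernels, variances)]
    p = x.shape[1]
    sizes = [p] + [n] * len(kernels)
    dim = sum(sizes)
    lhs = np.zeros((dim, dim))
    rhs = np.zeros(dim)
    offs = np.cumsum([0] + sizes)
    for a, za in enumerate(blocks):
        for b, zb in enumerate(blocks):
            lhs[offs[a]:offs[a + 1], offs[b]:offs[b + 1]] += za.T @ zb / s2e
        rhs[offs[a]:offs[a + 1]] += za.T @ y / s2e
    for k, prec in enumerate(precisions, start=1):
        lhs[offs[k]:offs[k + 1], offs[k]:offs[k + 1]] += prec
    sol = np.linalg.solve(lhs, rhs)
    return sol[:p], [sol[offs[k]:offs[k + 1]] for k in range(1, len(blocks))]


def simulate_mixed(rng, n, kernels, variances, s2e, beta=(1.0, 0.5)):
    x = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = x @ np.asarray(beta)
    for k, v in zip(kernels, variances):
        chol = np.linalg.cholesky(k + 1e-10 * np.eye(n))
        y = y + np.sqrt(v) * (chol @ rng.standard_normal(n))
    return x, y + np.sqrt(s2e) * rng.standard_normal(n)


class TestFitKernelModel:
    def test_zero_variance_reduces_to_least_squares(self, rng):
        n = 40
        k = wishart_kernel(rng, n)
        x, y = simulate_mixed(rng, n, [k], [1.0], 0.5)
        fit = fit_kernel_model(y, x, {"S": k}, mcmc=SHORT, seed=0,
                               fixed_variances={"S": 0.0, "e": 0.5})
        b_ls = np.linalg.lstsq(x, y, rcond=None)[0]
        se = _batch_se(fit.chains["b"])
        assert np.all(np.abs(fit.b_hat - b_ls) < 4 * se + 1e-8)
        assert np.allclose(fit.u_hat["S"], 0.0)

    def test_posterior_mean_matches_henderson_solve(self, rng):
        """At fixed variances the exact posterior mean is the MME solution;
        the chain estimate must agree within Monte-Carlo error."""
        n = 30
        k = wishart_kernel(rng, n, 60)
        x, y = simulate_mixed(rng, n, [k], [1.0], 0.49)
        fit = fit_kernel_model(y, x, {"S": k}, mcmc=MCMC(4000, 1000, 2), seed=3,
                               fixed_variances={"S": 1.0, "e": 0.49})
        b_mme, (u_mme,) = mme_solve(y, x, [k], [1.0], 0.49)
        z = np.abs(fit.u_hat["S"] - u_mme) / _batch_se(fit.chains["u_S"])
        assert np.mean(z <= 2.0) >= 0.9
        assert np.all(z <= 4.0)
        zb = np.abs(fit.b_hat - b_mme) / _batch_se(fit.chains["b"])
        assert np.all(zb <= 4.0)

    def test_kernel_order_exchange_invariance(self, rng):
        n = 60
        k1, k2 = wishart_kernel(rng, n), wishart_kernel(rng, n)
        x, y = simulate_mixed(rng, n, [k1, k2], [0.8, 0.6], 0.5)
        f12 = fit_kernel_model(y, x, {"S": k1, "G": k2}, mcmc=SHORT, seed=5)
        f21 = fit_kernel_model(y, x, {"G": k2, "S": k1}, mcmc=SHORT, seed=5)
        yhat12 = x @ f12.b_hat + f12.u_hat["S"] + f12.u_hat["G"]
        yhat21 = x @ f21.b_hat + f21.u_hat["S"] + f21.u_hat["G"]
        mc = np.sqrt(np.mean((yhat12 - y) ** 2)) * 0.1
        assert np.max(np.abs(yhat12 - yhat21)) < max(3 * mc, 0.3)

    def test_identity_kernel_matches_ridge_oracle(self, rng):
        """With K = c*I and fixed variances the exact posterior mean of u is
        a ridge shrinkage of the residuals; compare the exact MME solution
        and the chain against it."""
        n, c, s2u, s2e = 50, 2.0, 0.7, 0.4
        k = c * np.eye(n)
        x, y = simulate_mixed(rng, n, [k], [s2u], s2e)
        b_mme, (u_mme,) = mme_solve(y, x, [k], [s2u], s2e)
        # ridge oracle: u = (I + s2e/(c*s2u) I)^-1 (y - X b)
        lam = s2e / (c * s2u)
        u_ridge = (y - x @ b_mme) / (1.0 + lam)
        np.testing.assert_allclose(u_mme, u_ridge, atol=1e-6)
        fit = fit_kernel_model(y, x, {"S": k}, mcmc=MCMC(3000, 1000, 2), seed=2,
                               fixed_variances={"S": s2u, "e": s2e})
        z = np.abs(fit.u_hat["S"] - u_mme) / _batch_se(fit.chains["u_S"])
        assert np.mean(z <= 2.0) >= 0.9 and np.all(z <= 4.0)

    def test_residual_variance_bounded(self, rng):
        n = 80
        k = wishart_kernel(rng, n)
        x, y = simulate_mixed(rng, n, [k], [1.0], 1.0)
        fit = fit_kernel_model(y, x, {"S": k}, mcmc=SHORT, seed=7)
        s2e = fit.var_components["sigma2_e"]
        assert 0.0 < s2e < np.var(y) * 1.5

    def test_non_psd_kernel_rejected(self, rng):
        n = 10
        k = -np.eye(n)
        with pytest.raises(ValueError, match="not PSD"):
            fit_kernel_model(rng.standard_normal(n), np.ones((n, 1)), {"S": k},
                             mcmc=MCMC(10, 10, 1), seed=0)

    def test_deterministic_given_seed(self, rng):
        n = 25
        k = wishart_kernel(rng, n)
        x, y = simulate_mixed(rng, n, [k], [1.0], 0.5)
        a = fit_kernel_model(y, x, {"S": k}, mcmc=MCMC(200, 100, 2), seed=11)
        b = fit_kernel_model(y, x, {"S": k}, mcmc=MCMC(200, 100, 2), seed=11)
        np.testing.assert_array_equal(a.u_hat["S"], b.u_hat["S"])


class TestPrediction:
    def _exact_fit(self, y, x, k_trn, s2u, s2e, label="S"):
        b, (u,) = mme_solve(y, x, [k_trn], [s2u], s2e)
        return KernelFit(b_hat=b, u_hat={label: u}, var_components={}, chains={},
                         mcmc=MCMC(10, 0, 1), seed=0)

    def test_matches_missing_record_blup(self, rng):
        """Conditional-expectation prediction equals the BLUP of a full-model
        refit with test phenotypes treated as missing (fixed variances)."""
        n, n_trn, s2u, s2e = 25, 20, 1.0, 0.25
        k = wishart_kernel(rng, n)
        x, y = simulate_mixed(rng, n, [k], [s2u], s2e)
        trn, tst = np.arange(n_trn), np.arange(n_trn, n)
        fit = self._exact_fit(y[trn], x[trn], k[np.ix_(trn, trn)], s2u, s2e)
        pred = predict_kernel_testset(fit, "M2", {"S": k}, trn, tst, x_tst=x[tst])
        # oracle: full MME with incidence mapping train records to all n u's
        z = np.zeros((n_trn, n))
        z[np.arange(n_trn), trn] = 1.0
        lhs = np.block([
            [x[trn].T @ x[trn] / s2e, x[trn].T @ z / s2e],
            [z.T @ x[trn] / s2e, z.T @ z / s2e + np.linalg.inv(k) / s2u],
        ])
        rhs = np.concatenate([x[trn].T @ y[trn] / s2e, z.T @ y[trn] / s2e])
        sol = np.linalg.solve(lhs, rhs)
        oracle = x[tst] @ sol[:2] + sol[2:][tst]
        np.testing.assert_allclose(pred, oracle, atol=1e-6)

    def test_duplicate_cow_predicts_training_fitted_value(self, rng):
        n, s2u, s2e = 20, 1.0, 0.3
        k_trn = wishart_kernel(rng, n)
        x, y = simulate_mixed(rng, n, [k_trn], [s2u], s2e)
        # test cow duplicates training cow 4: same kernel row, same covariates
        full = np.zeros((n + 1, n + 1))
        full[:n, :n] = k_trn
        full[n, :n] = k_trn[4]
        full[:n, n] = k_trn[4]
        full[n, n] = k_trn[4, 4]
        fit = self._exact_fit(y, x, k_trn, s2u, s2e)
        pred = predict_kernel_testset(fit, "M3", {"S": full}, np.arange(n), [n],
                                      x_tst=x[[4]])
        fitted = x[4] @ fit.b_hat + fit.u_hat["S"][4]
        np.testing.assert_allclose(pred, [fitted], atol=1e-8)

    def test_model_difference_is_genomic_term(self, rng):
        n, n_trn = 30, 24
        ks = wishart_kernel(rng, n)
        kg = wishart_kernel(rng, n)
        x, y = simulate_mixed(rng, n, [ks], [1.0], 0.4)
        trn, tst = np.arange(n_trn), np.arange(n_trn, n)
        b, (u_s, u_g) = mme_solve(y[trn], x[trn],
                                  [ks[np.ix_(trn, trn)], kg[np.ix_(trn, trn)]],
                                  [1.0, 0.5], 0.4)
        fit = KernelFit(b_hat=b, u_hat={"S": u_s, "G": u_g}, var_components={},
                        chains={}, mcmc=MCMC(10, 0, 1), seed=0)
        p4 = predict_kernel_testset(fit, "M4", {"S": ks, "G": kg}, trn, tst, x[tst])
        p3 = predict_kernel_testset(fit, "M3", {"S": ks}, trn, tst, x[tst])
        gterm = kg[np.ix_(tst, trn)] @ np.linalg.solve(kg[np.ix_(trn, trn)], u_g)
        np.testing.assert_allclose(p4 - p3, gterm, atol=1e-8)


class TestBacksolve:
    def test_zero_additive_values_give_zero_effects(self, rng):
        d = rng.integers(0, 3, size=(10, 15)).astype(float)
        p = np.clip(d.mean(0) / 2, 0.05, 0.95)
        eff = backsolve_snp_effects(np.zeros(10), d, p)
        np.testing.assert_allclose(eff, 0.0)

    def test_single_snp_closed_form(self, rng):
        d = rng.integers(0, 3, size=(12, 1)).astype(float)
        while d.std() == 0:
            d = rng.integers(0, 3, size=(12, 1)).astype(float)
        p = np.array([d.mean() / 2])
        z = (d - 2 * p).ravel()
        u = rng.standard_normal(12) * 0.1 + z * 0.7
        eff = backsolve_snp_effects(u, d, p)
        # with one SNP, G = z z'/c is rank 1; a = z'G^+u/c = z'u/(z'z)
        np.testing.assert_allclose(eff, [z @ u / (z @ z)], atol=1e-6)

    def test_frequency_mismatch_rejected(self, rng):
        d = rng.integers(0, 3, size=(8, 5)).astype(float)
        with pytest.raises(ValueError, match="frequencies"):
            backsolve_snp_effects(np.zeros(8), d, np.full(4, 0.5))
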