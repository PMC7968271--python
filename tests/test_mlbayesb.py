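"""BayesB sampler: prior rules, limits, determinism, layer behaviour."""

import numpy as np
import pytest

from spectrakin import (
    LayerSpec,
    MixturePriorSpec,
    beta_prior_moments,
    default_hyperparameters,
    fit_bayesb,
    fit_multilayer_bayesb,
    predict_bayesb,
)
from spectrakin.mkl import MCMC, _batch_se

SHORT = MCMC(niter=1500, burnin=1500, thin=5)


class TestBetaPriorMoments:
    def test_reference_values(self):
        var, mean = beta_prior_moments(0.5, 10)
        assert round(var, 3) == 0.023
        assert mean == 0.5

    def test_direct_formula(self):
        var, mean = beta_prior_moments(0.2, 4)
        assert var == pytest.approx(0.2 * 0.8 / 5)
        assert round(var, 3) == 0.032
        assert mean == 0.2

    def test_concentration_limit(self):
        var, _ = beta_prior_moments(0.5, 1e9)
        assert var < 1e-9

    @pytest.mark.parametrize("args", [(0.0, 10), (1.0, 10), (0.5, 0.0), (0.5, -1)])
    def test_out_of_range(self, args):
        with pytest.raises(ValueError):
            beta_prior_moments(*args)


class TestDefaultHyperparameters:
    def test_equal_split_equal_widths(self, rng):
        y = rng.standard_normal(50)
        a = LayerSpec(rng.standard_normal((50, 10)), "IR")
        b = LayerSpec(rng.standard_normal((50, 10)), "SNP")
        scales, _ = default_hyperparameters(y, [a, b])
        # same prior mean pi; equal widths differ only through realized
        # column variances, which are all ~1 here
        assert scales["IR"][1] == pytest.approx(scales["SNP"][1], rel=0.2)

    def test_residual_prior_mode_complement(self, rng):
        y = rng.standard_normal(80) * 2.0
        layer = LayerSpec(rng.standard_normal((80, 5)), "IR")
        _, (df_e, s_e) = default_hyperparameters(y, [layer], r2_total=0.5)
        mode = df_e * s_e / (df_e + 2.0)
        assert mode == pytest.approx(0.5 * np.var(y, ddof=1))

    def test_scale_equivariance(self, rng):
        y = rng.standard_normal(60)
        design = rng.standard_normal((60, 8))
        s1, (_, se1) = default_hyperparameters(y, [LayerSpec(design, "IR")])
        s2, (_, se2) = default_hyperparameters(np.sqrt(2) * y, [LayerSpec(design, "IR")])
        assert s2["IR"][1] == pytest.approx(2 * s1["IR"][1])
        assert se2 == pytest.approx(2 * se1)

    def test_constant_y_errors(self):
        with pytest.raises(ValueError):
            default_hyperparameters(np.ones(20), [LayerSpec(np.eye(20), "IR")])


class TestFitBayesB:
    def test_seeded_determinism_bitwise(self, rng):
        y = rng.standard_normal(40)
        w = rng.standard_normal((40, 15))
        a = fit_bayesb(y, LayerSpec(w, "IR"), mcmc=MCMC(300, 300, 3), seed=5)
        b = fit_bayesb(y, LayerSpec(w, "IR"), mcmc=MCMC(300, 300, 3), seed=5)
        np.testing.assert_array_equal(a.effects["IR"], b.effects["IR"])
        np.testing.assert_array_equal(a.b_hat, b.b_hat)
        assert a.sigma2_e == b.sigma2_e

    def test_null_effects_shrink_with_sample_size(self):
        mags = {}
        for n in (50, 400):
            r = np.random.default_rng(17)
            w = r.standard_normal((n, 30))
            y = r.standard_normal(n)
            fit = fit_bayesb(y, LayerSpec(w, "IR"), mcmc=SHORT, seed=1)
            mags[n] = np.mean(np.abs(fit.effects["IR"]))
        assert mags[400] <= 0.5 * mags[50]

    def test_ridge_limit_matches_oracle(self, rng):
        """pi = 1 with an effectively-infinite-df slab is Bayesian ridge."""
        n, p = 150, 20
        w = rng.standard_normal((n, p))
        beta = rng.standard_normal(p) * 0.3
        y = w @ beta + rng.standard_normal(n)
        s0 = 10.0  # weak shrinkage: ridge is insensitive to sigma2_e here
        prior = MixturePriorSpec(df=1e6, scale=s0, pi_fixed=1.0)
        fit = fit_bayesb(y, LayerSpec(w, "IR", prior), mcmc=MCMC(3000, 1000, 2),
                         seed=4, store_effect_chains=True)
        s2e = fit.sigma2_e
        wc = w - w.mean(axis=0)
        a_ridge = np.linalg.solve(wc.T @ wc + s2e / s0 * np.eye(p),
                                  wc.T @ (y - y.mean()))
        z = np.abs(fit.effects["IR"] - a_ridge) / _batch_se(fit.chains["a_IR"])
        assert np.mean(z <= 2.0) >= 0.9
        assert np.all(z <= 4.0)

    def test_constant_y_errors(self, rng):
        with pytest.raises(ValueError):
            fit_bayesb(np.ones(20), LayerSpec(rng.standard_normal((20, 5)), "IR"),
                       mcmc=MCMC(50, 50, 1), seed=0)

    def test_thinned_and_full_run_summaries_agree(self, desk_bundle):
        w = desk_bundle.spectra.values
        w = (w - w.mean(0)) / w.std(0, ddof=1)
        y = desk_bundle.traits.values[:, 0]
        short = fit_bayesb(y, LayerSpec(w, "IR"), mcmc=MCMC(2000, 2000, 5), seed=3)
        longer = fit_bayesb(y, LayerSpec(w, "IR"), mcmc=MCMC(8000, 8000, 5), seed=9)
        corr = np.corrcoef(short.effects["IR"], longer.effects["IR"])[0, 1]
        assert corr > 0.95


class TestMultilayer:
    def test_empty_snp_layer_reduces_to_single_layer(self, rng):
        y = rng.standard_normal(30)
        w = rng.standard_normal((30, 10))
        # a SNP layer whose columns were all dropped has zero width
        single = fit_bayesb(y, LayerSpec(w, "IR"), mcmc=MCMC(200, 200, 2), seed=2)
        multi = fit_multilayer_bayesb(y, LayerSpec(w, "IR"),
                                      LayerSpec(np.empty((30, 0)), "SNP"),
                                      mcmc=MCMC(200, 200, 2), seed=2)
        np.testing.assert_array_equal(single.effects["IR"], multi.effects["IR"])

    def test_duplicate_layer_labels_error(self, rng):
        y = rng.standard_normal(30)
        w = rng.standard_normal((30, 5))
        with pytest.raises(ValueError, match="dupl"):
            fit_multilayer_bayesb(y, LayerSpec(w, "IR"), LayerSpec(w, "IR"),
                                  mcmc=MCMC(50, 50, 1), seed=0)

    def test_two_layers_fit_training_data_better(self, desk_bundle, desk_truth):
        w = desk_bundle.spectra.values
        w = (w - w.mean(0)) / w.std(0, ddof=1)
        zmat = desk_bundle.genotypes.dosages
        zmat = (zmat - zmat.mean(0)) / zmat.std(0, ddof=1)
        y = desk_bundle.traits.values[:, 0]
        one = fit_bayesb(y, LayerSpec(w, "IR"), mcmc=SHORT, seed=6)
        two = fit_multilayer_bayesb(y, LayerSpec(w, "IR"), LayerSpec(zmat, "SNP"),
                                    mcmc=SHORT, seed=6)
        f1 = w @ one.effects["IR"] + one.b_hat[0]
        f2 = w @ two.effects["IR"] + zmat @ two.effects["SNP"] + two.b_hat[0]
        assert np.corrcoef(f2, y)[0, 1] > np.corrcoef(f1, y)[0, 1]

    def test_inclusion_probabilities_valid_and_calibrated_under_null(self):
        r = np.random.default_rng(23)
        w = r.standard_normal((50, 30))
        y = r.standard_normal(50)
        fit = fit_bayesb(y, LayerSpec(w, "IR"), mcmc=SHORT, seed=8)
        incl = fit.inclusion["IR"]
        assert np.all((incl >= 0) & (incl <= 1))
        assert abs(incl.mean() - 0.5) <= 0.15

    def test_column_permutation_permutes_summaries(self, rng):
        """Permuting predictor columns permutes the posterior summaries (the
        scan order changes, so agreement is within Monte-Carlo error)."""
        n, p = 120, 12
        w = rng.standard_normal((n, p))
        beta = np.zeros(p)
        beta[[2, 7]] = 1.0
        y = w @ beta + rng.standard_normal(n) * 0.5
        perm = rng.permutation(p)
        f1 = fit_bayesb(y, LayerSpec(w, "IR"), mcmc=MCMC(4000, 2000, 4), seed=3)
        f2 = fit_bayesb(y, LayerSpec(w[:, perm], "IR"), mcmc=MCMC(4000, 2000, 4), seed=3)
        np.testing.assert_allclose(f2.effects["IR"], f1.effects["IR"][perm], atol=0.08)
        np.testing.assert_allclose(f2.inclusion["IR"], f1.inclusion["IR"][perm], atol=0.1)


class TestPredictBayesB:
    def _fit(self, rng, n=40, p_ir=8, p_snp=5):
        w = rng.standard_normal((n, p_ir))
        z = rng.standard_normal((n, p_snp))
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = w[:, 0] + z[:, 1] + rng.standard_normal(n) * 0.5
        fit = fit_multilayer_bayesb(y, LayerSpec(w, "IR"), LayerSpec(z, "SNP"),
                                    x=x, mcmc=MCMC(400, 400, 4), seed=9)
        return fit, x, w, z

    def test_zero_effects_give_fixed_part_only(self, rng):
        fit, x, w, z = self._fit(rng)
        fit.effects["IR"][:] = 0.0
        pred = predict_bayesb(fit, "M3", x_tst=x[:3], w_ir_tst=w[:3])
        np.testing.assert_allclose(pred, x[:3] @ fit.b_hat)

    def test_training_row_reproduces_fitted_value(self, rng):
        fit, x, w, z = self._fit(rng)
        pred = predict_bayesb(fit, "M4", x_tst=x[[5]], w_ir_tst=w[[5]], w_snp_tst=z[[5]])
        fitted = (x[5] @ fit.b_hat + w[5] @ fit.effects["IR"]
                  + z[5] @ fit.effects["SNP"])
        np.testing.assert_allclose(pred, [fitted])

    def test_m4_minus_m3_is_snp_term(self, rng):
        fit, x, w, z = self._fit(rng)
        p4 = predict_bayesb(fit, "M4", x_tst=x[:6], w_ir_tst=w[:6], w_snp_tst=z[:6])
        p3 = predict_bayesb(fit, "M3", x_tst=x[:6], w_ir_tst=w[:6])
        np.testing.assert_allclose(p4 - p3, z[:6] @ fit.effects["SNP"], atol=1e-12)

    def test_width_mismatch_rejected(self, rng):
        fit, x, w, z = self._fit(rng)
        with pytest.raises(ValueError, match="width"):
            predict_bayesb(fit, "M1", w_ir_tst=w[:, :4])

    def test_unknown_model_rejected(self, rng):
        fit, x, w, z = self._fit(rng)
        with pytest.raises(ValueError, match="M1-M4"):
            predict_bayesb(fit, "M7", w_ir_tst=w)
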