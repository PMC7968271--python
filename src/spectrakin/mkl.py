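"""Bayesian multiple kernel learning for phenotypic prediction.

The model is a Gaussian mixed model with on-farm fixed effects and one or
two kernel-structured random terms::

    y = X b + u_1 [+ u_2] + e,   u_k ~ N(0, K_k s2_k),   e ~ N(0, I s2_e)

where each K_k is a relationship matrix (spectral S, genomic G, or pedigree
A).  Inference is by Gibbs sampling: the fixed effects get a flat Gaussian
prior, each random vector is sampled from its multivariate-normal full
conditional through the eigendecomposition of its kernel (independent
regression on eigenvectors scaled by eigenvalues), and each variance
component from a scaled-inverse-chi-square full conditional.

Test-set phenotypes are predicted with the conditional-expectation
formulas of the M1-M7 model catalogue, e.g. for the two-kernel model::

    y_hat_tst = X_tst b_hat + S_tst,trn S_trn^-1 u_hat_IR
                            + G_tst,trn G_trn^-1 u_hat_g
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .kernels import RelationshipMatrix, solve_kernel

logger = logging.getLogger(__name__)

#: kernels entering the test-set prediction of each catalogue model
MODEL_KERNEL_TERMS = {
    "M1": ("S",),
    "M2": ("S",),
    "M3": ("S",),
    "M4": ("S", "G"),
    "M5": ("S",),
    "M6": ("S", "G"),
    "M7": ("S", "A"),
}

#: models whose prediction includes the fixed-effect term X_tst b_hat
MODELS_WITH_FIXED_TERM = ("M2", "M3", "M4", "M5", "M6", "M7")


@dataclass
class MCMC:
    """Chain settings: ``niter`` kept draws after ``burnin``, stored every
    ``thin`` draws.  Running posterior means use every post-burn-in draw."""

    niter: int = 50_000
    burnin: int = 50_000
    thin: int = 10

    def __post_init__(self) -> None:
        if self.niter < 1 or self.burnin < 0 or self.thin < 1:
            raise ValueError("invalid MCMC settings")

    @property
    def n_stored(self) -> int:
        return self.niter // self.thin


TEST_SCALE_MCMC = MCMC(niter=2_000, burnin=2_000, thin=5)


@dataclass
class KernelFit:
    """Posterior summaries of a multi-kernel fit."""

    b_hat: np.ndarray
    u_hat: dict[str, np.ndarray]
    var_components: dict[str, float]
    chains: dict[str, np.ndarray]
    mcmc: MCMC
    seed: int
    fixed_names: tuple[str, ...] = ()
    ess_warnings: tuple[str, ...] = ()


def _eig_kernel(k: np.ndarray, label: str) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition with PSD check; drops numerically-zero modes."""
    vals, vecs = np.linalg.eigh(k)
    top = max(float(vals[-1]), 1.0)
    if vals[0] < -1e-8 * top:
        raise ValueError(f"kernel {label!r} is not PSD (min eigenvalue {vals[0]:g})")
    keep = vals > 1e-10 * top
    return vals[keep], vecs[:, keep]


def _batch_se(chain: np.ndarray, n_batches: int = 25) -> np.ndarray:
    """Batch-means Monte-Carlo standard error along axis 0."""
    n = chain.shape[0]
    b = max(n // n_batches, 1)
    usable = (n // b) * b
    batches = chain[:usable].reshape(n // b, b, *chain.shape[1:]).mean(axis=1)
    return batches.std(axis=0, ddof=1) / np.sqrt(batches.shape[0])


def fit_kernel_model(
    y: np.ndarray,
    x: np.ndarray,
    kernels: dict[str, np.ndarray | RelationshipMatrix],
    mcmc: MCMC = TEST_SCALE_MCMC,
    seed: int = 0,
    df: float = 5.0,
    r2: float = 0.5,
    fixed_variances: dict[str, float] | None = None,
    eigs: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    store_u_chains: bool = True,
    fixed_names: tuple[str, ...] = (),
) -> KernelFit:
    """Gibbs sampler for the multi-kernel mixed model on the training rows.

    Parameters
    ----------
    y, x
        Training phenotypes and fixed-effect design (include the intercept
        column).
    kernels
        Label -> training-block kernel matrix (1 or 2 entries).
    fixed_variances
        Optional ``{"e": ..., "<label>": ...}`` map; listed components are
        held at the given value instead of being sampled (used by the
        Henderson-equation oracle checks).
    eigs
        Optional precomputed ``label -> (eigenvalues, eigenvectors)`` so a
        cross-validation fold decomposes each kernel once.
    df, r2
        Scaled-inverse-chi-square prior degrees of freedom, and the prior
        proportion of variance attributed to the random terms (split
        equally across kernels); prior scales follow the default rule of
        matching the prior mode to that partition.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if x.shape[0] != n:
        raise ValueError("X and y disagree on the number of records")
    if not kernels or len(kernels) > 2:
        raise ValueError("one or two kernel terms are supported")
    labels = list(kernels)
    kmats = {}
    for lab, k in kernels.items():
        kv = k.values if isinstance(k, RelationshipMatrix) else np.asarray(k, float)
        if kv.shape != (n, n):
            raise ValueError(f"kernel {lab!r} does not span the training rows")
        kmats[lab] = kv

    fixed_variances = dict(fixed_variances or {})
    rng = np.random.default_rng(seed)

    decomp = {}
    for lab in labels:
        if eigs and lab in eigs:
            decomp[lab] = eigs[lab]
        else:
            decomp[lab] = _eig_kernel(kmats[lab], lab)

    vary = float(np.var(y, ddof=1))
    if vary <= 0:
        raise ValueError("phenotype vector is constant")
    share = r2 / len(labels)
    # prior mode of s2_k * mean(diag(K)) = share * var(y); mode = df*S/(df+2)
    prior_scale = {
        lab: share * vary * (df + 2.0) / df / max(np.mean(np.diag(kmats[lab])), 1e-12)
        for lab in labels
    }
    prior_scale_e = (1.0 - r2) * vary * (df + 2.0) / df

    xtx = x.T @ x
    ridge = 1e-10 * max(np.trace(xtx), 1.0)
    cf = cho_factor(xtx + ridge * np.eye(x.shape[1]), lower=True)
    lower_chol = np.linalg.cholesky(xtx + ridge * np.eye(x.shape[1]))

    # state
    b = cho_solve(cf, x.T @ y)
    alpha = {lab: np.zeros(decomp[lab][0].size) for lab in labels}
    u = {lab: np.zeros(n) for lab in labels}
    s2 = {lab: fixed_variances.get(lab, share * vary) for lab in labels}
    s2e = fixed_variances.get("e", (1.0 - r2) * vary)

    total = mcmc.burnin + mcmc.niter
    n_stored = mcmc.n_stored
    b_mean = np.zeros_like(b)
    u_mean = {lab: np.zeros(n) for lab in labels}
    var_mean = {lab: 0.0 for lab in labels}
    var_mean_e = 0.0
    chains: dict[str, np.ndarray] = {"sigma2_e": np.empty(n_stored)}
    for lab in labels:
        chains[f"sigma2_{lab}"] = np.empty(n_stored)
        if store_u_chains:
            chains[f"u_{lab}"] = np.empty((n_stored, n))
    if store_u_chains:
        chains["b"] = np.empty((n_stored, x.shape[1]))

    resid = y - x @ b
    stored = 0
    for it in range(total):
        # --- fixed effects: flat prior, joint Gaussian full conditional
        resid += x @ b
        b_post = cho_solve(cf, x.T @ resid)
        z = rng.standard_normal(b.size)
        b = b_post + np.sqrt(s2e) * solve_triangular(lower_chol.T, z, lower=False)
        resid -= x @ b

        # --- kernel random vectors via eigen-regression
        for lab in labels:
            if lab in fixed_variances and fixed_variances[lab] == 0.0:
                continue  # degenerate prior: the term stays at zero
            d, v = decomp[lab]
            resid += u[lab]
            proj = v.T @ resid
            post_var = 1.0 / (1.0 / s2e + 1.0 / (d * s2[lab]))
            post_mean = post_var * proj / s2e
            alpha[lab] = post_mean + np.sqrt(post_var) * rng.standard_normal(d.size)
            u[lab] = v @ alpha[lab]
            resid -= u[lab]
            if lab not in fixed_variances:
                ss = np.sum(alpha[lab] ** 2 / d)
                s2[lab] = (ss + df * prior_scale[lab]) / rng.chisquare(df + d.size)

        # --- residual variance
        if "e" not in fixed_variances:
            s2e = (resid @ resid + df * prior_scale_e) / rng.chisquare(df + n)

        if it >= mcmc.burnin:
            kept = it - mcmc.burnin
            b_mean += b
            var_mean_e += s2e
            for lab in labels:
                u_mean[lab] += u[lab]
                var_mean[lab] += s2[lab]
            if kept % mcmc.thin == 0 and stored < n_stored:
                chains["sigma2_e"][stored] = s2e
                for lab in labels:
                    chains[f"sigma2_{lab}"][stored] = s2[lab]
                    if store_u_chains:
                        chains[f"u_{lab}"][stored] = u[lab]
                if store_u_chains:
                    chains["b"][stored] = b
                stored += 1

    b_mean /= mcmc.niter
    var_mean_e /= mcmc.niter
    for lab in labels:
        u_mean[lab] /= mcmc.niter
        var_mean[lab] /= mcmc.niter

    ess_warnings = []
    for name in [f"sigma2_{lab}" for lab in labels] + ["sigma2_e"]:
        chain = chains[name][:stored]
        if chain.size >= 50:
            se = _batch_se(chain)
            sd = chain.std(ddof=1)
            ess = (sd / se) ** 2 if se > 0 else float(chain.size)
            if ess < 30:
                msg = f"low effective sample size for {name}: {ess:.0f}"
                ess_warnings.append(msg)
                logger.warning(msg)

    var_components = {f"sigma2_{lab}": float(var_mean[lab]) for lab in labels}
    var_components["sigma2_e"] = float(var_mean_e)
    return KernelFit(
        b_hat=b_mean,
        u_hat={lab: u_mean[lab] for lab in labels},
        var_components=var_components,
        chains=chains,
        mcmc=mcmc,
        seed=seed,
        fixed_names=tuple(fixed_names),
        ess_warnings=tuple(ess_warnings),
    )


def predict_kernel_testset(
    fit: KernelFit,
    model: str,
    kernels_full: dict[str, np.ndarray | RelationshipMatrix],
    trn_idx: np.ndarray,
    tst_idx: np.ndarray,
    x_tst: np.ndarray | None = None,
) -> np.ndarray:
    """Conditional-expectation prediction for the test rows of one model.

    Implements exactly the model-specific linear combinations of the
    catalogue: every model propagates each fitted kernel term as
    ``K_tst,trn K_trn,trn^-1 u_hat``; M2-M7 add ``X_tst b_hat`` (the top-3
    marker covariates of M5/M6 ride along inside X).  M1 is the
    spectra-term-only prediction.
    """
    if model not in MODEL_KERNEL_TERMS:
        raise ValueError(f"unknown model {model!r}")
    trn_idx = np.asarray(trn_idx)
    tst_idx = np.asarray(tst_idx)
    pred = np.zeros(tst_idx.size)
    if model in MODELS_WITH_FIXED_TERM:
        if x_tst is None:
            raise ValueError(f"model {model} needs the test fixed-effect design")
        pred += x_tst @ fit.b_hat
    for lab in MODEL_KERNEL_TERMS[model]:
        if lab not in fit.u_hat:
            raise ValueError(f"fit has no {lab!r} term required by {model}")
        k = kernels_full[lab]
        kv = k.values if isinstance(k, RelationshipMatrix) else np.asarray(k, float)
        k_trn = kv[np.ix_(trn_idx, trn_idx)]
        k_cross = kv[np.ix_(tst_idx, trn_idx)]
        pred += k_cross @ solve_kernel(k_trn, fit.u_hat[lab])
    return pred


def backsolve_snp_effects(
    u_g: np.ndarray,
    dosages_trn: np.ndarray,
    allele_freq: np.ndarray,
) -> np.ndarray:
    """Recover per-SNP effects from a genomic kernel fit (GBLUP back-solution).

    With G = Z Z' / c, c = 2 * sum_j p_j (1 - p_j) and Z the dosages
    centered by 2p, the marker effects consistent with the fitted additive
    values are ``a_hat = Z' G^-1 u_hat_g / c``.  ``allele_freq`` must be the
    frequencies used to build G (scaling is otherwise unknown, which is an
    error by contract).
    """
    u_g = np.asarray(u_g, dtype=float)
    dosages_trn = np.asarray(dosages_trn, dtype=float)
    p = np.asarray(allele_freq, dtype=float)
    if p.shape != (dosages_trn.shape[1],):
        raise ValueError("allele frequencies do not match the SNP panel of G; "
                         "back-solution requires the frequencies G was built with")
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("monomorphic SNP in back-solution panel")
    z = dosages_trn - 2.0 * p
    c = 2.0 * np.sum(p * (1.0 - p))
    g = (z @ z.T) / c
    ginv_u = solve_kernel(g, u_g)
    return z.T @ ginv_u / c
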