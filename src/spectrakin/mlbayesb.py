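"""BayesB and multilayer BayesB via Gibbs sampling.

BayesB places a spike-and-slab prior on every regression coefficient: with
probability ``pi`` the effect is drawn from a scaled-t slab (implemented
hierarchically as a normal effect whose variance has a scaled-inverse
chi-square prior), otherwise it is exactly zero.  The multilayer extension
assigns an independent mixture prior to each predictor layer — here the
milk FTIR wavenumbers and the SNP dosages — so spectra and markers are
shrunk on their own terms::

    y = X b + sum_i W_IR_i a_IR_i + sum_j W_SNP_j a_SNP_j + e

``pi`` itself can carry a Beta hyper-prior parameterised by its prior mean
``probin`` and a concentration ``counts`` (prior variance
``probin * (1 - probin) / (counts + 1)``); with ``probin = 0.5`` and
``counts = 10`` the two derived quantities are 0.023 and 0.5.

The per-effect sweep is the computational hot spot and is compiled with
numba; everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .mkl import MCMC, TEST_SCALE_MCMC

logger = logging.getLogger(__name__)

#: default flat-ish Gaussian prior variance for fixed effects
FIXED_EFFECT_PRIOR_VAR = 1e8


def beta_prior_moments(prob_in: float, counts: float) -> tuple[float, float]:
    """Prior (variance, mean) of the Beta hyper-prior on ``pi``.

    A Beta distribution with mean ``prob_in`` and total concentration
    ``counts`` (shape parameters ``prob_in * counts`` and
    ``(1 - prob_in) * counts``) has variance
    ``prob_in * (1 - prob_in) / (counts + 1)``.
    """
    if not 0.0 < prob_in < 1.0:
        raise ValueError("prob_in must be in (0, 1)")
    if counts <= 0.0:
        raise ValueError("counts must be positive")
    return prob_in * (1.0 - prob_in) / (counts + 1.0), prob_in


@dataclass
class MixturePriorSpec:
    """Mixture prior of one layer: inclusion probability and t-slab."""

    probin: float = 0.5
    counts: float = 10.0
    df: float = 5.0
    scale: float | None = None  # filled by the default rule when None
    pi_fixed: float | None = None  # set to fix pi instead of Beta-updating it

    def __post_init__(self) -> None:
        beta_prior_moments(self.probin, self.counts)  # range check
        if self.df <= 0:
            raise ValueError("df must be positive")
        if self.pi_fixed is not None and not 0.0 < self.pi_fixed <= 1.0:
            raise ValueError("pi_fixed must be in (0, 1]")

    @property
    def pi_mean(self) -> float:
        return self.probin if self.pi_fixed is None else self.pi_fixed


@dataclass
class LayerSpec:
    """One predictor layer: standardized design plus its mixture prior."""

    design: np.ndarray
    label: str
    prior: MixturePriorSpec = field(default_factory=MixturePriorSpec)

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        if self.design.ndim != 2:
            raise ValueError(f"layer {self.label!r} design must be a matrix")


def default_hyperparameters(
    y: np.ndarray,
    layers: list[LayerSpec],
    r2_total: float = 0.5,
    df: float = 5.0,
    df_e: float = 5.0,
) -> tuple[dict[str, tuple[float, float]], tuple[float, float]]:
    """Default-rule scales: split ``r2_total`` equally across layers.

    Each layer's t-scale makes the prior expected variance it contributes,
    ``pi * sum_j var(W_j) * E[effect variance]`` with
    ``E[effect variance] = df * S / (df - 2)``, equal to its share of
    ``var(y) * r2_total``; the residual scale puts the prior mode of the
    scaled-inverse-chi-square at ``var(y) * (1 - r2_total)``.
    """
    y = np.asarray(y, dtype=float)
    vary = float(np.var(y, ddof=1))
    if vary <= 0:
        raise ValueError("phenotype vector is constant")
    if df <= 2:
        raise ValueError("slab df must exceed 2 for a finite prior variance")
    share = r2_total / len(layers)
    scales = {}
    for layer in layers:
        msx = float(np.sum(np.var(layer.design, axis=0, ddof=1)))
        if msx <= 0:
            raise ValueError(f"layer {layer.label!r} has zero total variance")
        scale = vary * share * (df - 2.0) / (df * layer.prior.pi_mean * msx)
        scales[layer.label] = (df, scale)
    s_e = vary * (1.0 - r2_total) * (df_e + 2.0) / df_e
    return scales, (df_e, s_e)


@dataclass
class BayesBFit:
    """Posterior summaries of a (multilayer) BayesB fit."""

    b_hat: np.ndarray
    effects: dict[str, np.ndarray]
    inclusion: dict[str, np.ndarray]
    pi_hat: dict[str, float]
    sigma2_e: float
    chains: dict[str, np.ndarray]
    mcmc: MCMC
    seed: int
    fixed_names: tuple[str, ...] = ()


@njit(cache=False)
def _bayesb_core(
    y,
    x,
    w,
    layer_start,
    df_l,
    scale_l,
    probin_l,
    counts_l,
    pi_fixed_l,      # <= 0 means "Beta-update pi"
    df_e,
    s_e,
    b_prior_var,
    burnin,
    niter,
    thin,
    seed,
    store_effects,
):
    np.random.seed(seed)
    n = y.shape[0]
    pf = x.shape[1]
    pt = w.shape[1]
    n_layers = layer_start.shape[0] - 1

    xtx = np.empty(pf)
    for j in range(pf):
        s = 0.0
        for i in range(n):
            s += x[i, j] * x[i, j]
        xtx[j] = s
    wtw = np.empty(pt)
    for j in range(pt):
        s = 0.0
        for i in range(n):
            s += w[i, j] * w[i, j]
        wtw[j] = s

    b = np.zeros(pf)
    a = np.zeros(pt)
    delta = np.zeros(pt, dtype=np.uint8)
    s2a = np.empty(pt)
    for l in range(n_layers):
        for j in range(layer_start[l], layer_start[l + 1]):
            s2a[j] = scale_l[l]
    pi = np.empty(n_layers)
    for l in range(n_layers):
        pi[l] = probin_l[l] if pi_fixed_l[l] <= 0.0 else pi_fixed_l[l]
    vy = np.var(y)
    s2e = vy * 0.5 if vy > 0.0 else 1.0

    r = y.copy()

    n_stored = niter // thin
    b_mean = np.zeros(pf)
    a_mean = np.zeros(pt)
    incl_mean = np.zeros(pt)
    pi_mean = np.zeros(n_layers)
    s2e_mean = 0.0
    s2e_chain = np.empty(n_stored)
    pi_chain = np.empty((n_stored, n_layers))
    if store_effects:
        a_chain = np.empty((n_stored, pt))
        b_chain = np.empty((n_stored, pf))
    else:
        a_chain = np.empty((1, pt))
        b_chain = np.empty((1, pf))

    stored = 0
    for it in range(burnin + niter):
        # fixed effects, coordinate-wise, vague Gaussian prior
        for j in range(pf):
            if b[j] != 0.0:
                for i in range(n):
                    r[i] += x[i, j] * b[j]
            rhs = 0.0
            for i in range(n):
                rhs += x[i, j] * r[i]
            prec = xtx[j] / s2e + 1.0 / b_prior_var
            mean = rhs / s2e / prec
            bj = mean + np.random.standard_normal() / math.sqrt(prec)
            b[j] = bj
            for i in range(n):
                r[i] -= x[i, j] * bj

        # layers: integrated Bernoulli draw, then effect draw when included
        for l in range(n_layers):
            k_in = 0
            for j in range(layer_start[l], layer_start[l + 1]):
                if a[j] != 0.0:
                    for i in range(n):
                        r[i] += w[i, j] * a[j]
                rhs = 0.0
                for i in range(n):
                    rhs += w[i, j] * r[i]
                c = wtw[j]
                s2 = s2a[j]
                q = c + s2e / s2
                log_bf = 0.5 * (rhs * rhs / (s2e * q)) - 0.5 * math.log(c * s2 / s2e + 1.0)
                if pi[l] >= 1.0:
                    p_in = 1.0
                else:
                    lo = math.log(pi[l] / (1.0 - pi[l])) + log_bf
                    if lo > 35.0:
                        p_in = 1.0
                    elif lo < -35.0:
                        p_in = 0.0
                    else:
                        p_in = 1.0 / (1.0 + math.exp(-lo))
                if np.random.random() < p_in:
                    var = s2e / q
                    mean = rhs / q
                    aj = mean + math.sqrt(var) * np.random.standard_normal()
                    a[j] = aj
                    delta[j] = 1
                    k_in += 1
                    for i in range(n):
                        r[i] -= w[i, j] * aj
                else:
                    a[j] = 0.0
                    delta[j] = 0
                # per-effect slab variance (scaled-inv-chi2 full conditional;
                # prior draw when excluded)
                s2a[j] = (df_l[l] * scale_l[l] + a[j] * a[j]) / np.random.chisquare(
                    df_l[l] + delta[j]
                )
            if pi_fixed_l[l] <= 0.0:
                p_l = layer_start[l + 1] - layer_start[l]
                pi[l] = np.random.beta(
                    probin_l[l] * counts_l[l] + k_in,
                    (1.0 - probin_l[l]) * counts_l[l] + (p_l - k_in),
                )

        sse = 0.0
        for i in range(n):
            sse += r[i] * r[i]
        s2e = (sse + df_e * s_e) / np.random.chisquare(n + df_e)

        if it >= burnin:
            kept = it - burnin
            for j in range(pf):
                b_mean[j] += b[j]
            for j in range(pt):
                a_mean[j] += a[j]
                incl_mean[j] += delta[j]
            for l in range(n_layers):
                pi_mean[l] += pi[l]
            s2e_mean += s2e
            if kept % thin == 0 and stored < n_stored:
                s2e_chain[stored] = s2e
                for l in range(n_layers):
                    pi_chain[stored, l] = pi[l]
                if store_effects:
                    for j in range(pt):
                        a_chain[stored, j] = a[j]
                    for j in range(pf):
                        b_chain[stored, j] = b[j]
                stored += 1

    inv = 1.0 / niter
    for j in range(pf):
        b_mean[j] *= inv
    for j in range(pt):
        a_mean[j] *= inv
        incl_mean[j] *= inv
    for l in range(n_layers):
        pi_mean[l] *= inv
    s2e_mean *= inv
    return b_mean, a_mean, incl_mean, pi_mean, s2e_mean, s2e_chain, pi_chain, a_chain, b_chain


def _fit(
    y: np.ndarray,
    layers: list[LayerSpec],
    x: np.ndarray | None,
    mcmc: MCMC,
    seed: int,
    r2_total: float,
    store_effect_chains: bool,
    fixed_names: tuple[str, ...],
) -> BayesBFit:
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 records for a BayesB fit")
    if np.var(y) == 0:
        raise ValueError("phenotype vector is constant")
    labels = [layer.label for layer in layers]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicated layer labels: {labels}")
    for layer in layers:
        if layer.design.shape[0] != n:
            raise ValueError(f"layer {layer.label!r} rows do not match y")
    if x is None:
        x = np.ones((n, 1))
        fixed_names = fixed_names or ("intercept",)
    x = np.asarray(x, dtype=float)

    # fill missing slab scales with the default rule
    need = [layer for layer in layers if layer.prior.scale is None]
    if need:
        scales, _ = default_hyperparameters(y, layers, r2_total=r2_total)
        for layer in need:
            layer.prior.scale = scales[layer.label][1]
    vary = float(np.var(y, ddof=1))
    df_e = 5.0
    s_e = vary * (1.0 - r2_total) * (df_e + 2.0) / df_e

    w = np.asfortranarray(np.hstack([layer.design for layer in layers]))
    widths = [layer.design.shape[1] for layer in layers]
    layer_start = np.concatenate([[0], np.cumsum(widths)]).astype(np.int64)
    df_l = np.array([layer.prior.df for layer in layers])
    scale_l = np.array([layer.prior.scale for layer in layers])
    probin_l = np.array([layer.prior.probin for layer in layers])
    counts_l = np.array([layer.prior.counts for layer in layers])
    pi_fixed_l = np.array(
        [-1.0 if layer.prior.pi_fixed is None else layer.prior.pi_fixed for layer in layers]
    )

    out = _bayesb_core(
        y,
        np.asfortranarray(x),
        w,
        layer_start,
        df_l,
        scale_l,
        probin_l,
        counts_l,
        pi_fixed_l,
        df_e,
        s_e,
        FIXED_EFFECT_PRIOR_VAR,
        mcmc.burnin,
        mcmc.niter,
        mcmc.thin,
        int(seed) % (2**31),
        store_effect_chains,
    )
    b_mean, a_mean, incl_mean, pi_mean, s2e_mean, s2e_chain, pi_chain, a_chain, b_chain = out

    effects, inclusion, pi_hat, chains = {}, {}, {}, {"sigma2_e": s2e_chain}
    for i, layer in enumerate(layers):
        lo, hi = layer_start[i], layer_start[i + 1]
        effects[layer.label] = a_mean[lo:hi]
        inclusion[layer.label] = incl_mean[lo:hi]
        pi_hat[layer.label] = float(pi_mean[i])
        chains[f"pi_{layer.label}"] = pi_chain[:, i]
        if store_effect_chains:
            chains[f"a_{layer.label}"] = a_chain[:, lo:hi]
    if store_effect_chains:
        chains["b"] = b_chain
    return BayesBFit(
        b_hat=b_mean,
        effects=effects,
        inclusion=inclusion,
        pi_hat=pi_hat,
        sigma2_e=float(s2e_mean),
        chains=chains,
        mcmc=mcmc,
        seed=seed,
        fixed_names=tuple(fixed_names),
    )


def fit_bayesb(
    y: np.ndarray,
    layer: LayerSpec,
    x: np.ndarray | None = None,
    mcmc: MCMC = TEST_SCALE_MCMC,
    seed: int = 0,
    r2_total: float = 0.5,
    store_effect_chains: bool = False,
    fixed_names: tuple[str, ...] = (),
) -> BayesBFit:
    """Single-layer BayesB (spectra-only in the model catalogue)."""
    return _fit(y, [layer], x, mcmc, seed, r2_total, store_effect_chains, fixed_names)


def fit_multilayer_bayesb(
    y: np.ndarray,
    ir_layer: LayerSpec,
    snp_layer: LayerSpec,
    x: np.ndarray | None = None,
    mcmc: MCMC = TEST_SCALE_MCMC,
    seed: int = 0,
    r2_total: float = 0.5,
    store_effect_chains: bool = False,
    fixed_names: tuple[str, ...] = (),
) -> BayesBFit:
    """Two-layer BayesB with separate mixture priors for spectra and SNPs."""
    if snp_layer.design.shape[1] == 0:
        return _fit(y, [ir_layer], x, mcmc, seed, r2_total, store_effect_chains, fixed_names)
    return _fit(
        y, [ir_layer, snp_layer], x, mcmc, seed, r2_total, store_effect_chains, fixed_names
    )


def predict_bayesb(
    fit: BayesBFit,
    model: str,
    x_tst: np.ndarray | None = None,
    w_ir_tst: np.ndarray | None = None,
    w_snp_tst: np.ndarray | None = None,
) -> np.ndarray:
    """Catalogue prediction: M1 = W_IR a; M2/M3 add X b; M4 adds W_SNP a.

    Test designs must be standardized with the training statistics.
    """
    if model not in ("M1", "M2", "M3", "M4"):
        raise ValueError(f"BayesB supports M1-M4, not {model!r}")
    if w_ir_tst is None:
        raise ValueError("spectra test design is required for every BayesB model")
    a_ir = fit.effects["IR"]
    if w_ir_tst.shape[1] != a_ir.size:
        raise ValueError("test spectra width does not match the training layer")
    pred = w_ir_tst @ a_ir
    if model in ("M2", "M3", "M4"):
        if x_tst is None:
            raise ValueError(f"model {model} needs the test fixed-effect design")
        pred = pred + x_tst @ fit.b_hat
    if model == "M4":
        if w_snp_tst is None:
            raise ValueError("model M4 needs the test SNP design")
        a_snp = fit.effects["SNP"]
        if w_snp_tst.shape[1] != a_snp.size:
            raise ValueError("test SNP width does not match the training layer")
        pred = pred + w_snp_tst @ a_snp
    return pred
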