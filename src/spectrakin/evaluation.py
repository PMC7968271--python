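"""Model catalogue, cross-validation designs, and prediction metrics.

Seven covariate sets (M1-M7) are benchmarked across three inference
methods — multiple kernel learning, (multilayer) BayesB, and the PLS
baseline — but only the combinations of the catalogue are constructible:
the kernel method fits all seven, BayesB fits M1-M4 (it performs variable
selection internally, so the top-marker models are not applicable), and
PLS fits M1-M4 and M7.

Two resampling designs evaluate each combination: repeated random
sub-sampling at the cow level (default 716 train / 250 test), and
herd-blocked cross-validation (default 65 train / 20 test herds) in which
training and testing cows never share a herd, the herd fixed effect is
dropped from every model, and M2 (herd + spectra) is excluded.

Predictive performance is summarised by the squared Pearson correlation
between observed and predicted test phenotypes (predictive R^2) and the
slope of the regression of observed on predicted (dispersion bias; 1 is
unbiased).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import DataBundle, standardize_columns
from .kernels import RelationshipMatrix, genomic_kernel, pedigree_kernel, spectral_kernel
from .mkl import (
    MCMC,
    TEST_SCALE_MCMC,
    backsolve_snp_effects,
    fit_kernel_model,
    predict_kernel_testset,
    _eig_kernel,
)
from .mlbayesb import LayerSpec, fit_bayesb, fit_multilayer_bayesb, predict_bayesb
from .pls_baseline import fit_pls, pc_features, predict_pls

logger = logging.getLogger(__name__)

MODELS = ("M1", "M2", "M3", "M4", "M5", "M6", "M7")
METHODS = ("kernel", "bayesb", "pls")

#: covariate flags per catalogue model
MODEL_COVARIATES: dict[str, frozenset[str]] = {
    "M1": frozenset({"ftir"}),
    "M2": frozenset({"herd", "ftir"}),
    "M3": frozenset({"herd", "dim", "parity", "ftir"}),
    "M4": frozenset({"herd", "dim", "parity", "ftir", "genomics"}),
    "M5": frozenset({"herd", "dim", "parity", "ftir", "top_markers"}),
    "M6": frozenset({"herd", "dim", "parity", "ftir", "genomics", "top_markers"}),
    "M7": frozenset({"herd", "dim", "parity", "ftir", "pedigree"}),
}

#: method x model combinations that exist in the catalogue
ALLOWED: dict[str, tuple[str, ...]] = {
    "kernel": MODELS,
    "bayesb": ("M1", "M2", "M3", "M4"),
    "pls": ("M1", "M2", "M3", "M4", "M7"),
}


class CatalogueError(ValueError):
    """Requested a method x model combination outside the catalogue."""


@dataclass(frozen=True)
class ModelCatalogueEntry:
    model_id: str
    method: str
    covariates: frozenset[str]

    @property
    def fixed_terms(self) -> tuple[str, ...]:
        return tuple(t for t in ("herd", "dim", "parity") if t in self.covariates)


def catalogue_entry(model_id: str, method: str, herd_cv: bool = False) -> ModelCatalogueEntry:
    """Construct a catalogue entry, enforcing the allowed combinations.

    Under herd cross-validation the herd effect is stripped from every
    model and M2 (herd + spectra only) is not constructible.
    """
    if method not in ALLOWED:
        raise CatalogueError(f"unknown method {method!r}; choose from {METHODS}")
    if model_id not in MODEL_COVARIATES:
        raise CatalogueError(f"unknown model {model_id!r}; choose from {MODELS}")
    if model_id not in ALLOWED[method]:
        raise CatalogueError(f"{model_id} is not defined for method {method!r}")
    cov = MODEL_COVARIATES[model_id]
    if herd_cv:
        if model_id == "M2":
            raise CatalogueError("M2 is excluded under herd cross-validation")
        cov = cov - {"herd"}
    return ModelCatalogueEntry(model_id=model_id, method=method, covariates=cov)


@dataclass(frozen=True)
class AssembledModel:
    """What a catalogue entry wires together for its target method."""

    entry: ModelCatalogueEntry
    fixed_terms: tuple[str, ...]
    kernel_terms: tuple[str, ...] = ()
    layers: tuple[str, ...] = ()
    pls_blocks: tuple[str, ...] = ()


def build_model(entry: ModelCatalogueEntry) -> AssembledModel:
    """Wire fixed terms and random structure for one catalogue entry."""
    mid, cov = entry.model_id, entry.covariates
    fixed = ("intercept",) + entry.fixed_terms
    if "top_markers" in cov:
        fixed = fixed + ("top3_snps",)
    if entry.method == "kernel":
        kterms = ("S",)
        if "genomics" in cov:
            kterms = ("S", "G")
        elif "pedigree" in cov:
            kterms = ("S", "A")
        return AssembledModel(entry, fixed, kernel_terms=kterms)
    if entry.method == "bayesb":
        layers = ("IR", "SNP") if "genomics" in cov else ("IR",)
        return AssembledModel(entry, fixed, layers=layers)
    blocks = tuple(t for t in entry.fixed_terms) + ("ftir",)
    if "genomics" in cov:
        blocks = blocks + ("G_pcs",)
    if "pedigree" in cov:
        blocks = blocks + ("A_pcs",)
    return AssembledModel(entry, ("intercept",), pls_blocks=blocks)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Squared Pearson correlation of observed vs predicted."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.size != predicted.size or observed.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.std(predicted) == 0 or np.std(observed) == 0:
        warnings.warn("constant vector: predictive R^2 undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(observed, predicted)[0, 1] ** 2)


def regression_slope(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Slope of regressing observed on predicted: cov(o, p) / var(p)."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.size != predicted.size or observed.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    vp = np.var(predicted, ddof=1)
    if vp == 0:
        warnings.warn("constant predictions: slope undefined", stacklevel=2)
        return float("nan")
    cov = np.cov(observed, predicted, ddof=1)[0, 1]
    return float(cov / vp)


# ---------------------------------------------------------------------------
# top-SNP selection
# ---------------------------------------------------------------------------


def select_top_snps(
    effects: np.ndarray, snp_ids: np.ndarray, k: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The ``k`` SNPs with the largest absolute effects.

    Ties are broken by SNP order (stable sort), which is logged; an
    all-zero effect vector degenerates to the first ``k`` SNPs with a
    warning.  Returns (indices, ids, effects).
    """
    effects = np.asarray(effects, float)
    snp_ids = np.asarray(snp_ids, dtype=object)
    if k > effects.size:
        raise ValueError(f"k={k} exceeds panel size {effects.size}")
    if np.all(effects == 0):
        warnings.warn("all marker effects are zero; selecting the first k by order",
                      stacklevel=2)
    order = np.argsort(-np.abs(effects), kind="stable")
    mag = np.abs(effects[order])
    if mag.size > k and mag[k - 1] == mag[k]:
        logger.info("tie at the top-%d boundary broken by SNP order", k)
    top = order[:k]
    return top, snp_ids[top], effects[top]


# ---------------------------------------------------------------------------
# per-fold machinery
# ---------------------------------------------------------------------------


class _FoldContext:
    """Caches the fold-specific pieces shared across catalogue entries."""

    def __init__(
        self,
        bundle: DataBundle,
        trn: np.ndarray,
        tst: np.ndarray,
        g_kernel: RelationshipMatrix | None,
        a_kernel: RelationshipMatrix | None,
        standardize_scope: str = "train",
    ):
        self.bundle = bundle
        self.trn = np.asarray(trn)
        self.tst = np.asarray(tst)
        self.g_kernel = g_kernel
        self.a_kernel = a_kernel
        stats_rows = self.trn if standardize_scope == "train" else None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.w_all, self.w_stats = standardize_columns(
                bundle.spectra.values, stats_from=stats_rows
            )
        self.s_kernel = spectral_kernel(self.w_all, bundle.cow_ids)
        self._snp_z: np.ndarray | None = None
        self._eigs: dict[str, tuple] = {}
        self._designs: dict[tuple, tuple[np.ndarray, tuple[str, ...]]] = {}
        self._pcs: dict[str, np.ndarray] = {}

    # -- genotype layer (train-standardized dosages over all cows)
    @property
    def snp_z(self) -> np.ndarray:
        if self._snp_z is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self._snp_z, self._snp_stats = standardize_columns(
                    self.bundle.genotypes.dosages, stats_from=self.trn
                )
        return self._snp_z

    def kernel(self, label: str) -> RelationshipMatrix:
        if label == "S":
            return self.s_kernel
        if label == "G":
            if self.g_kernel is None:
                raise ValueError("genomic kernel not available in this run")
            return self.g_kernel
        if label == "A":
            if self.a_kernel is None:
                raise ValueError("pedigree kernel not available in this run")
            return self.a_kernel
        raise KeyError(label)

    def eig(self, label: str, kmat: np.ndarray):
        """Eigendecomposition cached per kernel per fold."""
        if label not in self._eigs:
            self._eigs[label] = _eig_kernel(kmat, label)
        return self._eigs[label]

    def pcs(self, label: str) -> np.ndarray:
        if label not in self._pcs:
            scores, count = pc_features(self.kernel(label[0]))
            logger.info("retained %d principal components of %s", count, label[0])
            self._pcs[label] = scores
        return self._pcs[label]

    def design(
        self, terms: tuple[str, ...], snp3_idx: np.ndarray | None = None
    ) -> tuple[np.ndarray, tuple[str, ...]]:
        """Fixed-effect design over all cows from training-row levels.

        Herd and parity are one-hot with first-level reference; DIM is a
        single linear covariate centered on the training mean.  Test levels
        unseen in training get the zero (reference-mean) effect.
        """
        key = (terms, None if snp3_idx is None else tuple(snp3_idx))
        if key in self._designs:
            return self._designs[key]
        farm = self.bundle.farm
        n = self.bundle.n_cows
        cols = [np.ones((n, 1))]
        names = ["intercept"]
        if "herd" in terms:
            levels = sorted(set(farm.herd[self.trn]))
            for lev in levels[1:]:
                cols.append((farm.herd == lev).astype(float)[:, None])
                names.append(f"herd[{lev}]")
            unseen = set(farm.herd[self.tst]) - set(levels)
            if unseen:
                logger.info("%d test herd level(s) unseen in training mapped to "
                            "the reference-mean effect", len(unseen))
        if "dim" in terms:
            cols.append((farm.dim - farm.dim[self.trn].mean())[:, None])
            names.append("dim")
        if "parity" in terms:
            levels = sorted(set(farm.parity[self.trn]))
            for lev in levels[1:]:
                cols.append((farm.parity == lev).astype(float)[:, None])
                names.append(f"parity[{lev}]")
        if snp3_idx is not None:
            z = self.snp_z[:, snp3_idx]
            cols.append(z)
            names.extend(f"snp3[{self.bundle.genotypes.snp_ids[j]}]" for j in snp3_idx)
        x = np.hstack(cols)
        out = (x, tuple(names))
        self._designs[key] = out
        return out


def _predictions_for_entries(
    ctx: _FoldContext,
    y: np.ndarray,
    entries: list[ModelCatalogueEntry],
    mcmc: MCMC,
    seeds: dict[tuple[str, str], int],
    df: float = 5.0,
    r2_prior: float = 0.5,
    pls_max_components: int = 50,
    allele_freq: np.ndarray | None = None,
) -> dict[tuple[str, str], np.ndarray]:
    """Fit and predict every requested entry on one train/test split."""
    bundle, trn, tst = ctx.bundle, ctx.trn, ctx.tst
    preds: dict[tuple[str, str], np.ndarray] = {}

    kernel_entries = [e for e in entries if e.method == "kernel"]
    need_top3 = any("top_markers" in e.covariates for e in kernel_entries)
    m4_fit = None
    top3_idx = None

    def fit_kernel_entry(entry: ModelCatalogueEntry):
        assembled = build_model(entry)
        snp3 = top3_idx if "top_markers" in entry.covariates else None
        x_all, names = ctx.design(entry.fixed_terms, snp3_idx=snp3)
        kernels_full: dict[str, RelationshipMatrix | np.ndarray] = {}
        for lab in assembled.kernel_terms:
            if lab == "G" and "top_markers" in entry.covariates:
                # M6: rebuild G from all markers excluding the selected top 3
                keep = np.setdiff1d(np.arange(bundle.genotypes.m_snp), top3_idx)
                kernels_full["G"] = genomic_kernel(bundle.genotypes.dosages[:, keep],
                                                   ids=bundle.cow_ids)
            else:
                kernels_full[lab] = ctx.kernel(lab)
        k_trn = {lab: (k.values if isinstance(k, RelationshipMatrix) else k)
                 [np.ix_(trn, trn)] for lab, k in kernels_full.items()}
        eigs = {}
        for lab, km in k_trn.items():
            cache_key = lab if (lab != "G" or "top_markers" not in entry.covariates) \
                else f"G_excl_{tuple(top3_idx)}"
            eigs[lab] = ctx.eig(cache_key, km)
        fit = fit_kernel_model(
            y[trn], x_all[trn], k_trn, mcmc=mcmc,
            seed=seeds[(entry.model_id, "kernel")], df=df, r2=r2_prior,
            eigs=eigs, store_u_chains=False, fixed_names=names,
        )
        pred = predict_kernel_testset(
            fit, entry.model_id, kernels_full, trn, tst, x_tst=x_all[tst]
        )
        return fit, pred

    if need_top3:
        # top-3 markers are selected from the training fold of the kernel M4 fit
        base = next(e for e in kernel_entries if "top_markers" in e.covariates)
        m4_like = ModelCatalogueEntry(
            "M4", "kernel", (base.covariates - {"top_markers"}) | {"genomics"}
        )
        m4_fit, m4_pred = fit_kernel_entry(m4_like)
        if ("M4", "kernel") in [(e.model_id, e.method) for e in kernel_entries]:
            preds[("M4", "kernel")] = m4_pred
        freqs = (allele_freq if allele_freq is not None
                 else bundle.genotypes.dosages.mean(axis=0) / 2.0)
        effects = backsolve_snp_effects(
            m4_fit.u_hat["G"], bundle.genotypes.dosages[trn], freqs
        )
        top3_idx, _, _ = select_top_snps(effects, bundle.genotypes.snp_ids, k=3)

    for entry in kernel_entries:
        key = (entry.model_id, "kernel")
        if key in preds:
            continue
        _, preds[key] = fit_kernel_entry(entry)

    # ---- BayesB -----------------------------------------------------------
    bayesb_entries = [e for e in entries if e.method == "bayesb"]
    for entry in bayesb_entries:
        x_all, names = ctx.design(entry.fixed_terms)
        ir = LayerSpec(ctx.w_all[trn], "IR")
        seed = seeds[(entry.model_id, "bayesb")]
        if "genomics" in entry.covariates:
            snp = LayerSpec(ctx.snp_z[trn], "SNP")
            fit = fit_multilayer_bayesb(y[trn], ir, snp, x=x_all[trn], mcmc=mcmc,
                                        seed=seed, fixed_names=names)
            pred = predict_bayesb(fit, entry.model_id, x_tst=x_all[tst],
                                  w_ir_tst=ctx.w_all[tst], w_snp_tst=ctx.snp_z[tst])
        else:
            fit = fit_bayesb(y[trn], ir, x=x_all[trn], mcmc=mcmc, seed=seed,
                             fixed_names=names)
            pred = predict_bayesb(fit, entry.model_id, x_tst=x_all[tst],
                                  w_ir_tst=ctx.w_all[tst])
        preds[(entry.model_id, "bayesb")] = pred

    # ---- PLS ----------------------------------------------------------------
    pls_entries = [e for e in entries if e.method == "pls"]
    for entry in pls_entries:
        assembled = build_model(entry)
        blocks_all: list[np.ndarray] = []
        for block in assembled.pls_blocks:
            if block == "herd":
                x_all, _ = ctx.design(("herd",))
                blocks_all.append(x_all[:, 1:])
            elif block == "dim":
                blocks_all.append(ctx.bundle.farm.dim[:, None].astype(float))
            elif block == "parity":
                x_all, _ = ctx.design(("parity",))
                blocks_all.append(x_all[:, 1:])
            elif block == "ftir":
                blocks_all.append(bundle.spectra.values)
            elif block == "G_pcs":
                blocks_all.append(ctx.pcs("G_pcs"))
            elif block == "A_pcs":
                blocks_all.append(ctx.pcs("A_pcs"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_pls(
                y[trn], [b[trn] for b in blocks_all],
                max_components=pls_max_components,
                seed=seeds[(entry.model_id, "pls")],
            )
            preds[(entry.model_id, "pls")] = predict_pls(fit, [b[tst] for b in blocks_all])

    return preds


# ---------------------------------------------------------------------------
# cross-validation drivers
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    """Per trait x model x method x repeat metrics plus fold assignments."""

    records: pd.DataFrame
    folds: list[dict[str, list]]
    seed: int
    scheme: str

    def summary(self) -> pd.DataFrame:
        """Mean and SD of R^2 and slope over repeats."""
        return (
            self.records.groupby(["trait", "model", "method"])
            .agg(
                r2_mean=("r2", "mean"),
                r2_sd=("r2", "std"),
                slope_mean=("slope", "mean"),
                slope_sd=("slope", "std"),
                repeats=("repeat", "count"),
            )
            .reset_index()
        )


def _resolve_entries(entries, herd_cv: bool) -> list[ModelCatalogueEntry]:
    out = []
    for item in entries:
        if isinstance(item, ModelCatalogueEntry):
            out.append(item)
        else:
            model_id, method = item
            out.append(catalogue_entry(model_id, method, herd_cv=herd_cv))
    return out


def _shared_kernels(bundle: DataBundle, entries) -> tuple:
    need_g = any("genomics" in e.covariates or "top_markers" in e.covariates
                 for e in entries)
    need_a = any("pedigree" in e.covariates for e in entries)
    g = genomic_kernel(bundle.genotypes) if need_g else None
    a = pedigree_kernel(bundle.pedigree, bundle.cow_ids) if need_a else None
    return g, a


def _run_cv(
    bundle: DataBundle,
    entries: list[ModelCatalogueEntry],
    traits: list[str],
    splits: list[tuple[np.ndarray, np.ndarray]],
    seed: int,
    scheme: str,
    mcmc: MCMC,
    pls_max_components: int,
    standardize_scope: str,
) -> CVReport:
    g_kernel, a_kernel = _shared_kernels(bundle, entries)
    allele_freq = bundle.genotypes.dosages.mean(axis=0) / 2.0 if g_kernel is not None else None
    rows = []
    folds = []
    seed_seq = np.random.SeedSequence(seed)
    repeat_seqs = seed_seq.spawn(len(splits))
    trait_idx = {t: i for i, t in enumerate(bundle.traits.trait_names)}
    for rep, (trn, tst) in enumerate(splits):
        folds.append({
            "repeat": rep,
            "train": [str(c) for c in bundle.cow_ids[trn]],
            "test": [str(c) for c in bundle.cow_ids[tst]],
        })
        ctx = _FoldContext(bundle, trn, tst, g_kernel, a_kernel,
                           standardize_scope=standardize_scope)
        rep_rng = np.random.default_rng(repeat_seqs[rep])
        for trait in traits:
            y = bundle.traits.values[:, trait_idx[trait]]
            seeds = {
                (e.model_id, e.method): int(rep_rng.integers(2**31))
                for e in entries
            }
            # the M5/M6 path needs an M4 seed even when M4 was not requested
            seeds.setdefault(("M4", "kernel"), int(rep_rng.integers(2**31)))
            preds = _predictions_for_entries(
                ctx, y, entries, mcmc, seeds,
                pls_max_components=pls_max_components, allele_freq=allele_freq,
            )
            for e in entries:
                pred = preds[(e.model_id, e.method)]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rows.append({
                        "trait": trait,
                        "model": e.model_id,
                        "method": e.method,
                        "repeat": rep,
                        "r2": r_squared(y[tst], pred),
                        "slope": regression_slope(y[tst], pred),
                    })
    return CVReport(records=pd.DataFrame(rows), folds=folds, seed=seed, scheme=scheme)


def random_subsampling_cv(
    bundle: DataBundle,
    entries,
    traits: list[str] | None = None,
    n_test: int = 250,
    repeats: int = 10,
    seed: int = 0,
    mcmc: MCMC = TEST_SCALE_MCMC,
    pls_max_components: int = 50,
    standardize_scope: str = "train",
) -> CVReport:
    """Repeated random sub-sampling CV with uniform cow-level splits.

    With the full-scale cohort the defaults reproduce the 716-train /
    250-test partition.  Fold assignment is a seeded permutation of the
    sorted cow ids, so it is invariant to row ordering.
    """
    n = bundle.n_cows
    if not 0 < n_test < n:
        raise ValueError("n_test must be in (0, n_cows)")
    entries = _resolve_entries(entries, herd_cv=False)
    traits = list(traits or bundle.traits.trait_names)
    order = np.argsort(np.asarray(bundle.cow_ids, dtype=str))
    seq = np.random.SeedSequence([seed, 0x5EED])
    splits = []
    for child in seq.spawn(repeats):
        rng = np.random.default_rng(child)
        perm = rng.permutation(n)
        tst = np.sort(order[perm[:n_test]])
        trn = np.sort(order[perm[n_test:]])
        splits.append((trn, tst))
    return _run_cv(bundle, entries, traits, splits, seed, "random", mcmc,
                   pls_max_components, standardize_scope)


def herd_cv(
    bundle: DataBundle,
    entries,
    traits: list[str] | None = None,
    n_train_herds: int = 65,
    n_test_herds: int = 20,
    repeats: int = 10,
    seed: int = 0,
    mcmc: MCMC = TEST_SCALE_MCMC,
    pls_max_components: int = 50,
    standardize_scope: str = "train",
) -> CVReport:
    """Herd-blocked CV: herds sampled without replacement into train/test.

    The herd effect is stripped from every fixed-effect set and M2 is not
    allowed.  Cows in herds assigned to neither set are left out of that
    repeat.
    """
    herds = np.array(sorted(set(bundle.farm.herd)), dtype=object)
    if len(herds) < n_train_herds + n_test_herds:
        raise ValueError(
            f"{len(herds)} herds cannot supply {n_train_herds} train + "
            f"{n_test_herds} test herds"
        )
    entries = _resolve_entries(entries, herd_cv=True)
    traits = list(traits or bundle.traits.trait_names)
    seq = np.random.SeedSequence([seed, 0x4E4D])
    splits = []
    for child in seq.spawn(repeats):
        rng = np.random.default_rng(child)
        perm = rng.permutation(len(herds))
        trn_herds = set(herds[perm[:n_train_herds]])
        tst_herds = set(herds[perm[n_train_herds:n_train_herds + n_test_herds]])
        assert not trn_herds & tst_herds, "train/test herds overlap"
        trn = np.flatnonzero(np.isin(bundle.farm.herd, list(trn_herds)))
        tst = np.flatnonzero(np.isin(bundle.farm.herd, list(tst_herds)))
        splits.append((trn, tst))
    return _run_cv(bundle, entries, traits, splits, seed, "herd", mcmc,
                   pls_max_components, standardize_scope)
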