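"""Calibrated synthetic cow-level datasets.

No public dataset accompanies the milk-protein prediction problem this
package addresses, so every component is exercised against a generator that
emulates the statistical structure the models assume:

* a cohort of cows distributed over commercial herds (default 966 cows in
  85 herds, 11.4 +/- 2.4 cows per herd), with days in milk (169.8 +/-
  101.8) and parity (2.4 +/- 1.2) covariates;
* a pedigree of founders plus one random-mating offspring generation, with
  founder alleles gene-dropped to give family-structured genotypes;
* a handful of large-effect QTL plus a polygenic background that together
  make up each trait's heritable variance;
* FTIR spectra that load the herd factor and the genetic value on smooth
  wavenumber curves, plus AR(1) channel-correlated noise — so spectra share
  herd and genetic signal with the traits, which is exactly the structure
  that makes random sub-sampling cross-validation optimistic relative to
  herd-blocked cross-validation;
* traits rescaled to the milk-protein means/SDs (% of total milk N).

Ground truth (breeding values, QTL positions/effects, herd effects,
variance shares) is returned alongside the data bundle for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .data_io import (
    DataBundle,
    GenotypeMatrix,
    OnFarmTable,
    Pedigree,
    SpectraMatrix,
    TraitTable,
    UNKNOWN_PARENT,
)

#: milk-protein trait catalogue: name -> (mean, SD), % of total milk N
TRAIT_MOMENTS = {
    "TP": (89.1, 2.25),
    "TCN": (78.0, 1.23),
    "TWP": (11.1, 1.70),
    "kCN": (9.45, 1.48),
    "bCN": (32.3, 2.45),
    "aS1CN": (25.7, 1.79),
    "aS2CN": (9.20, 1.14),
    "bLG": (8.68, 1.56),
    "aLA": (2.39, 0.50),
}


@dataclass
class SimConfig:
    """Generator settings; defaults mirror the cohort the models target."""

    n_cows: int = 966
    n_herds: int = 85
    cows_per_herd_mean: float = 11.4
    cows_per_herd_sd: float = 2.4
    dim_mean: float = 169.8
    dim_sd: float = 101.8
    parity_mean: float = 2.4
    parity_sd: float = 1.2
    m_ir: int = 1060
    wavenumber_max: float = 5011.0
    wavenumber_min: float = 925.0
    m_snp: int = 2000
    n_qtl: int = 3
    qtl_variance_share: float = 0.6  # share of genetic variance carried by the QTL
    h2: float | dict[str, float] = 0.5
    herd_variance_share: float = 0.25
    covariate_variance_share: float = 0.05
    spectra_herd_loading: float = 1.0
    spectra_genetic_loading: float = 1.0
    #: squared correlation between the genetic value and the genetic signal
    #: the spectra carry; < 1 means markers hold information the spectra do
    #: not, which is what makes adding genomics to spectra worthwhile
    spectra_genetic_fidelity: float = 0.5
    spectra_ar1_rho: float = 0.9
    traits: tuple[str, ...] = tuple(TRAIT_MOMENTS)
    trait_moments: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(TRAIT_MOMENTS)
    )
    missing_genotype_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cows, self.n_herds, self.m_ir, self.m_snp) < 1:
            raise ValueError("all counts must be positive")
        if self.n_qtl < 0 or self.n_qtl > self.m_snp:
            raise ValueError("n_qtl must be in [0, m_snp]")
        for name, h2 in self.h2_by_trait().items():
            total = h2 + self.herd_variance_share + self.covariate_variance_share
            if not 0.0 <= h2 <= 1.0 or total > 1.0:
                raise ValueError(
                    f"variance shares for trait {name} exceed 1 (h2={h2}, "
                    f"herd={self.herd_variance_share}, "
                    f"covariates={self.covariate_variance_share})"
                )

    def h2_by_trait(self) -> dict[str, float]:
        if isinstance(self.h2, dict):
            return {t: float(self.h2.get(t, 0.5)) for t in self.traits}
        return {t: float(self.h2) for t in self.traits}

    @classmethod
    def desk_scale(cls, **overrides) -> "SimConfig":
        """Reduced profile used throughout the test suite."""
        base = cls(n_cows=300, n_herds=26, m_ir=200, m_snp=500)
        return replace(base, **overrides) if overrides else base


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    breeding_values: np.ndarray  # n_cows x n_traits, trait units
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray  # effects of the shared genetic factor, unit scale
    herd_effects: np.ndarray  # per-herd factor, unit scale
    herd_of_cow: np.ndarray
    genetic_factor: np.ndarray  # shared standardized genetic value per cow
    herd_signature_curves: np.ndarray  # low-rank smooth herd spectral signatures
    genetic_loading_curve: np.ndarray
    variance_shares: dict[str, dict[str, float]]
    trait_names: tuple[str, ...]


def _herd_sizes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    sizes = np.maximum(
        np.round(rng.normal(cfg.cows_per_herd_mean, cfg.cows_per_herd_sd, cfg.n_herds)), 3
    ).astype(int)
    # adjust to sum exactly to n_cows
    while sizes.sum() > cfg.n_cows:
        j = rng.integers(cfg.n_herds)
        if sizes[j] > 3:
            sizes[j] -= 1
    while sizes.sum() < cfg.n_cows:
        sizes[rng.integers(cfg.n_herds)] += 1
    return sizes


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, size: int
) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = out < low
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < low
    return out


def _smooth_curve(rng: np.random.Generator, m: int) -> np.ndarray:
    """Unit-RMS smooth random loading across wavenumber channels."""
    raw = gaussian_filter1d(rng.standard_normal(m), sigma=max(m / 40, 2.0), mode="nearest")
    return raw / np.sqrt(np.mean(raw**2))


def _scale_to_var(x: np.ndarray, target_var: float) -> np.ndarray:
    """Center and rescale a component to an exact realized variance.

    Components are deviations from the cohort mean, so the configured trait
    mean is the cohort mean and variance shares are hit exactly per sample.
    """
    x = x - x.mean()
    v = float(np.var(x))
    if v <= 0 or target_var <= 0:
        return np.zeros_like(x)
    return x * np.sqrt(target_var / v)


def simulate_dataset(cfg: SimConfig) -> tuple[DataBundle, SimTruth]:
    """Generate one aligned data bundle plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)

    # --- herds and on-farm covariates -------------------------------------
    sizes = _herd_sizes(cfg, rng)
    herd_of_cow = np.repeat(np.arange(cfg.n_herds), sizes)
    herd_labels = np.array([f"H{h + 1:03d}" for h in range(cfg.n_herds)], dtype=object)
    dim = _truncated_normal(rng, cfg.dim_mean, cfg.dim_sd, 0.0, cfg.n_cows)
    parity = np.maximum(
        np.round(rng.normal(cfg.parity_mean, cfg.parity_sd, cfg.n_cows)), 1
    ).astype(int)

    # --- pedigree: founders + one offspring generation ---------------------
    n_founders = max(40, cfg.n_cows // 2)
    n_sires = n_founders // 2
    sire_ids = np.array([f"S{i + 1:04d}" for i in range(n_sires)], dtype=object)
    dam_ids = np.array([f"D{i + 1:04d}" for i in range(n_founders - n_sires)], dtype=object)
    cow_ids = np.array([f"C{i + 1:04d}" for i in range(cfg.n_cows)], dtype=object)
    sire_of = rng.integers(n_sires, size=cfg.n_cows)
    dam_of = rng.integers(n_founders - n_sires, size=cfg.n_cows)
    individual = np.concatenate([sire_ids, dam_ids, cow_ids])
    sire_col = np.concatenate(
        [np.full(n_founders, UNKNOWN_PARENT, dtype=object), sire_ids[sire_of]]
    )
    dam_col = np.concatenate(
        [np.full(n_founders, UNKNOWN_PARENT, dtype=object), dam_ids[dam_of]]
    )
    pedigree = Pedigree(individual, sire_col, dam_col)

    # --- genotypes: founder haplotypes gene-dropped to the cows ------------
    p_ref = rng.uniform(0.05, 0.5, cfg.m_snp)
    hap1 = (rng.random((n_founders, cfg.m_snp)) < p_ref).astype(np.int8)
    hap2 = (rng.random((n_founders, cfg.m_snp)) < p_ref).astype(np.int8)
    dam_offset = n_sires

    def gamete(parent_rows: np.ndarray) -> np.ndarray:
        pick = rng.random((cfg.n_cows, cfg.m_snp)) < 0.5
        return np.where(pick, hap1[parent_rows], hap2[parent_rows])

    dosages = (gamete(sire_of) + gamete(dam_offset + dam_of)).astype(float)
    snp_ids = np.array([f"SNP{j + 1:05d}" for j in range(cfg.m_snp)], dtype=object)

    # --- shared genetic factor: QTL + polygenic background -----------------
    freq = dosages.mean(axis=0) / 2.0
    informative = np.flatnonzero((freq >= 0.15) & (freq <= 0.85))
    if informative.size < cfg.n_qtl:
        informative = np.argsort(np.abs(freq - 0.5))[: max(cfg.n_qtl, 1)]
    qtl_indices = np.sort(rng.choice(informative, size=cfg.n_qtl, replace=False))
    sd_all = dosages.std(axis=0)
    sd_all[sd_all == 0] = 1.0
    z = (dosages - 2.0 * freq) / sd_all

    # planted QTL are equal-magnitude (random sign): every QTL carries the
    # same share of the QTL variance, so each one is unambiguously "large"
    qtl_effects = rng.choice([-1.0, 1.0], cfg.n_qtl)
    g_qtl = z[:, qtl_indices] @ qtl_effects if cfg.n_qtl else np.zeros(cfg.n_cows)
    poly_cols = np.setdiff1d(np.arange(cfg.m_snp), qtl_indices)
    g_poly = z[:, poly_cols] @ rng.standard_normal(poly_cols.size)
    g = _scale_to_var(g_qtl, cfg.qtl_variance_share) + _scale_to_var(
        g_poly, 1.0 - cfg.qtl_variance_share
    )
    g = _scale_to_var(g, 1.0)  # shared standardized genetic value

    # --- herd factor and covariate effects (unit scale) --------------------
    herd_effects = rng.standard_normal(cfg.n_herds)
    herd_term = _scale_to_var(herd_effects[herd_of_cow], 1.0)
    dim_z = (dim - dim.mean()) / dim.std()
    par_z = (parity - parity.mean()) / max(parity.std(), 1e-9)
    cov_term = _scale_to_var(dim_z + 0.7 * par_z, 1.0)

    # --- traits -------------------------------------------------------------
    h2 = cfg.h2_by_trait()
    n_traits = len(cfg.traits)
    values = np.empty((cfg.n_cows, n_traits))
    bv = np.empty((cfg.n_cows, n_traits))
    shares: dict[str, dict[str, float]] = {}
    for t, name in enumerate(cfg.traits):
        mean, sd = cfg.trait_moments.get(name, (0.0, 1.0))
        resid_share = 1.0 - h2[name] - cfg.herd_variance_share - cfg.covariate_variance_share
        g_t = _scale_to_var(g, h2[name])
        pheno = (
            g_t
            + _scale_to_var(herd_term, cfg.herd_variance_share)
            + _scale_to_var(cov_term, cfg.covariate_variance_share)
            + rng.standard_normal(cfg.n_cows) * np.sqrt(resid_share)
        )
        values[:, t] = mean + sd * pheno
        bv[:, t] = sd * g_t
        shares[name] = {
            "h2": h2[name],
            "herd": cfg.herd_variance_share,
            "covariates": cfg.covariate_variance_share,
            "residual": resid_share,
        }

    # --- spectra ------------------------------------------------------------
    wavenumbers = np.linspace(cfg.wavenumber_max, cfg.wavenumber_min, cfg.m_ir)
    channel = np.linspace(0.0, 1.0, cfg.m_ir)
    baseline = 0.4 + 0.3 * np.exp(-((channel - 0.25) ** 2) / 0.02) + 0.2 * np.sin(
        2.5 * np.pi * channel
    )
    # Herd enters the spectra as a herd-specific signature: every herd gets
    # its own independent smooth curve (unrelated to the herd trait effect).
    # Spectra therefore cluster herdmates — which is what lets cow-level
    # random CV borrow herd means through the spectral kernel, one degree of
    # freedom per herd — without carrying a transferable herd-to-trait
    # mapping, so the borrowed signal vanishes for unseen herds under
    # herd-blocked CV.
    herd_curves = np.vstack([_smooth_curve(rng, cfg.m_ir) for _ in range(cfg.n_herds)])
    load_g = _smooth_curve(rng, cfg.m_ir)
    fid = cfg.spectra_genetic_fidelity
    if not 0.0 <= fid <= 1.0:
        raise ValueError("spectra_genetic_fidelity must be in [0, 1]")
    g_spec = np.sqrt(fid) * g + np.sqrt(1.0 - fid) * rng.standard_normal(cfg.n_cows)
    noise = rng.standard_normal((cfg.n_cows, cfg.m_ir))
    for c in range(1, cfg.m_ir):  # AR(1) across adjacent wavenumbers
        noise[:, c] = cfg.spectra_ar1_rho * noise[:, c - 1] + np.sqrt(
            1.0 - cfg.spectra_ar1_rho**2
        ) * noise[:, c]
    spectra_values = (
        baseline
        + cfg.spectra_herd_loading * herd_curves[herd_of_cow]
        + cfg.spectra_genetic_loading * np.outer(g_spec, load_g)
        + 0.5 * noise
    )
    spectra = SpectraMatrix(spectra_values, wavenumbers, cow_ids)

    # --- optional missingness for QC/imputation exercises -------------------
    if cfg.missing_genotype_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_genotype_rate
        dosages = dosages.copy()
        dosages[mask] = np.nan

    bundle = DataBundle(
        spectra=spectra,
        genotypes=GenotypeMatrix(dosages, snp_ids, cow_ids),
        pedigree=pedigree,
        farm=OnFarmTable(cow_ids, herd_labels[herd_of_cow], dim, parity),
        traits=TraitTable(cow_ids, values, tuple(cfg.traits)),
    )
    truth = SimTruth(
        breeding_values=bv,
        qtl_indices=qtl_indices,
        qtl_effects=qtl_effects,
        herd_effects=herd_effects,
        herd_of_cow=herd_of_cow,
        genetic_factor=g,
        herd_signature_curves=herd_curves,
        genetic_loading_curve=load_g,
        variance_shares=shares,
        trait_names=tuple(cfg.traits),
    )
    return bundle, truth


def realized_h2(bundle: DataBundle, truth: SimTruth) -> dict[str, float]:
    """var(true breeding value) / var(trait) on the realized sample."""
    out = {}
    for t, name in enumerate(truth.trait_names):
        vp = float(np.var(bundle.traits.values[:, t]))
        if vp <= 0:
            raise ValueError(f"trait {name} has zero variance")
        out[name] = float(np.var(truth.breeding_values[:, t])) / vp
    return out
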