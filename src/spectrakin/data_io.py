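"""Input tables, validation, quality control and preprocessing.

Four cow-level tables drive every model in this package:

* milk FTIR spectra (cows x wavenumbers, absorbance, cm^-1 column labels),
* SNP genotypes (cows x markers, 0/1/2 dosages with missing codes),
* a three-column pedigree (individual, sire, dam; ``0`` = unknown parent),
* on-farm covariates (herd, days in milk, parity) and the milk-protein
  trait table (fractions expressed as % of total milk N).

This module reads and writes the delimited-text form of each table, applies
the standard preprocessing (acquisition averaging, genotype QC and binomial
imputation, PCA/Mahalanobis outlier screening, column standardization) and
enforces strict identifier reconciliation before any modelling happens.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: sentinel for an unknown parent in pedigree files
UNKNOWN_PARENT = "0"

#: tokens read as a missing genotype call (any negative number also counts)
MISSING_TOKENS = ("NA", "NaN", "nan", ".", "")


class FormatError(ValueError):
    """Malformed or inconsistent input data."""


class QCError(ValueError):
    """Quality control left no usable data."""


class AlignmentError(ValueError):
    """Cow identifiers do not reconcile across tables."""


class PedigreeError(ValueError):
    """Invalid pedigree (cycle, missing parent record, ...)."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class SpectraMatrix:
    """Cow-by-wavenumber absorbance matrix.

    Parameters
    ----------
    values
        ``(n_cows, m_ir)`` real matrix, no missing entries.
    wavenumbers
        Strictly monotone channel labels in cm^-1 (instruments typically
        report them in descending order).
    cow_ids
        ``n_cows`` unique identifiers.
    """

    values: np.ndarray
    wavenumbers: np.ndarray
    cow_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.cow_ids = np.asarray(self.cow_ids, dtype=object)
        n, m = self.values.shape
        if m < 1:
            raise FormatError("spectra need at least one wavenumber")
        if self.wavenumbers.shape != (m,):
            raise FormatError("wavenumber labels do not match matrix width")
        if self.cow_ids.shape != (n,):
            raise FormatError("cow ids do not match matrix height")
        diffs = np.diff(self.wavenumbers)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise FormatError("wavenumbers must be strictly monotone")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("spectra contain missing or non-finite entries")
        if len(set(self.cow_ids)) != n:
            raise FormatError("duplicate cow ids in spectra")

    @property
    def n_cows(self) -> int:
        return self.values.shape[0]

    @property
    def m_ir(self) -> int:
        return self.values.shape[1]


@dataclass
class GenotypeMatrix:
    """Cow-by-SNP dosage matrix; missing calls are ``NaN`` internally."""

    dosages: np.ndarray
    snp_ids: np.ndarray
    cow_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.cow_ids = np.asarray(self.cow_ids, dtype=object)
        n, m = self.dosages.shape
        if self.snp_ids.shape != (m,) or self.cow_ids.shape != (n,):
            raise FormatError("genotype labels do not match matrix shape")
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.all(np.isin(observed, (0.0, 1.0, 2.0))):
            raise FormatError("genotype dosages must be 0, 1, 2 or missing")

    @property
    def n_cows(self) -> int:
        return self.dosages.shape[0]

    @property
    def m_snp(self) -> int:
        return self.dosages.shape[1]

    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing calls."""
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def reference_allele_freq(self) -> np.ndarray:
        """Per-SNP reference allele frequency from the observed calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_freq(self) -> np.ndarray:
        p = self.reference_allele_freq()
        return np.minimum(p, 1.0 - p)


@dataclass
class Pedigree:
    """Three-column pedigree; ``"0"`` marks an unknown parent."""

    individual: np.ndarray
    sire: np.ndarray
    dam: np.ndarray

    def __post_init__(self) -> None:
        self.individual = np.asarray(self.individual, dtype=object)
        self.sire = np.asarray(self.sire, dtype=object)
        self.dam = np.asarray(self.dam, dtype=object)
        if not (len(self.individual) == len(self.sire) == len(self.dam)):
            raise FormatError("pedigree columns differ in length")
        if len(set(self.individual)) != len(self.individual):
            raise FormatError("duplicate individuals in pedigree")
        # run the topological sort once so cycles fail fast at load time
        self.topological_order()

    def __len__(self) -> int:
        return len(self.individual)

    def parents(self) -> dict[object, tuple[object, object]]:
        return {
            ind: (s, d)
            for ind, s, d in zip(self.individual, self.sire, self.dam)
        }

    def topological_order(self) -> list[object]:
        """Founder-first ordering; raises :class:`PedigreeError` on a cycle."""
        parents = {
            ind: tuple(p for p in (s, d) if p != UNKNOWN_PARENT)
            for ind, s, d in zip(self.individual, self.sire, self.dam)
        }
        order: list[object] = []
        state: dict[object, int] = {}  # 0 visiting, 1 done

        for root in self.individual:
            if state.get(root) == 1:
                continue
            stack = [(root, iter(parents.get(root, ())))]
            state[root] = 0
            path = [root]
            while stack:
                node, it = stack[-1]
                advanced = False
                for par in it:
                    if par not in parents:
                        continue  # parent without its own record: treated as founder
                    st = state.get(par)
                    if st == 0:
                        cycle = path[path.index(par):] + [par]
                        raise PedigreeError(
                            "pedigree cycle detected: " + " -> ".join(map(str, cycle))
                        )
                    if st is None:
                        state[par] = 0
                        stack.append((par, iter(parents[par])))
                        path.append(par)
                        advanced = True
                        break
                if not advanced:
                    stack.pop()
                    path.pop()
                    state[node] = 1
                    order.append(node)
        return order


@dataclass
class OnFarmTable:
    """Herd, days in milk and parity for every cow."""

    cow_ids: np.ndarray
    herd: np.ndarray
    dim: np.ndarray
    parity: np.ndarray

    def __post_init__(self) -> None:
        self.cow_ids = np.asarray(self.cow_ids, dtype=object)
        self.herd = np.asarray(self.herd, dtype=object)
        self.dim = np.asarray(self.dim, dtype=float)
        self.parity = np.asarray(self.parity, dtype=int)
        n = len(self.cow_ids)
        if not (len(self.herd) == len(self.dim) == len(self.parity) == n):
            raise FormatError("on-farm columns differ in length")
        if np.any(~np.isfinite(self.dim)) or np.any(self.dim < 0):
            raise FormatError("DIM must be finite and >= 0")
        if np.any(self.parity < 1):
            raise FormatError("parity must be a positive integer")


@dataclass
class TraitTable:
    """Milk-protein phenotypes (% of total milk N), one column per trait."""

    cow_ids: np.ndarray
    values: np.ndarray
    trait_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.cow_ids = np.asarray(self.cow_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.trait_names = tuple(self.trait_names)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.shape != (len(self.cow_ids), len(self.trait_names)):
            raise FormatError("trait table shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("trait values must be finite")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.trait_names.index(name)]


@dataclass
class DataBundle:
    """The aligned set of tables a model run consumes."""

    spectra: SpectraMatrix
    genotypes: GenotypeMatrix
    pedigree: Pedigree
    farm: OnFarmTable
    traits: TraitTable

    @property
    def cow_ids(self) -> np.ndarray:
        return self.spectra.cow_ids

    @property
    def n_cows(self) -> int:
        return self.spectra.n_cows


def make_bundle(
    spectra: SpectraMatrix,
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    farm: OnFarmTable,
    traits: TraitTable,
) -> DataBundle:
    """Join the five tables on cow id, strictly.

    Every cow present in the spectra must appear in genotypes, on-farm,
    trait and pedigree tables; otherwise the join aborts with a
    reconciliation report listing the offending ids per table.
    """
    ref = list(spectra.cow_ids)
    ref_set = set(ref)
    report = {}
    for name, ids in (
        ("genotypes", set(genotypes.cow_ids)),
        ("farm", set(farm.cow_ids)),
        ("traits", set(traits.cow_ids)),
        ("pedigree", set(pedigree.individual)),
    ):
        missing = sorted(map(str, ref_set - ids))
        extra = [] if name == "pedigree" else sorted(map(str, ids - ref_set))
        if missing or extra:
            report[name] = {"missing": missing, "extra": extra}
    if report:
        raise AlignmentError(f"cow ids do not reconcile across tables: {report}")

    def order(ids: np.ndarray) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(ids)}
        return np.array([lookup[c] for c in ref])

    gi = order(genotypes.cow_ids)
    fi = order(farm.cow_ids)
    ti = order(traits.cow_ids)
    return DataBundle(
        spectra=spectra,
        genotypes=GenotypeMatrix(genotypes.dosages[gi], genotypes.snp_ids, spectra.cow_ids),
        pedigree=pedigree,
        farm=OnFarmTable(spectra.cow_ids, farm.herd[fi], farm.dim[fi], farm.parity[fi]),
        traits=TraitTable(spectra.cow_ids, traits.values[ti], traits.trait_names),
    )


# ---------------------------------------------------------------------------
# acquisition averaging
# ---------------------------------------------------------------------------


def average_acquisitions(
    raw: Mapping[object, np.ndarray], wavenumbers: Sequence[float]
) -> SpectraMatrix:
    """Average replicate spectral acquisitions per cow.

    ``raw`` maps each cow id to an ``(n_replicates, m_ir)`` array on the
    common ``wavenumbers`` grid; each cow's replicates are reduced to their
    arithmetic mean.
    """
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    cow_ids, rows = [], []
    for cow, reps in raw.items():
        arr = np.atleast_2d(np.asarray(reps, dtype=float))
        if arr.shape[0] < 1:
            raise FormatError(f"cow {cow!r} has no acquisitions")
        if arr.shape[1] != wavenumbers.size:
            raise FormatError(
                f"cow {cow!r}: replicate grid has {arr.shape[1]} channels, "
                f"expected {wavenumbers.size}"
            )
        cow_ids.append(cow)
        rows.append(arr.mean(axis=0))
    return SpectraMatrix(np.vstack(rows), wavenumbers, np.array(cow_ids, dtype=object))


# ---------------------------------------------------------------------------
# genotype QC and imputation
# ---------------------------------------------------------------------------


def genotype_qc(
    g: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.05,
) -> tuple[GenotypeMatrix, dict]:
    """Remove SNPs with call rate or MAF strictly below the thresholds.

    Values exactly at a threshold are kept (the filters are stated as
    removal for ``< 0.95`` and ``< 0.05``).  Returns the filtered matrix and
    a per-SNP JSON-serializable report.
    """
    call = g.call_rate()
    maf = g.minor_allele_freq()
    keep = np.ones(g.m_snp, dtype=bool)
    decisions = []
    for j, snp in enumerate(g.snp_ids):
        reasons = []
        if call[j] < call_rate_min:
            reasons.append("call_rate")
        if np.isnan(maf[j]) or maf[j] < maf_min:
            reasons.append("maf")
        if reasons:
            keep[j] = False
        decisions.append(
            {
                "snp": str(snp),
                "call_rate": float(call[j]),
                "maf": None if np.isnan(maf[j]) else float(maf[j]),
                "kept": bool(keep[j]),
                "reasons": reasons,
            }
        )
    if not keep.any():
        raise QCError("no SNPs survive quality control")
    report = {
        "call_rate_min": call_rate_min,
        "maf_min": maf_min,
        "n_input": int(g.m_snp),
        "n_kept": int(keep.sum()),
        "n_removed": int((~keep).sum()),
        "snps": decisions,
    }
    out = GenotypeMatrix(g.dosages[:, keep], g.snp_ids[keep], g.cow_ids)
    return out, report


def impute_genotypes(g: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Fill missing calls with Binomial(2, p_ref) draws per SNP.

    ``p_ref`` is the reference allele frequency computed from the observed
    calls of that SNP; a SNP with no observed call has an undefined
    frequency and raises.
    """
    p = g.reference_allele_freq()
    if np.any(np.isnan(p)):
        bad = [str(s) for s in g.snp_ids[np.isnan(p)]]
        raise QCError(f"cannot impute SNPs with no observed calls: {bad[:5]}")
    rng = np.random.default_rng(seed)
    dosages = g.dosages.copy()
    miss_rows, miss_cols = np.nonzero(np.isnan(dosages))
    dosages[miss_rows, miss_cols] = rng.binomial(2, p[miss_cols]).astype(float)
    return GenotypeMatrix(dosages, g.snp_ids, g.cow_ids)


# ---------------------------------------------------------------------------
# spectral outlier screening
# ---------------------------------------------------------------------------


def spectral_outlier_screen(
    s: SpectraMatrix,
    n_components: int = 5,
    distance_quantile: float = 0.99,
) -> np.ndarray:
    """Flag cows with extreme Mahalanobis distance in PC space.

    The spectra are centered, projected on the leading ``n_components``
    principal components, and each cow's Mahalanobis distance in that space
    is compared with the chi-square quantile ``distance_quantile`` (the
    squared distance of a multivariate normal is chi-square with
    ``n_components`` degrees of freedom).  Cows are flagged only — never
    removed automatically.
    """
    n, m = s.values.shape
    if not 0 < n_components < min(n, m):
        raise ValueError("n_components must be in (0, min(n_cows, m_ir))")
    if not 0.0 < distance_quantile < 1.0:
        raise ValueError("distance_quantile must be in (0, 1)")
    centered = s.values - s.values.mean(axis=0)
    _, sing, vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = sing[:n_components] ** 2 / (n - 1)
    if np.any(eigvals <= 1e-12 * max(eigvals[0], 1.0)):
        raise ValueError(
            "singular principal-component covariance; use fewer components"
        )
    scores = centered @ vt[:n_components].T
    d2 = np.sum(scores**2 / eigvals, axis=1)
    threshold = sps.chi2.ppf(distance_quantile, df=n_components)
    flagged = s.cow_ids[d2 > threshold]
    logger.info("spectral outlier screen flagged %d/%d cows", len(flagged), n)
    return flagged


# ---------------------------------------------------------------------------
# column standardization
# ---------------------------------------------------------------------------


@dataclass
class ColumnStats:
    """Training-row means/SDs plus the retained-column mask."""

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kept is None:
            self.kept = np.ones(len(self.mean), dtype=bool)

    def transform(self, m: np.ndarray) -> np.ndarray:
        """Apply the stored centering/scaling to new rows."""
        m = np.asarray(m, dtype=float)
        if m.shape[1] != len(self.kept):
            raise FormatError(
                f"matrix has {m.shape[1]} columns, stats expect {len(self.kept)}"
            )
        return (m[:, self.kept] - self.mean[self.kept]) / self.sd[self.kept]


def standardize_columns(
    m: np.ndarray,
    stats_from: np.ndarray | Sequence[int] | None = None,
) -> tuple[np.ndarray, ColumnStats]:
    """Center and scale columns to mean 0 / unit sample SD (ddof=1).

    Statistics come from the ``stats_from`` row subset (default: all rows)
    and are applied to every row, so held-out rows can be transformed with
    the same :class:`ColumnStats` without leakage.  Columns constant on the
    statistics rows are dropped with a warning.
    """
    m = np.asarray(m, dtype=float)
    rows = m if stats_from is None else m[np.asarray(stats_from)]
    if rows.shape[0] < 2:
        raise FormatError("need at least two rows to estimate column SDs")
    mean = rows.mean(axis=0)
    sd = rows.std(axis=0, ddof=1)
    kept = sd > 0
    if not kept.all():
        warnings.warn(
            f"dropping {int((~kept).sum())} zero-variance column(s) before "
            "standardization",
            stacklevel=2,
        )
    sd_safe = np.where(kept, sd, 1.0)
    stats = ColumnStats(mean=mean, sd=sd_safe, kept=kept)
    return stats.transform(m), stats


# ---------------------------------------------------------------------------
# delimited-text readers / writers
# ---------------------------------------------------------------------------


def read_spectra(path) -> SpectraMatrix:
    """CSV with cow ids in the first column and cm^-1 labels as header."""
    df = pd.read_csv(path, index_col=0)
    return SpectraMatrix(
        df.to_numpy(dtype=float),
        np.array([float(c) for c in df.columns]),
        df.index.to_numpy(dtype=object).astype(str),
    )


def write_spectra(s: SpectraMatrix, path) -> None:
    pd.DataFrame(
        s.values, index=pd.Index(s.cow_ids, name="cow_id"),
        columns=[f"{w:g}" for w in s.wavenumbers],
    ).to_csv(path)


def read_genotypes(path, missing_sentinel: float | None = None) -> GenotypeMatrix:
    """CSV of dosages; NA tokens and negative values count as missing."""
    df = pd.read_csv(path, index_col=0, na_values=list(MISSING_TOKENS))
    dosages = df.to_numpy(dtype=float)
    dosages[dosages < 0] = np.nan
    if missing_sentinel is not None:
        dosages[dosages == missing_sentinel] = np.nan
    return GenotypeMatrix(
        dosages,
        df.columns.to_numpy(dtype=object).astype(str),
        df.index.to_numpy(dtype=object).astype(str),
    )


def write_genotypes(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        g.dosages, index=pd.Index(g.cow_ids, name="cow_id"), columns=list(g.snp_ids)
    )
    df.to_csv(path, na_rep="NA")


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] != 3:
        raise FormatError("pedigree file must have exactly three columns")
    return Pedigree(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), df.iloc[:, 2].to_numpy())


def write_pedigree(p: Pedigree, path) -> None:
    pd.DataFrame(
        {"individual": p.individual, "sire": p.sire, "dam": p.dam}
    ).to_csv(path, index=False)


def read_onfarm(path) -> OnFarmTable:
    df = pd.read_csv(path, dtype={0: str})
    return OnFarmTable(
        df.iloc[:, 0].to_numpy(dtype=object),
        df["herd"].astype(str).to_numpy(dtype=object),
        df["dim"].to_numpy(dtype=float),
        df["parity"].to_numpy(dtype=int),
    )


def write_onfarm(f: OnFarmTable, path) -> None:
    pd.DataFrame(
        {"cow_id": f.cow_ids, "herd": f.herd, "dim": f.dim, "parity": f.parity}
    ).to_csv(path, index=False)


def read_traits(path) -> TraitTable:
    df = pd.read_csv(path, index_col=0)
    return TraitTable(
        df.index.to_numpy(dtype=object).astype(str),
        df.to_numpy(dtype=float),
        tuple(df.columns),
    )


def write_traits(t: TraitTable, path) -> None:
    pd.DataFrame(
        t.values, index=pd.Index(t.cow_ids, name="cow_id"), columns=list(t.trait_names)
    ).to_csv(path)
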