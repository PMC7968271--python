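"""Relationship matrices: spectral S, genomic G, pedigree A.

All three matrices play the same role in the mixed models of this package:
they are the covariance structure of a random effect, one entry per pair of
cows.  ``S`` summarises the similarity of milk FTIR profiles (standardized
wavenumber cross-products), ``G`` is VanRaden's first genomic relationship
matrix from centered SNP dosages, and ``A`` is the pedigree-expected
numerator relationship matrix built with the recursive tabular method.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .data_io import GenotypeMatrix, Pedigree, SpectraMatrix, UNKNOWN_PARENT

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-10
PSD_TOL = 1e-8


class KernelError(ValueError):
    """Invalid input for a relationship-matrix construction."""


@dataclass
class RelationshipMatrix:
    """Symmetric n x n similarity matrix with provenance tag."""

    values: np.ndarray
    ids: np.ndarray
    kind: str  # "spectral" | "genomic" | "pedigree"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray(self.ids, dtype=object)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise KernelError("relationship matrix shape does not match ids")
        asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
        if asym > SYMMETRY_TOL * max(1.0, np.max(np.abs(self.values))):
            raise KernelError(f"matrix is not symmetric (max asymmetry {asym:g})")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, rows, cols=None) -> np.ndarray:
        """Index by integer positions; ``cols`` defaults to ``rows``."""
        rows = np.asarray(rows)
        cols = rows if cols is None else np.asarray(cols)
        return self.values[np.ix_(rows, cols)]


def _check_psd(values: np.ndarray, what: str) -> None:
    eigvals = np.linalg.eigvalsh(values)
    floor = -PSD_TOL * max(float(eigvals[-1]), 1.0)
    if eigvals[0] < floor:
        raise KernelError(f"{what} kernel is not positive semidefinite "
                          f"(min eigenvalue {eigvals[0]:g})")


def spectral_kernel(
    w: np.ndarray | SpectraMatrix,
    ids: Sequence | None = None,
) -> RelationshipMatrix:
    """S = W W' / m from a column-standardized wavenumber matrix.

    ``w`` must already be centered and scaled per column (training-row
    statistics in cross-validation); ``m`` is the number of retained
    wavenumber columns.  With centered columns the row sums of S are zero
    and its trace equals ``n - 1`` (unbiased column SDs).
    """
    if isinstance(w, SpectraMatrix):
        ids = w.cow_ids if ids is None else ids
        w = w.values
    w = np.asarray(w, dtype=float)
    n, m = w.shape
    if n < 2:
        raise KernelError("need at least two cows for a spectral kernel")
    if m < 1:
        raise KernelError("no informative wavenumbers: all columns were dropped")
    if ids is None:
        ids = np.arange(n)
    s = (w @ w.T) / m
    return RelationshipMatrix(s, np.asarray(ids, dtype=object), "spectral")


def genomic_kernel(
    g: GenotypeMatrix | np.ndarray,
    ids: Sequence | None = None,
    allele_freq: np.ndarray | None = None,
) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    G = Z Z' / (2 * sum_j p_j (1 - p_j)) with Z the dosages centered by
    twice the reference allele frequency.  ``allele_freq`` overrides the
    frequencies (e.g. to reuse full-data frequencies on a subset); by
    default they come from the construction set itself.  Monomorphic SNPs
    are a hard error — QC should have removed them.
    """
    if isinstance(g, GenotypeMatrix):
        if np.isnan(g.dosages).any():
            raise KernelError("genomic kernel needs imputed (complete) dosages")
        ids = g.cow_ids if ids is None else ids
        dosages = g.dosages
    else:
        dosages = np.asarray(g, dtype=float)
    if ids is None:
        ids = np.arange(dosages.shape[0])
    p = dosages.mean(axis=0) / 2.0 if allele_freq is None else np.asarray(allele_freq, float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise KernelError("monomorphic SNP present (allele frequency 0 or 1); "
                          "run genotype QC first")
    z = dosages - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    gmat = (z @ z.T) / denom
    return RelationshipMatrix(gmat, np.asarray(ids, dtype=object), "genomic")


def pedigree_kernel(p: Pedigree, subset: Sequence) -> RelationshipMatrix:
    """Numerator relationship matrix restricted to ``subset``.

    The full matrix is built over the whole pedigree with the recursive
    tabular method on a topological (founder-first) ordering —
    ``A_ii = 1 + 0.5 * A_{sire,dam}`` and
    ``A_ij = 0.5 * (A_{j,sire(i)} + A_{j,dam(i)})`` for earlier ``j`` —
    and only then restricted to the requested cows, so all ancestral
    relationships are accounted for.
    """
    order = p.topological_order()
    idx = {ind: k for k, ind in enumerate(order)}
    parents = p.parents()
    n = len(order)
    a = np.zeros((n, n))
    for i, ind in enumerate(order):
        s, d = parents[ind]
        si = idx.get(s, -1) if s != UNKNOWN_PARENT else -1
        di = idx.get(d, -1) if d != UNKNOWN_PARENT else -1
        asd = a[si, di] if (si >= 0 and di >= 0) else 0.0
        a[i, i] = 1.0 + 0.5 * asd
        if i:
            rel = np.zeros(i)
            if si >= 0:
                rel += a[:i, si]
            if di >= 0:
                rel += a[:i, di]
            a[:i, i] = a[i, :i] = 0.5 * rel
    subset = np.asarray(subset, dtype=object)
    missing = [str(c) for c in subset if c not in idx]
    if missing:
        raise KernelError(f"subset ids absent from pedigree: {missing[:5]}")
    pos = np.array([idx[c] for c in subset])
    return RelationshipMatrix(a[np.ix_(pos, pos)], subset, "pedigree")


def solve_kernel(k_trn: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve K x = rhs via Cholesky, retrying once with a 1e-8 diagonal jitter.

    Relationship matrices built from centered columns (S, and G on small
    panels) are singular by construction; the jittered retry is logged and a
    second failure is a hard error.
    """
    from scipy.linalg import cho_factor, cho_solve

    try:
        return cho_solve(cho_factor(k_trn, lower=True), rhs)
    except np.linalg.LinAlgError:
        logger.info("kernel solve singular; retrying with 1e-8 diagonal jitter")
        jitter = 1e-8 * max(np.trace(k_trn) / len(k_trn), 1.0)
        jittered = k_trn + jitter * np.eye(len(k_trn))
        try:
            return cho_solve(cho_factor(jittered, lower=True), rhs)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise KernelError("training kernel block is singular even after "
                              "diagonal jitter") from exc


def write_kernel(k: RelationshipMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(k.values, index=pd.Index(k.ids, name=k.kind), columns=list(k.ids)).to_csv(path)


def read_kernel(path, kind: str) -> RelationshipMatrix:
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    return RelationshipMatrix(
        df.to_numpy(dtype=float), df.index.to_numpy(dtype=object).astype(str), kind
    )
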