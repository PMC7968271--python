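"""Partial least squares baseline.

PLS regresses the phenotype on latent variables that maximise the
covariance between predictors and response — the standard chemometric
baseline for FTIR calibration.  Genomic and pedigree information enters as
principal-component features of the corresponding relationship matrix
(eigenvectors scaled by the square-root eigenvalues, keeping the smallest
count that explains more than 80% of the variation).  The number of latent
variables is chosen by inner cross-validated RMSE with a hard cap of 50,
and test-set prediction applies the training-selected projection:
``y_hat_tst = Q_tst q_hat_trn``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .data_io import ColumnStats, standardize_columns
from .kernels import RelationshipMatrix

MAX_COMPONENTS = 50


def pc_features(
    k: RelationshipMatrix | np.ndarray,
    variance_target: float = 0.80,
) -> tuple[np.ndarray, int]:
    """Principal-component scores of a PSD kernel.

    Returns eigenvectors scaled by the square-root eigenvalues, keeping the
    smallest count whose cumulative eigenvalue share strictly exceeds
    ``variance_target``.
    """
    if not 0.0 < variance_target < 1.0:
        raise ValueError("variance_target must be in (0, 1)")
    kv = k.values if isinstance(k, RelationshipMatrix) else np.asarray(k, float)
    vals, vecs = np.linalg.eigh(kv)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    top = max(float(vals[0]), 1.0)
    if vals[-1] < -1e-8 * top:
        raise ValueError("kernel is not positive semidefinite")
    vals = np.clip(vals, 0.0, None)
    total = vals.sum()
    if total <= 0:
        raise ValueError("kernel has no variance")
    share = np.cumsum(vals) / total
    count = int(np.searchsorted(share, variance_target, side="right")) + 1
    count = min(count, int(np.sum(vals > 0)))
    scores = vecs[:, :count] * np.sqrt(vals[:count])
    return scores, count


@dataclass
class PLSFit:
    """Trained PLS pipeline: column stats, chosen rank, and the projection."""

    model: PLSRegression
    n_components: int
    stats: ColumnStats
    y_mean: float
    inner_rmse: np.ndarray  # RMSE per candidate component count (1-based)

    @property
    def x_scores(self) -> np.ndarray:
        return self.model.x_scores_

    @property
    def x_weights(self) -> np.ndarray:
        return self.model.x_weights_


def fit_pls(
    y: np.ndarray,
    blocks: list[np.ndarray],
    max_components: int = MAX_COMPONENTS,
    inner_folds: int = 10,
    seed: int = 0,
) -> PLSFit:
    """Fit PLS on column-concatenated, standardized predictor blocks.

    The component count minimising inner-CV root mean squared error over
    ``1..min(max_components, rank)`` is selected, then the final model is
    refit on all training rows at that count.
    """
    if inner_folds < 2:
        raise ValueError("need at least 2 inner folds for component selection")
    y = np.asarray(y, dtype=float)
    xraw = np.hstack([np.asarray(b, dtype=float) for b in blocks])
    if xraw.shape[0] != y.size:
        raise ValueError("predictor blocks and y disagree on rows")
    x, stats = standardize_columns(xraw)
    y_mean = float(y.mean())
    yc = y - y_mean

    n, p = x.shape
    inner_folds = min(inner_folds, n)
    min_fold_train = n - (n // inner_folds + 1)
    kmax = max(1, min(max_components, n - 1, p, min_fold_train - 1))

    kf = KFold(n_splits=inner_folds, shuffle=True, random_state=int(seed) % (2**31))
    splits = list(kf.split(x))
    sse = np.zeros(kmax)
    count = np.zeros(kmax)
    for trn, val in splits:
        k_fit = min(kmax, len(trn) - 1, p)
        pls = PLSRegression(n_components=k_fit, scale=False)
        pls.fit(x[trn], yc[trn])
        # predictions for every truncation rank from one decomposition
        rot = pls.x_rotations_  # p x k_fit
        coef_q = pls.y_loadings_.ravel()  # k_fit
        t_val = (x[val] - x[trn].mean(axis=0)) @ rot
        cum = np.cumsum(t_val * coef_q, axis=1) + yc[trn].mean()
        for k in range(k_fit):
            err = yc[val] - cum[:, k]
            sse[k] += float(err @ err)
            count[k] += len(val)
    with np.errstate(invalid="ignore", divide="ignore"):
        rmse = np.sqrt(sse / count)
    best = int(np.nanargmin(rmse)) + 1

    model = PLSRegression(n_components=best, scale=False)
    model.fit(x, yc)
    return PLSFit(model=model, n_components=best, stats=stats, y_mean=y_mean, inner_rmse=rmse)


def predict_pls(fit: PLSFit, blocks: list[np.ndarray]) -> np.ndarray:
    """Project test rows with the training stats and trained components."""
    xraw = np.hstack([np.asarray(b, dtype=float) for b in blocks])
    x = fit.stats.transform(xraw)
    return fit.model.predict(x).ravel() + fit.y_mean
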