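"""Nucleus QC, median-ratio log normalization and HVG selection.

Quality filters follow the usual snRNA-seq conventions: nuclei are kept when
their detected-feature count lies strictly between a lower and upper bound
and when the fraction of reads mapping to mitochondrial genes stays below a
cap (low-complexity debris and dying nuclei are removed on those grounds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess


@dataclass(frozen=True)
class QCThresholds:
    """Nucleus-level quality-control cutoffs.

    ``min_features``/``max_features`` are exclusive bounds on the number of
    detected genes; ``max_mito_fraction`` is an exclusive upper bound on the
    fraction of counts assigned to mitochondrial genes.
    """

    min_features: int = 200
    max_features: int = 10_000
    max_mito_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.min_features >= self.max_features:
            raise ValueError("min_features must be < max_features")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")


@dataclass
class NormalizedMatrix:
    """Log-normalized expression with the size factors that produced it.

    ``matrix`` is cell x gene; ``size_factors`` holds the per-cell library
    sizes ``s_c``; values are ``ln(1 + counts * median(s)/s_c)``.
    """

    matrix: np.ndarray
    size_factors: np.ndarray
    gene_names: list[str]
    cell_names: list[str]
    scheme: str = "median-ratio-log1p"


def _as_dense(counts) -> np.ndarray:
    if sparse.issparse(counts):
        return np.asarray(counts.todense())
    return np.asarray(counts)


def qc_filter(
    counts,
    gene_names,
    mito_gene_ids,
    thresholds: QCThresholds | None = None,
) -> np.ndarray:
    """Boolean keep-mask over cells from feature-count and mito-fraction rules.

    A cell is kept iff ``min_features < detected genes < max_features`` and
    mito fraction ``< max_mito_fraction`` (all strict).

    Parameters
    ----------
    counts
        cell x gene count matrix (dense or sparse).
    gene_names
        Column labels of ``counts``.
    mito_gene_ids
        Subset of ``gene_names`` flagged as mitochondrial.
    thresholds
        Cutoffs; defaults to ``QCThresholds()``.
    """
    thresholds = thresholds or QCThresholds()
    gene_names = list(gene_names)
    mito_set = set(mito_gene_ids)
    unknown = mito_set - set(gene_names)
    if unknown:
        raise ValueError(f"mito genes absent from feature space: {sorted(unknown)[:5]}")

    X = counts.tocsr() if sparse.issparse(counts) else np.asarray(counts)
    if sparse.issparse(X):
        n_features = np.asarray((X > 0).sum(axis=1)).ravel()
        totals = np.asarray(X.sum(axis=1)).ravel()
        mito_cols = [i for i, g in enumerate(gene_names) if g in mito_set]
        mito_counts = (
            np.asarray(X[:, mito_cols].sum(axis=1)).ravel() if mito_cols else 0.0
        )
    else:
        n_features = (X > 0).sum(axis=1)
        totals = X.sum(axis=1)
        mito_mask = np.array([g in mito_set for g in gene_names])
        mito_counts = X[:, mito_mask].sum(axis=1) if mito_mask.any() else 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    keep = (
        (n_features > thresholds.min_features)
        & (n_features < thresholds.max_features)
        & (mito_frac < thresholds.max_mito_fraction)
    )
    if not keep.any():
        warnings.warn("qc_filter removed every cell", stacklevel=2)
    return keep


def normalize_log(counts, gene_names=None, cell_names=None) -> NormalizedMatrix:
    """Median-ratio log normalization: ``x = ln(1 + c * median(s)/s_c)``.

    ``s_c`` is the total count of cell ``c``.  Cells with zero total counts
    are excluded (with a warning) since they admit no size factor.
    """
    X = _as_dense(counts).astype(float)
    if (X < 0).any():
        raise ValueError("counts must be nonnegative")
    n_cells, n_genes = X.shape
    gene_names = list(gene_names) if gene_names is not None else [f"g{i}" for i in range(n_genes)]
    cell_names = list(cell_names) if cell_names is not None else [f"c{i}" for i in range(n_cells)]

    s = X.sum(axis=1)
    nonzero = s > 0
    if not nonzero.all():
        warnings.warn(
            f"excluding {int((~nonzero).sum())} zero-total cells from normalization",
            stacklevel=2,
        )
        X = X[nonzero]
        s = s[nonzero]
        cell_names = [c for c, keep in zip(cell_names, nonzero) if keep]

    s_bar = float(np.median(s))
    scaled = X * (s_bar / s)[:, None]
    return NormalizedMatrix(
        matrix=np.log1p(scaled),
        size_factors=s,
        gene_names=gene_names,
        cell_names=cell_names,
    )


def _variance_trend(log_mean: np.ndarray, log_var: np.ndarray) -> np.ndarray:
    """Local-regression mean-variance trend, robust to hypervariable genes.

    Genes far above a robust linear baseline would otherwise pull the local
    fit through their own point (self-influence is total at leverage-one
    positions), so they are excluded from trend fitting and receive an
    interpolated trend value instead.
    """
    # Theil-Sen baseline: immune to the leverage of hypervariable genes
    if len(log_mean) > 2000:
        sub = np.linspace(0, len(log_mean) - 1, 2000).astype(int)
        idx = np.argsort(log_mean, kind="stable")[sub]
        slope, intercept, *_ = stats.theilslopes(log_var[idx], log_mean[idx])
    else:
        slope, intercept, *_ = stats.theilslopes(log_var, log_mean)
    resid = log_var - (slope * log_mean + intercept)
    mad = np.median(np.abs(resid - np.median(resid))) * 1.4826
    inlier = np.abs(resid - np.median(resid)) <= max(3 * mad, 1e-6)
    if inlier.sum() < 3:
        inlier = np.ones_like(inlier, dtype=bool)
    order = np.argsort(log_mean[inlier], kind="stable")
    x_in = log_mean[inlier][order]
    y_fit = lowess(
        log_var[inlier][order], x_in, frac=0.3, return_sorted=False, it=2
    )
    return np.interp(log_mean, x_in, y_fit)


def select_hvg(counts, gene_names, n_top: int) -> list[str]:
    """Rank genes by standardized variance and return the top ``n_top``.

    The ranking follows the vst convention: fit a mean-variance trend (local
    regression of log10 variance on log10 mean), z-score each gene's counts
    with the trend-predicted standard deviation, clip at ``sqrt(N)``, and
    rank by the variance of the clipped z-scores.  Ties break
    lexicographically by gene id so the ordering is deterministic.
    """
    X = _as_dense(counts).astype(float)
    gene_names = list(gene_names)
    n_cells, n_genes = X.shape
    if n_top > n_genes:
        raise ValueError("n_top exceeds the number of genes")

    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if n_cells > 1 else np.zeros(n_genes)

    std_var = np.zeros(n_genes)
    positive = (mean > 0) & (var > 0)
    if positive.sum() >= 3:
        log_mean = np.log10(mean[positive])
        log_var = np.log10(var[positive])
        fitted = _variance_trend(log_mean, log_var)
        expected_sd = np.sqrt(10.0**fitted)
        clip = np.sqrt(n_cells)
        sub = X[:, positive]
        z = (sub - mean[positive]) / expected_sd
        np.clip(z, -clip, clip, out=z)
        # variance of clipped z-scores around the clipped mean
        std_var[positive] = ((z - z.mean(axis=0)) ** 2).sum(axis=0) / max(n_cells - 1, 1)

    order = sorted(range(n_genes), key=lambda i: (-std_var[i], gene_names[i]))
    return [gene_names[i] for i in order[:n_top]]


def qc_report(counts, gene_names, mito_gene_ids, thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Per-cell QC metrics plus the keep decision (for CSV export)."""
    X = _as_dense(counts)
    gene_names = list(gene_names)
    mito_mask = np.array([g in set(mito_gene_ids) for g in gene_names])
    totals = X.sum(axis=1)
    report = pd.DataFrame(
        {
            "n_features": (X > 0).sum(axis=1),
            "total_counts": totals,
            "mito_fraction": np.where(
                totals > 0, X[:, mito_mask].sum(axis=1) / np.maximum(totals, 1), 0.0
            )
            if mito_mask.any()
            else 0.0,
        }
    )
    report["keep"] = qc_filter(X, gene_names, mito_gene_ids, thresholds)
    return report
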