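"""Cell-type-adjusted quasi-Poisson differential expression.

Each tumor type is contrasted against the non-tumor referent with a
log-link count GLM per gene:

    log E[y_c] = offset_c + b0 + b1 * tumor_c (+ cell-type factor)

where ``offset_c`` is the log size factor.  Inference is quasi-Poisson: the
variance is a free multiple ``phi`` of the mean, estimated as Pearson
chi-square over residual degrees of freedom, and the Wald test on the group
coefficient scales the SE by ``sqrt(phi)`` with a t reference distribution
on the residual df.  The "adjusted" model adds the major cell type as a
covariate, which removes the spurious marginal differences created when
tumor and non-tumor tissue differ in cell-type composition; the
"unadjusted" model omits it and therefore mixes composition with biology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from pedcns.pathway_enrichment import bh_adjust

MAX_ITER = 50


@dataclass
class DEDesign:
    """Design for one gene-level GLM fit."""

    group: np.ndarray  # boolean: True = tumor, False = referent
    offset: np.ndarray  # log size factors
    celltype: np.ndarray | None = None  # optional major-cell-type labels


@dataclass
class ModelComparison:
    """Set algebra between adjusted and unadjusted significant genes."""

    per_type: pd.DataFrame
    gene_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def _design_matrix(design: DEDesign) -> np.ndarray:
    cols = [np.ones(len(design.group)), design.group.astype(float)]
    if design.celltype is not None:
        levels = pd.unique(design.celltype)
        for lev in levels[1:]:  # first level is the reference
            cols.append((design.celltype == lev).astype(float))
    return np.column_stack(cols)


def fit_gene_glm(counts_g: np.ndarray, design: DEDesign) -> tuple[float, float, float, bool]:
    """Quasi-Poisson Wald test on the tumor-vs-referent coefficient.

    Returns ``(estimate, se, p, converged)``; a non-converged or separated
    fit is flagged and reported with ``p = 1``.
    """
    y = np.asarray(counts_g, dtype=float)
    for value in (True, False):
        if (design.group == value).sum() < 2:
            raise ValueError("need >= 2 cells per group level")
    X = _design_matrix(design)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X, family=sm.families.Poisson(), offset=design.offset)
            res = model.fit(maxiter=MAX_ITER, scale="X2")
        if not res.converged or not np.all(np.isfinite(res.bse)):
            return float(res.params[1]), float("nan"), 1.0, False
        estimate = float(res.params[1])
        se = float(res.bse[1])  # already scaled by sqrt(phi) via scale="X2"
        df = res.df_resid
        if se == 0 or df <= 0:
            return estimate, se, 1.0, False
        t = estimate / se
        p = float(2.0 * stats.t.sf(abs(t), df))
        return estimate, se, p, True
    except (np.linalg.LinAlgError, ValueError):
        return 0.0, float("nan"), 1.0, False


def run_de(
    counts,
    gene_names: list[str],
    cells: pd.DataFrame,
    size_factors: np.ndarray,
    hvg: list[str] | None = None,
    adjust: bool = True,
    referent: str = "non_tumor",
    fdr: float = 0.05,
    min_cells: int = 50,
) -> pd.DataFrame:
    """Per-gene quasi-Poisson DE of every tumor type vs the referent.

    Parameters
    ----------
    counts
        cell x gene raw counts (dense or sparse), aligned with ``cells``.
    cells
        Per-cell table with columns ``group`` (tumor type or referent) and,
        when ``adjust``, ``cell_type``.
    size_factors
        Per-cell library sizes; their log enters as the GLM offset.
    hvg
        Gene subset to test (typically the top 4000 most variable);
        defaults to all genes.
    adjust
        Include the major cell type factor.
    referent
        Group treated as baseline (non-tumor tissue).

    Returns
    -------
    pandas.DataFrame
        One row per (gene, tumor type) with estimate (natural-log fold
        change), SE, p, BH-adjusted p (within each tumor type), direction
        and significance at ``fdr``.
    """
    from scipy import sparse

    X = counts.toarray() if sparse.issparse(counts) else np.asarray(counts)
    if referent not in set(cells["group"]):
        raise ValueError(f"referent group {referent!r} absent")
    gene_pos = {g: i for i, g in enumerate(gene_names)}
    test_genes = list(hvg) if hvg is not None else list(gene_names)
    missing = [g for g in test_genes if g not in gene_pos]
    if missing:
        raise ValueError(f"unknown genes in hvg list, e.g. {missing[:5]}")

    log_sf = np.log(np.asarray(size_factors, dtype=float))
    tumor_types = sorted(set(cells["group"]) - {referent})
    model_name = "adjusted" if adjust else "unadjusted"

    frames = []
    for ttype in tumor_types:
        in_contrast = cells["group"].isin([ttype, referent]).to_numpy()
        if (cells["group"] == ttype).sum() < min_cells:
            warnings.warn(f"tumor type {ttype} has < {min_cells} cells", stacklevel=2)
        sub = X[in_contrast]
        design = DEDesign(
            group=(cells.loc[in_contrast, "group"] == ttype).to_numpy(),
            offset=log_sf[in_contrast],
            celltype=cells.loc[in_contrast, "cell_type"].to_numpy() if adjust else None,
        )
        rows = []
        for g in test_genes:
            est, se, p, ok = fit_gene_glm(sub[:, gene_pos[g]], design)
            rows.append((g, est, se, p, ok))
        table = pd.DataFrame(rows, columns=["gene", "estimate", "se", "p", "converged"])
        table["tumor_type"] = ttype
        table["model"] = model_name
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
        table["direction"] = np.where(table["estimate"] >= 0, "up", "down")
        table["significant"] = table["p_adj"] < fdr
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def compare_models(adjusted: pd.DataFrame, unadjusted: pd.DataFrame) -> ModelComparison:
    """Adjusted-vs-unadjusted significant-gene set algebra per tumor type.

    ``sign_discordant`` genes are significant in both models with opposite
    estimate signs; ``estimate_ratio`` is unadjusted/adjusted (per gene).
    """
    merged = adjusted.merge(
        unadjusted,
        on=["gene", "tumor_type"],
        suffixes=("_adj", "_unadj"),
        validate="one_to_one",
    )
    if len(merged) != len(adjusted):
        raise ValueError("models must cover the same (gene, tumor type) universe")

    with np.errstate(divide="ignore", invalid="ignore"):
        merged["estimate_ratio"] = merged["estimate_unadj"] / merged["estimate_adj"]
    both = merged["significant_adj"] & merged["significant_unadj"]
    merged["class"] = np.select(
        [
            both,
            merged["significant_adj"] & ~merged["significant_unadj"],
            ~merged["significant_adj"] & merged["significant_unadj"],
        ],
        ["both", "adjusted_only", "unadjusted_only"],
        default="neither",
    )
    merged["sign_discordant"] = both & (
        np.sign(merged["estimate_adj"]) != np.sign(merged["estimate_unadj"])
    )

    per_type = (
        merged.groupby("tumor_type")
        .agg(
            n_both=("class", lambda s: int((s == "both").sum())),
            n_adjusted_only=("class", lambda s: int((s == "adjusted_only").sum())),
            n_unadjusted_only=("class", lambda s: int((s == "unadjusted_only").sum())),
            n_sign_discordant=("sign_discordant", "sum"),
        )
        .reset_index()
    )
    return ModelComparison(per_type=per_type, gene_table=merged)
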