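"""Clustering, marker-based cell typing, and module (stemness) scores.

Clusters come from the standard single-cell recipe — PCA on the scaled
matrix, a shared-nearest-neighbor graph, modularity-based community
detection (Leiden) at a configurable resolution.  Clusters are then assigned
a major brain cell type by classical markers (astrocytes by GFAP/AQP4,
oligodendrocytes by MOG/PLP1, and so on); marker-negative populations can be
overridden downstream by single-cell gene-set enrichment, which is how
populations such as neural stem-like cells that lack their classical
markers get resolved.
"""

from __future__ import annotations

import warnings
from importlib import resources

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc

from pedcns.preprocess import NormalizedMatrix

UNRESOLVED = "UNRESOLVED"

#: Classical marker genes for major brain cell types.
CLASSICAL_MARKERS: dict[str, list[str]] = {
    "AST": ["GFAP", "AQP4"],
    "EN": ["FN1", "COL4A1"],
    "MAC/MG": ["CSF1R", "PTPRC"],
    "NEU/UBC": ["RBFOX3", "RELN"],
    "NEU_INH/INT": ["GAD2"],
    "NSC": ["SOX2", "CD44"],
    "OLIG": ["MOG", "PLP1"],
    "OPC": ["PDGFRA"],
    "RGC": ["VIM", "NES", "PAX6"],
    "ST": ["FAP"],
    "TC": ["CD3E"],
}

#: Classical cancer stem cell markers used for stemness module scoring.
STEMNESS_MARKERS: list[str] = [
    "ITGA6", "CD44", "PROM1", "NES", "MSI1", "MYC", "NANOG", "SOX1",
    "SOX2", "POU5F1", "VIM", "SDC1", "SDC2", "GPC1", "GPC2",
]


def load_packaged_markers() -> dict[str, list[str]]:
    """Marker table shipped with the package (CSV: cell_type, gene)."""
    with resources.files("pedcns.data").joinpath("classical_markers.csv").open() as fh:
        table = pd.read_csv(fh)
    return {t: list(g["gene"]) for t, g in table.groupby("cell_type", sort=False)}


def cluster_cells(
    normalized: NormalizedMatrix,
    n_pcs: int = 50,
    n_neighbors: int = 30,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community labels on an SNN graph of the PCA embedding.

    Returns integer labels, contiguous from 0, deterministic given
    ``seed``.  ``n_pcs`` is reduced with a warning when the matrix is
    smaller than requested.
    """
    X = np.asarray(normalized.matrix, dtype=np.float64)
    n_cells, n_genes = X.shape
    if n_cells < n_neighbors + 1:
        raise ValueError("need at least n_neighbors + 1 cells")
    max_pcs = min(n_cells - 1, n_genes - 1)
    if n_pcs > max_pcs:
        warnings.warn(f"reducing n_pcs from {n_pcs} to {max_pcs}", stacklevel=2)
        n_pcs = max_pcs

    adata = ad.AnnData(X=X.copy())
    sc.pp.scale(adata, max_value=10)
    sc.tl.pca(adata, n_comps=n_pcs, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=n_neighbors, random_state=seed)
    sc.tl.leiden(
        adata,
        resolution=resolution,
        random_state=seed,
        key_added="cluster",
        flavor="igraph",
        n_iterations=2,
        directed=False,
    )
    labels = adata.obs["cluster"].astype(int).to_numpy()
    # relabel to contiguous ids ordered by first appearance
    _, contiguous = np.unique(labels, return_inverse=True)
    return contiguous


def score_markers(
    normalized: NormalizedMatrix,
    clusters: np.ndarray,
    markers: dict[str, list[str]] | None = None,
) -> dict[int, str]:
    """Assign each cluster the cell type with the highest marker score.

    The score of type ``T`` in cluster ``k`` is the mean over T's markers of
    (cluster-mean expression - global-mean expression).  Exact ties yield
    ``UNRESOLVED``; types with no marker present in the feature space are
    skipped.
    """
    markers = markers if markers is not None else CLASSICAL_MARKERS
    X = np.asarray(normalized.matrix)
    gene_index = {g: i for i, g in enumerate(normalized.gene_names)}
    global_mean = X.mean(axis=0)

    usable = {}
    for ctype, genes in markers.items():
        present = [gene_index[g] for g in genes if g in gene_index]
        if not present:
            warnings.warn(f"no markers of {ctype} in feature space", stacklevel=2)
            continue
        usable[ctype] = present

    assignment: dict[int, str] = {}
    for k in np.unique(clusters):
        in_k = clusters == k
        cluster_mean = X[in_k].mean(axis=0)
        scores = {
            ctype: float(np.mean(cluster_mean[idx] - global_mean[idx]))
            for ctype, idx in usable.items()
        }
        if not scores:
            assignment[int(k)] = UNRESOLVED
            continue
        best = max(scores.values())
        winners = sorted(t for t, s in scores.items() if s == best)
        assignment[int(k)] = winners[0] if len(winners) == 1 else UNRESOLVED
    return assignment


def module_score(
    normalized: NormalizedMatrix,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Expression-bin-matched module score per cell.

    All genes are binned into ``n_bins`` by average expression; for each set
    gene, ``n_ctrl`` control genes are drawn (with replacement, seeded) from
    the non-set genes of its bin.  The score is the mean expression of the
    set genes minus the mean expression over all control draws — so a set
    whose genes merely sit in highly expressed bins scores ~0, while a
    genuine program shift scores positive.
    """
    X = np.asarray(normalized.matrix)
    gene_index = {g: i for i, g in enumerate(normalized.gene_names)}
    set_idx = [gene_index[g] for g in gene_set if g in gene_index]
    if not set_idx:
        raise ValueError("gene_set has no overlap with the feature space")

    rng = np.random.default_rng(seed)
    avg = X.mean(axis=0)
    n_bins = min(n_bins, len(avg))
    # quantile bins on average expression; rank-based to tolerate ties
    order = np.argsort(avg, kind="stable")
    bins = np.empty(len(avg), dtype=int)
    bins[order] = np.minimum((np.arange(len(avg)) * n_bins) // len(avg), n_bins - 1)

    in_set = np.zeros(len(avg), dtype=bool)
    in_set[set_idx] = True
    ctrl_idx: list[int] = []
    for g in set_idx:
        pool = np.flatnonzero((bins == bins[g]) & ~in_set)
        if pool.size == 0:  # bin holds only set genes; self-control
            pool = np.flatnonzero(bins == bins[g])
        ctrl_idx.extend(rng.choice(pool, size=n_ctrl, replace=True))
    return X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)


def stemness_score(
    normalized: NormalizedMatrix,
    gene_set: list[str] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Module score over a stem-cell-associated gene list (default packaged)."""
    return module_score(normalized, gene_set or STEMNESS_MARKERS, seed=seed)


def annotate(
    normalized: NormalizedMatrix,
    markers: dict[str, list[str]] | None = None,
    groups: pd.Series | None = None,
    n_pcs: int = 50,
    n_neighbors: int = 30,
    resolution: float = 1.0,
    stemness_genes: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster, type and stemness-score every cell in one pass."""
    clusters = cluster_cells(
        normalized, n_pcs=n_pcs, n_neighbors=n_neighbors, resolution=resolution, seed=seed
    )
    type_of = score_markers(normalized, clusters, markers)
    try:
        stem = stemness_score(normalized, stemness_genes, seed=seed)
    except ValueError:
        stem = np.full(len(clusters), np.nan)
    out = pd.DataFrame(
        {
            "cluster": clusters,
            "cell_type": [type_of[int(k)] for k in clusters],
            "stemness": stem,
        },
        index=pd.Index(normalized.cell_names, name="cell"),
    )
    if groups is not None:
        out["group"] = groups.reindex(out.index)
    return out
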