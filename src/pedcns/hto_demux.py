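"""Hashtag-oligo (cell hashing) demultiplexing.

Each pooled sample is stained with a distinct lipid-tagged oligonucleotide
before pooling; a nucleus is assigned to the sample whose tag it is positive
for.  A tag is "positive" in a nucleus when its raw count exceeds a high
quantile of a negative-binomial background distribution, which is fitted on
the cells least stained for that tag (identified by clustering the CLR-
normalized tag profile).  Exactly one positive tag yields a singlet call,
two or more a doublet, none a negative — the classifier therefore degrades
to a high NEGATIVE rate when staining efficiency is poor, which is exactly
the failure mode genotype-based rescue is designed to absorb.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

DOUBLET = "DOUBLET"
NEGATIVE = "NEGATIVE"


def clr_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Centered log transform of tag counts, per tag across cells.

    ``clr_ct = ln(x_ct + 1) - mean_c ln(x_ct + 1)``.  Centering is per tag
    (column) across cells, the modern default margin for hashing data.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two tags")
    log1p = np.log1p(counts.astype(float))
    if counts.shape[0] < 2:
        warnings.warn("single-cell pool: CLR is degenerate, returning zeros", stacklevel=2)
        return log1p * 0.0
    return log1p - log1p.mean(axis=0)


def _nb_background_threshold(background: np.ndarray, q: float) -> float:
    """Quantile-``q`` cutoff of a method-of-moments NB fit to background counts.

    Falls back to a Poisson quantile when the sample is underdispersed.
    """
    m = background.mean()
    v = background.var(ddof=1) if background.size > 1 else 0.0
    if m <= 0:
        return 0.0
    if v <= m:  # underdispersed: NB has no valid size parameter
        return float(stats.poisson.ppf(q, m))
    size = m * m / (v - m)
    p = size / (size + m)
    return float(stats.nbinom.ppf(q, size, p))


def classify_hto(
    counts: pd.DataFrame,
    tag_to_sample: dict[str, str] | None = None,
    positive_quantile: float = 0.99,
    seed: int = 0,
) -> pd.DataFrame:
    """Classify each nucleus as a sample singlet, DOUBLET, or NEGATIVE.

    Parameters
    ----------
    counts
        cell x tag raw counts (index = cell barcodes).
    tag_to_sample
        Optional map from tag name to sample name; identity when omitted.
    positive_quantile
        Background NB quantile above which a raw count calls the tag
        positive; must lie in (0.5, 1).
    seed
        Seed for the background-identification clustering.

    Returns
    -------
    pandas.DataFrame
        Indexed by cell with columns ``label`` (sample, DOUBLET or
        NEGATIVE), ``margin`` (top CLR minus second CLR) and one boolean
        ``positive_<tag>`` column per tag.

    Notes
    -----
    Background cells for each tag are found by partitioning the CLR profiles
    into ``n_tags + 1`` clusters and taking, per tag, the cluster with the
    lowest mean CLR for that tag (ties break by cluster index).
    """
    if not 0.5 < positive_quantile < 1:
        raise ValueError("positive_quantile must lie in (0.5, 1)")
    tags = list(counts.columns)
    tag_to_sample = tag_to_sample or {t: t for t in tags}
    if set(tags) - set(tag_to_sample):
        raise ValueError("every tag must map to a sample")

    raw = counts.to_numpy(dtype=float)
    clr = clr_normalize(counts).to_numpy()
    n_cells, n_tags = raw.shape

    k = min(n_tags + 1, n_cells)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    clusters = km.fit_predict(clr)

    positives = np.zeros((n_cells, n_tags), dtype=bool)
    for j, tag in enumerate(tags):
        if raw[:, j].sum() == 0:
            warnings.warn(f"tag {tag} has all-zero counts; never positive", stacklevel=2)
            continue
        cluster_means = np.array(
            [clr[clusters == c, j].mean() if (clusters == c).any() else np.inf for c in range(k)]
        )
        background_cluster = int(np.argmin(cluster_means))  # ties -> lowest index
        background = raw[clusters == background_cluster, j]
        cutoff = _nb_background_threshold(background, positive_quantile)
        positives[:, j] = raw[:, j] > cutoff

    n_pos = positives.sum(axis=1)
    sorted_clr = np.sort(clr, axis=1)
    margin = sorted_clr[:, -1] - sorted_clr[:, -2]

    labels = np.empty(n_cells, dtype=object)
    labels[n_pos == 0] = NEGATIVE
    labels[n_pos >= 2] = DOUBLET
    singlet = n_pos == 1
    top_tag = positives.argmax(axis=1)
    for i in np.flatnonzero(singlet):
        labels[i] = tag_to_sample[tags[top_tag[i]]]

    out = pd.DataFrame({"label": labels, "margin": margin}, index=counts.index)
    for j, tag in enumerate(tags):
        out[f"positive_{tag}"] = positives[:, j]
    return out
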