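"""Genotype-based donor deconvolution with binomial doublet modelling.

Bulk RNA-seq of each pooled sample provides a donor genotype (alternate
allele dosage in {0, 0.5, 1}) at a panel of SNPs; each nucleus is genotyped
sparsely at those sites.  Given a per-base error rate ``eps``, the alternate
read count at a covered SNP is Binomial with success probability

    mu = eps + (1 - 2 eps) * dosage,

so each singlet hypothesis (one donor) and each doublet hypothesis (the
average dosage of an unordered donor pair, a 50:50 mixture) has a closed-form
log-likelihood.  Posterior assignment uses a doublet prior ``delta`` spread
over pairs, and a confidence threshold ``tau`` below which the nucleus is
left UNASSIGNED.  This is the known-genotype regime: donor genotypes come
from bulk data, nothing is estimated variationally.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

DOUBLET = "DOUBLET"
UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class VariantRecord:
    """A bulk-called variant with its read support."""

    snp_id: str
    depth: int
    alt_depth: int

    @property
    def allele_frequency(self) -> float:
        return self.alt_depth / self.depth if self.depth else 0.0


def filter_variants(
    records,
    min_depth: int = 10,
    min_af: float = 0.05,
    min_alt: int = 5,
):
    """Keep variants with depth >= 10, allele frequency >= 5% and alt depth >= 5.

    All three rules are inclusive ("at least") boundaries.  Accepts a list of
    :class:`VariantRecord` or a DataFrame with columns ``depth`` and
    ``alt_depth``; returns the same container type filtered.
    """
    if isinstance(records, pd.DataFrame):
        af = records["alt_depth"] / records["depth"].where(records["depth"] > 0, 1)
        keep = (
            (records["depth"] >= min_depth)
            & (af >= min_af)
            & (records["alt_depth"] >= min_alt)
        )
        return records.loc[keep]
    return [
        r
        for r in records
        if r.depth >= min_depth
        and r.allele_frequency >= min_af
        and r.alt_depth >= min_alt
    ]


def _binom_logpmf_terms(alt: np.ndarray, depth: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Elementwise log Binomial(alt; depth, mu), coefficient included."""
    coef = gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = coef + alt * np.log(mu) + (depth - alt) * np.log1p(-mu)
    # 0 * log(0) situations only arise when mu in {0,1}; handle exactly
    term = np.where((alt == 0) & (mu == 0), coef, term)
    term = np.where((alt == depth) & (mu == 1), coef, term)
    return term


def singlet_loglik(
    alt: np.ndarray,
    depth: np.ndarray,
    dosages: np.ndarray,
    eps: float = 0.01,
) -> float:
    """Log-likelihood that one cell's allele counts come from one donor.

    Parameters
    ----------
    alt, depth
        Per-SNP alternate and total read counts of the cell (aligned to
        ``dosages``).
    dosages
        Donor dosages in {0, 0.5, 1}; NaN entries (missing genotype) and
        zero-depth SNPs are skipped.
    eps
        Sequencing/allelic error rate, in (0, 0.5).
    """
    if not 0 < eps < 0.5:
        raise ValueError("eps must lie in (0, 0.5)")
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    dosages = np.asarray(dosages, dtype=float)
    covered = (depth > 0) & ~np.isnan(dosages)
    if not covered.any():
        return 0.0
    mu = eps + (1.0 - 2.0 * eps) * dosages[covered]
    return float(_binom_logpmf_terms(alt[covered], depth[covered], mu).sum())


def doublet_loglik(
    alt: np.ndarray,
    depth: np.ndarray,
    dosages_i: np.ndarray,
    dosages_j: np.ndarray,
    eps: float = 0.01,
) -> float:
    """Log-likelihood under a 50:50 doublet of two donors (mean dosage)."""
    mixed = (np.asarray(dosages_i, dtype=float) + np.asarray(dosages_j, dtype=float)) / 2.0
    return singlet_loglik(alt, depth, mixed, eps)


def enumerate_hypotheses(donors: list[str], delta: float):
    """(label, prior) pairs: K singlets and C(K,2) unordered doublets."""
    k = len(donors)
    hypotheses = [(d, (1.0 - delta) / k) for d in donors]
    pairs = list(itertools.combinations(donors, 2))
    if pairs:
        hypotheses += [(f"{DOUBLET}({a},{b})", delta / len(pairs)) for a, b in pairs]
    return hypotheses


def assign_genotype(
    allele_counts: pd.DataFrame,
    genotypes: pd.DataFrame,
    eps: float = 0.01,
    delta: float = 0.05,
    tau: float = 0.9,
) -> pd.DataFrame:
    """Posterior donor assignment of every cell, with doublet hypotheses.

    Parameters
    ----------
    allele_counts
        Long-format table with columns ``cell``, ``snp``, ``ref_count``,
        ``alt_count``.
    genotypes
        donor x SNP dosage matrix ({0, 0.5, 1}, NaN = missing).
    eps
        Allele error rate (fixed, not estimated).
    delta
        Prior doublet probability, split evenly across unordered pairs.
    tau
        Assignment threshold: max posterior < tau leaves the cell
        UNASSIGNED.

    Returns
    -------
    pandas.DataFrame
        Indexed by cell, with ``label`` (donor name, ``DOUBLET(i,j)`` or
        ``UNASSIGNED``), ``posterior`` of the winning hypothesis,
        ``n_covered_snps`` and one ``post_<hypothesis>`` column each.
    """
    donors = list(genotypes.index)
    if len(donors) < 2:
        raise ValueError("need at least two donors")
    snps = list(genotypes.columns)
    # warn on indistinct donor pairs
    for a, b in itertools.combinations(donors, 2):
        ga, gb = genotypes.loc[a], genotypes.loc[b]
        both = ~(ga.isna() | gb.isna())
        if not (ga[both] != gb[both]).any():
            warnings.warn(f"donors {a} and {b} share every genotype", stacklevel=2)

    snp_index = {s: i for i, s in enumerate(snps)}
    cells = list(pd.unique(allele_counts["cell"]))
    cell_index = {c: i for i, c in enumerate(cells)}

    alt = np.zeros((len(cells), len(snps)))
    depth = np.zeros((len(cells), len(snps)))
    known = allele_counts[allele_counts["snp"].isin(snp_index)]
    rows = known["cell"].map(cell_index).to_numpy()
    cols = known["snp"].map(snp_index).to_numpy()
    np.add.at(alt, (rows, cols), known["alt_count"].to_numpy(dtype=float))
    np.add.at(
        depth,
        (rows, cols),
        (known["alt_count"] + known["ref_count"]).to_numpy(dtype=float),
    )

    hypotheses = enumerate_hypotheses(donors, delta)
    labels = [h for h, _ in hypotheses]
    log_priors = np.log([p for _, p in hypotheses])

    # per-hypothesis dosage vectors
    G = genotypes.to_numpy(dtype=float)
    dosage_rows = [G[donors.index(d)] for d in donors]
    for a, b in itertools.combinations(range(len(donors)), 2):
        dosage_rows.append((G[a] + G[b]) / 2.0)
    H = np.vstack(dosage_rows)  # hypotheses x SNPs

    mu = eps + (1.0 - 2.0 * eps) * H  # hypotheses x SNPs (NaN propagates)
    covered = depth > 0  # cells x SNPs
    coef = gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)

    logliks = np.zeros((len(cells), len(hypotheses)))
    with np.errstate(divide="ignore", invalid="ignore"):
        log_mu = np.log(mu)
        log_1mu = np.log1p(-mu)
    for h in range(len(hypotheses)):
        usable = covered & ~np.isnan(H[h])[None, :]
        term = coef + alt * log_mu[h][None, :] + (depth - alt) * log_1mu[h][None, :]
        logliks[:, h] = np.where(usable, np.nan_to_num(term, nan=0.0, neginf=-1e30), 0.0).sum(axis=1)

    log_post = logliks + log_priors[None, :]
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    posteriors = np.exp(log_post)

    n_covered = covered.sum(axis=1)
    # a cell with no covered SNP carries no evidence: report a flat posterior
    posteriors[n_covered == 0] = 1.0 / len(hypotheses)
    best = posteriors.argmax(axis=1)
    best_post = posteriors[np.arange(len(cells)), best]

    out_labels = []
    for i in range(len(cells)):
        if n_covered[i] == 0 or best_post[i] < tau:
            out_labels.append(UNASSIGNED)
        else:
            out_labels.append(labels[best[i]])

    out = pd.DataFrame(
        {
            "label": out_labels,
            "posterior": best_post,
            "n_covered_snps": n_covered,
        },
        index=pd.Index(cells, name="cell"),
    )
    for h, lab in enumerate(labels):
        out[f"post_{lab}"] = posteriors[:, h]
    out.attrs["eps"] = eps
    out.attrs["delta"] = delta
    out.attrs["tau"] = tau
    return out


def is_doublet_label(label: str) -> bool:
    return label.startswith(DOUBLET)
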