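"""Cross-tumor-type direction concordance and pathway over-representation.

When the same gene universe is tested for differential expression against a
common non-tumor referent in several tumor types, one can ask whether the
genes significant in *every* type tend to move in the same direction.  Under
a null in which each type's direction is an independent fair coin, only
``2 / 2**T`` of direction patterns are fully concordant across ``T`` types;
the observed concordant fraction is compared to that expectation with a
one-sample proportion test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Conventional reporting floor for vanishingly small p-values.
P_DISPLAY_FLOOR = 2.2e-16


def expected_concordance(n_types: int) -> float:
    """Expected fraction of genes with one direction across all ``n_types``.

    Each tumor-type contrast contributes an independent up/down direction, so
    among the ``2**T`` equiprobable direction patterns exactly two (all-up,
    all-down) are fully concordant.

    Parameters
    ----------
    n_types
        Number of tumor-type contrasts ``T`` (>= 1).

    Returns
    -------
    float
        ``2 / 2**T``; e.g. 0.03125 for six tumor types.
    """
    if n_types < 1:
        raise ValueError(f"n_types must be >= 1, got {n_types}")
    return 2.0 / (2.0**n_types)


@dataclass
class ConcordanceResult:
    """Per-k sharing table and all-types direction concordance."""

    n_types: int
    #: number of genes significant in exactly k types, k = 0..T
    shared_counts: dict[int, int] = field(default_factory=dict)
    n_all_types: int = 0
    n_same_direction: int = 0
    observed_proportion: float | None = None
    expected_proportion: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_types_shared": list(self.shared_counts.keys()),
                "n_genes": list(self.shared_counts.values()),
            }
        )


def direction_concordance(de_tables: dict[str, pd.DataFrame]) -> ConcordanceResult:
    """Tally gene sharing across tumor types and direction concordance.

    Parameters
    ----------
    de_tables
        Mapping tumor type -> per-gene table with columns ``gene``,
        ``significant`` (bool) and ``direction`` ("up"/"down").  All tables
        must cover the same gene universe.

    Returns
    -------
    ConcordanceResult
        Counts of genes significant in exactly k of T types; among the genes
        significant in all T, the number (and fraction) whose direction is
        identical everywhere, with the analytic expectation ``2/2**T``.
    """
    types = sorted(de_tables)
    n_types = len(types)
    universes = [frozenset(t["gene"]) for t in de_tables.values()]
    if len(set(universes)) != 1:
        raise ValueError("DE tables must share a common gene universe")

    sig = pd.DataFrame(
        {
            t: de_tables[t].set_index("gene")["significant"].astype(bool)
            for t in types
        }
    )
    direction = pd.DataFrame(
        {t: de_tables[t].set_index("gene")["direction"] for t in types}
    )

    k_per_gene = sig.sum(axis=1)
    shared_counts = {
        k: int((k_per_gene == k).sum()) for k in range(n_types + 1)
    }

    all_sig = k_per_gene == n_types
    n_all = int(all_sig.sum())
    if n_all:
        dirs = direction.loc[all_sig]
        same = (dirs.nunique(axis=1) == 1).sum()
    else:
        same = 0

    return ConcordanceResult(
        n_types=n_types,
        shared_counts=shared_counts,
        n_all_types=n_all,
        n_same_direction=int(same),
        observed_proportion=(same / n_all) if n_all else None,
        expected_proportion=expected_concordance(n_types),
    )


def proportion_test(
    k: int, n: int, p0: float, continuity: bool = True
) -> tuple[float, float, float]:
    """One-sample chi-square proportion test (two-sided).

    This is the classical single-proportion test with Yates continuity
    correction (the default of the conventional ``prop.test``).

    Parameters
    ----------
    k, n
        Successes and trials.
    p0
        Null proportion, in (0, 1).
    continuity
        Apply the Yates correction (capped so it cannot overshoot).

    Returns
    -------
    (statistic, p_value, p_display)
        Chi-square statistic (1 df), the exact two-sided p-value, and the
        displayed p-value floored at 2.2e-16 per the common reporting
        convention.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")

    diff = abs(k - n * p0)
    if continuity:
        diff = max(diff - 0.5, 0.0)
    statistic = diff**2 / (n * p0 * (1.0 - p0))
    p_value = float(stats.chi2.sf(statistic, df=1))
    # the displayed value is floored; the stored value stays exact
    p_display = max(p_value, P_DISPLAY_FLOOR)
    return float(statistic), p_value, p_display


def hypergeom_ora(
    hit_list, gene_set, universe
) -> tuple[float, int]:
    """Upper-tail hypergeometric over-representation test.

    Parameters
    ----------
    hit_list
        Genes of interest (e.g. concordantly upregulated genes).
    gene_set
        Pathway membership.
    universe
        All genes eligible for either list; ``hit_list`` and ``gene_set``
        must be subsets.

    Returns
    -------
    (p_value, overlap)
        ``P(X >= overlap)`` for ``X ~ Hypergeom(|U|, |set|, |hits|)``, and
        the observed overlap count.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    hits = set(hit_list)
    members = set(gene_set)
    if not hits <= universe or not members <= universe:
        raise ValueError("hit_list and gene_set must be subsets of universe")
    overlap = len(hits & members)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(hits)))
    return min(p, 1.0), overlap
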