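"""Integration of HTO and genotype demultiplexing calls.

Decision procedure per nucleus:

===================  ========================  ==========================
HTO call             genotype call             outcome
===================  ========================  ==========================
sample_k             same donor k              keep (CONCORDANT)
sample_k             different donor           discard (DISCORDANT_DROP)
sample_k             UNASSIGNED or DOUBLET     keep HTO label (HTO_ONLY)
DOUBLET / NEGATIVE   confident donor k         keep donor k (GENOTYPE_RESCUE)
DOUBLET / NEGATIVE   UNASSIGNED or DOUBLET     discard (BOTH_UNDETERMINED)
===================  ========================  ==========================

The HTO-singlet/genotype-doublet row treats a genotype doublet call as an
undetermined assignment and keeps the HTO label; set
``keep_hto_when_gt_doublet=False`` to discard those nuclei instead, since
either reading is defensible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from pedcns import genotype_demux, hto_demux

DISCARDED = "DISCARDED"

CONCORDANT = "CONCORDANT"
HTO_ONLY = "HTO_ONLY"
GENOTYPE_RESCUE = "GENOTYPE_RESCUE"
DISCORDANT_DROP = "DISCORDANT_DROP"
BOTH_UNDETERMINED = "BOTH_UNDETERMINED"

_KEPT = {CONCORDANT, HTO_ONLY, GENOTYPE_RESCUE}


@dataclass
class DemuxSummary:
    """Yield accounting of the integrated demultiplexing run."""

    provenance_counts: dict[str, int] = field(default_factory=dict)
    n_integrated: int = 0
    n_hto_only_method: int = 0
    n_genotype_only_method: int = 0
    gain_vs_hto_pct: float | None = None
    gain_vs_genotype_pct: float | None = None

    def to_dict(self) -> dict:
        return {
            "provenance_counts": dict(self.provenance_counts),
            "n_integrated": self.n_integrated,
            "n_hto_only_method": self.n_hto_only_method,
            "n_genotype_only_method": self.n_genotype_only_method,
            "gain_vs_hto_pct": self.gain_vs_hto_pct,
            "gain_vs_genotype_pct": self.gain_vs_genotype_pct,
        }


def _is_hto_singlet(label: str) -> bool:
    return label not in (hto_demux.DOUBLET, hto_demux.NEGATIVE)


def _is_gt_singlet(label: str) -> bool:
    return label != genotype_demux.UNASSIGNED and not genotype_demux.is_doublet_label(label)


def integrate_calls(
    hto_calls: pd.DataFrame,
    gt_calls: pd.DataFrame,
    keep_hto_when_gt_doublet: bool = True,
) -> pd.DataFrame:
    """Combine per-cell HTO and genotype calls into final sample labels.

    Parameters
    ----------
    hto_calls, gt_calls
        Outputs of :func:`pedcns.hto_demux.classify_hto` and
        :func:`pedcns.genotype_demux.assign_genotype`; must cover the same
        cells.  Tag-to-sample and donor-to-sample naming must agree.

    Returns
    -------
    pandas.DataFrame
        Indexed by cell with columns ``label`` (sample name or DISCARDED)
        and ``provenance``.
    """
    hto_cells = set(hto_calls.index)
    gt_cells = set(gt_calls.index)
    if hto_cells != gt_cells:
        diff = sorted(hto_cells.symmetric_difference(gt_cells))
        raise ValueError(f"call sets differ on {len(diff)} cells, e.g. {diff[:5]}")

    gt_calls = gt_calls.reindex(hto_calls.index)
    labels, provenance = [], []
    for hto_label, gt_label in zip(hto_calls["label"], gt_calls["label"]):
        if _is_hto_singlet(hto_label):
            if _is_gt_singlet(gt_label):
                if gt_label == hto_label:
                    labels.append(hto_label)
                    provenance.append(CONCORDANT)
                else:
                    labels.append(DISCARDED)
                    provenance.append(DISCORDANT_DROP)
            elif genotype_demux.is_doublet_label(gt_label) and not keep_hto_when_gt_doublet:
                labels.append(DISCARDED)
                provenance.append(DISCORDANT_DROP)
            else:  # genotype undetermined (UNASSIGNED or doublet-as-undetermined)
                labels.append(hto_label)
                provenance.append(HTO_ONLY)
        else:  # HTO doublet or negative
            if _is_gt_singlet(gt_label):
                labels.append(gt_label)
                provenance.append(GENOTYPE_RESCUE)
            else:
                labels.append(DISCARDED)
                provenance.append(BOTH_UNDETERMINED)

    return pd.DataFrame({"label": labels, "provenance": provenance}, index=hto_calls.index)


def summarize_yield(
    integrated: pd.DataFrame,
    hto_calls: pd.DataFrame,
    gt_calls: pd.DataFrame,
) -> DemuxSummary:
    """Nucleus-yield accounting for the three demultiplexing strategies.

    ``gain = 100 * (N_integrated - N_other) / N_other`` measures the extra
    nuclei the integrated approach recovers over a single-method run.
    """
    counts = integrated["provenance"].value_counts().to_dict()
    n_integrated = int(integrated["provenance"].isin(_KEPT).sum())
    n_hto = int(hto_calls["label"].map(_is_hto_singlet).sum())
    n_gt = int(gt_calls["label"].map(_is_gt_singlet).sum())
    return DemuxSummary(
        provenance_counts=counts,
        n_integrated=n_integrated,
        n_hto_only_method=n_hto,
        n_genotype_only_method=n_gt,
        gain_vs_hto_pct=percent_gain(n_integrated, n_hto),
        gain_vs_genotype_pct=percent_gain(n_integrated, n_gt),
    )


def percent_gain(n_integrated: int, n_other: int) -> float | None:
    """``100 * (N_integrated - N_other) / N_other``; None when undefined."""
    if n_other == 0:
        return None
    return 100.0 * (n_integrated - n_other) / n_other
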