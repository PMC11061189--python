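"""Readers and writers for the standard on-disk formats.

Expression matrices travel as MatrixMarket (genes x cells, with
``barcodes.tsv``/``features.tsv``), HTO counts as CSV, per-cell allele
counts and donor genotypes as TSV, gene sets as GMT, donor genotypes
alternatively as a minimal VCF whose GT field is converted to dosage.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse


def read_mtx_dir(path: str | Path):
    """Read matrix.mtx + barcodes.tsv + features.tsv; returns (csr cell x gene, genes, barcodes)."""
    path = Path(path)
    mat = scio.mmread(path / "matrix.mtx").tocsr().T.tocsr()  # stored genes x cells
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].tolist()
    if mat.shape != (len(barcodes), len(features)):
        raise ValueError("matrix dimensions do not match barcodes/features")
    return mat, features, barcodes


def read_hto_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"cell", "snp", "ref_count", "alt_count"}
    if not required <= set(table.columns):
        raise ValueError(f"allele-count table needs columns {sorted(required)}")
    return table


def read_genotypes_tsv(path: str | Path) -> pd.DataFrame:
    """Donor x SNP dosage table (dosages in {0, 0.5, 1}, blank = missing)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    values = table.to_numpy(dtype=float)
    valid = np.isin(values[~np.isnan(values)], [0.0, 0.5, 1.0])
    if not valid.all():
        raise ValueError("dosages must be 0, 0.5 or 1 (or missing)")
    return table


_GT_DOSAGE = {
    "0/0": 0.0, "0|0": 0.0,
    "0/1": 0.5, "1/0": 0.5, "0|1": 0.5, "1|0": 0.5,
    "1/1": 1.0, "1|1": 1.0,
    "./.": np.nan, ".|.": np.nan, ".": np.nan,
}


def read_genotypes_vcf(path: str | Path) -> pd.DataFrame:
    """Minimal VCF reader: GT of each sample column -> dosage per variant.

    Variants are keyed ``CHROM:POS``; only the GT subfield is interpreted.
    """
    samples: list[str] = []
    records: dict[str, list[float]] = {}
    snp_ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                records = {s: [] for s in samples}
                continue
            if not samples:
                raise ValueError("VCF lacks a #CHROM header line")
            snp_ids.append(f"{fields[0]}:{fields[1]}")
            fmt = fields[8].split(":")
            gt_pos = fmt.index("GT")
            for s, cell in zip(samples, fields[9:]):
                gt = cell.split(":")[gt_pos]
                if gt not in _GT_DOSAGE:
                    raise ValueError(f"unsupported GT value {gt!r}")
                records[s].append(_GT_DOSAGE[gt])
    return pd.DataFrame(records, index=snp_ids).T


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def write_matrix_dir(counts, gene_names, barcodes, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mat = counts if sparse.issparse(counts) else sparse.csr_matrix(counts)
    scio.mmwrite(path / "matrix.mtx", mat.T)
    pd.Series(list(barcodes)).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
    pd.Series(list(gene_names)).to_csv(path / "features.tsv", sep="\t", index=False, header=False)
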