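"""Synthetic pooled snRNA-seq pools with ground truth.

The generator emulates the data structure of a multiplexed single-nuclei
experiment on tumor and non-tumor tissue:

* 2-4 samples pooled per run, each stained with one hashtag oligo (HTO);
  staining can be weak (``hto_stain_efficiency`` < 1), the failure mode that
  motivates genotype-based rescue;
* donor genotypes at a SNP panel (dosages 0 / 0.5 / 1) with sparse per-cell
  allele counts (Poisson depth, binomial alt reads with allele error);
* doublets formed by summing two singlet profiles, with the mean dosage of
  the two donors at every SNP;
* cell types defined by marker/program genes, with per-group (tumor type)
  cell-type composition and within-cell-type differential-expression
  effects;
* a flagged mitochondrial gene subset with a configurable count share, so
  QC filtering is exercisable.

All counts are negative binomial, parameterized by mean and dispersion
(variance ``m + a m^2``).  Every draw flows from a single
``numpy.random.Generator`` seeded by ``SimConfig.seed``, so a fixed config
reproduces the dataset exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

DOSAGE_LEVELS = np.array([0.0, 0.5, 1.0])
_BASES = "ACGT"


class ConfigurationError(ValueError):
    """Raised when a SimConfig cannot produce a valid dataset."""


@dataclass
class SimConfig:
    """Parameters of one synthetic pool.

    Defaults reflect a realistic pooled run: 2500 nuclei per sample (the
    targeted band for this kind of experiment is 2500-5000), a 5% doublet
    rate, a 50-SNP donor-discriminating panel at sparse coverage, and
    overdispersed tag/UMI counts (NB dispersion 0.5).
    """

    n_samples_per_pool: int = 4
    n_nuclei_per_sample: int = 2500
    doublet_rate: float = 0.05
    n_snps: int = 50
    snp_depth_mean: float = 2.0
    allele_error: float = 0.01
    hto_signal_mean: float = 200.0
    hto_background_mean: float = 5.0
    hto_stain_efficiency: float = 0.8
    n_genes: int = 1000
    n_celltypes: int = 3
    nb_dispersion: float = 0.5
    n_mito_genes: int = 20
    mito_fraction: float = 0.02
    program_size: int = 30
    program_strength: float = 4.0
    marker_strength: float = 8.0
    base_mean: float = 0.5
    library_sigma: float = 0.3
    composition_by_group: dict[str, list[float]] | None = None
    sample_groups: list[str] | None = None
    de_effects: dict[str, np.ndarray] | None = None
    marker_table: dict[str, list[str]] | None = None
    gene_sets: dict[str, list[str]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.doublet_rate < 0.5:
            raise ConfigurationError("doublet_rate must lie in [0, 0.5)")
        for name in (
            "hto_signal_mean",
            "hto_background_mean",
            "snp_depth_mean",
            "base_mean",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 <= self.hto_stain_efficiency <= 1:
            raise ConfigurationError("hto_stain_efficiency must lie in [0, 1]")
        if not 0 <= self.allele_error < 0.5:
            raise ConfigurationError("allele_error must lie in [0, 0.5)")
        if self.sample_groups is None:
            self.sample_groups = ["non_tumor"] + ["tumor"] * (self.n_samples_per_pool - 1)
        if len(self.sample_groups) != self.n_samples_per_pool:
            raise ConfigurationError("sample_groups must have one entry per sample")
        if self.composition_by_group is None:
            uniform = [1.0 / self.n_celltypes] * self.n_celltypes
            self.composition_by_group = {g: list(uniform) for g in set(self.sample_groups)}
        for group, comp in self.composition_by_group.items():
            comp = np.asarray(comp, dtype=float)
            if len(comp) != self.n_celltypes:
                raise ConfigurationError(
                    f"composition for group {group} must have {self.n_celltypes} entries"
                )
            if (comp < 0).any() or (comp > 1).any() or not np.isclose(comp.sum(), 1.0):
                raise ConfigurationError(
                    f"composition for group {group} must be a probability vector"
                )

    @property
    def sample_names(self) -> list[str]:
        return [f"sample_{i}" for i in range(self.n_samples_per_pool)]

    @property
    def celltype_names(self) -> list[str]:
        return [f"type_{i}" for i in range(self.n_celltypes)]


@dataclass
class SimTruth:
    """Ground truth of a simulated pool.

    ``cells`` has one row per emitted barcode (sample of origin, doublet
    partner, cell type, group); ``genes`` carries per-gene flags and true
    effects; ``gene_sets`` records set membership.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame
    gene_sets: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class PoolDataset:
    """One pool's raw data: expression, HTO, allele counts, genotypes."""

    counts: sparse.csr_matrix
    gene_names: list[str]
    barcodes: list[str]
    hto: pd.DataFrame | None
    tag_to_sample: dict[str, str] | None
    allele_counts: pd.DataFrame | None
    genotypes: pd.DataFrame | None
    metadata: dict = field(default_factory=dict)

    @property
    def mito_gene_ids(self) -> list[str]:
        return [g for g in self.gene_names if g.startswith("MT-")]


def make_barcodes(n: int, length: int = 16) -> list[str]:
    """Deterministic, collision-free synthetic barcodes (base-4 16-mers)."""
    if n > 4**length:
        raise ConfigurationError("too many barcodes for the requested length")
    barcodes = []
    for i in range(n):
        digits = []
        x = i
        for _ in range(length):
            digits.append(_BASES[x % 4])
            x //= 4
        barcodes.append("".join(reversed(digits)))
    return barcodes


def simulate_genotypes(config: SimConfig) -> pd.DataFrame:
    """Donor x SNP dosage matrix with every donor pair distinct.

    Dosages are drawn uniformly over {0, 0.5, 1}; the matrix is resampled
    until all pairs of donors differ at >= 1 SNP.  Raises
    :class:`ConfigurationError` when fewer than ``n_donors`` distinct
    genotype vectors exist (``3**n_snps < n_donors``).
    """
    n_donors = config.n_samples_per_pool
    if config.n_snps < 1:
        raise ConfigurationError("n_snps must be >= 1")
    if n_donors < 2:
        raise ConfigurationError("need at least two donors")
    if 3**min(config.n_snps, 40) < n_donors:
        raise ConfigurationError("n_snps too small to distinguish all donors")

    rng = np.random.default_rng(config.seed)
    for _ in range(1000):
        G = rng.choice(DOSAGE_LEVELS, size=(n_donors, config.n_snps))
        if len({tuple(row) for row in G}) == n_donors:
            return pd.DataFrame(
                G,
                index=config.sample_names,
                columns=[f"snp_{j}" for j in range(config.n_snps)],
            )
    raise ConfigurationError("could not generate distinct donor genotypes")


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson sample with variance ``m + dispersion * m^2``."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _gene_means(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Per-cell-type mean vectors plus the gene annotation table.

    Layout: the first ``n_mito_genes`` genes are mitochondrial; each cell
    type then owns a block of ``program_size`` program genes (upregulated
    ``program_strength``-fold in that type), the first two of which are its
    markers (``marker_strength``-fold).
    """
    n_genes, n_types = config.n_genes, config.n_celltypes
    needed = config.n_mito_genes + n_types * config.program_size
    if needed > n_genes:
        raise ConfigurationError("n_genes too small for mito + program blocks")

    gene_names = [f"MT-{i}" for i in range(config.n_mito_genes)] + [
        f"gene_{i}" for i in range(n_genes - config.n_mito_genes)
    ]
    base = rng.lognormal(mean=np.log(config.base_mean), sigma=0.6, size=n_genes)

    means = np.tile(base, (n_types, 1))
    marker_table: dict[str, list[str]] = {}
    program_table: dict[str, list[str]] = {}
    start = config.n_mito_genes
    for t in range(n_types):
        block = slice(start + t * config.program_size, start + (t + 1) * config.program_size)
        means[t, block] *= config.program_strength
        idx = list(range(block.start, block.stop))
        markers = idx[:2]
        means[t, markers] = base[markers] * config.marker_strength
        tname = config.celltype_names[t]
        marker_table[tname] = [gene_names[i] for i in markers]
        program_table[tname] = [gene_names[i] for i in idx]

    # mito block: fixed share of total counts, identical across types
    non_mito_total = means[:, config.n_mito_genes :].sum(axis=1).mean()
    mito_total = config.mito_fraction / (1.0 - config.mito_fraction) * non_mito_total
    means[:, : config.n_mito_genes] = mito_total / config.n_mito_genes

    genes = pd.DataFrame(
        {
            "gene": gene_names,
            "is_mito": [g.startswith("MT-") for g in gene_names],
        }
    )
    return means, genes, {"markers": marker_table, "programs": program_table}


def simulate_pool(config: SimConfig, genotypes: pd.DataFrame | None = None) -> tuple[PoolDataset, SimTruth]:
    """Generate one pool (expression + HTO + allele counts) with truth.

    Parameters
    ----------
    config
        Simulation parameters.
    genotypes
        Donor x SNP dosages from :func:`simulate_genotypes`; generated
        on the fly when omitted.

    Returns
    -------
    (PoolDataset, SimTruth)
    """
    if genotypes is None:
        genotypes = simulate_genotypes(config)
    if list(genotypes.index) != config.sample_names:
        raise ConfigurationError("genotypes must cover exactly the pool's samples")

    rng = np.random.default_rng(config.seed)
    samples = config.sample_names
    group_of = dict(zip(samples, config.sample_groups))
    n_total = config.n_samples_per_pool * config.n_nuclei_per_sample

    # --- truth assignment -------------------------------------------------
    sample1 = np.repeat(samples, config.n_nuclei_per_sample)
    is_doublet = rng.random(n_total) < config.doublet_rate
    sample2 = np.full(n_total, "", dtype=object)
    for i in np.flatnonzero(is_doublet):
        others = [s for s in samples if s != sample1[i]]
        sample2[i] = rng.choice(others)

    def draw_type(sample: str) -> str:
        comp = np.asarray(config.composition_by_group[group_of[sample]], dtype=float)
        return config.celltype_names[rng.choice(config.n_celltypes, p=comp)]

    type1 = np.array([draw_type(s) for s in sample1], dtype=object)
    type2 = np.array(
        [draw_type(sample2[i]) if is_doublet[i] else "" for i in range(n_total)],
        dtype=object,
    )

    barcodes = make_barcodes(n_total)

    # --- expression -------------------------------------------------------
    means, genes, tables = _gene_means(config, rng)
    type_index = {t: i for i, t in enumerate(config.celltype_names)}
    de = config.de_effects or {}
    group_mult = {
        g: np.exp(np.asarray(de[g], dtype=float)) if g in de else None
        for g in set(config.sample_groups)
    }

    def component_counts(sample: str, ctype: str) -> np.ndarray:
        m = means[type_index[ctype]].copy()
        mult = group_mult[group_of[sample]]
        if mult is not None:
            m = m * mult
        lib = rng.lognormal(mean=0.0, sigma=config.library_sigma)
        return _nb_draws(rng, m * lib, config.nb_dispersion)

    X = np.zeros((n_total, config.n_genes), dtype=np.int64)
    for i in range(n_total):
        X[i] = component_counts(sample1[i], type1[i])
        if is_doublet[i]:
            X[i] += component_counts(sample2[i], type2[i])

    # --- HTO counts -------------------------------------------------------
    tags = [f"tag_{s}" for s in samples]
    tag_to_sample = dict(zip(tags, samples))
    hto = _nb_draws(
        rng,
        np.full((n_total, len(tags)), config.hto_background_mean),
        config.nb_dispersion,
    ).astype(np.int64)
    sample_pos = {s: j for j, s in enumerate(samples)}
    for i in range(n_total):
        true_tags = [sample_pos[sample1[i]]]
        if is_doublet[i]:
            true_tags.append(sample_pos[sample2[i]])
        for j in true_tags:
            if rng.random() < config.hto_stain_efficiency:
                hto[i, j] = _nb_draws(
                    rng, np.array(config.hto_signal_mean), config.nb_dispersion
                )

    # --- SNP allele counts ------------------------------------------------
    G = genotypes.to_numpy(dtype=float)
    dosage = np.empty((n_total, config.n_snps))
    for i in range(n_total):
        d = G[sample_pos[sample1[i]]]
        if is_doublet[i]:
            d = (d + G[sample_pos[sample2[i]]]) / 2.0
        dosage[i] = d
    depth = rng.poisson(config.snp_depth_mean, size=(n_total, config.n_snps))
    mu = config.allele_error + (1.0 - 2.0 * config.allele_error) * dosage
    alt = rng.binomial(depth, mu)
    rows, cols = np.nonzero(depth)
    allele_counts = pd.DataFrame(
        {
            "cell": [barcodes[i] for i in rows],
            "snp": [genotypes.columns[j] for j in cols],
            "ref_count": depth[rows, cols] - alt[rows, cols],
            "alt_count": alt[rows, cols],
        }
    )

    gene_sets = config.gene_sets or {
        f"program_{t}": tables["programs"][t] for t in config.celltype_names
    }

    dataset = PoolDataset(
        counts=sparse.csr_matrix(X),
        gene_names=list(genes["gene"]),
        barcodes=barcodes,
        hto=pd.DataFrame(hto, index=barcodes, columns=tags),
        tag_to_sample=tag_to_sample,
        allele_counts=allele_counts,
        genotypes=genotypes,
        metadata={
            "sample_groups": group_of,
            "marker_table": config.marker_table or tables["markers"],
            "seed": config.seed,
        },
    )
    truth = SimTruth(
        cells=pd.DataFrame(
            {
                "barcode": barcodes,
                "sample_of_origin": sample1,
                "doublet_partner": sample2,
                "is_doublet": is_doublet,
                "cell_type": type1,
                "cell_type_2": type2,
                "group": [group_of[s] for s in sample1],
            }
        ),
        genes=genes,
        gene_sets=gene_sets,
    )
    return dataset, truth


def simulate_confounded_expression(
    config: SimConfig | None = None,
    n_confounded: int = 100,
    n_effect: int = 100,
    n_background: int = 300,
    baseline_high: float = 10.0,
    baseline_low: float = 1.0,
    effect_lnfc: float = 1.0,
    ballast_mean: float = 30.0,
) -> tuple[PoolDataset, SimTruth]:
    """Two-group dataset where composition alone drives marginal differences.

    The default design has two cell types mixed 80/20 in the non-tumor group
    and 20/80 in the tumor group.  ``n_confounded`` genes have cell-type
    baselines of 10 vs 1 and *zero* within-type group effect — marginally
    they differ ~3-fold between groups purely through composition.
    ``n_effect`` genes carry a genuine within-type ln-fold-change of 1.0 in
    the tumor group, and ``n_background`` genes are flat nulls at
    ``ballast_mean``.  The background block carries most of each cell's
    library, mimicking a transcriptome in which the genes under test are a
    small share of total counts, so library-size factors track sequencing
    depth rather than cell-type content.  Truth flags each gene class, so
    unadjusted/adjusted DE can be scored against it.
    """
    if config is None:
        config = SimConfig(
            n_samples_per_pool=2,
            n_nuclei_per_sample=1000,
            doublet_rate=0.0,
            n_celltypes=2,
            n_genes=n_confounded + n_effect + n_background,
            n_mito_genes=0,
            sample_groups=["non_tumor", "tumor"],
            composition_by_group={"non_tumor": [0.8, 0.2], "tumor": [0.2, 0.8]},
            seed=0,
        )
    if len(set(config.sample_groups)) < 2:
        raise ConfigurationError("need >= 2 groups for a confounding design")
    if config.n_celltypes != 2:
        raise ConfigurationError("the confounding design uses exactly 2 cell types")
    n_genes = n_confounded + n_effect + n_background
    if config.n_genes != n_genes:
        raise ConfigurationError("config.n_genes must equal the gene-class total")

    rng = np.random.default_rng(config.seed)
    gene_names = [f"gene_{i}" for i in range(n_genes)]
    # rows: cell types; confounded genes differ by type, others do not
    means = np.full((2, n_genes), 1.0)
    means[0, :n_confounded] = baseline_high
    means[1, :n_confounded] = baseline_low
    means[:, n_confounded + n_effect :] = ballast_mean

    lnfc = np.zeros(n_genes)
    lnfc[n_confounded : n_confounded + n_effect] = effect_lnfc
    tumor_groups = [g for g in set(config.sample_groups) if g != "non_tumor"]
    group_mult = {g: np.exp(lnfc) for g in tumor_groups}
    group_mult["non_tumor"] = None

    samples = config.sample_names
    group_of = dict(zip(samples, config.sample_groups))
    n_total = config.n_samples_per_pool * config.n_nuclei_per_sample
    sample1 = np.repeat(samples, config.n_nuclei_per_sample)
    types = np.empty(n_total, dtype=object)
    X = np.zeros((n_total, n_genes), dtype=np.int64)
    for i in range(n_total):
        comp = np.asarray(config.composition_by_group[group_of[sample1[i]]])
        t = int(rng.choice(2, p=comp))
        types[i] = config.celltype_names[t]
        m = means[t].copy()
        mult = group_mult[group_of[sample1[i]]]
        if mult is not None:
            m = m * mult
        lib = rng.lognormal(0.0, config.library_sigma)
        X[i] = _nb_draws(rng, m * lib, config.nb_dispersion)

    barcodes = make_barcodes(n_total)
    genes = pd.DataFrame(
        {
            "gene": gene_names,
            "is_mito": False,
            "confounded_null": [i < n_confounded for i in range(n_genes)],
            "true_lnfc": lnfc,
        }
    )
    dataset = PoolDataset(
        counts=sparse.csr_matrix(X),
        gene_names=gene_names,
        barcodes=barcodes,
        hto=None,
        tag_to_sample=None,
        allele_counts=None,
        genotypes=None,
        metadata={"sample_groups": group_of, "seed": config.seed},
    )
    truth = SimTruth(
        cells=pd.DataFrame(
            {
                "barcode": barcodes,
                "sample_of_origin": sample1,
                "doublet_partner": "",
                "is_doublet": False,
                "cell_type": types,
                "cell_type_2": "",
                "group": [group_of[s] for s in sample1],
            }
        ),
        genes=genes,
    )
    return dataset, truth


def write_pool(dataset: PoolDataset, truth: SimTruth, outdir: str | Path) -> Path:
    """Write a pool to disk in plain-text formats (MTX/TSV/CSV/JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scio.mmwrite(outdir / "matrix.mtx", dataset.counts.T)  # genes x cells convention
    pd.Series(dataset.barcodes).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    pd.Series(dataset.gene_names).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    if dataset.hto is not None:
        dataset.hto.to_csv(outdir / "hto_counts.csv")
    if dataset.allele_counts is not None:
        dataset.allele_counts.to_csv(outdir / "allele_counts.tsv", sep="\t", index=False)
    if dataset.genotypes is not None:
        dataset.genotypes.to_csv(outdir / "genotypes.tsv", sep="\t")
    truth.cells.to_csv(outdir / "truth_cells.csv", index=False)
    truth.genes.to_csv(outdir / "truth_genes.csv", index=False)
    payload = {
        "tag_to_sample": dataset.tag_to_sample,
        "metadata": {
            k: v for k, v in dataset.metadata.items() if k != "marker_table"
        },
        "gene_sets": truth.gene_sets,
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=2, default=str))
    return outdir
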