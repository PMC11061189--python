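# pedcns

Pooled single-nuclei RNA-seq analysis for tumor studies that multiplex
several samples per sequencing run — written around the analysis needs of
pediatric CNS tumor cohorts, where tissue is scarce, pools mix tumor and
non-tumor samples, and hashtag staining of decades-old frozen tissue is
often too weak to demultiplex on its own.

The package provides, as a library plus a `pdx` command line:

* **Integrated demultiplexing.** Nuclei are first classified from hashtag
  oligonucleotide (HTO) counts (CLR normalization, negative-binomial
  background thresholds per tag). Independently, each nucleus is assigned
  to a donor from sparse per-cell SNP allele counts given bulk-derived
  donor genotypes, with binomial singlet/doublet likelihoods
  (`mu = eps + (1 - 2 eps) * dosage`, doublets use the mean dosage of the
  donor pair). The two calls are integrated: concordant calls are kept,
  discordant ones dropped, and nuclei the HTO method leaves undetermined
  are rescued by their genotype call — recovering a large fraction of an
  otherwise-lost pool.
* **Cell typing.** Leiden clustering on an SNN graph of the PCA embedding,
  marker-score assignment of major brain cell types (GFAP/AQP4 astrocytes,
  MOG/PLP1 oligodendrocytes, ...), and expression-bin-matched module
  scores (e.g. a stemness score over classical stem-cell markers).
* **Single-cell pathway scoring.** Variance-adjusted Mahalanobis (VAM)
  gene-set scores `S_cP = sum_j x_cj^2 / v_j` with a permutation-gamma
  null, BH correction across nuclei, binary enrichment calls at FDR 0.1,
  and per-cluster differential enrichment via rank-sum tests on the
  binary indicator.
* **Cell-type-adjusted differential expression.** Per-gene quasi-Poisson
  GLMs (log link, log-size-factor offset, Wald t-tests with Pearson
  dispersion) contrasting each tumor type against non-tumor tissue, with
  and without a major-cell-type covariate. Comparing the two models
  separates genuine within-cell-type expression changes from differences
  that only reflect cell-type composition.
* **Cross-tumor-type concordance.** Tallies of genes significant in k of T
  tumor types, the fraction moving in one direction among the genes
  significant in all T, the analytic null `2 / 2^T` (3.13% for six types),
  a one-sample proportion test, and hypergeometric over-representation of
  gene sets.
* **A synthetic-data generator** that emulates the pooled design with full
  ground truth (sample of origin, doublets, cell types, programmed
  effects), so every stage is testable against known answers.

## Worked example: rescuing a weakly stained pool

```python
from pedcns import synthetic_data as sd
from pedcns.hto_demux import classify_hto
from pedcns.genotype_demux import assign_genotype
from pedcns.demux_integration import integrate_calls, summarize_yield

cfg = sd.SimConfig(
    n_samples_per_pool=4, n_nuclei_per_sample=1000, doublet_rate=0.05,
    hto_stain_efficiency=0.5,   # only half the nuclei get signal-level tags
    n_snps=50, snp_depth_mean=2.0,
    n_genes=60, program_size=10, n_mito_genes=5, seed=101,
)
genotypes = sd.simulate_genotypes(cfg)
dataset, truth = sd.simulate_pool(cfg, genotypes)

hto = classify_hto(dataset.hto, dataset.tag_to_sample, seed=0)
gt = assign_genotype(dataset.allele_counts, genotypes).reindex(dataset.barcodes)
gt["label"] = gt["label"].fillna("UNASSIGNED")
integrated = integrate_calls(hto, gt)
summary = summarize_yield(integrated, hto, gt)
print("provenance:", summary.provenance_counts)
print(f"kept {summary.n_integrated} nuclei "
      f"(HTO alone: {summary.n_hto_only_method}, genotype alone: {summary.n_genotype_only_method})")
print(f"gain over HTO-only: {summary.gain_vs_hto_pct:.1f}%")
```

Output:

```
provenance: {'GENOTYPE_RESCUE': 2143, 'CONCORDANT': 1666, 'HTO_ONLY': 96, 'BOTH_UNDETERMINED': 95}
kept 3905 nuclei (HTO alone: 1762, genotype alone: 3809)
gain over HTO-only: 121.6%
```

With staining efficiency 0.5, the HTO classifier alone confidently assigns
only 1,762 of 4,000 nuclei; 2,143 more are rescued by their genotype call
(in this simulation the rescued labels are >99% correct against ground
truth), 95 remain undetermined by both methods and are discarded, and the
integrated yield is 3,905 nuclei — a 121.6% gain over hashing alone.

The same analysis runs end to end from the shell:

```bash
pdx run --seed 1 --out demo_run          # simulate + demux + annotate + DE
pdx simulate --config sim.yaml --seed 1 --out pool/
pdx demux-hto --hto-csv pool/hto_counts.csv --out hto.csv
pdx demux-gt --allele-tsv pool/allele_counts.tsv --genotypes pool/genotypes.tsv --out gt.csv
pdx demux-integrate --hto-calls hto.csv --gt-calls gt.csv --out integrated.csv
```

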