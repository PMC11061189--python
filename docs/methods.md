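# Methods

This note documents the statistical models implemented in `pedcns`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions that were
genuinely open.

## Synthetic pooled pools

`synthetic_data.SimConfig` / `simulate_pool` generate one multiplexed pool
with complete ground truth. The generative model, per nucleus:

* **Sample of origin.** Each of the `n_samples_per_pool` (default 4)
  samples contributes `n_nuclei_per_sample` nuclei (default 2,500, the
  middle of the 2,500–5,000 band a pooled run targets). With probability
  `doublet_rate` (default 0.05) a nucleus is a doublet: a second sample is
  drawn uniformly from the other pooled samples and the expression profile
  is the **sum of two independently drawn singlet profiles** — the
  simplest generative doublet model, adequate because downstream methods
  only rely on doublets being mixtures.
* **HTO counts.** One tag per sample. The true tag(s) receive
  negative-binomial counts at `hto_signal_mean` (default 200) with
  probability `hto_stain_efficiency`, otherwise — and for all other tags —
  NB counts at `hto_background_mean` (default 5). All NB draws are
  mean/dispersion parameterized (variance `m + a m^2`, dispersion
  `a = 0.5` by default), matching the overdispersion of tag and UMI
  counts. Staining efficiency defaults to 0.8; lowering it reproduces the
  qualitative failure mode of weakly stained pools (rising NEGATIVE rate)
  without asserting any particular real-world magnitude, which is not
  quantified anywhere we could anchor it.
* **SNP allele counts.** Donor genotypes are dosages drawn uniformly from
  {0, 0.5, 1} per SNP (no Hardy–Weinberg structure is imposed), resampled
  until every donor pair differs somewhere. Per cell and SNP, read depth
  is Poisson(`snp_depth_mean`, default 2 — deliberately sparse), and
  alternate reads are Binomial(depth, `eps + (1-2 eps) * dosage`) with
  allele error `eps = 0.01`. Doublets use the mean dosage of their two
  donors.
* **Expression.** Each cell type owns a block of `program_size` program
  genes upregulated `program_strength`-fold (markers within the block get
  `marker_strength`-fold, default 8). Baseline gene means are log-normal
  around `base_mean`; per-cell library factors are log-normal with sigma
  0.3; per-group (tumor-type) `de_effects` multiply means within every
  cell type. The first `n_mito_genes` genes are flagged mitochondrial and
  carry a fixed share (`mito_fraction`, default 2%) of expected counts so
  QC filtering is exercisable.

Not emulated (by design): transcriptome-wide biological covariance beyond
the cell-type programs, cross-pool batch effects, and ambient RNA. Passing
tests therefore demonstrate correctness of the algorithms under the stated
generative assumptions, not robustness to every artifact of real tissue.

### The confounding design

`simulate_confounded_expression` builds the two-group dataset used to
demonstrate cell-type-composition confounding: two cell types mixed 80/20
in non-tumor and 20/80 in tumor; 100 "confounded null" genes with type
baselines 10 vs 1 and zero within-type group effect (their marginal
between-group fold change, (0.8·10+0.2·1)/(0.2·10+0.8·1) ≈ 2.93, is pure
composition); 100 genes with a genuine within-type ln-fold-change of 1.0;
and 300 flat background genes at mean 30. The background block
deliberately dominates each cell's library, mimicking a real transcriptome
in which the genes under test are a small share of total counts — this
keeps library-size factors a proxy for sequencing depth rather than for
cell-type content, which is the regime in which offset-based DE is
meaningful.

## Quality control and normalization

Nuclei are kept when detected features lie strictly between 200 and 10,000
and the mitochondrial read fraction is strictly below 5% (both bounds
treated as strict inequalities). Normalization is median-ratio log:
`x = ln(1 + c * median(s)/s_c)` with `s_c` the cell's total counts; the
size factors are reused as GLM offsets so normalization and DE are
mutually consistent. HVG ranking is vst-style standardized variance: a
local regression (lowess) of log10 variance on log10 mean supplies the
expected variance, z-scores are clipped at sqrt(N), and genes are ranked
by the variance of the clipped z-scores (ties broken by gene id). Because
hypervariable genes at extreme mean positions would otherwise pull the
local fit through their own point, trend fitting excludes genes more than
3 robust SDs above a Theil–Sen baseline and interpolates the trend there
instead.

## HTO demultiplexing

Tag counts are CLR-transformed per tag across cells
(`ln(x+1) - mean_cells ln(x+1)`), the modern default margin. Cells are
partitioned into `n_tags + 1` groups (k-means on the CLR profile with a
fixed seed — the partition only supplies per-tag background populations,
so any stable k-medoids-like partitioning works); per tag, the cluster
with the lowest mean is the background, a negative binomial is fitted to
its raw counts by method of moments (Poisson fallback when
underdispersed), and a cell is positive for the tag when its raw count
exceeds the NB quantile `q = 0.99`. Exactly one positive tag → singlet;
two or more → DOUBLET; none → NEGATIVE. `q` and the seed are configurable
since published analyses rarely state them.

## Genotype demultiplexing

Known-genotype donor deconvolution: hypotheses are the K singlets (prior
`(1-delta)/K` each) and the C(K,2) unordered doublets (prior
`delta/C(K,2)` each, mixture taken 50:50). Per covered SNP the alternate
count is Binomial(depth, `eps + (1-2 eps) * dosage`), with missing
genotypes skipped; log-likelihoods are summed and posteriors computed by
log-sum-exp. A cell is labeled by its maximum-posterior hypothesis when
that posterior reaches `tau = 0.9`, otherwise UNASSIGNED; zero-coverage
cells report a flat posterior. `eps = 0.01` is fixed rather than
estimated, and `tau` is this package's operational definition of
"confidently assigned" — neither has a canonical published value. A
genotype-free variational mode is out of scope: bulk genotypes for every
pooled sample are assumed, as a bulk-sequenced cohort provides.

Bulk variant records feeding the genotype table are filtered at total
depth ≥ 10, allele frequency ≥ 5%, and alternate depth ≥ 5 (inclusive
bounds).

## Integrating the two methods

Per nucleus: concordant singlet calls are kept; HTO-singlet/genotype-
different-donor conflicts are discarded; an HTO singlet whose genotype
call is undetermined (UNASSIGNED, or DOUBLET — treated as undetermined by
default, toggleable since either reading is defensible) keeps its HTO
label; HTO-undetermined nuclei with a confident genotype singlet are
rescued with the donor label; nuclei undetermined by both are discarded.
Yield gains are reported as `100 * (N_integrated - N_method) / N_method`.

## Clustering, cell typing, module scores

Clustering: PCA (default 50 components) on the scaled normalized matrix,
SNN graph at `n_neighbors = 30`, Leiden modularity optimization at
resolution 1.0 with fixed seed (the specific community-detection variant
is an implementation choice; determinism is the requirement). Cluster
cell-type assignment: per cluster and type, the mean over the type's
markers of (cluster-mean − global-mean) normalized expression; argmax
wins, exact ties are UNRESOLVED. Marker-negative populations (e.g.
stem-like clusters that do not express SOX2/CD44) are expected to be
resolved by gene-set enrichment: the VAM cell-type validation flags can
override a weak marker argmax.

Module scores bin all genes into 24 expression bins and draw 100 control
genes per set gene from the non-set genes of its bin (with replacement,
seeded); the score is mean set expression minus mean control expression.
Excluding set genes from control pools keeps the score an unbiased
contrast when a set is concentrated in few bins; when a bin contains only
set genes the pool falls back to the full bin. The default stemness list
is the classical stem-cell marker panel shipped in
`pedcns/data/stemness_markers.gmt`; any user GMT is accepted.

## VAM pathway scoring

Per-cell score for set P: `S_cP = sum_{j in P} x_cj^2 / v_j` with `v_j`
the per-gene sample variance floored at 1e-8 — a squared distance from the
origin with diagonal variance adjustment. The variance estimator is the
plain sample variance: a technical-variance decomposition would need
spike-ins or trend fits that a standard droplet experiment does not
provide, and the permutation-calibrated null makes the simpler estimator
self-consistent (verified by the uniform-null property test). The null
permutes each gene's values across cells independently (`n_null_perms`
default 100), fits a gamma by method of moments to the null scores, and
takes upper-tail p-values; per set, BH across cells at FDR 0.1 yields the
binary enrichment call. Cell-type validation uses the unadjusted p at
0.05.

Per-cluster differential enrichment runs a tie-corrected rank-sum test on
the 0/1 indicator (cluster vs rest) — algebraically a pooled two-
proportion z-test with (N−1) variance normalization, which the tests
verify to 1e-6. Fold change is `log2((p_k + c)/(p_rest + c))` with
pseudocount `c = 1e-3` (the untied choice; any small c gives the same
sign); BH is applied per cluster by default (global family behind a
flag), and only positive-direction sets are reported significant.

## Differential expression

Per gene and tumor type, cells of that type plus all non-tumor cells enter
a log-link count GLM with the log size factor as offset; the adjusted
model adds the major cell type as a factor (major types, not fine
clusters). Inference is quasi-Poisson: dispersion `phi = Pearson X^2 /
df_resid`, Wald t-statistics with SE scaled by `sqrt(phi)` on the residual
df (a likelihood-ratio alternative was considered and not needed; the
Wald-with-Pearson-dispersion convention matches the common
single-cell-GLM toolkits). Non-converged or separated fits are flagged
and reported at p = 1. BH is applied within each (tumor type, model)
family; significance at FDR 0.05; direction is the estimate's sign. All
tumor samples of a type form one factor level regardless of pool.

Model comparison classifies each gene per tumor type as significant in
both / adjusted-only / unadjusted-only, flags sign-discordant genes
(significant in both, opposite signs), and reports the
unadjusted/adjusted estimate ratio.

## Concordance statistics

With T tumor types each compared to the same referent, the null
probability that a gene's direction agrees in all T contrasts is
`2 / 2^T` (two concordant patterns among `2^T` equiprobable ones) —
0.03125, i.e. 3.13%, at T = 6; the value is stored at full precision and
rounded only for display. The observed concordant fraction among
genes significant in all T types is tested with a one-sample chi-square
proportion test with Yates continuity correction (toggleable); displayed
p-values are floored at 2.2e-16 while the exact value is stored.
Over-representation uses the upper-tail hypergeometric probability
`P(X >= overlap)` with BH across sets when batched.

## Problem sizes used in the test suite

The simulation-backed tests run at reduced but statistically adequate
sizes chosen so each check retains power: demultiplexing recovery on a
4,000-nucleus pool (50 SNPs, depth 2, staining efficiency 0.5), the
confounding demonstration on 2,000 cells x 500 genes, VAM null
calibration on 5,000 cells, quasi-Poisson calibration on 500 null genes,
and brute-force oracle comparisons on ≤ 4 donors / ≤ 15-gene universes
where exhaustive enumeration is possible.

## Known limitations

* Genotypes are scoped per pool; cross-pool genotype sharing is not
  modeled.
* The generator's doublets are always cross-sample mixtures; same-sample
  doublets (invisible to both demultiplexing methods) are not emulated.
* VAM p-values are calibrated against the permutation null of the
  observed matrix; strong global structure (e.g. unremoved batch effects)
  would make that null conservative.
* Library-size offsets conflate depth with content when the tested genes
  dominate the library; the DE machinery assumes the usual regime in
  which they do not.
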