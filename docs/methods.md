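# Methods

This note documents the models and procedures implemented in `dielmat`, the
parameters that matter, the design choices made where the design was open,
and what the synthetic benchmark does and does not demonstrate.

## Community census

The census works on a taxon × sample table of fold coverage per 100 million
reads: `fold_coverage = (mapped bases / MAG length) × (1e8 / library reads)`.
The unit's name fixes the formula only up to convention; we use per-base
coverage rescaled linearly to a 100 M read library so tables from libraries
of different depths are directly comparable.

Taxon classes are rule-based and exhaustive: **core** taxa have at least
1-fold coverage in every sample; **rare** taxa have median coverage below
1-fold; **variable** taxa are the remainder (median at or above the cutoff
with at least one sample below it). Because median ≥ min, the rules cannot
overlap. Multiplying all coverages by c > 1 can only move taxa toward
core/variable, never toward rare (tested as a property).

Diversity and difference statistics operate on per-sample relative
abundance (columns renormalized to 1):

- **Shannon H** in bits (log base 2, the convention of the standard
  ecological toolkits; the base is a parameter).
- **Bray–Curtis** via `scipy.spatial.distance`.
- **ANOSIM**: R = (mean between-group rank − mean within-group rank) /
  (n(n−1)/4) over the upper-triangle distances with midranks for ties. The
  permutation p-value uses the (t+1)/(B+1) convention that counts the
  observed labelling, so the smallest achievable p with B permutations is
  1/(B+1) and the test is exactly calibrated under exchangeability
  (rejection at p ≤ 0.05 occurs at rate 0.05 under the null). The
  permutation stream is seeded; scikit-bio's implementation serves as an
  independent cross-check in the tests, never as the implementation.
- **ANCOM**: counts receive a pseudocount of 1 (simplest zero-handling),
  and for each taxon i, W_i counts taxa j for which a one-way ANOVA on
  log(x_i/x_j) across groups has p < 0.05. Taxa with W ≥ 0.7(m−1) are
  flagged — the method's common empirical default cutoff. Log-ratios make W
  invariant to per-sample scaling (property-tested with random per-sample
  factors).
- **Kruskal–Wallis** via `scipy.stats.kruskal` (midrank tie correction,
  chi-square p). A fully constant input returns H = 0, p = 1 rather than an
  error.

## Expression pipeline

Reads are counted per MAG gene; because abundant taxa often have fragmented
or closely related MAGs, counts are summed per ortholog cluster per taxon
(`aggregate_counts`), conserving totals exactly and failing loudly on gene
ids missing from the catalog. Clusters with fewer than `min_total` summed
counts per series are dropped before normalization. The default
`min_total = 10` is a conventional low-count filter; the source analysis
states a filter without a threshold.

**RLE size factors** are median-of-ratios: the reference profile is the
per-gene geometric mean across samples over genes with no zero anywhere;
each sample's factor is the median ratio to the reference, rescaled to
geometric mean 1. **CPM** converts the size factors to norm factors relative
to library size (again geometric mean 1) and divides each count by the
sample's effective library (library × norm factor) × 1e−6. This composition
is exactly 1-homogeneous in each sample's counts, so multiplying one
sample's raw counts by any c > 0 changes neither that sample's CPM vector
nor any other's — the pipeline invariance the tests check to 1e−9. A
consequence worth noting: CPM columns sum to 1e6/norm-factor, not exactly
1e6; per-sample quantities that must be shares (the active-taxa tiers)
therefore divide by the sample's total CPM rather than by the nominal 1e6.

**Highly expressed** genes have mean CPM strictly above 1, with the mean
taken across the union of samples from all series (one network is built on
genes filtered once; a per-series variant is a parameter away). **Active
taxa** come in two tiers: tier 1 holds ≥ 1% of total CPM in every sample of
every series; tier 2 reaches 1% in at least one sample. The share
denominator uses retained-gene CPM; whether the original analyses used all
aligned reads instead is not stated, and at desk scale the difference is a
few percent of the denominator.

## Diel timing

A gene's peak is the clock time of its maximum expression — invariant to
any strictly increasing per-gene transform, so it is indifferent to whether
CPM, log CPM or z-scores are supplied. Ties break to the earliest tied
time; constant rows are flagged and excluded from interpretation. For
display-style summaries the package z-scales log2(CPM + 1) per gene
(pseudocount 1; population standard deviation).

Day/night windows come from sunrise and sunset in the series design; dawn
and dusk are overlays of ±1.5 h (configurable) around sunrise and sunset
respectively, taking precedence over the plain day/night split. A taxon's
profile reports the percentage of its highly expressed genes peaking at
each sample time (sums to 100), the majority phase (day or night if > 50%,
else mixed), and dawn/dusk flags at ≥ 20%.

Peaks are computed per series and cross-series consistency is reported, not
averaged.

## Consensus co-expression network

Within each series, expression is log2(CPM+1) z-scaled per gene (Pearson
correlation is unaffected by the per-gene affine part; the transform only
tames the heavy tails of CPM before the SVD-based eigengenes). Genes
constant in any series are dropped. The signed similarity (1 + r)/2 maps
r = −1 to 0 and r = 1 to 1; soft power β = 18 (the conventional signed-
network choice when scale-free fit is poor) sharpens it into the adjacency.
Topological overlap smooths adjacency by shared neighborhoods. Per-series
TOMs are calibrated by a single multiplicative factor equating each
series' 0.95-quantile of off-diagonal entries to the cross-series mean of
those quantiles, then combined by elementwise minimum: a pair of genes is
only as co-expressed as its weakest series shows.

Module detection is a deterministic simplification of the hybrid dynamic
tree cut used by the established co-expression toolchain (whose heuristic
has many moving parts): average-linkage clustering of 1 − TOM, cut at a
static height of `cut_quantile × max merge height` (default 0.99). For TOM
dissimilarities the maximum merge height is ≈ 1, so this is an absolute cut
just below 1 — unrelated genes, whose pairwise dissimilarity is ≈ 1, stay
out of every module, while genuine modules merge far below the cut. (A
quantile of the merge-height *distribution* was considered and rejected:
with many unassigned genes more than half the merges sit at ≈ 1, so any
high quantile of the distribution collapses everything into one cluster.)
Clusters smaller than `min_module_size = 30` fall into ME0. Modules whose
eigengenes agree closely in every series — max over series of
(1 − Pearson r) below `merge_cut = 0.25` — are merged iteratively, closest
pair first, until stable. Final labels ME1, ME2, … are ordered by
decreasing size; planted-truth recovery (adjusted Rand index ≥ 0.90 on the
benchmark below) is the contract this simplification must meet.

The **eigengene** is the first right singular vector of the module's
gene-standardized expression block (unit norm per series), sign-oriented to
correlate nonnegatively with the module's mean profile. Timing categories
map each series' eigengene peak time through the phase windows (dawn and
dusk before day/night); a module gets the common label when all series
agree and "variable" otherwise — one defensible formalization of
"qualitatively similar peak times", applied algorithmically rather than by
inspection. A Newick dendrogram of modules (average linkage on 1 − mean
cross-series eigengene correlation) accompanies the categories.

## Overrepresentation

For each taxon, the background is its highly expressed gene clusters with a
COG category (unannotated clusters are excluded from both counts; each
cluster carries a single category). Each (module, category) cell with k ≥ 1
genes is tested with the exact hypergeometric upper tail
P(X ≥ k | N, K, n); Benjamini–Hochberg adjustment is applied within the
taxon's family of tests (a global family is available by flag), and
q < 0.05 marks significance. The family size per taxon is reported in every
row so the correction is auditable. By default ME0 genes remain in the
background; a flag excludes them.

## Synthetic data: what it emulates and what it does not

The generator plants: (i) a 71-taxon × 34-sample coverage table with 12
core / 24 variable / 35 rare taxa whose rows satisfy the census rules *by
construction* (core rows are 1 + log-normal; variable rows keep both middle
order statistics at or above 1-fold with at least one dip below; rare rows
put more than half their samples below 1-fold), plus a between-spring
abundance shift on five variable taxa so the group statistics have signal;
(ii) an ortholog catalog with 1–3 member MAG genes per cluster and one COG
category per cluster; (iii) three diel series shaped like a two-spring
study (two 12-point series at 2 h spacing, one 8-point series at 3 h),
negative-binomial counts (dispersion 0.1, library 2 × 10⁶ — values chosen
as typical for desk-scale RNA series and exposed in the config) around
mean curves μ_g(t) = baseline_g × diel_g(t), column-normalized to the
library size, with diel_g a mean-one von-Mises-shaped curve peaking at the
gene's module phase and flat genes identically 1; counts are split
multinomially across member MAG genes so aggregation has real work to undo.
Planted module phases (12:00, 00:00, 06:00, 18:00 in the default scenario)
sit on both sampling grids and map to the four diel windows.

Default problem sizes (71 taxa × 60 gene clusters, ~700 highly expressed
genes in the network) were chosen so the full pipeline and its tests
complete in seconds while leaving every statistical contrast detectable;
they are two orders of magnitude below a real study's gene count, so
absolute numbers (module counts, enrichment counts) are not comparable to a
full-scale analysis — only the rules, recoveries and calibrations are.

Known limitations the benchmark exposes honestly:

- **Per-gene peak recovery under noise is sampling-limited.** With NB
  dispersion 0.1 and peak/trough amplitude 4, the mean difference between a
  gene's peak timepoint and its neighbors (≈ 9–12%) is far below the NB
  noise floor (CV ≈ √0.1 ≈ 32%), so a single series recovers a gene's peak
  within ±2 h for ≈ 85% of module genes at 2 h sampling — and for far fewer
  on coarser grids, where ±2 h excludes even the adjacent timepoint.
  Module-level (eigengene) timing is much more stable because it averages
  tens of genes.
- **Compositional coupling.** CPM is a closed measure: when a large module
  peaks, every other gene's CPM is depressed. RLE absorbs much but not all
  of this, and the residual can shift an eigengene's apparent peak by one
  sampling step in scenarios where most of a taxon's genes share one phase
  — visible in the default scenario as an occasional "variable" category
  for a planted dawn or dusk module. Real communities, with genes spread
  over many phases, are less lumpy than this worst case.
- The generator does not simulate reads, assembly or binning artifacts,
  rRNA carryover, taxon abundance drift within a series, or multi-category
  genes; passing tests say nothing about those error modes.

## Numerical conventions

Midranks everywhere ranks are used; permutation p-values include the
observed statistic; eigengene sign ties (exactly zero correlation with the
mean profile) keep the SVD's orientation; argmax ties take the earliest
time; all stage seeds derive deterministically from the single run seed via
`SeedSequence`, and reruns with the same inputs and seed produce
byte-identical outputs and manifests.
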