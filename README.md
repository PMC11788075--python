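# dielmat

Analysis pipeline for diel (24 h) gene-expression dynamics in hot-spring
phototrophic microbial mat communities, with a synthetic-data generator that
plants ground truth for every stage.

In circumneutral hot-spring outflow channels, stratified mats dominated by
oxygenic cyanobacteria swing between hyperoxic photosynthesis by day and
anoxic fermentation by night. Multi-year metagenome sampling yields a census
of genus- to species-level taxa (groups of metagenome-assembled genomes,
MAGs, sharing ortholog groups), and diel metatranscriptome time series
(samples every 2–3 h over 24 h) reveal when each taxon's genes peak. This
package implements the statistical core of that analysis for microbial
ecologists who have (or want to simulate) a taxon coverage table, a
pan-genome ortholog catalog, and per-series count matrices:

- **Community census** — core / variable / rare taxon classes from fold
  coverage per 100 M reads (core: ≥ 1-fold in every sample; rare: median
  < 1-fold; variable: in between); Shannon diversity
  H = −Σᵢ pᵢ log₂ pᵢ; Bray–Curtis dissimilarity d(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ);
  ANOSIM (rank-based R with seeded permutation p-values); ANCOM (W statistic
  counting significant one-way ANOVAs on pairwise log-ratios); Kruskal–Wallis.
- **Expression pipeline** — per-MAG-gene counts summed per ortholog cluster
  per taxon; low-count filtering; RLE (median-of-ratios) size factors;
  counts per million against each sample's effective library, exactly
  invariant to rescaling any sample's raw counts; "highly expressed" genes
  (mean CPM > 1) and two tiers of "active taxa" (≥ 1% of a sample's CPM in
  every sample, or in at least one).
- **Diel timing** — per-gene peak time (argmax over the series), day/night
  windows with dawn/dusk overlays from sunrise/sunset, and per-taxon peak
  profiles (majority day/night, ≥ 20% dawn- or dusk-peaking flags).
- **Consensus co-expression network** — signed adjacency
  a₍ᵢⱼ₎ = ((1 + rᵢⱼ)/2)^β with soft power β = 18, topological overlap
  t₍ᵢⱼ₎ = (Σᵤ a₍ᵢᵤ₎a₍ᵤⱼ₎ + a₍ᵢⱼ₎)/(min(kᵢ,kⱼ) + 1 − a₍ᵢⱼ₎), per-series TOMs
  quantile-calibrated and combined by elementwise minimum, average-linkage
  clustering with a static height cut and minimum module size 30, eigengene
  (first principal component) merging at mergeCutHeight 0.25, and per-module
  diel timing categories (morning/day, evening/night, dawn, dusk, variable).
- **Overrepresentation** — exact hypergeometric upper tails for COG
  categories per (taxon, module), Benjamini–Hochberg FDR within each taxon,
  q < 0.05.

The synthetic generator plants all of the above: abundance classes that
trigger the census rules by construction, negative-binomial counts around
von-Mises-shaped diel mean curves exp(κ cos(2π(t−φ)/24)) with κ = ln(A)/2
(peak-to-trough ratio A), module memberships with known phases, MAG
fragmentation undone by the aggregation stage, and COG-category enrichments.

## Worked example

```python
from dielmat.synthetic import default_scenario
from dielmat import census, expression, network

scenario = default_scenario(seed=1)
result = census.census(scenario.coverage, group_by="spring", n_perm=999, seed=1)
print("taxon classes:", result.class_counts())
print(f"ANOSIM R = {result.anosim_r:.3f} (p = {result.anosim_p:.3f})")

exprs = {}
for cs in scenario.countsets:
    agg = expression.aggregate_counts(scenario.mag_counts[cs.series_id], scenario.catalog)
    filtered, _ = expression.filter_low_counts(agg, min_total=10)
    exprs[cs.series_id] = expression.cpm(filtered, expression.rle_size_factors(filtered))

he = expression.highly_expressed(list(exprs.values()), threshold=1.0)
tier1, tier2 = expression.active_taxa(exprs, scenario.catalog)
print(f"highly expressed genes: {len(he)}; active taxa: {len(tier1)} tier-1, {len(tier2)} tier-2")

expr = {sid: m.values.loc[m.values.index.intersection(he)] for sid, m in exprs.items()}
common = None
for x in expr.values():
    common = x.index if common is None else common.intersection(x.index)
expr = {sid: x.loc[common] for sid, x in expr.items()}
modules, _ = network.build_consensus_modules(expr, beta=18)
categories, _ = network.categorize_timing(
    modules, {cs.series_id: cs.design for cs in scenario.countsets})
print("module sizes:", modules.sizes.to_dict())
print("timing categories:", categories)
```

prints

```
taxon classes: {'rare': 35, 'variable': 24, 'core': 12}
ANOSIM R = 0.356 (p = 0.001)
highly expressed genes: 687; active taxa: 8 tier-1, 3 tier-2
module sizes: {'ME0': 393, 'ME1': 77, 'ME2': 77, 'ME3': 76, 'ME4': 62}
timing categories: {'ME1': 'dusk', 'ME2': 'variable', 'ME3': 'evening/night', 'ME4': 'morning/day'}
```

The simulated community of 71 taxa over 34 metagenome samples splits into 12
core, 24 variable and 35 rare taxa exactly as planted; the two springs'
communities differ (ANOSIM R = 0.356 at the smallest achievable p); the 8
planted highly active taxa are recovered as tier 1; and the four planted
co-expression modules reappear (ME1–ME4, ordered by size) with the remaining
flat genes left unassigned in ME0. Three of the four module timing
categories match their planted diel windows here; the dawn module is read as
"variable" because compositional coupling between large day- and
night-peaking modules shifts its apparent peak by one 2 h sampling step in
one series (see `docs/methods.md`).

The same pipeline is available from the shell:

```sh
dielmat simulate --outdir sim --seed 1
dielmat all --config sim/run_config.json --outdir sim/results
```

which writes per-stage TSV/JSON outputs and a `manifest.json` whose checksums
are byte-identical across reruns with the same inputs and seed. Stages can
also be run individually (`dielmat census|normalize|timing|modules|ora`).

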