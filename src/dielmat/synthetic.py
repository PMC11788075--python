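"""Synthetic communities, ortholog catalogs and diel count series with planted truth.

The generator emulates the structure of a multi-year hot-spring mat study:

* a taxon x sample fold-coverage table with planted core / variable / rare
  abundance classes and an optional between-spring composition shift;
* a pan-genome ortholog catalog in which each gene cluster belongs to one
  genus- to species-level taxon and lists its member MAG genes;
* several diel metatranscriptome time series (8-12 points over 24 h) of
  negative-binomial counts around phase-shifted unimodal diel mean curves,
  with co-expression modules planted at known clock phases and counts split
  multinomially across member MAG genes so the aggregation stage has real
  work to do.

All outputs are deterministic functions of the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import DAY_HOURS
from .census import CORE_COVERAGE_CUTOFF, CoverageTable, classify_taxa

# single-letter COG functional categories with desk-realistic frequencies;
# "-" marks unannotated gene clusters (excluded from enrichment tests)
DEFAULT_COG_FREQUENCIES = {
    "C": 0.06, "E": 0.07, "F": 0.03, "G": 0.06, "H": 0.04, "I": 0.03,
    "J": 0.08, "K": 0.07, "L": 0.06, "M": 0.06, "N": 0.02, "O": 0.05,
    "P": 0.05, "Q": 0.03, "R": 0.05, "S": 0.05, "T": 0.05, "U": 0.02,
    "V": 0.02, "-": 0.10,
}

_COG_ANNOTATIONS = {
    "C": "NADH-quinone oxidoreductase subunit",
    "E": "amino acid biosynthesis enzyme",
    "G": "sugar ABC transporter permease",
    "J": "50S ribosomal protein",
    "K": "sigma factor family transcriptional regulator",
    "L": "DNA polymerase subunit",
    "M": "cell wall biosynthesis glycosyltransferase",
    "O": "molecular chaperone DnaK-family",
    "P": "ferric iron ABC transporter",
    "T": "two-component sensor histidine kinase",
}


@dataclass
class CommunitySpec:
    """Parameters of the planted community abundance table."""

    n_taxa: int = 71
    n_samples: int = 34
    class_targets: Mapping[str, int] = field(
        default_factory=lambda: {"core": 12, "variable": 24, "rare": 35}
    )
    group_labels: Sequence[str] | None = None  # per sample; default half MS, half OS
    lognormal_mu: float = 0.7
    lognormal_sigma: float = 0.8
    n_group_effect_taxa: int = 5
    group_effect_fold: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        total = sum(self.class_targets.get(c, 0) for c in ("core", "variable", "rare"))
        if total != self.n_taxa:
            raise ValueError(
                f"class_targets sum to {total}, expected n_taxa={self.n_taxa}"
            )
        if self.group_labels is not None and len(self.group_labels) != self.n_samples:
            raise ValueError("group_labels must have one entry per sample")


@dataclass
class SampleDesign:
    """Clock times and day/night geometry of one diel time series."""

    series_id: str
    sample_times: np.ndarray
    sunrise: float = 6.0
    sunset: float = 20.0
    dawn_halfwidth: float = 1.5
    dusk_halfwidth: float = 1.5

    def __post_init__(self):
        t = np.asarray(self.sample_times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if t.min() < 0 or t.max() >= DAY_HOURS:
            raise ValueError("sample_times must lie in [0, 24)")
        if not self.sunrise < self.sunset:
            raise ValueError("sunrise must precede sunset")
        self.sample_times = t

    @property
    def sample_names(self) -> list[str]:
        return [f"{self.series_id}_T{t:04.1f}" for t in self.sample_times]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_names,
                "series_id": self.series_id,
                "time_h": self.sample_times,
                "sunrise": self.sunrise,
                "sunset": self.sunset,
                "dawn_halfwidth": self.dawn_halfwidth,
                "dusk_halfwidth": self.dusk_halfwidth,
            }
        ).set_index("sample")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, series_id: str | None = None) -> "SampleDesign":
        sid = series_id or str(df["series_id"].iloc[0])
        sub = df[df["series_id"] == sid] if "series_id" in df.columns else df
        return cls(
            series_id=sid,
            sample_times=sub["time_h"].to_numpy(dtype=float),
            sunrise=float(sub["sunrise"].iloc[0]),
            sunset=float(sub["sunset"].iloc[0]),
            dawn_halfwidth=float(sub["dawn_halfwidth"].iloc[0]),
            dusk_halfwidth=float(sub["dusk_halfwidth"].iloc[0]),
        )


@dataclass
class ModulePlan:
    """One planted co-expression module: members, peak phase and amplitude."""

    module_id: str
    phase_hours: float
    amplitude: float
    member_taxa: Mapping[str, int]  # taxon -> number of member genes

    def __post_init__(self):
        if not 0 <= self.phase_hours < DAY_HOURS:
            raise ValueError("phase_hours must lie in [0, 24)")
        if self.amplitude < 1:
            raise ValueError("amplitude (peak/trough fold change) must be >= 1")
        if self.n_genes < 1:
            raise ValueError("module must contain at least one gene")

    @property
    def n_genes(self) -> int:
        return int(sum(self.member_taxa.values()))


@dataclass
class NoiseModel:
    """Count noise: NB dispersion, sequencing depth, fraction of flat genes."""

    dispersion: float = 0.1
    library_size: float = 2e6
    flat_gene_fraction: float | None = None  # None: whatever the plans leave flat

    def __post_init__(self):
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.flat_gene_fraction is not None and not 0 <= self.flat_gene_fraction <= 1:
            raise ValueError("flat_gene_fraction must lie in [0, 1]")


@dataclass
class DielCountSet:
    """Raw ortholog x sample counts for one time series."""

    series_id: str
    counts: pd.DataFrame  # genes x samples, nonnegative integers
    design: SampleDesign

    def __post_init__(self):
        if list(self.counts.columns) != self.design.sample_names:
            raise ValueError("count columns must align with the design's samples")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator."""

    module: pd.Series  # gene -> module id ("" for flat genes)
    phase: pd.Series  # gene -> peak clock hour (NaN for flat genes)
    amplitude: pd.Series  # gene -> peak/trough fold change (1 for flat genes)
    baselines: pd.Series
    expected: dict  # series_id -> genes x samples expected-count DataFrame

    def module_genes(self) -> pd.Index:
        return self.module.index[self.module != ""]


def diel_curve(times, phase_hours: float, amplitude: float) -> np.ndarray:
    """Unimodal periodic mean curve exp(kappa cos(2 pi (t - phase)/24)).

    kappa = ln(amplitude)/2 so the peak/trough ratio equals ``amplitude``;
    the curve is rescaled to mean 1 over the full cycle so the gene baseline
    stays interpretable as its average expression level.
    """
    if amplitude < 1:
        raise ValueError("amplitude must be >= 1")
    t = np.asarray(times, dtype=float)
    kappa = np.log(amplitude) / 2.0
    raw = np.exp(kappa * np.cos(2 * np.pi * (t - phase_hours) / DAY_HOURS))
    grid = np.linspace(0, DAY_HOURS, 512, endpoint=False)
    mean = np.exp(kappa * np.cos(2 * np.pi * (grid - phase_hours) / DAY_HOURS)).mean()
    return raw / mean


def generate_coverage_table(
    spec: CommunitySpec,
) -> tuple[CoverageTable, pd.Series]:
    """Generate a fold-coverage table whose rows trigger the planted classes.

    Planted "core" rows have minimum coverage >= 1 in every sample by
    construction; planted "rare" rows have more than half their samples below
    1-fold so the median is < 1; planted "variable" rows keep the median at or
    above 1 while dipping below 1 in at least one sample. A subset of variable
    taxa carries a multiplicative between-group abundance shift so that the
    group-difference statistics have signal to find.
    """
    rng = np.random.default_rng(spec.seed)
    n, s = spec.n_taxa, spec.n_samples
    taxa = [f"taxon_{i + 1:02d}" for i in range(n)]

    planted = (
        ["core"] * spec.class_targets.get("core", 0)
        + ["variable"] * spec.class_targets.get("variable", 0)
        + ["rare"] * spec.class_targets.get("rare", 0)
    )
    classes = pd.Series(planted, index=taxa, name="class")

    if spec.group_labels is None:
        groups = np.array(["MS"] * (s - s // 2) + ["OS"] * (s // 2))
    else:
        groups = np.asarray(list(spec.group_labels))
    group_names = pd.unique(groups)

    mu, sigma = spec.lognormal_mu, spec.lognormal_sigma
    n_low_max = (s - 1) // 2  # keeps the median at or above the core cutoff
    n_low_min = s // 2 + 1  # forces the median below the core cutoff

    rows = np.empty((n, s))
    for i, cls in enumerate(planted):
        if cls == "core":
            rows[i] = 1.0 + rng.lognormal(mu, sigma, s)
        elif cls == "variable":
            row = 1.0 + rng.lognormal(mu - 1.0, sigma, s)
            n_low = int(rng.integers(1, n_low_max + 1))
            low_pos = rng.choice(s, size=n_low, replace=False)
            row[low_pos] = rng.uniform(0.05, 0.9, n_low)
            rows[i] = row
        else:  # rare
            row = rng.uniform(0.01, 0.9, s)
            n_high = int(rng.integers(0, s - n_low_min + 1))
            if n_high:
                high_pos = rng.choice(s, size=n_high, replace=False)
                row[high_pos] = 1.0 + rng.lognormal(mu - 1.5, sigma, n_high)
            rows[i] = row

    # between-group composition shift on a few variable taxa; only entries
    # already at or above the core cutoff are scaled, so the shift can never
    # flip a planted class (sub-cutoff dips and the median side stay put)
    variable_idx = [i for i, c in enumerate(planted) if c == "variable"]
    n_eff = min(spec.n_group_effect_taxa, len(variable_idx))
    effect_idx = list(rng.choice(variable_idx, size=n_eff, replace=False))
    if n_eff and len(group_names) >= 2:
        boosted = groups == group_names[0]
        for i in effect_idx:
            mask = boosted & (rows[i] >= CORE_COVERAGE_CUTOFF)
            rows[i][mask] *= spec.group_effect_fold

    sample_names = [f"{g}_s{i + 1:02d}" for i, g in enumerate(groups)]
    values = pd.DataFrame(rows, index=taxa, columns=sample_names)

    years = rng.choice([2004, 2005, 2006, 2007, 2009], size=s)
    # most samples from the 60 degC sites, as in a temperature-gradient survey
    temps = np.where(rng.random(s) < 0.65, 60, rng.choice([50, 55, 65], size=s))
    layers = np.where(rng.random(s) < 0.12, "undermat", "top")
    meta = pd.DataFrame(
        {"spring": groups, "year": years, "temperature": temps, "layer": layers},
        index=pd.Index(sample_names, name="sample"),
    )

    cov = CoverageTable(values=values, sample_metadata=meta)
    recovered = classify_taxa(cov)
    if not recovered.equals(classes):  # generator-level self check
        raise AssertionError("planted classes violate the census rules")
    return cov, classes


def generate_catalog(
    taxa: Sequence[str],
    genes_per_taxon: int = 30,
    n_mags_per_taxon: int = 3,
    cog_frequencies: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate an ortholog catalog: gene cluster -> taxon, member MAG genes, COG.

    Each cluster belongs to exactly one taxon and lists at least one member
    MAG gene; one COG category (possibly "-" for unannotated) is drawn per
    cluster from ``cog_frequencies``.
    """
    taxa = list(taxa)
    if not taxa:
        raise ValueError("taxa list must be nonempty")
    if genes_per_taxon < 1:
        raise ValueError("genes_per_taxon must be >= 1")
    freqs = dict(cog_frequencies or DEFAULT_COG_FREQUENCIES)
    cats = list(freqs)
    probs = np.array([freqs[c] for c in cats], dtype=float)
    if not np.isclose(probs.sum(), 1.0, atol=1e-8):
        raise ValueError("cog_frequencies must sum to 1")

    rng = np.random.default_rng(seed)
    records = []
    for taxon in taxa:
        n_member = rng.integers(1, n_mags_per_taxon + 1, size=genes_per_taxon)
        cluster_cats = rng.choice(cats, size=genes_per_taxon, p=probs)
        for g in range(genes_per_taxon):
            mags = rng.choice(n_mags_per_taxon, size=n_member[g], replace=False)
            members = ",".join(
                f"{taxon}_MAG{m + 1}_g{g + 1:04d}" for m in sorted(mags)
            )
            cat = str(cluster_cats[g])
            records.append(
                {
                    "cluster": f"{taxon}_GC{g + 1:04d}",
                    "taxon": taxon,
                    "member_genes": members,
                    "cog_category": cat,
                    "annotation": _COG_ANNOTATIONS.get(cat, "hypothetical protein"),
                }
            )
    return pd.DataFrame.from_records(records).set_index("cluster")


def _assign_modules(
    catalog: pd.DataFrame,
    plans: Sequence[ModulePlan],
    noise: NoiseModel,
    rng: np.random.Generator,
) -> tuple[pd.Series, pd.Series, pd.Series]:
    genes = catalog.index
    module = pd.Series("", index=genes, dtype=object)
    phase = pd.Series(np.nan, index=genes, dtype=float)
    amplitude = pd.Series(1.0, index=genes, dtype=float)

    by_taxon = {t: list(sub.index) for t, sub in catalog.groupby("taxon", sort=False)}
    used: dict[str, int] = {t: 0 for t in by_taxon}
    for plan in plans:
        for taxon, count in plan.member_taxa.items():
            if taxon not in by_taxon:
                raise ValueError(f"module plan references unknown taxon {taxon!r}")
            avail = by_taxon[taxon][used[taxon] :]
            if len(avail) < count:
                raise ValueError(
                    f"taxon {taxon!r} has only {len(avail)} unassigned gene "
                    f"clusters, module {plan.module_id!r} needs {count}"
                )
            chosen = avail[:count]
            used[taxon] += count
            module.loc[chosen] = plan.module_id
            phase.loc[chosen] = plan.phase_hours
            amplitude.loc[chosen] = plan.amplitude

    if noise.flat_gene_fraction is not None:
        target_flat = int(round(noise.flat_gene_fraction * len(genes)))
        planted_genes = module.index[module != ""]
        excess = target_flat - int((module == "").sum())
        if excess > 0:
            demote = rng.choice(planted_genes, size=min(excess, len(planted_genes)), replace=False)
            module.loc[demote] = ""
            phase.loc[demote] = np.nan
            amplitude.loc[demote] = 1.0
    return module, phase, amplitude


def generate_diel_counts(
    catalog: pd.DataFrame,
    designs: Sequence[SampleDesign],
    plans: Sequence[ModulePlan],
    noise: NoiseModel,
    seed: int = 0,
    taxon_activity: Mapping[str, float] | None = None,
    baseline_mean: float = 50.0,
    baseline_sigma: float = 0.8,
) -> tuple[list[DielCountSet], dict[str, pd.DataFrame], PlantedTruth]:
    """Generate NB diel count series (plus per-MAG-gene splits) with truth.

    Per-series expected counts are mu_g(t) = baseline_g * diel_g(t) *
    library/sum, column-normalized so each sample's expected total equals the
    library size. Counts are drawn negative-binomially (dispersion 0 reduces
    to Poisson) per ortholog cluster and then split multinomially across the
    cluster's member MAG genes, emulating multi-mapped reads spread over the
    pan-genome. Module membership and phases are shared across series.
    """
    if not len(designs):
        raise ValueError("designs must be nonempty")
    for plan in plans:
        if plan.amplitude < 1:
            raise ValueError("amplitude must be >= 1")
    rng = np.random.default_rng(seed)
    genes = catalog.index
    module, phase, amplitude = _assign_modules(catalog, plans, noise, rng)

    activity = pd.Series(1.0, index=genes)
    if taxon_activity:
        factors = catalog["taxon"].map(lambda t: taxon_activity.get(t, 1.0))
        activity = factors.astype(float)
    baselines = (
        pd.Series(
            rng.lognormal(np.log(baseline_mean) - baseline_sigma**2 / 2, baseline_sigma, len(genes)),
            index=genes,
        )
        * activity
    )

    countsets: list[DielCountSet] = []
    mag_counts: dict[str, pd.DataFrame] = {}
    expected: dict[str, pd.DataFrame] = {}
    members = catalog["member_genes"].str.split(",")
    for design in designs:
        t = design.sample_times
        curves = np.ones((len(genes), len(t)))
        planted_mask = module.to_numpy() != ""
        for gi in np.flatnonzero(planted_mask):
            curves[gi] = diel_curve(t, float(phase.iloc[gi]), float(amplitude.iloc[gi]))
        mu = baselines.to_numpy()[:, None] * curves
        mu = mu / mu.sum(axis=0, keepdims=True) * noise.library_size
        if noise.dispersion == 0:
            counts = rng.poisson(mu)
        else:
            size = 1.0 / noise.dispersion
            counts = rng.negative_binomial(size, size / (size + mu))
        cdf = pd.DataFrame(counts, index=genes, columns=design.sample_names)
        countsets.append(DielCountSet(design.series_id, cdf, design))
        expected[design.series_id] = pd.DataFrame(
            mu, index=genes, columns=design.sample_names
        )

        # multinomial split of each cluster's counts across its member MAG genes
        rows = []
        index = []
        for gi, gene in enumerate(genes):
            mem = members.iloc[gi]
            k = len(mem)
            if k == 1:
                split = counts[gi][None, :]
            else:
                split = np.stack(
                    [rng.multinomial(c, np.full(k, 1.0 / k)) for c in counts[gi]],
                    axis=1,
                )
            for mi, mg in enumerate(mem):
                rows.append(split[mi])
                index.append(mg)
        mag_counts[design.series_id] = pd.DataFrame(
            np.asarray(rows), index=pd.Index(index, name="mag_gene"),
            columns=design.sample_names,
        )

    truth = PlantedTruth(
        module=module, phase=phase, amplitude=amplitude,
        baselines=baselines, expected=expected,
    )
    return countsets, mag_counts, truth


# ---------------------------------------------------------------------------
# default study scenario


def default_designs() -> list[SampleDesign]:
    """Three diel series shaped like the study's: two 12-point (2 h) and one
    8-point (3 h) series over a 24 h cycle."""
    return [
        SampleDesign("MS2005", np.arange(0, 24, 2.0), sunset=19.0),
        SampleDesign("MS2009", np.arange(0, 24, 2.0), sunset=19.0),
        SampleDesign("OS2009", np.arange(0, 24, 3.0), sunset=19.0),
    ]


@dataclass
class Scenario:
    """A fully planted study: community, catalog, diel series and truths."""

    coverage: CoverageTable
    classes: pd.Series
    catalog: pd.DataFrame
    designs: list[SampleDesign]
    plans: list[ModulePlan]
    noise: NoiseModel
    countsets: list[DielCountSet]
    mag_counts: dict[str, pd.DataFrame]
    truth: PlantedTruth
    active_taxa: list[str]
    tier2_taxa: list[str]
    planted_enrichments: list[tuple[str, str, str]]  # (taxon, module, category)


def default_scenario(seed: int = 0) -> Scenario:
    """Build the default desk-scale study: 71 taxa / 34 metagenome samples,
    8 highly active taxa plus 3 second-tier taxa, 3 diel series, 4 planted
    modules peaking at midday, night, dawn and dusk, and 4 planted
    COG-category enrichments."""
    spec = CommunitySpec(seed=seed)
    coverage, classes = generate_coverage_table(spec)

    core = [t for t in classes.index if classes[t] == "core"]
    variable = [t for t in classes.index if classes[t] == "variable"]
    active = core[:8]
    tier2 = variable[:3]

    catalog = generate_catalog(
        classes.index, genes_per_taxon=60, n_mags_per_taxon=3, seed=seed + 1
    )

    # phases sit on both sampling grids (2 h and 3 h) and map to the four
    # diel windows: midday, night, dawn and dusk; second-tier taxa join
    # existing modules, which also makes their CPM share cross the 1% line
    # only around the module peak
    # a dominant taxon contributes most genes of each module (the study's
    # modules are mostly single-taxon dominated) with smaller contributions
    # from a second active taxon and, for three modules, a second-tier taxon
    plans = [
        ModulePlan("M1", phase_hours=12.0, amplitude=4.0,
                   member_taxa={active[0]: 45, active[1]: 15}),
        ModulePlan("M2", phase_hours=0.0, amplitude=4.0,
                   member_taxa={active[2]: 45, active[3]: 15, tier2[0]: 15}),
        ModulePlan("M3", phase_hours=6.0, amplitude=4.0,
                   member_taxa={active[4]: 45, active[5]: 15, tier2[1]: 15}),
        ModulePlan("M4", phase_hours=18.0, amplitude=4.0,
                   member_taxa={active[6]: 45, active[7]: 15, tier2[2]: 15}),
    ]
    activity = {t: 50.0 for t in active}
    activity.update({t: 4.0 for t in tier2})
    for t in classes.index:
        activity.setdefault(t, 0.005)

    noise = NoiseModel()
    designs = default_designs()
    countsets, mag_counts, truth = generate_diel_counts(
        catalog, designs, plans, noise, seed=seed + 2, taxon_activity=activity
    )

    # plant COG-category enrichments inside specific (taxon, module) cells
    planted_enrichments = []
    rng = np.random.default_rng(seed + 3)
    for taxon, module_id, category in (
        (active[0], "M1", "J"),
        (active[2], "M2", "C"),
        (active[4], "M3", "E"),
        (active[6], "M4", "O"),
    ):
        cell = catalog.index[
            (catalog["taxon"] == taxon) & (truth.module == module_id)
        ]
        chosen = cell[rng.random(len(cell)) < 0.7]
        catalog.loc[chosen, "cog_category"] = category
        catalog.loc[chosen, "annotation"] = _COG_ANNOTATIONS.get(
            category, "hypothetical protein"
        )
        planted_enrichments.append((taxon, module_id, category))

    return Scenario(
        coverage=coverage, classes=classes, catalog=catalog, designs=designs,
        plans=plans, noise=noise, countsets=countsets, mag_counts=mag_counts,
        truth=truth, active_taxa=active, tier2_taxa=tier2,
        planted_enrichments=planted_enrichments,
    )


def write_scenario(scenario: Scenario, outdir) -> dict:
    """Write a scenario to TSV/JSON files and return a run-config dict.

    The returned mapping plugs straight into :class:`dielmat.RunConfig` so a
    simulated study can be analyzed end to end from files.
    """
    from pathlib import Path

    from .io import write_json, write_matrix, write_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    coverage_path = outdir / "coverage.tsv"
    write_matrix(scenario.coverage.values, coverage_path)
    meta_path = outdir / "samples.tsv"
    write_table(scenario.coverage.sample_metadata, meta_path)
    catalog_path = outdir / "catalog.tsv"
    write_table(scenario.catalog, catalog_path)

    counts, designs = {}, {}
    for cs in scenario.countsets:
        sid = cs.series_id
        p = outdir / f"mag_counts_{sid}.tsv"
        write_matrix(scenario.mag_counts[sid], p)
        counts[sid] = str(p)
        p = outdir / f"design_{sid}.tsv"
        write_table(cs.design.to_frame(), p)
        designs[sid] = str(p)

    truth_path = outdir / "truth.json"
    write_json(
        {
            "classes": scenario.classes,
            "module": scenario.truth.module,
            "phase": {
                g: (None if np.isnan(v) else float(v))
                for g, v in scenario.truth.phase.items()
            },
            "active_taxa": scenario.active_taxa,
            "tier2_taxa": scenario.tier2_taxa,
            "planted_enrichments": [list(t) for t in scenario.planted_enrichments],
        },
        truth_path,
    )
    return {
        "coverage": str(coverage_path),
        "sample_metadata": str(meta_path),
        "catalog": str(catalog_path),
        "counts": counts,
        "designs": designs,
    }
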