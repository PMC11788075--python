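"""Stage wiring: census -> normalize -> timing -> modules -> ora.

Each stage reads its inputs from files and writes its outputs to files, so a
stage run standalone from the command line and the same stage run inside
``run_all`` produce identical results. ``run_all`` records a manifest with
the package version, seed, parameters and SHA-256 checksums of all inputs
and outputs; reruns with the same inputs, configuration and seed produce
byte-identical manifests.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from ._utils import stage_seed
from . import census as census_mod
from . import enrichment as enrichment_mod
from . import expression as expression_mod
from . import network as network_mod
from . import timing as timing_mod
from .io import (
    read_matrix,
    read_table,
    sha256_file,
    write_json,
    write_matrix,
    write_table,
)
from .synthetic import SampleDesign


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """All inputs and stage parameters of a full run.

    Defaults follow the study's stated settings: 1-fold coverage per 100 M
    reads for the core cutoff, mean CPM > 1 for highly expressed genes, a 1%
    CPM share for active taxa, soft power 18, minimum module size 30,
    mergeCutHeight 0.25, q < 0.05, 999 permutations.
    """

    coverage: str = ""
    sample_metadata: str = ""
    catalog: str = ""
    counts: dict = field(default_factory=dict)  # series_id -> mag-gene counts TSV
    designs: dict = field(default_factory=dict)  # series_id -> design TSV
    outdir: str = "out"
    seed: int = 0

    group_by: str = "spring"
    sample_filter: dict | None = None
    n_perm: int = 999
    ancom_alpha: float = 0.05

    min_total: int = 10
    cpm_threshold: float = 1.0
    share_threshold: float = 0.01

    beta: float = 18.0
    consensus_quantile: float = 0.95
    min_module_size: int = 30
    cut_quantile: float = 0.99
    merge_cut: float = 0.25

    ora_alpha: float = 0.05
    ora_family: str = "per-taxon"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)


def _load_designs(cfg: RunConfig) -> dict[str, SampleDesign]:
    out = {}
    for sid, path in cfg.designs.items():
        out[sid] = SampleDesign.from_frame(read_table(path).reset_index(), sid)
    return out


def stage_census(cfg: RunConfig, outdir: Path) -> dict[str, str]:
    cov = census_mod.CoverageTable(
        values=read_matrix(cfg.coverage),
        sample_metadata=read_table(cfg.sample_metadata),
    )
    result = census_mod.census(
        cov,
        group_by=cfg.group_by,
        sample_filter=cfg.sample_filter,
        n_perm=cfg.n_perm,
        seed=stage_seed(cfg.seed, "census"),
        ancom_alpha=cfg.ancom_alpha,
    )
    outputs = {}
    classes_path = outdir / "taxon_classes.tsv"
    write_table(result.classes.to_frame(), classes_path)
    outputs["taxon_classes"] = str(classes_path)
    bc_path = outdir / "bray_curtis.tsv"
    write_matrix(result.bray_curtis, bc_path)
    outputs["bray_curtis"] = str(bc_path)
    summary_path = outdir / "census.json"
    write_json(
        {
            "class_counts": result.class_counts(),
            "shannon": result.shannon,
            "anosim": {
                "R": result.anosim_r,
                "p": result.anosim_p,
                "n_perm": result.anosim_n_perm,
            },
            "ancom": {"W": result.ancom_w, "flagged": result.ancom_flagged},
            "kruskal_wallis": {"H": result.kruskal_h, "p": result.kruskal_p},
        },
        summary_path,
    )
    outputs["census_summary"] = str(summary_path)
    return outputs


def stage_normalize(cfg: RunConfig, outdir: Path) -> dict[str, str]:
    catalog = read_table(cfg.catalog)
    outputs = {}
    exprs: dict[str, expression_mod.ExpressionMatrix] = {}
    for sid, counts_path in cfg.counts.items():
        mag_counts = read_matrix(counts_path)
        agg = expression_mod.aggregate_counts(mag_counts, catalog)
        filtered, n_removed = expression_mod.filter_low_counts(agg, cfg.min_total)
        factors = expression_mod.rle_size_factors(filtered)
        expr = expression_mod.cpm(filtered, factors)
        exprs[sid] = expr
        p = outdir / f"ortholog_counts_{sid}.tsv"
        write_matrix(filtered, p)
        outputs[f"ortholog_counts_{sid}"] = str(p)
        p = outdir / f"cpm_{sid}.tsv"
        write_matrix(expr.values, p)
        outputs[f"cpm_{sid}"] = str(p)
        p = outdir / f"size_factors_{sid}.tsv"
        write_table(factors.to_frame(), p)
        outputs[f"size_factors_{sid}"] = str(p)

    he = expression_mod.highly_expressed(
        [exprs[sid] for sid in sorted(exprs)], threshold=cfg.cpm_threshold
    )
    tier1, tier2 = expression_mod.active_taxa(
        {sid: exprs[sid] for sid in sorted(exprs)},
        catalog,
        share_threshold=cfg.share_threshold,
    )
    genes_path = outdir / "gene_sets.json"
    write_json(
        {
            "highly_expressed": sorted(he),
            "n_highly_expressed": len(he),
            "active_taxa_tier1": tier1,
            "active_taxa_tier2": tier2,
        },
        genes_path,
    )
    outputs["gene_sets"] = str(genes_path)
    return outputs


def stage_timing(cfg: RunConfig, outdir: Path, normalize_dir: Path) -> dict[str, str]:
    import json

    catalog = read_table(cfg.catalog)
    designs = _load_designs(cfg)
    gene_sets = json.loads((normalize_dir / "gene_sets.json").read_text())
    he = pd.Index(gene_sets["highly_expressed"])
    outputs = {}
    for sid in sorted(cfg.counts):
        expr = read_matrix(normalize_dir / f"cpm_{sid}.tsv")
        sub = expr.loc[expr.index.intersection(he)]
        design = designs[sid]
        peaks = timing_mod.peak_times(sub, design)
        p = outdir / f"peak_times_{sid}.tsv"
        write_table(peaks, p)
        outputs[f"peak_times_{sid}"] = str(p)
        profiles = timing_mod.taxon_profiles(sub, catalog, design)
        p = outdir / f"peak_profiles_{sid}.json"
        write_json({t: prof.to_dict() for t, prof in profiles.items()}, p)
        outputs[f"peak_profiles_{sid}"] = str(p)
    return outputs


def stage_modules(cfg: RunConfig, outdir: Path, normalize_dir: Path) -> dict[str, str]:
    import json

    catalog = read_table(cfg.catalog)
    designs = _load_designs(cfg)
    gene_sets = json.loads((normalize_dir / "gene_sets.json").read_text())
    he = pd.Index(gene_sets["highly_expressed"])
    expr_per_series = {}
    for sid in sorted(cfg.counts):
        expr = read_matrix(normalize_dir / f"cpm_{sid}.tsv")
        expr_per_series[sid] = expr.loc[expr.index.intersection(he)]
    common = None
    for x in expr_per_series.values():
        common = x.index if common is None else common.intersection(x.index)
    expr_per_series = {sid: x.loc[common] for sid, x in expr_per_series.items()}

    modules, _ = network_mod.build_consensus_modules(
        expr_per_series,
        beta=cfg.beta,
        quantile=cfg.consensus_quantile,
        min_module_size=cfg.min_module_size,
        cut_quantile=cfg.cut_quantile,
        merge_cut=cfg.merge_cut,
    )
    summary, spectrum = network_mod.module_composition(modules, catalog)
    categories, newick = network_mod.categorize_timing(modules, designs)
    modules.timing_category = categories
    modules.composition = summary

    outputs = {}
    p = outdir / "module_assignment.tsv"
    write_table(modules.assignment.rename("module").to_frame(), p)
    outputs["module_assignment"] = str(p)
    for sid, eg in modules.eigengenes.items():
        ep = outdir / f"eigengenes_{sid}.tsv"
        write_matrix(eg, ep)
        outputs[f"eigengenes_{sid}"] = str(ep)
    p = outdir / "module_summary.json"
    write_json(
        {
            "sizes": modules.sizes,
            "timing_category": categories,
            "dominant_taxon": summary["dominant_taxon"] if len(summary) else {},
            "dominant_fraction": summary["dominant_fraction"] if len(summary) else {},
        },
        p,
    )
    outputs["module_summary"] = str(p)
    p = outdir / "module_spectrum.tsv"
    write_matrix(spectrum, p)
    outputs["module_spectrum"] = str(p)
    p = outdir / "eigengene_dendrogram.nwk"
    p.write_text(newick + "\n", encoding="utf-8")
    outputs["eigengene_dendrogram"] = str(p)
    return outputs


def stage_ora(cfg: RunConfig, outdir: Path, modules_dir: Path) -> dict[str, str]:
    catalog = read_table(cfg.catalog)
    assignment = read_table(modules_dir / "module_assignment.tsv")["module"]
    table = enrichment_mod.ora(
        assignment, catalog, alpha=cfg.ora_alpha, family=cfg.ora_family
    )
    p = outdir / "enrichment.tsv"
    write_table(table, p, index=False)
    return {"enrichment": str(p)}


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage in order and write a reproducibility manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {"coverage": cfg.coverage, "sample_metadata": cfg.sample_metadata,
              "catalog": cfg.catalog}
    inputs.update({f"counts_{sid}": p for sid, p in cfg.counts.items()})
    inputs.update({f"design_{sid}": p for sid, p in cfg.designs.items()})

    stage_outputs: dict[str, dict[str, str]] = {}
    plan = [
        ("census", lambda d: stage_census(cfg, d)),
        ("normalize", lambda d: stage_normalize(cfg, d)),
        ("timing", lambda d: stage_timing(cfg, d, outdir / "normalize")),
        ("modules", lambda d: stage_modules(cfg, d, outdir / "normalize")),
        ("ora", lambda d: stage_ora(cfg, d, outdir / "modules")),
    ]
    for name, fn in plan:
        stage_dir = outdir / name
        stage_dir.mkdir(parents=True, exist_ok=True)
        try:
            stage_outputs[name] = fn(stage_dir)
        except Exception as exc:  # abort naming the failing stage
            raise StageError(name, exc) from exc

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: v
            for k, v in asdict(cfg).items()
            if k not in ("coverage", "sample_metadata", "catalog", "counts",
                          "designs", "outdir")
        },
        "input_checksums": {k: sha256_file(v) for k, v in inputs.items() if v},
        "stages": {
            name: {key: sha256_file(path) for key, path in outs.items()}
            for name, outs in stage_outputs.items()
        },
        # stored relative to the output directory so that reruns in different
        # locations yield byte-identical manifests
        "stage_outputs": {
            name: {
                key: str(Path(path).relative_to(outdir))
                for key, path in outs.items()
            }
            for name, outs in stage_outputs.items()
        },
    }
    write_json(manifest, outdir / "manifest.json")
    return manifest
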