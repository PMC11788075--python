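"""Signed consensus co-expression networks, module detection and eigengenes.

The construction follows the weighted co-expression network recipe: a signed
Pearson similarity raised to a soft-thresholding power beta gives the
adjacency a_ij = ((1 + r_ij)/2)^beta; the topological overlap matrix (TOM)
smooths adjacency by shared neighborhoods; per-series TOMs are quantile-
calibrated onto a common scale and combined by elementwise minimum into a
consensus network (a gene pair is only as connected as its weakest series).
Modules come from average-linkage hierarchical clustering of the consensus
TOM dissimilarity with a static height cut and a minimum size, followed by
iterative merging of modules whose eigengenes (first principal components)
are correlated above 1 - mergeCutHeight in every series. Final labels ME1,
ME2, ... are ordered by decreasing size; ME0 collects unassigned genes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from ._utils import linkage_to_newick
from .synthetic import SampleDesign
from .timing import PhaseWindows, zscale_log2_frame

UNASSIGNED = "ME0"


@dataclass
class ModuleSet:
    """Gene -> module assignment with per-series eigengenes and summaries."""

    assignment: pd.Series  # gene -> "ME1".. / "ME0"
    eigengenes: dict[str, pd.DataFrame]  # series -> module x sample (unit norm)
    sizes: pd.Series = field(default_factory=pd.Series)
    timing_category: dict[str, str] = field(default_factory=dict)
    composition: pd.DataFrame = field(default_factory=pd.DataFrame)

    def modules(self) -> list[str]:
        return [m for m in self.sizes.index if m != UNASSIGNED]


def signed_adjacency(expr: pd.DataFrame, beta: float = 18.0) -> pd.DataFrame:
    """Signed adjacency ((1 + r)/2)^beta from gene-wise Pearson correlation.

    Genes that are constant across samples have no defined correlation and
    must be removed beforehand; they are reported by name.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    arr = expr.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if (sd == 0).any():
        bad = expr.index[sd == 0].tolist()
        raise ValueError(
            f"constant gene(s) present: {', '.join(map(str, bad[:5]))}"
            + ("..." if len(bad) > 5 else "")
        )
    r = np.corrcoef(arr)
    a = np.clip((1.0 + r) / 2.0, 0.0, 1.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def tom(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: t_ij = (sum_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1-a_ij).

    The sum excludes u in {i, j}; k_i is the connectivity sum_{u != i} a_iu;
    the diagonal is 1.
    """
    a = adjacency.to_numpy(dtype=float)
    n = a.shape[0]
    k = a.sum(axis=1) - np.diag(a)
    prod = a @ a
    # remove u = i and u = j terms (diagonal of a is 1)
    shared = prod - a * np.diag(a)[:, None] - a * np.diag(a)[None, :]
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (shared + a) / denom
    np.fill_diagonal(t, 1.0)
    t = np.clip(t, 0.0, 1.0)
    return pd.DataFrame(t, index=adjacency.index, columns=adjacency.columns)


def calibrate_and_consensus(
    toms: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
    quantile: float = 0.95,
) -> pd.DataFrame:
    """Quantile-calibrate per-series TOMs and take their elementwise minimum.

    Each TOM is scaled multiplicatively so that the ``quantile``-th quantile
    of its off-diagonal entries equals the mean of those quantiles across
    series; the consensus entry is then the minimum across series, clipped to
    [0, 1]. Identical inputs are a fixed point.
    """
    mats = list(toms.values()) if isinstance(toms, Mapping) else list(toms)
    if len(mats) < 2:
        raise ValueError("consensus needs at least two series")
    index = mats[0].index
    for m in mats[1:]:
        if not m.index.equals(index):
            raise ValueError("gene sets must be identical across series")
    n = len(index)
    iu = np.triu_indices(n, k=1)
    qs = [float(np.quantile(m.to_numpy()[iu], quantile)) for m in mats]
    target = float(np.mean(qs))
    scaled = []
    for m, q in zip(mats, qs):
        if q <= 0:
            raise ValueError("degenerate TOM: calibration quantile is zero")
        scaled.append(m.to_numpy() * (target / q))
    cons = np.clip(np.minimum.reduce(scaled), 0.0, 1.0)
    np.fill_diagonal(cons, 1.0)
    return pd.DataFrame(cons, index=index, columns=index)


def eigengene(expr_block: pd.DataFrame) -> tuple[np.ndarray, float]:
    """First principal component of a standardized gene x sample block.

    Returns the unit-norm sample-space eigengene, sign-oriented to correlate
    nonnegatively with the module's mean standardized profile, and the
    fraction of variance it explains.
    """
    if expr_block.shape[0] < 1:
        raise ValueError("module must be nonempty")
    if expr_block.shape[1] < 2:
        raise ValueError("need at least two samples per series")
    x = expr_block.to_numpy(dtype=float)
    sd = x.std(axis=1, keepdims=True)
    x = np.divide(
        x - x.mean(axis=1, keepdims=True), sd, out=np.zeros_like(x), where=sd > 0
    )
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    e = vt[0]
    mean_profile = x.mean(axis=0)
    if float(e @ mean_profile) < 0:
        e = -e
    var_explained = float(s[0] ** 2 / (s**2).sum()) if s.sum() > 0 else 0.0
    return e, var_explained


def _module_eigengenes(
    genes_by_module: Mapping[str, Sequence],
    expr_per_series: Mapping[str, pd.DataFrame],
) -> dict[str, pd.DataFrame]:
    out = {}
    for sid, expr in expr_per_series.items():
        rows = {}
        for mod, genes in genes_by_module.items():
            rows[mod], _ = eigengene(expr.loc[list(genes)])
        out[sid] = pd.DataFrame(rows, index=expr.columns).T
    return out


def _eigengene_dissimilarity(
    eg_per_series: Mapping[str, pd.DataFrame], aggregate: str = "max"
) -> pd.DataFrame:
    """Module x module dissimilarity from eigengene correlations.

    ``max``: consensus dissimilarity max_series (1 - r); ``mean``:
    1 - mean_series r (used for the summary dendrogram).
    """
    mats = []
    for eg in eg_per_series.values():
        r = np.corrcoef(eg.to_numpy())
        r = np.atleast_2d(r)
        mats.append(1.0 - r if aggregate == "max" else r)
    idx = next(iter(eg_per_series.values())).index
    if aggregate == "max":
        d = np.maximum.reduce(mats)
    else:
        d = 1.0 - np.mean(mats, axis=0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=idx, columns=idx)


def detect_modules(
    consensus_tom: pd.DataFrame,
    expr_per_series: Mapping[str, pd.DataFrame],
    min_module_size: int = 30,
    cut_quantile: float = 0.99,
    merge_cut: float = 0.25,
) -> ModuleSet:
    """Cut the consensus TOM dendrogram into modules and merge similar ones.

    Average-linkage hierarchical clustering on 1 - TOM is cut at
    ``cut_quantile`` x (maximum merge height) — an absolute static cut near 1
    for TOM dissimilarities, so unrelated genes (pairwise dissimilarity ~1)
    stay out of every module. Clusters smaller than ``min_module_size`` fall
    into ME0. Modules whose eigengenes disagree by less than ``merge_cut``
    (max over series of 1 - Pearson r) are merged iteratively until stable.
    """
    genes = consensus_tom.index
    n = len(genes)
    if n < min_module_size:
        return ModuleSet(
            assignment=pd.Series(UNASSIGNED, index=genes),
            eigengenes={},
            sizes=pd.Series({UNASSIGNED: n}),
        )
    dissim = 1.0 - consensus_tom.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    z = sch.linkage(squareform(dissim, checks=False), method="average")
    cut_height = cut_quantile * float(z[:, 2].max())
    flat = sch.fcluster(z, t=cut_height, criterion="distance")

    clusters: dict[str, list] = {}
    for cl in np.unique(flat):
        members = list(genes[flat == cl])
        if len(members) >= min_module_size:
            clusters[f"raw{cl}"] = members

    if not clusters:
        return ModuleSet(
            assignment=pd.Series(UNASSIGNED, index=genes),
            eigengenes={},
            sizes=pd.Series({UNASSIGNED: n}),
        )

    # iterative eigengene-based merging: closest pair below merge_cut first
    while len(clusters) > 1:
        eg = _module_eigengenes(clusters, expr_per_series)
        d = _eigengene_dissimilarity(eg, aggregate="max")
        arr = d.to_numpy().copy()
        np.fill_diagonal(arr, np.inf)
        i, j = np.unravel_index(np.argmin(arr), arr.shape)
        if arr[i, j] >= merge_cut:
            break
        a, b = d.index[i], d.index[j]
        clusters[a] = clusters[a] + clusters.pop(b)

    ordered = sorted(
        clusters.items(), key=lambda kv: (-len(kv[1]), kv[0])
    )
    assignment = pd.Series(UNASSIGNED, index=genes, dtype=object)
    final: dict[str, list] = {}
    for rank, (_, members) in enumerate(ordered, start=1):
        label = f"ME{rank}"
        final[label] = members
        assignment.loc[members] = label

    eigengenes = _module_eigengenes(final, expr_per_series)
    sizes = assignment.value_counts()
    return ModuleSet(assignment=assignment, eigengenes=eigengenes, sizes=sizes)


def module_composition(
    modules: ModuleSet, catalog: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Taxon make-up of each module and module spectrum of each taxon.

    Returns (per-module summary with the dominant taxon and its fraction of
    the module, per-taxon fraction of its genes landing in each module).
    """
    taxa = catalog.loc[modules.assignment.index, "taxon"]
    tab = pd.crosstab(modules.assignment, taxa)
    dominant = tab.idxmax(axis=1)
    fraction = tab.max(axis=1) / tab.sum(axis=1)
    summary = pd.DataFrame(
        {
            "size": tab.sum(axis=1),
            "dominant_taxon": dominant,
            "dominant_fraction": fraction,
            "n_taxa": (tab > 0).sum(axis=1),
        }
    )
    spectrum = (tab / tab.sum(axis=0)).T  # taxon x module, rows sum to 1
    return summary, spectrum


def categorize_timing(
    modules: ModuleSet,
    designs: Mapping[str, SampleDesign],
    windows: Mapping[str, PhaseWindows] | None = None,
) -> tuple[dict[str, str], str]:
    """Assign each module a diel timing category from its eigengene peaks.

    Per series, the eigengene's peak sample time maps to dawn / dusk /
    morning-day / evening-night; the module's category is the common label
    when all series agree and "variable" otherwise. Also returns a Newick
    dendrogram of modules clustered by 1 - mean-across-series eigengene
    correlation (average linkage).
    """
    if not modules.eigengenes:
        return {}, ";"
    win = windows or {
        sid: PhaseWindows.from_design(d) for sid, d in designs.items()
    }
    labels_per_series: dict[str, dict[str, str]] = {}
    for sid, eg in modules.eigengenes.items():
        design = designs[sid]
        t = design.sample_times
        w = win[sid]
        labels = {}
        for mod in eg.index:
            peak_t = float(t[int(np.argmax(eg.loc[mod].to_numpy()))])
            labels[mod] = str(w.classify([peak_t])[0])
        labels_per_series[sid] = labels

    categories = {}
    mods = next(iter(modules.eigengenes.values())).index
    for mod in mods:
        seen = {labels_per_series[sid][mod] for sid in labels_per_series}
        categories[str(mod)] = seen.pop() if len(seen) == 1 else "variable"

    if len(mods) > 1:
        d = _eigengene_dissimilarity(modules.eigengenes, aggregate="mean")
        z = sch.linkage(squareform(d.to_numpy(), checks=False), method="average")
        newick = linkage_to_newick(z, list(d.index))
    else:
        newick = f"{mods[0]};" if len(mods) else ";"
    return categories, newick


def build_consensus_modules(
    expr_per_series: Mapping[str, pd.DataFrame],
    beta: float = 18.0,
    quantile: float = 0.95,
    min_module_size: int = 30,
    cut_quantile: float = 0.99,
    merge_cut: float = 0.25,
    log_transform: bool = True,
) -> tuple[ModuleSet, pd.DataFrame]:
    """End-to-end consensus network: expression -> modules.

    Genes constant in any series are dropped (no defined correlation there);
    expression is log2(x+1) z-scaled per gene within each series before
    correlation. Returns the ModuleSet and the consensus TOM.
    """
    prepared: dict[str, pd.DataFrame] = {}
    keep = None
    for sid, expr in expr_per_series.items():
        x = zscale_log2_frame(expr) if log_transform else expr
        nonconst = x.index[x.std(axis=1) > 0]
        keep = nonconst if keep is None else keep.intersection(nonconst)
        prepared[sid] = x
    prepared = {sid: x.loc[keep] for sid, x in prepared.items()}

    toms = {
        sid: tom(signed_adjacency(x, beta=beta)) for sid, x in prepared.items()
    }
    cons = calibrate_and_consensus(toms, quantile=quantile)
    modules = detect_modules(
        cons,
        prepared,
        min_module_size=min_module_size,
        cut_quantile=cut_quantile,
        merge_cut=merge_cut,
    )
    return modules, cons
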