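"""Ortholog-level count aggregation, RLE normalization, CPM, expression filters.

Per-MAG-gene counts are summed into one row per ortholog cluster per taxon,
low-total clusters are dropped, relative-log-expression (median-of-ratios)
size factors absorb compositional library differences, and counts-per-million
are computed against each sample's effective library. Gene- and taxon-level
activity filters (mean CPM > 1; >= 1% of a sample's CPM) reproduce the
"highly expressed gene" and "active taxa" definitions used downstream.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import geometric_mean

MILLION = 1e6


@dataclass
class ExpressionMatrix:
    """CPM matrix with the size factors that produced it.

    ``size_factors`` are median-of-ratios size factors rescaled to geometric
    mean 1; CPMs divide each count by the sample's effective library
    (library x norm factor), which makes every sample's CPM vector exactly
    invariant to rescaling that sample's raw counts.
    """

    values: pd.DataFrame  # genes x samples, CPM
    size_factors: pd.Series

    def __post_init__(self):
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")


def _member_to_cluster(catalog: pd.DataFrame) -> pd.Series:
    mapping = {}
    for cluster, members in catalog["member_genes"].items():
        for m in members.split(","):
            mapping[m] = cluster
    return pd.Series(mapping, name="cluster")


def aggregate_counts(
    per_mag_gene_counts: pd.DataFrame, catalog: pd.DataFrame
) -> pd.DataFrame:
    """Sum per-MAG-gene counts into one row per ortholog cluster.

    Every MAG gene id in the counts must appear in the catalog; total counts
    are conserved exactly. Clusters absent from the counts get zero rows so
    the output covers the whole catalog.
    """
    mapping = _member_to_cluster(catalog)
    missing = per_mag_gene_counts.index.difference(mapping.index)
    if len(missing):
        raise KeyError(
            f"MAG gene id(s) not in catalog: {', '.join(map(str, missing[:5]))}"
            + ("..." if len(missing) > 5 else "")
        )
    clusters = mapping.loc[per_mag_gene_counts.index]
    agg = per_mag_gene_counts.groupby(clusters.to_numpy()).sum()
    agg = agg.reindex(catalog.index, fill_value=0)
    agg.index.name = "cluster"
    return agg


def filter_low_counts(
    counts: pd.DataFrame, min_total: int = 10
) -> tuple[pd.DataFrame, int]:
    """Keep genes whose summed counts across samples reach ``min_total``.

    Returns the filtered matrix and the number of removed genes. Idempotent.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = counts.sum(axis=1) >= min_total
    return counts.loc[keep], int((~keep).sum())


def rle_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios (RLE) size factors, rescaled to geometric mean 1.

    The reference profile is the per-gene geometric mean across samples,
    restricted to genes with no zero count anywhere; each sample's factor is
    the median of its counts over the reference.
    """
    arr = counts.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in every sample; apply a stronger "
            "low-count filter before RLE normalization"
        )
    ref = np.exp(np.mean(np.log(arr[allpos]), axis=1))
    ratios = arr[allpos] / ref[:, None]
    factors = np.median(ratios, axis=0)
    factors = factors / geometric_mean(factors)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def cpm(counts: pd.DataFrame, size_factors: pd.Series) -> ExpressionMatrix:
    """Counts per million over each sample's effective library.

    The size factors (geometric mean 1) are converted to per-sample norm
    factors relative to library size, and CPM_gs = count_gs / (library_s x
    norm_factor_s) x 1e6. With RLE size factors this composition is exactly
    1-homogeneous in each sample's counts, so multiplying one sample's raw
    counts by any c > 0 leaves that sample's CPM vector unchanged.
    """
    sf = size_factors.reindex(counts.columns)
    if sf.isna().any() or (sf <= 0).any():
        raise ValueError("size factors must be positive and cover all samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size in sample(s): {bad}")
    norm = sf / lib
    norm = norm / geometric_mean(norm)
    effective = lib * norm
    values = counts.div(effective, axis=1) * MILLION
    return ExpressionMatrix(values=values, size_factors=sf)


def highly_expressed(
    expr: ExpressionMatrix | Sequence[ExpressionMatrix], threshold: float = 1.0
) -> pd.Index:
    """Genes with mean CPM strictly above ``threshold``.

    The mean is taken across the union of samples from all provided series
    (one network is built on genes filtered once across all series).
    """
    mats = [expr] if isinstance(expr, ExpressionMatrix) else list(expr)
    combined = pd.concat([m.values for m in mats], axis=1)
    means = combined.mean(axis=1)
    return combined.index[means > threshold]


def taxon_shares(expr: ExpressionMatrix, catalog: pd.DataFrame) -> pd.DataFrame:
    """Per-sample fraction of total CPM contributed by each taxon.

    The denominator is the sample's total CPM over all retained genes, so
    shares sum to 1 when every gene is assigned to a taxon and to less
    otherwise.
    """
    taxa = catalog.loc[catalog.index.intersection(expr.values.index), "taxon"]
    sub = expr.values.loc[taxa.index]
    shares = sub.groupby(taxa.to_numpy()).sum() / expr.values.sum(axis=0)
    shares.index.name = "taxon"
    return shares


def active_taxa(
    expr_per_series: Mapping[str, ExpressionMatrix] | Sequence[ExpressionMatrix],
    catalog: pd.DataFrame,
    share_threshold: float = 0.01,
) -> tuple[list[str], list[str]]:
    """Two activity tiers from per-sample taxon CPM shares.

    Tier 1: taxa at or above ``share_threshold`` of total CPM in every sample
    of every series; tier 2: taxa reaching it in at least one sample but not
    tier 1.
    """
    mats = (
        list(expr_per_series.values())
        if isinstance(expr_per_series, Mapping)
        else list(expr_per_series)
    )
    shares = pd.concat([taxon_shares(m, catalog) for m in mats], axis=1).fillna(0.0)
    always = shares.min(axis=1) >= share_threshold
    ever = shares.max(axis=1) >= share_threshold
    tier1 = shares.index[always].tolist()
    tier2 = shares.index[ever & ~always].tolist()
    return tier1, tier2
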