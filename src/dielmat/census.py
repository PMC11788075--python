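"""Community census: abundance classification and diversity / difference statistics.

Works on a taxon x sample fold-coverage table (fold coverage per 100 million
reads). Taxa are partitioned into *core* (at least 1-fold coverage in every
sample), *rare* (median coverage below 1-fold) and *variable* (everything in
between); per-sample Shannon diversity, Bray-Curtis dissimilarities, ANOSIM,
ANCOM and Kruskal-Wallis tests quantify differences between sample groups
(e.g. the two springs).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.spatial.distance import pdist, squareform

CORE_COVERAGE_CUTOFF = 1.0  # fold coverage per 100 M reads


@dataclass
class CoverageTable:
    """Taxon x sample fold-coverage matrix plus per-sample metadata.

    ``values`` has taxa as rows and samples as columns; entries are fold
    coverage per 100 million reads. ``sample_metadata`` is indexed by sample
    label and typically carries spring, year, temperature and layer columns.
    """

    values: pd.DataFrame
    sample_metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        v = self.values
        if v.index.has_duplicates or v.columns.has_duplicates:
            raise ValueError("taxon and sample labels must be unique")
        if (v.to_numpy() < 0).any():
            raise ValueError("coverage values must be nonnegative")
        if len(self.sample_metadata) and not self.sample_metadata.index.equals(
            v.columns
        ):
            self.sample_metadata = self.sample_metadata.reindex(v.columns)

    @property
    def taxa(self):
        return list(self.values.index)

    @property
    def samples(self):
        return list(self.values.columns)


@dataclass
class CensusResult:
    classes: pd.Series
    shannon: pd.Series
    bray_curtis: pd.DataFrame
    anosim_r: float
    anosim_p: float
    anosim_n_perm: int
    ancom_w: pd.Series
    ancom_flagged: list
    kruskal_h: float
    kruskal_p: float

    def class_counts(self) -> dict:
        return self.classes.value_counts().to_dict()


def fold_coverage(mapped_bases: float, mag_length: float, library_reads: float) -> float:
    """Fold coverage per 100 million reads.

    (mapped bases / MAG length) scaled to a 100 M read library; linear in
    sequencing depth so tables from libraries of different sizes are
    comparable.
    """
    if mag_length <= 0:
        raise ValueError("mag_length must be positive")
    if library_reads <= 0:
        raise ValueError("library_reads must be positive")
    return (mapped_bases / mag_length) * (1e8 / library_reads)


def classify_taxa(cov: CoverageTable | pd.DataFrame) -> pd.Series:
    """Partition taxa into core / variable / rare abundance classes.

    core: >= 1-fold coverage per 100 M reads in every sample;
    rare: median coverage < 1 (and not core);
    variable: everything else. The classes are exhaustive and disjoint.
    """
    values = cov.values if isinstance(cov, CoverageTable) else cov
    if values.shape[1] < 1 or values.shape[0] < 1:
        raise ValueError("coverage table must have at least one taxon and sample")
    arr = values.to_numpy(dtype=float)
    mins = arr.min(axis=1)
    medians = np.median(arr, axis=1)
    out = np.where(
        mins >= CORE_COVERAGE_CUTOFF,
        "core",
        np.where(medians < CORE_COVERAGE_CUTOFF, "rare", "variable"),
    )
    return pd.Series(out, index=values.index, name="class")


def relative_abundance(values: pd.DataFrame) -> pd.DataFrame:
    """Column-normalize coverage to per-sample relative abundance."""
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero total coverage: {bad}")
    return values / totals


def shannon(abundances, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log_base p_i (renormalized internally)."""
    p = np.asarray(abundances, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise ValueError("abundances must not all be zero")
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(base))


def shannon_per_sample(values: pd.DataFrame, base: float = 2.0) -> pd.Series:
    return pd.Series(
        {s: shannon(values[s].to_numpy(), base=base) for s in values.columns},
        name="shannon",
    )


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("inputs must be nonnegative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    from scipy.spatial.distance import braycurtis

    return float(braycurtis(x, y))


def bray_curtis_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between sample columns."""
    mat = squareform(pdist(values.to_numpy(dtype=float).T, metric="braycurtis"))
    return pd.DataFrame(mat, index=values.columns, columns=values.columns)


def anosim(
    dist,
    groups: Sequence,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4), with
    midranks for ties; the p-value counts permuted statistics >= observed,
    using the (t+1)/(B+1) convention that includes the observed labelling.
    """
    d = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, dtype=float)
    labels = np.asarray(list(groups))
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    if len(labels) != n:
        raise ValueError("group labels must match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValueError(f"each group needs >= 2 members; singleton group(s): {small}")

    iu, ju = np.triu_indices(n, k=1)
    ranks = st.rankdata(d[iu, ju])  # midranks
    denom = n * (n - 1) / 4.0

    def statistic(lab: np.ndarray) -> float:
        within = lab[iu] == lab[ju]
        return float((ranks[~within].mean() - ranks[within].mean()) / denom)

    r_obs = statistic(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if statistic(rng.permutation(labels)) >= r_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return r_obs, p


def ancom(
    counts: pd.DataFrame,
    groups: Sequence,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    w_cutoff: float = 0.7,
) -> tuple[pd.Series, list]:
    """Analysis of composition of microbiomes.

    For each taxon i, W_i counts the taxa j for which a one-way ANOVA on
    log((x_i + pseudocount)/(x_j + pseudocount)) across groups is significant
    at ``alpha``. Taxa with W_i >= w_cutoff * (m - 1) are flagged as
    differentially abundant. Log-ratios make the statistic invariant to
    per-sample scaling of the counts.
    """
    m = counts.shape[0]
    if m < 2:
        raise ValueError("ANCOM needs at least two taxa")
    labels = np.asarray(list(groups))
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    logx = np.log(counts.to_numpy(dtype=float) + pseudocount)
    group_cols = [np.flatnonzero(labels == g) for g in uniq]
    w = np.zeros(m, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(m):
            ratios = logx[i][None, :] - logx  # (m, n_samples)
            _, pvals = st.f_oneway(*[ratios[:, c] for c in group_cols], axis=1)
            pvals = np.asarray(pvals, dtype=float)
            pvals[i] = np.nan  # self-ratio is identically zero
            w[i] = int(np.nansum(pvals < alpha))
    w_series = pd.Series(w, index=counts.index, name="W")
    flagged = w_series.index[w_series >= w_cutoff * (m - 1)].tolist()
    return w_series, flagged


def kruskal_wallis(values: Sequence, groups: Sequence) -> tuple[float, float]:
    """Kruskal-Wallis H test (midrank tie correction, chi-square p-value)."""
    values = np.asarray(list(values), dtype=float)
    labels = np.asarray(list(groups))
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    samples = [values[labels == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be nonempty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = st.kruskal(*samples)
    return float(h), float(p)


def census(
    cov: CoverageTable,
    group_by: str = "spring",
    sample_filter: dict | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    ancom_alpha: float = 0.05,
    shannon_base: float = 2.0,
) -> CensusResult:
    """Run the full metagenome census on a coverage table.

    Classification uses all samples; the group statistics (ANOSIM, ANCOM,
    Kruskal-Wallis on Shannon H) are computed on the subset selected by
    ``sample_filter`` (metadata column -> required value), grouped by the
    ``group_by`` metadata column.
    """
    classes = classify_taxa(cov)
    rel = relative_abundance(cov.values)
    h = shannon_per_sample(rel, base=shannon_base)

    meta = cov.sample_metadata
    if group_by not in meta.columns:
        raise ValueError(f"metadata has no column {group_by!r}")
    keep = pd.Series(True, index=meta.index)
    if sample_filter:
        for col, val in sample_filter.items():
            keep &= meta[col] == val
    sub = rel.loc[:, keep[keep].index]
    groups = meta.loc[keep[keep].index, group_by]

    bc = bray_curtis_matrix(sub)
    r, p = anosim(bc, groups, n_perm=n_perm, seed=seed)
    w, flagged = ancom(cov.values.loc[:, sub.columns], groups, alpha=ancom_alpha)
    kh, kp = kruskal_wallis(h.loc[sub.columns], groups)
    return CensusResult(
        classes=classes,
        shannon=h,
        bray_curtis=bc,
        anosim_r=r,
        anosim_p=p,
        anosim_n_perm=n_perm,
        ancom_w=w,
        ancom_flagged=flagged,
        kruskal_h=kh,
        kruskal_p=kp,
    )
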