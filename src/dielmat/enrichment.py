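"""Per-taxon, per-module overrepresentation of COG functional categories.

For each taxon, the background is its highly expressed gene clusters that
carry a COG category; for every (module, category) cell with at least one
gene, an exact hypergeometric upper tail asks whether the category is
overrepresented among the taxon's genes in that module, and Benjamini-
Hochberg FDR control is applied within the taxon's family of tests
(q < 0.05 marks significance).
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .network import UNASSIGNED, ModuleSet

NO_CATEGORY = "-"


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K successes, n draws). Exact."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    if not 0 <= k <= min(n, K):
        raise ValueError("need 0 <= k <= min(n, K)")
    return float(st.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(
    modules: ModuleSet | pd.Series,
    catalog: pd.DataFrame,
    background: Mapping[str, Sequence] | None = None,
    alpha: float = 0.05,
    family: str = "per-taxon",
    exclude_unassigned_background: bool = False,
) -> pd.DataFrame:
    """Overrepresentation of COG categories per (taxon, module).

    ``modules`` is a ModuleSet or a gene -> module Series over the highly
    expressed genes. The default background for a taxon is all of its genes
    in the assignment that carry a COG category (optionally excluding ME0);
    an explicit ``background`` mapping taxon -> gene ids overrides it.
    ``family`` controls the BH correction family: "per-taxon" (default) or
    "global". Rows with k = 0 are not tested. Taxa with empty backgrounds
    are skipped.
    """
    assignment = modules.assignment if isinstance(modules, ModuleSet) else modules
    if family not in ("per-taxon", "global"):
        raise ValueError("family must be 'per-taxon' or 'global'")

    info = catalog.loc[assignment.index, ["taxon", "cog_category"]].copy()
    info["module"] = assignment
    info = info[info["cog_category"] != NO_CATEGORY]

    rows = []
    for taxon, sub in info.groupby("taxon", sort=True):
        if background is not None:
            bg_genes = pd.Index(background.get(taxon, []))
            bg = info.loc[info.index.intersection(bg_genes)]
            bg = bg[bg["taxon"] == taxon]
        else:
            bg = sub
        if exclude_unassigned_background:
            bg = bg[bg["module"] != UNASSIGNED]
        N = len(bg)
        if N == 0:
            continue
        cat_totals = bg["cog_category"].value_counts()
        for module, msub in bg.groupby("module", sort=True):
            n = len(msub)
            counts = msub["cog_category"].value_counts()
            for category, k in counts.items():
                K = int(cat_totals[category])
                rows.append(
                    {
                        "taxon": taxon,
                        "module": module,
                        "category": category,
                        "k": int(k),
                        "n": int(n),
                        "K": K,
                        "N": int(N),
                        "p": hypergeom_upper_tail(int(k), K, int(n), int(N)),
                    }
                )
    table = pd.DataFrame.from_records(
        rows, columns=["taxon", "module", "category", "k", "n", "K", "N", "p"]
    )
    if not len(table):
        table["q"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
        table["n_tests"] = pd.Series(dtype=int)
        return table

    q = np.empty(len(table))
    n_tests = np.empty(len(table), dtype=int)
    if family == "global":
        q[:] = bh_fdr(table["p"].to_numpy())
        n_tests[:] = len(table)
    else:
        for taxon, idx in table.groupby("taxon").groups.items():
            pos = table.index.get_indexer(idx)
            q[pos] = bh_fdr(table.loc[idx, "p"].to_numpy())
            n_tests[pos] = len(idx)
    table["q"] = q
    table["significant"] = table["q"] < alpha
    table["n_tests"] = n_tests
    return table
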