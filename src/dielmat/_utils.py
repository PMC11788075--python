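"""Small shared helpers: seeding, circular time arithmetic, geometric means."""
from __future__ import annotations

import numpy as np

#: period of the diel cycle in hours
DAY_HOURS = 24.0

# Fixed per-stage salts so that every stage draws from an independent stream
# derived from the single run seed. Values are arbitrary but frozen.
_STAGE_SALTS = {
    "simulate": 101,
    "census": 211,
    "normalize": 307,
    "timing": 401,
    "modules": 503,
    "ora": 601,
}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed (< 2**31) from the run seed."""
    ss = np.random.SeedSequence([int(seed), _STAGE_SALTS[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def circular_distance(a, b, period: float = DAY_HOURS):
    """Shortest distance between two clock times on a circle of given period."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period
    return np.minimum(d, period - d)


def geometric_mean(x) -> float:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(x))))


def linkage_to_newick(Z, labels) -> str:
    """Serialize a scipy linkage matrix to a Newick string with branch lengths."""
    import scipy.cluster.hierarchy as sch

    tree = sch.to_tree(Z)

    def rec(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
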