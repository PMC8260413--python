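"""Individual genetic distances and neighbor-joining trees.

The distance is allele-sharing (identity-by-state): for samples i and j,
d(i, j) = mean |dosage_i - dosage_j| / 2 over sites called in both, i.e.
one minus the shared-allele proportion.  The tree is Saitou-Nei neighbor
joining with deterministic tie-breaking (lowest taxon-index pair) and
negative branch lengths clamped to zero with the deficit moved to the
sister branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .variant_store import MISSING, GenotypeMatrix


class PopStructureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# IBS distance
# ---------------------------------------------------------------------------

def ibs_distance_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Symmetric samples x samples allele-sharing distance matrix."""
    if gm.n_samples < 2:
        raise PopStructureError("need >= 2 samples")
    g = gm.genotypes.astype(float)
    g[gm.genotypes == MISSING] = np.nan
    n = gm.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g - g[:, [i]])          # sites x samples, nan where either missing
        counts = np.sum(~np.isnan(diff), axis=0)
        if np.any(counts[i + 1 :] == 0) or counts[i] == 0:
            j = int(np.flatnonzero(counts == 0)[0])
            raise PopStructureError(
                f"samples {gm.sample_ids[i]} and {gm.sample_ids[j]} share no called sites"
            )
        with np.errstate(invalid="ignore"):
            d[i] = np.nansum(diff, axis=0) / counts / 2.0
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    label: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf():
            return self.label or ""
        inner = ",".join(
            f"{child._newick()}:{length:.10g}" for child, length in self.children
        )
        return f"({inner})"

    def leaf_labels(self) -> list[str]:
        if self.is_leaf():
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaf_labels())
        return out

    def tip_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths between every pair of leaves, keyed (min, max)."""
        dists: dict[tuple[str, str], float] = {}

        def recurse(node: TreeNode) -> dict[str, float]:
            if node.is_leaf():
                return {node.label: 0.0}
            sub = []
            for child, length in node.children:
                m = recurse(child)
                sub.append({k: v + length for k, v in m.items()})
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    for la, da in sub[i].items():
                        for lb, db in sub[j].items():
                            key = (la, lb) if la < lb else (lb, la)
                            dists[key] = da + db
            merged: dict[str, float] = {}
            for m in sub:
                merged.update(m)
            return merged

        recurse(self)
        return dists


def neighbor_joining(dist: np.ndarray, labels: list[str]) -> TreeNode:
    """Saitou-Nei neighbor joining of a symmetric distance matrix.

    Iteratively joins the pair minimizing Q(i, j) = (n - 2) d(i, j)
    - sum_k d(i, k) - sum_k d(j, k); ends with a trifurcating unrooted root
    (for 3+ taxa).  Deterministic: Q-ties resolve to the lowest-index pair.
    """
    d = np.asarray(dist, dtype=float).copy()
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise PopStructureError("matrix/label size mismatch")
    if not np.allclose(d, d.T, atol=1e-8):
        raise PopStructureError("distance matrix is not symmetric")
    if n < 3:
        raise PopStructureError("need >= 3 taxa")

    nodes: list[TreeNode] = [TreeNode(label=l) for l in labels]

    while len(nodes) > 3:
        m = d.shape[0]
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair among minima
        best = np.unravel_index(int(np.argmin(q)), q.shape)
        i, j = sorted(best)
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        dn = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = dn[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]

    # final trifurcation from the three-point formulas
    (d01, d02, d12) = (d[0, 1], d[0, 2], d[1, 2])
    l0 = (d01 + d02 - d12) / 2.0
    l1 = (d01 + d12 - d02) / 2.0
    l2 = (d02 + d12 - d01) / 2.0
    lengths = [max(l, 0.0) for l in (l0, l1, l2)]
    return TreeNode(children=list(zip(nodes, lengths)))


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, transferring the deficit to its sister."""
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return li, max(lj, 0.0)


def nj_tree_from_matrix(gm: GenotypeMatrix) -> TreeNode:
    return neighbor_joining(ibs_distance_matrix(gm), list(gm.sample_ids))
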