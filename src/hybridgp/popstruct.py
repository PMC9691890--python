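"""Genetic distances, UPGMA clustering and Newick export.

Population structure among the inbred parents is summarised by the
identity-by-state (IBS) distance — one minus the average per-marker allele
sharing, where sharing for a dosage pair (a, b) is 1 − |a − b| / 2 — and an
UPGMA (average-linkage) dendrogram with ultrametric branch lengths (node
height = half the merge distance).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from .core import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = v


@dataclass
class TreeNode:
    """Binary ultrametric tree; leaves carry names, internal nodes heights."""

    name: str | None = None
    height: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None and self.right is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return self.left.leaves() + self.right.leaves()

    def newick(self) -> str:
        return self._nwk(parent_height=None) + ";"

    def _nwk(self, parent_height):
        if self.is_leaf:
            body = self.name
        else:
            body = f"({self.left._nwk(self.height)},{self.right._nwk(self.height)})"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - self.height:.10g}"

    def cut(self, k: int) -> list[list[str]]:
        """Leaf partition into k clusters by cutting the highest merges."""
        clusters = [self]
        while len(clusters) < k:
            top = max(
                (c for c in clusters if not c.is_leaf),
                key=lambda c: c.height,
                default=None,
            )
            if top is None:
                break
            clusters.remove(top)
            clusters += [top.left, top.right]
        return [c.leaves() for c in clusters]


def ibs_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise IBS distance over markers non-missing in both samples."""
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = g.dosage.astype(float)
    valid = g.dosage != MISSING
    d[~valid] = 0.0
    n = g.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid
        diff = np.abs(d[i] - d) / 2.0
        diff[~both] = 0.0
        shared = both.sum(axis=1)
        if (shared[np.arange(n) != i] == 0).any():
            raise ValueError("sample pair with zero shared markers")
        out[i] = diff.sum(axis=1) / shared
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(sample_ids=list(g.sample_ids), values=out)


def upgma(d: DistanceMatrix) -> TreeNode:
    """UPGMA tree (proportional average linkage, ultrametric heights).

    Node heights are half the merge distance, so cophenetic distances of the
    output reproduce an ultrametric input exactly.
    """
    v = d.values
    if not np.isfinite(v).all():
        raise ValueError("non-finite distances")
    n = len(d.sample_ids)
    if n == 1:
        return TreeNode(name=d.sample_ids[0])
    Z = average(squareform(v, checks=False))
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=d.sample_ids[i]) for i in range(n)
    }
    for step, (a, b, dist, _cnt) in enumerate(Z):
        nodes[n + step] = TreeNode(
            height=dist / 2.0, left=nodes[int(a)], right=nodes[int(b)]
        )
    return nodes[n + len(Z) - 1]


def cophenetic(tree: TreeNode) -> DistanceMatrix:
    """Cophenetic distances implied by the ultrametric tree."""
    leaves = tree.leaves()
    idx = {name: i for i, name in enumerate(leaves)}
    n = len(leaves)
    out = np.zeros((n, n))

    def walk(node: TreeNode):
        if node.is_leaf:
            return [node.name]
        ll, rr = walk(node.left), walk(node.right)
        for a in ll:
            for b in rr:
                out[idx[a], idx[b]] = out[idx[b], idx[a]] = 2.0 * node.height
        return ll + rr

    walk(tree)
    return DistanceMatrix(sample_ids=leaves, values=out)


def write_newick(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def write_distance_matrix(d: DistanceMatrix, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(d.values, index=d.sample_ids, columns=d.sample_ids).to_csv(
        path, sep="\t", index_label="sample"
    )


def cluster_concordance(tree: TreeNode, truth: dict[str, int], k: int) -> float:
    """Fraction of samples whose k-cluster tree assignment matches the true
    grouping under the best cluster-to-group relabelling (greedy)."""
    parts = tree.cut(k)
    # greedy majority mapping
    n_match = 0
    used = set()
    scored = []
    for ci, part in enumerate(parts):
        counts: dict[int, int] = {}
        for s in part:
            counts[truth[s]] = counts.get(truth[s], 0) + 1
        for grp, c in counts.items():
            scored.append((c, ci, grp))
    assigned = {}
    for c, ci, grp in sorted(scored, reverse=True):
        if ci in assigned or grp in used:
            continue
        assigned[ci] = grp
        used.add(grp)
        n_match += c
    total = sum(len(p) for p in parts)
    return n_match / total
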