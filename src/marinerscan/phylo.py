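"""Neighbor-joining trees and phylogenetic cluster assignment.

Saitou-Nei neighbor joining with deterministic tie-breaking (smallest
node-index pair on equal Q) and non-negative branch lengths (a negative
branch is clamped to zero, its deficit moved to the sibling so the pair
sum is preserved). Cluster assignment labels each unanchored leaf by the
smallest clade that contains it together with anchor taxa of exactly one
cluster.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from io import StringIO
from typing import Optional

import dendropy
import numpy as np

from .distances import DistanceMatrix

__all__ = ["PhyloTree", "nj_tree", "assign_clusters"]


@dataclass
class PhyloTree:
    newick: str

    def tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick, schema="newick")

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree().leaf_node_iter())


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def _fmt(node: str, length: float) -> str:
    return f"{node}:{max(length, 0.0):.10g}"


def nj_tree(dm: DistanceMatrix, outgroup: Optional[str] = None) -> PhyloTree:
    """Neighbor joining on a fully defined distance matrix.

    The returned tree is unrooted (trifurcating root in the newick) unless
    ``outgroup`` is given, in which case it is rooted on the midpoint of
    the outgroup's branch.
    """
    bad = dm.undefined_pairs()
    if bad:
        raise ValueError(f"undefined distances for pairs: {bad}")
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    # node bookkeeping: ids 0..n-1 are leaves, new ids count upward
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(dm.d[i, j])

    def d(i: int, j: int) -> float:
        return 0.0 if i == j else dist[(min(i, j), max(i, j))]

    labels = {i: dm.taxa[i] for i in range(n)}
    active = list(range(n))
    next_id = n
    while len(active) > 3:
        r = len(active)
        row_sum = {i: sum(d(i, k) for k in active) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (r - 2) * d(i, j) - row_sum[i] - row_sum[j]
                key = (q, min(i, j), max(i, j))
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = d(i, j)
        li = dij / 2 + (row_sum[i] - row_sum[j]) / (2 * (r - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            duk = (d(i, k) + d(j, k) - dij) / 2
            dist[(min(u, k), max(u, k))] = max(duk, 0.0)
        labels[u] = f"({_fmt(labels[i], li)},{_fmt(labels[j], lj)})"
        active = [k for k in active if k not in (i, j)] + [u]
    a, b, c = active
    la = (d(a, b) + d(a, c) - d(b, c)) / 2
    lb = (d(a, b) + d(b, c) - d(a, c)) / 2
    lc = (d(a, c) + d(b, c) - d(a, b)) / 2
    newick = (f"({_fmt(labels[a], la)},{_fmt(labels[b], lb)},"
              f"{_fmt(labels[c], lc)});")
    tree = PhyloTree(newick=newick)
    if outgroup is None:
        return tree
    dtree = tree.tree()
    og = None
    for lf in dtree.leaf_node_iter():
        if lf.taxon.label == outgroup:
            og = lf
            break
    if og is None:
        raise KeyError(f"outgroup {outgroup!r} not among taxa")
    half = (og.edge.length or 0.0) / 2
    dtree.reroot_at_edge(og.edge, length1=half, length2=half)
    out = StringIO()
    dtree.write(file=out, schema="newick", suppress_rooting=True)
    return PhyloTree(newick=out.getvalue().strip())


def assign_clusters(tree: PhyloTree, anchors: dict[str, list[str]]
                    ) -> dict[str, str]:
    """Assign every leaf a cluster label from anchor taxa.

    For each unanchored leaf, ancestors are walked from the parent toward
    the root; the first ancestor whose clade contains any anchor decides:
    anchors of exactly one label assign that label, mixed anchors leave
    the leaf "unassigned" (e.g. a leaf sister to the whole ingroup).
    """
    dtree = tree.tree()
    leaf_nodes = {lf.taxon.label: lf for lf in dtree.leaf_node_iter()}
    anchor_of: dict[str, str] = {}
    for label, taxa in anchors.items():
        for t in taxa:
            if t not in leaf_nodes:
                raise KeyError(f"anchor taxon {t!r} not in tree")
            anchor_of[t] = label

    clade: dict = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            clade[node] = frozenset([node.taxon.label])
        else:
            clade[node] = frozenset().union(*(clade[c]
                                              for c in node.child_nodes()))

    def labels_in(side: frozenset[str]) -> set[str]:
        return {anchor_of[t] for t in side if t in anchor_of}

    # monophyly sanity check on the anchor sets themselves
    for label, taxa in anchors.items():
        clean = any(set(taxa) <= s and labels_in(s) == {label}
                    for s in clade.values())
        if not clean:
            warnings.warn(f"anchor set for cluster {label!r} is not "
                          "monophyletic with respect to the other anchors")

    out: dict[str, str] = {}
    for leaf in sorted(leaf_nodes):
        if leaf in anchor_of:
            out[leaf] = anchor_of[leaf]
            continue
        node = leaf_nodes[leaf].parent_node
        assigned = "unassigned"
        while node is not None:
            lab = labels_in(clade[node])
            if lab:
                if len(lab) == 1:
                    assigned = lab.pop()
                break
            node = node.parent_node
        out[leaf] = assigned
    return out
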