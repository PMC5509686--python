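"""Tree construction and manipulation for diversity analyses.

Neighbor joining is the built-in tree builder (an externally built Newick
tree can be supplied anywhere a tree is consumed); reference grafting
attaches newly delimited OTUs to a fixed backbone phylogeny by their
nearest reference neighbor, enabling the comparison of diversity indices
computed with and without reference context.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .distances import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "neighbor_joining",
    "graft_to_backbone",
    "prune_to_tips",
    "total_branch_length",
    "patristic_matrix",
    "tree_from_linkage",
]


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining on a complete distance matrix.

    The pair minimizing ``Q(i, j) = (n - 2) d(i, j) - r_i - r_j`` is joined
    at each step; ties break on the lexicographically smallest ID pair, so
    the result does not depend on input order.  Negative branch-length
    estimates are clamped to zero with the deficit moved to the sister
    edge (logged).  Returns an unrooted tree (trifurcating seed node).
    """
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("neighbor joining requires a complete distance matrix")
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    order = np.argsort(np.asarray(dm.ids, dtype=object))
    labels = [dm.ids[i] for i in order]
    d = dm.values[np.ix_(order, order)].astype(float).copy()

    tree = dendropy.Tree()
    ns = tree.taxon_namespace
    nodes: list[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = ns.new_taxon(lab)
        nodes.append(node)
    names = list(labels)
    n_clamped = 0

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # deterministic tie-break: smallest (name_i, name_j) pair
        cand = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((names[i], names[j]))), i, j)
            for i, j in cand if i < j
        )
        _, i, j = best
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj, li = dij, 0.0
            n_clamped += 1
        elif lj < 0:
            li, lj = dij, 0.0
            n_clamped += 1
        if li < 0 or lj < 0:  # dij itself negative (non-metric input)
            li, lj = max(li, 0.0), max(lj, 0.0)
        new = dendropy.Node()
        a, b = nodes[i], nodes[j]
        new.add_child(a)
        new.add_child(b)
        a.edge.length = float(li)
        b.edge.length = float(lj)
        dk = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = dk[keep]
        d_new[:-1, -1] = dk[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [min(names[i], names[j])]

    # join the last three on the seed node with the exact 3-point lengths
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    lens = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    for node, l in zip(nodes, lens):
        if l < 0:
            n_clamped += 1
            l = 0.0
        tree.seed_node.add_child(node)
        node.edge.length = float(l)
    if n_clamped:
        logger.info("clamped %d negative branch length(s) to zero", n_clamped)
    return tree


def graft_to_backbone(
    query_rows: Mapping[str, Mapping[str, float]],
    backbone: dendropy.Tree,
) -> dendropy.Tree:
    """Attach queries to a backbone at their nearest reference neighbor.

    Each query joins the midpoint of the pendant edge of the reference tip
    it is closest to (finite distances only), as a cherry with pendant
    length ``max(d / 2, 1e-6)``.  Backbone topology and the remaining
    branch lengths are untouched.  Queries are processed in sorted order;
    a second query nearest to the same reference attaches to that tip's
    (already subdivided) pendant edge.
    """
    tree = backbone.clone(depth=1)
    tip_of = {l.taxon.label: l for l in tree.leaf_node_iter()}
    no_ref = [
        q for q, row in query_rows.items()
        if not any(np.isfinite(v) for r, v in row.items() if r in tip_of)
    ]
    if no_ref:
        raise ValueError(
            f"quer{'ies' if len(no_ref) > 1 else 'y'} with no finite distance "
            f"to any reference: {sorted(no_ref)}"
        )
    ns = tree.taxon_namespace
    for q in sorted(query_rows):
        row = {
            r: v for r, v in query_rows[q].items()
            if r in tip_of and np.isfinite(v)
        }
        nearest = min(row, key=lambda r: (row[r], r))
        ref_tip = tip_of[nearest]
        pend = ref_tip.edge.length or 0.0
        parent = ref_tip.parent_node
        junction = dendropy.Node(edge_length=pend / 2.0)
        parent.remove_child(ref_tip)
        parent.add_child(junction)
        junction.add_child(ref_tip)
        ref_tip.edge.length = pend / 2.0
        q_node = dendropy.Node(edge_length=max(row[nearest] / 2.0, 1e-6))
        q_node.taxon = ns.new_taxon(q)
        junction.add_child(q_node)
    return tree


def prune_to_tips(tree: dendropy.Tree, tips: Sequence[str]) -> dendropy.Tree:
    """Minimal spanning subtree of ``tips``, retaining the original root.

    Unsampled degree-two internal nodes are collapsed with their branch
    lengths summed; the path from the root down to the subtree is kept, so
    total branch length is the root-inclusive quantity Faith's PD uses.
    """
    wanted = set(tips)
    if not wanted:
        raise ValueError("tip subset must be non-empty")
    have = {l.taxon.label for l in tree.leaf_node_iter()}
    unknown = wanted - have
    if unknown:
        raise KeyError(f"unknown tip(s): {sorted(unknown)}")
    pruned = tree.clone(depth=1)
    keep = set()
    for leaf in pruned.leaf_node_iter():
        if leaf.taxon.label in wanted:
            node = leaf
            while node is not None and id(node) not in keep:
                keep.add(id(node))
                node = node.parent_node
    for node in pruned.postorder_node_iter():
        if id(node) in keep or node.parent_node is None:
            continue
        node.parent_node.remove_child(node)
    # collapse unsampled degree-2 internals (never the root), summing lengths
    for node in list(pruned.postorder_node_iter()):
        parent = node.parent_node
        if parent is None or node.is_leaf():
            continue
        kids = node.child_nodes()
        if len(kids) == 1:
            child = kids[0]
            child.edge.length = (child.edge.length or 0.0) + (node.edge.length or 0.0)
            node.remove_child(child)
            parent.add_child(child)
            parent.remove_child(node)
    return pruned


def total_branch_length(tree: dendropy.Tree) -> float:
    return float(
        sum(
            e.length or 0.0
            for e in tree.preorder_edge_iter()
            if e.head_node.parent_node is not None
        )
    )


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Tip-to-tip path-length (patristic) distance matrix as a DataFrame."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(
        (l.taxon for l in tree.leaf_node_iter()), key=lambda t: t.label
    )
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    labels = [t.label for t in taxa]
    return pd.DataFrame(out, index=labels, columns=labels)


def tree_from_linkage(z: np.ndarray, labels: Sequence[str]) -> dendropy.Tree:
    """Convert a SciPy linkage matrix (e.g. UPGMA) to a dendropy tree.

    Heights are cophenetic: each tip-to-ancestor path length equals half
    the merge height, as for an ultrametric average-linkage dendrogram.
    """
    n = len(labels)
    tree = dendropy.Tree()
    ns = tree.taxon_namespace
    heights: dict[int, float] = {}
    nodes: dict[int, dendropy.Node] = {}
    for i, lab in enumerate(labels):
        node = dendropy.Node()
        node.taxon = ns.new_taxon(str(lab))
        nodes[i] = node
        heights[i] = 0.0
    for k, (a, b, h, _) in enumerate(z):
        a, b = int(a), int(b)
        new = dendropy.Node()
        for child in (a, b):
            new.add_child(nodes[child])
            nodes[child].edge.length = h / 2.0 - heights[child]
        nodes[n + k] = new
        heights[n + k] = h / 2.0
    root = nodes[n + len(z) - 1]
    for child in root.child_nodes():
        tree.seed_node.add_child(child)
    return tree
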