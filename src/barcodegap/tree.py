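"""Neighbor-joining trees, midpoint rooting, lineage extraction and
misidentification flagging.

The NJ tree is not an end in itself here: it guides the extraction of
*lineages* — maximal clades whose members are all within a pairwise
p-distance cutoff of one another (default 1%).  Each lineage receives an
identity by majority rule over the taxonomic labels of its members; a
member whose own label disagrees with the majority and that sits at very
low distance from majority-labelled members is flagged as a putative
misidentification (the classic symptom being a single specimen of one
species nested at ~0% distance inside a large clade of another).

Trees are :class:`skbio.TreeNode` objects with tips named by sequence id,
so Newick round-tripping and standard tree operations come for free.  The
NJ agglomeration itself is implemented here so the tie-breaking rules
(lexicographically smallest (row, column) pair on equal Q) and the
clamping of negative branch-length estimates to zero are explicit and
reproducible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from skbio import TreeNode

from .alignment import TaxonLabel
from .distances import DistanceMatrix
from .errors import TreeSizeError


def _tree_node(name=None, children=(), lengths=()):
    node = TreeNode(name=name)
    for child, length in zip(children, lengths):
        child.length = max(0.0, float(length))  # clamp negative estimates
        node.append(child)
    return node


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Standard NJ agglomeration on the Q-criterion.

    Joins the pair minimising Q at each step, breaking ties by the
    lexicographically smallest (row, column) index pair; negative branch
    lengths are clamped to zero.  Returns an unrooted tree (degree-3
    root node) whose tip names are ``dm.ids``.
    """
    n = len(dm.ids)
    if n < 3:
        raise TreeSizeError(f"neighbor joining needs >= 3 sequences, got {n}")
    D = dm.values.astype(float).copy()
    nodes = [TreeNode(name=i) for i in dm.ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # np.argmin scans row-major: first minimum is the smallest (i, j)
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        new = _tree_node(children=(nodes[i], nodes[j]), lengths=(li, lj))
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D_next = np.zeros((m - 1, m - 1))
        D_next[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D_next[-1, : m - 2] = D_next[: m - 2, -1] = d_new[keep]
        D = D_next
        nodes = [nodes[k] for k in keep] + [new]

    # three-point closed form for the final star join
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    return _tree_node(children=tuple(nodes), lengths=(l0, l1, l2))


# ---------------------------------------------------------------------------
# midpoint rooting


def _edge_graph(tree: TreeNode) -> dict:
    """Adjacency map {node_key: [(neighbor_key, length), ...]} of the tree."""
    adj: dict = {}

    def key(node):
        return node.name if node.is_tip() else id(node)

    for node in tree.traverse(include_self=True):
        adj.setdefault(key(node), [])
    for node in tree.traverse(include_self=False):
        u, v = key(node.parent), key(node)
        w = float(node.length or 0.0)
        adj[u].append((v, w))
        adj[v].append((u, w))
    return adj


def _path(adj: dict, src, dst) -> list:
    """Unique path [(node, edge_length_from_previous), ...] in a tree."""
    stack = [(src, None)]
    parent = {src: None}
    while stack:
        node, _ = stack.pop()
        if node == dst:
            break
        for nbr, w in adj[node]:
            if nbr not in parent:
                parent[nbr] = (node, w)
                stack.append((nbr, w))
    path = []
    node = dst
    while node is not None:
        prev = parent[node]
        path.append((node, prev[1] if prev else 0.0))
        node = prev[0] if prev else None
    return list(reversed(path))


def _rebuild_rooted(adj: dict, root_key, names: Mapping) -> TreeNode:
    def build(node_key, parent_key, length):
        node = TreeNode(name=names.get(node_key), length=length)
        for nbr, w in adj[node_key]:
            if nbr != parent_key:
                node.append(build(nbr, node_key, w))
        return node

    root = build(root_key, None, None)
    root.length = None
    return root


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root the tree at the midpoint of the longest tip-to-tip path.

    Ties between equally long paths are broken by the lexicographically
    smallest sorted pair of tip names.
    """
    tips = sorted(t.name for t in tree.tips())
    if len(tips) < 2:
        raise TreeSizeError("midpoint rooting needs >= 2 tips")
    tipdm = tree.tip_tip_distances()
    best = None
    for a in tips:
        for b in tips:
            if a < b:
                d = float(tipdm[a, b])
                cand = (-d, a, b)
                if best is None or cand < best:
                    best = cand
    total, a, b = -best[0], best[1], best[2]

    adj = _edge_graph(tree)
    names = {t.name: t.name for t in tree.tips()}
    path = _path(adj, a, b)
    half = total / 2.0
    cum = 0.0
    for idx in range(1, len(path)):
        node, w = path[idx]
        if cum + w >= half - 1e-12:
            u = path[idx - 1][0]
            x = half - cum  # distance from u along edge (u, node)
            u_is_tip = len(adj[u]) == 1
            node_is_tip = len(adj[node]) == 1
            if x <= 1e-12 and not u_is_tip:
                root_key = u
            elif w - x <= 1e-12 and not node_is_tip:
                root_key = node
            else:
                root_key = "__midpoint_root__"
                adj[u] = [(k, l) for k, l in adj[u] if k != node] + [(root_key, x)]
                adj[node] = [(k, l) for k, l in adj[node] if k != u] + [
                    (root_key, w - x)
                ]
                adj[root_key] = [(u, x), (node, w - x)]
            return _rebuild_rooted(adj, root_key, names)
        cum += w
    raise RuntimeError("midpoint not found on longest path")  # pragma: no cover


# ---------------------------------------------------------------------------
# lineages


@dataclass
class Lineage:
    """A maximal low-divergence clade of the rooted NJ tree."""

    clade_number: int  # 1-based, in preorder
    member_ids: list
    member_labels: list  # parallel to member_ids
    labels_present: Counter
    majority_label: TaxonLabel
    tie: bool
    max_internal_distance: float


@dataclass
class MisidFlag:
    sequence_id: str
    own_label: TaxonLabel
    clade_majority_label: TaxonLabel
    min_distance_to_majority: float


def majority_label(labels: Counter) -> tuple:
    """Most frequent label; ties resolved to the lexicographically
    smallest full label, with the tie reported."""
    if not labels:
        raise ValueError("empty label multiset")
    top = max(labels.values())
    winners = sorted((lab for lab, c in labels.items() if c == top), key=lambda l: l.full)
    return winners[0], len(winners) > 1


def extract_lineages(
    tree: TreeNode,
    dm: DistanceMatrix,
    labels: Mapping[str, TaxonLabel],
    cutoff: float = 0.01,
) -> list:
    """Partition the tips into maximal clades of pairwise distance < cutoff.

    The rooted tree is walked in preorder; the first (shallowest) clade on
    each root-to-tip path whose members are all within ``cutoff`` of each
    other becomes a lineage, and its subtree is not descended further.
    Singletons are allowed, so the lineages always partition the tips.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    index = {rec_id: k for k, rec_id in enumerate(dm.ids)}
    lineages: list = []

    def max_internal(tip_ids):
        if len(tip_ids) == 1:
            return 0.0
        idx = [index[t] for t in tip_ids]
        sub = dm.values[np.ix_(idx, idx)]
        return float(sub.max())

    def visit(node):
        tip_ids = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        dmax = max_internal(tip_ids)
        if dmax < cutoff:
            member_labels = [labels[t] for t in tip_ids]
            counts = Counter(member_labels)
            maj, tie = majority_label(counts)
            lineages.append(
                Lineage(
                    clade_number=len(lineages) + 1,
                    member_ids=tip_ids,
                    member_labels=member_labels,
                    labels_present=counts,
                    majority_label=maj,
                    tie=tie,
                    max_internal_distance=dmax,
                )
            )
            return
        for child in node.children:
            visit(child)

    visit(tree)
    return lineages


def flag_misidentifications(
    lineages: list,
    dm: DistanceMatrix,
    max_dist: float = 0.01,
) -> list:
    """Flag lineage members whose label disagrees with the clade majority.

    A member is flagged when its own species label differs from its
    lineage's majority label and its minimum distance to any
    majority-labelled member is at most ``max_dist`` — i.e. it is
    genetically indistinguishable from a differently-named cluster.
    """
    index = {rec_id: k for k, rec_id in enumerate(dm.ids)}
    flags = []
    for lin in lineages:
        maj_key = lin.majority_label.species_key()
        maj_idx = [
            index[m]
            for m, lab in zip(lin.member_ids, lin.member_labels)
            if lab.species_key() == maj_key
        ]
        for m, lab in zip(lin.member_ids, lin.member_labels):
            if lab.species_key() == maj_key:
                continue
            dmin = float(dm.values[index[m], maj_idx].min())
            if dmin <= max_dist:
                flags.append(
                    MisidFlag(
                        sequence_id=m,
                        own_label=lab,
                        clade_majority_label=lin.majority_label,
                        min_distance_to_majority=dmin,
                    )
                )
    return flags
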