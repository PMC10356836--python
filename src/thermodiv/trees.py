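"""Rooted-tree utilities shared by the likelihood and diversity code.

Trees are handled as :class:`dendropy.Tree` objects at the API surface and
converted once to flat index arrays for numerical work.  Node indexing
convention: tips are ``0 .. n_tips-1`` (in the order of ``tip_labels``),
internal nodes are ``n_tips .. 2*n_tips-2`` in postorder, so every child index
is smaller than its parent's and the root is last.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "TreeArrays",
    "to_arrays",
    "read_newick",
    "node_depths",
    "is_ultrametric",
    "make_ultrametric",
    "patristic_matrix",
    "prune_to_taxa",
    "branching_times",
]


@dataclass
class TreeArrays:
    """Flat representation of a rooted binary tree.

    Attributes
    ----------
    n_tips : int
        Number of leaves.
    left, right : ndarray of int
        Child indices of internal node ``n_tips + i`` (postorder).
    blen : ndarray of float
        Branch length subtending each node (root entry is 0).
    tip_labels : list of str
        Taxon label of tip ``i``.
    """

    n_tips: int
    left: np.ndarray
    right: np.ndarray
    blen: np.ndarray
    tip_labels: list

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    def depths(self) -> np.ndarray:
        """Height of every node above the present (tips at their own depth)."""
        d = np.zeros(self.n_nodes)
        # walk from root downward: parent depth minus child branch length
        # root-to-node distances first
        dist = np.zeros(self.n_nodes)
        for i in range(self.n_tips - 2, -1, -1):
            node = self.n_tips + i
            for c in (self.left[i], self.right[i]):
                dist[c] = dist[node] + self.blen[c]
        maxd = dist.max()
        d = maxd - dist
        return d


def read_newick(path_or_str, from_path: bool = True) -> dendropy.Tree:
    if from_path:
        return dendropy.Tree.get(path=str(path_or_str), schema="newick")
    return dendropy.Tree.get(data=path_or_str, schema="newick")


def _check_binary(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        nch = len(node.child_nodes())
        if nch not in (0, 2):
            raise ValueError(
                f"tree is not strictly binary: node with {nch} children "
                f"({node.taxon.label if node.taxon else 'internal'})"
            )


def to_arrays(tree: dendropy.Tree) -> TreeArrays:
    """Convert a rooted binary dendropy tree to :class:`TreeArrays`.

    Polytomies and negative branch lengths are rejected.  Unifurcations
    (including a root with a single child) are suppressed first.
    """
    tree = tree.clone(depth=1)
    tree.suppress_unifurcations()
    _check_binary(tree)
    tips = [nd for nd in tree.leaf_node_iter()]
    n_tips = len(tips)
    if n_tips < 2:
        raise ValueError("tree must have at least 2 tips")
    index = {}
    tip_labels = []
    for i, nd in enumerate(tips):
        index[nd] = i
        tip_labels.append(nd.taxon.label if nd.taxon else f"tip{i}")
    internal = [nd for nd in tree.postorder_internal_node_iter()]
    if len(internal) != n_tips - 1:
        raise ValueError("tree is not strictly binary")
    left = np.empty(n_tips - 1, dtype=np.int64)
    right = np.empty(n_tips - 1, dtype=np.int64)
    blen = np.zeros(2 * n_tips - 1)
    for j, nd in enumerate(internal):
        index[nd] = n_tips + j
        ch = nd.child_nodes()
        left[j], right[j] = index[ch[0]], index[ch[1]]
    for nd, idx in index.items():
        el = nd.edge.length
        if el is None:
            el = 0.0
        if el < 0:
            raise ValueError(f"negative branch length {el}")
        blen[idx] = el
    blen[2 * n_tips - 2] = 0.0  # root edge ignored
    return TreeArrays(n_tips=n_tips, left=left, right=right, blen=blen,
                      tip_labels=tip_labels)


def node_depths(tree: dendropy.Tree) -> dict:
    """Root-to-node distance for every node."""
    depths = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depths[nd] = 0.0
        else:
            depths[nd] = depths[nd.parent_node] + (nd.edge.length or 0.0)
    return depths


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    d = node_depths(tree)
    tipd = np.array([d[nd] for nd in tree.leaf_node_iter()])
    span = tipd.max()
    if span == 0:
        return True
    return (tipd.max() - tipd.min()) / span <= rel_tol


def make_ultrametric(tree: dendropy.Tree, rel_tol: float = 0.01) -> dendropy.Tree:
    """Extend terminal branches so all tips reach the maximum depth.

    Deviations larger than ``rel_tol`` (fraction of tree depth) are rejected:
    silently linearizing a strongly non-clock tree changes the analysis.
    """
    tree = tree.clone(depth=1)
    d = node_depths(tree)
    tips = list(tree.leaf_node_iter())
    tipd = np.array([d[nd] for nd in tips])
    span = tipd.max()
    if span <= 0:
        raise ValueError("tree has zero depth")
    dev = (span - tipd.min()) / span
    if dev > rel_tol:
        raise ValueError(
            f"tree deviates from ultrametricity by {dev:.3g} (> {rel_tol}); "
            "supply a time-calibrated tree"
        )
    for nd, depth in zip(tips, tipd):
        nd.edge.length = (nd.edge.length or 0.0) + (span - depth)
    return tree


def patristic_matrix(tree: dendropy.Tree):
    """Tip-to-tip patristic distance matrix (polytomies allowed).

    Returns ``(labels, D)`` with ``D[i, j]`` the sum of branch lengths on the
    path between tips ``i`` and ``j``.  Computed in one postorder sweep
    (O(n^2) total) and intended to be cached by callers: null-model loops must
    not recompute it.
    """
    leaves = list(tree.leaf_node_iter())
    n = len(leaves)
    labels = [lf.taxon.label if lf.taxon else f"tip{i}"
              for i, lf in enumerate(leaves)]
    pos = {id(lf): i for i, lf in enumerate(leaves)}
    D = np.zeros((n, n))
    below = {}
    dist = {}
    for lf in leaves:
        below[id(lf)] = np.array([pos[id(lf)]])
        dist[id(lf)] = np.array([0.0])
    for nd in tree.postorder_internal_node_iter():
        parts = []
        for ch in nd.child_nodes():
            b = below.pop(id(ch))
            dd = dist.pop(id(ch)) + (ch.edge.length or 0.0)
            parts.append((b, dd))
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                bi, di = parts[i]
                bj, dj = parts[j]
                D[np.ix_(bi, bj)] = di[:, None] + dj[None, :]
                D[np.ix_(bj, bi)] = dj[:, None] + di[None, :]
        below[id(nd)] = np.concatenate([p[0] for p in parts])
        dist[id(nd)] = np.concatenate([p[1] for p in parts])
    return labels, D


def prune_to_taxa(tree: dendropy.Tree, labels) -> dendropy.Tree:
    """Subtree induced by the given tip labels (unifurcations suppressed)."""
    keep = set(labels)
    tree = tree.clone(depth=1)
    taxa = [t for t in tree.taxon_namespace if t.label in keep]
    missing = keep - {t.label for t in taxa}
    if missing:
        raise KeyError(f"taxa not on tree: {sorted(missing)[:5]}...")
    tree.retain_taxa(taxa)
    tree.suppress_unifurcations()
    return tree


def branching_times(tree: dendropy.Tree) -> np.ndarray:
    """Internal-node heights above the present, descending (root first)."""
    arr = to_arrays(tree)
    d = arr.depths()
    bt = d[arr.n_tips:]
    return np.sort(bt)[::-1]
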