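"""Phylogeny data model, Newick I/O and subtree decomposition.

The M statistic reads only the *topology* of a rooted, strictly bifurcating
tree: every internal node with at least three descendant tips defines a
subtree whose two child branches are compared against each other.  Branch
lengths are carried along for simulation and for patristic distances but are
never consulted by the statistic itself.

Internally a :class:`Phylogeny` stores the tree as flat integer arrays
(children, parents, postorder) so that the per-permutation evaluation of M
can be fully vectorised; dendropy handles all Newick parsing and writing.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PolytomyError",
    "SubtreePartition",
    "read_newick",
    "write_newick",
    "decompose_subtrees",
    "pair_mrca_index",
]

NO_NODE = -1


class PolytomyError(ValueError):
    """Raised when a tree contains a non-bifurcating internal node."""


@dataclass(frozen=True, eq=False)
class Phylogeny:
    """A rooted, strictly bifurcating phylogeny over ``n`` uniquely labelled tips.

    Nodes are integers ``0 .. 2n-2``: tips are ``0 .. n-1`` (ordered as in the
    source Newick), internal nodes follow, and the root is always the last
    node.  ``left_child``/``right_child`` are ``NO_NODE`` for tips;
    ``branch_length`` is ``nan`` where the source tree had no length.
    """

    tip_labels: tuple[str, ...]
    left_child: np.ndarray
    right_child: np.ndarray
    parent: np.ndarray
    branch_length: np.ndarray

    # ---- derived, cached on first use -------------------------------------
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def is_tip(self, node: int) -> bool:
        return node < self.n_tips

    @property
    def postorder_internal(self) -> np.ndarray:
        """Internal node ids in postorder (children before parents)."""
        if "post" not in self._cache:
            order = []
            stack = [self.root]
            while stack:  # reverse preorder == postorder when reversed
                v = stack.pop()
                order.append(v)
                if not self.is_tip(v):
                    stack.append(int(self.left_child[v]))
                    stack.append(int(self.right_child[v]))
            self._cache["post"] = np.array(
                [v for v in reversed(order) if not self.is_tip(v)], dtype=np.intp
            )
        return self._cache["post"]

    @property
    def clade_size(self) -> np.ndarray:
        """Number of descendant tips per node (tips count themselves)."""
        if "csize" not in self._cache:
            size = np.ones(self.n_nodes, dtype=np.intp)
            for v in self.postorder_internal:
                size[v] = size[self.left_child[v]] + size[self.right_child[v]]
            self._cache["csize"] = size
        return self._cache["csize"]

    def clade_tips(self, node: int) -> frozenset[str]:
        """Labels of all tips descending from ``node`` (itself if a tip)."""
        idx = self.clade_tip_indices(node)
        return frozenset(self.tip_labels[i] for i in idx)

    def clade_tip_indices(self, node: int) -> np.ndarray:
        if "ctips" not in self._cache:
            tips: list[np.ndarray | None] = [None] * self.n_nodes
            for i in range(self.n_tips):
                tips[i] = np.array([i], dtype=np.intp)
            for v in self.postorder_internal:
                tips[v] = np.concatenate(
                    [tips[self.left_child[v]], tips[self.right_child[v]]]
                )
            self._cache["ctips"] = tips
        return self._cache["ctips"][node]

    # ---- invariants -------------------------------------------------------
    def validate(self) -> "Phylogeny":
        if self.n_tips < 3:
            raise ValueError(f"a phylogeny needs >= 3 tips, got {self.n_tips}")
        if len(set(self.tip_labels)) != self.n_tips:
            dupes = {t for t in self.tip_labels if self.tip_labels.count(t) > 1}
            raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
        if any(not lbl for lbl in self.tip_labels):
            raise ValueError("empty tip label")
        finite = self.branch_length[np.isfinite(self.branch_length)]
        if (finite < 0).any():
            raise ValueError("negative branch length")
        return self

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = self.tip_depths()
        return bool(np.ptp(depths) <= tol * max(1.0, float(np.max(depths))))

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path lengths (requires branch lengths)."""
        bl = np.nan_to_num(self.branch_length, nan=0.0)
        depth = np.zeros(self.n_nodes)
        for v in self.postorder_internal[::-1]:  # preorder
            for c in (self.left_child[v], self.right_child[v]):
                depth[c] = depth[v] + bl[c]
        return depth[: self.n_tips]

    def patristic_matrix(self) -> np.ndarray:
        """Pairwise sum of branch lengths between tips, in tip order."""
        n = self.n_tips
        depth = np.zeros(self.n_nodes)
        bl = np.nan_to_num(self.branch_length, nan=0.0)
        for v in self.postorder_internal[::-1]:
            for c in (self.left_child[v], self.right_child[v]):
                depth[c] = depth[v] + bl[c]
        out = np.zeros((n, n))
        mrca = pair_mrca_index(self)
        lbl = {t: i for i, t in enumerate(self.tip_labels)}
        for (a, b), v in mrca.items():
            i, j = lbl[a], lbl[b]
            d = depth[i] + depth[j] - 2.0 * depth[v]
            out[i, j] = out[j, i] = d
        return out

    # ---- dendropy bridge --------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        seed = tree.seed_node
        leaves = [lf for lf in tree.leaf_node_iter()]
        labels = [lf.taxon.label if lf.taxon else (lf.label or "") for lf in leaves]
        n = len(leaves)
        if n < 3:
            raise ValueError(f"a phylogeny needs >= 3 tips, got {n}")
        # reject polytomies (incl. unrooted basal trifurcations) up front
        for nd in tree.preorder_node_iter():
            k = len(nd.child_nodes())
            if k not in (0, 2):
                where = nd.taxon.label if nd.taxon else (nd.label or "internal node")
                raise PolytomyError(
                    f"tree is not strictly bifurcating: node '{where}' has {k} "
                    "children; the M statistic is defined for dichotomous trees"
                )
        n_nodes = 2 * n - 1
        left = np.full(n_nodes, NO_NODE, dtype=np.intp)
        right = np.full(n_nodes, NO_NODE, dtype=np.intp)
        parent = np.full(n_nodes, NO_NODE, dtype=np.intp)
        blen = np.full(n_nodes, np.nan)
        ids: dict[dendropy.Node, int] = {}
        tip_i = itertools.count(0)
        int_i = itertools.count(n)
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                ids[nd] = next(tip_i)
            elif nd is seed:
                ids[nd] = n_nodes - 1
            else:
                ids[nd] = next(int_i)
        for nd, v in ids.items():
            if nd.edge.length is not None:
                blen[v] = float(nd.edge.length)
            kids = nd.child_nodes()
            if kids:
                left[v], right[v] = ids[kids[0]], ids[kids[1]]
                parent[ids[kids[0]]] = v
                parent[ids[kids[1]]] = v
        return cls(tuple(labels), left, right, parent, blen).validate()

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes = {}
        for v in range(self.n_nodes):
            nd = dendropy.Node()
            if self.is_tip(v):
                nd.taxon = taxa.new_taxon(self.tip_labels[v])
            b = self.branch_length[v]
            nd.edge.length = None if np.isnan(b) else float(b)
            nodes[v] = nd
        for v in self.postorder_internal:
            nodes[v].add_child(nodes[int(self.left_child[v])])
            nodes[v].add_child(nodes[int(self.right_child[v])])
        tree.seed_node = nodes[self.root]
        return tree


@dataclass(frozen=True)
class SubtreePartition:
    """The subtree decomposition driving M.

    One entry per internal node with >= 3 descendant tips: the node id and the
    tip-label sets of its two child branches, in source child order (the
    ordering is arbitrary; the subtree score weights both branches equally).
    """

    entries: tuple[tuple[int, frozenset[str], frozenset[str]], ...]

    @property
    def n_subtrees(self) -> int:
        return len(self.entries)


def read_newick(source: str) -> Phylogeny:
    """Parse a rooted Newick tree (a literal string or a file path).

    Polytomies — including the basal trifurcation of unrooted trees — are
    rejected: the subtree decomposition requires a dichotomous tree.
    """
    text = source
    if "(" not in source:  # no tree syntax: treat as a path
        with open(source) as fh:
            text = fh.read()
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises various error classes
        raise ValueError(f"could not parse Newick: {exc}") from exc
    return Phylogeny.from_dendropy(dtree)


def write_newick(tree: Phylogeny, path: str | None = None) -> str:
    """Serialise to Newick; returns the string and optionally writes a file."""
    out = tree.to_dendropy().as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip() + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(out)
    return out


def decompose_subtrees(tree: Phylogeny) -> SubtreePartition:
    """Decompose into the subtrees scored by M.

    Every internal node with at least three descendant tips contributes one
    entry; cherries (two-tip internal nodes) carry no within/cross contrast
    and are excluded.
    """
    size = tree.clade_size
    entries = []
    for v in tree.postorder_internal[::-1]:  # root first, for readability
        if size[v] >= 3:
            entries.append(
                (
                    int(v),
                    tree.clade_tips(int(tree.left_child[v])),
                    tree.clade_tips(int(tree.right_child[v])),
                )
            )
    return SubtreePartition(tuple(entries))


def pair_mrca_index(tree: Phylogeny) -> dict[tuple[str, str], int]:
    """Map every unordered tip pair to its most recent common ancestor.

    The pairs whose MRCA is node ``v`` are exactly the cross pairs of the
    subtree rooted at ``v``; this is what lets all subtree averages be
    accumulated in one O(n^2) pass per permutation.
    """
    out: dict[tuple[str, str], int] = {}
    for v in tree.postorder_internal:
        li = tree.clade_tip_indices(int(tree.left_child[v]))
        ri = tree.clade_tip_indices(int(tree.right_child[v]))
        for i in li:
            for j in ri:
                a, b = tree.tip_labels[i], tree.tip_labels[j]
                key = (a, b) if a <= b else (b, a)
                out[key] = int(v)
    return out


def condensed_pair_mrca(tree: Phylogeny) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised MRCA index: arrays (i, j, mrca_node) over all tip pairs i<j."""
    ii, jj, vv = [], [], []
    for v in tree.postorder_internal:
        li = tree.clade_tip_indices(int(tree.left_child[v]))
        ri = tree.clade_tip_indices(int(tree.right_child[v]))
        a, b = np.meshgrid(li, ri, indexing="ij")
        a, b = a.ravel(), b.ravel()
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        ii.append(lo)
        jj.append(hi)
        vv.append(np.full(lo.shape, v, dtype=np.intp))
    return np.concatenate(ii), np.concatenate(jj), np.concatenate(vv)
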