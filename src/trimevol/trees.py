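"""Phylogeny handling: an array-backed rooted tree plus NJ and random trees.

Likelihood computations need little more than a postorder traversal with
branch lengths, so trees are stored as flat parent/length arrays.  Newick
parsing and writing go through dendropy; neighbor joining goes through
scikit-bio.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj


class TreeError(ValueError):
    pass


class Tree:
    """Rooted phylogeny as flat arrays.

    Leaves occupy node ids ``0 .. n_leaves-1`` (aligned with ``taxa``);
    internal nodes follow, the root last.  ``lengths[i]`` is the branch above
    node ``i`` (zero for the root).  Polytomies are allowed; for reversible
    models the (arbitrary) rooting does not affect the likelihood.
    """

    def __init__(self, taxa, parent, lengths, children):
        self.taxa = list(taxa)
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float)
        self.children = [list(c) for c in children]
        self.n_leaves = len(self.taxa)
        self.n_nodes = len(self.parent)
        self.root = self.n_nodes - 1
        self.postorder_internal = self._postorder_internal()

    def _postorder_internal(self):
        order = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if node < self.n_leaves:
                continue
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for ch in self.children[node]:
                    stack.append((ch, False))
        return order

    @property
    def total_length(self) -> float:
        return float(self.lengths[: self.n_nodes - 1].sum())

    # -- construction -------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, allow_negative: bool = False) -> "Tree":
        tree = tree.clone(depth=1)
        tree.suppress_unifurcations()
        leaves = [lf for lf in tree.leaf_node_iter()]
        if len(leaves) < 2:
            raise TreeError("tree must have at least 2 leaves")
        taxa = [lf.taxon.label for lf in leaves]
        if len(set(taxa)) != len(taxa):
            raise TreeError("duplicate leaf labels")
        ids = {id(lf): i for i, lf in enumerate(leaves)}
        internals = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
        for k, nd in enumerate(internals):
            ids[id(nd)] = len(leaves) + k
        n_nodes = len(leaves) + len(internals)
        parent = np.full(n_nodes, -1, dtype=int)
        lengths = np.zeros(n_nodes)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        for nd in tree.postorder_node_iter():
            i = ids[id(nd)]
            el = nd.edge.length
            if el is None:
                el = 0.0
            if el < 0:
                if not allow_negative:
                    raise TreeError(f"negative branch length {el}")
            lengths[i] = el
            if nd.parent_node is not None:
                p = ids[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
        root_id = ids[id(tree.seed_node)]
        if root_id != n_nodes - 1:  # postorder guarantees root is last internal
            raise TreeError("internal error: root not last node")
        lengths[root_id] = 0.0
        return cls(taxa, parent, lengths, children)

    @classmethod
    def from_newick(cls, newick: str, allow_negative: bool = False) -> "Tree":
        dt = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls.from_dendropy(dt, allow_negative=allow_negative)

    # -- serialisation -------------------------------------------------

    def to_newick(self) -> str:
        def render(node: int) -> str:
            if node < self.n_leaves:
                core = self.taxa[node]
            else:
                core = "(" + ",".join(render(c) for c in self.children[node]) + ")"
            if node == self.root:
                return core
            return f"{core}:{self.lengths[node]:.10g}"

        return render(self.root) + ";"

    def scaled(self, factor: float) -> "Tree":
        t = Tree(self.taxa, self.parent, self.lengths * factor, self.children)
        return t


def nj_tree(labels, distances: np.ndarray) -> Tree:
    """Neighbor-joining tree from a distance matrix (negative lengths clamped)."""
    labels = list(labels)
    d = np.asarray(distances, dtype=float)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    skt = _skbio_nj(DistanceMatrix(d, ids=labels))
    buf = io.StringIO()
    skt.write(buf, format="newick")
    tree = Tree.from_newick(buf.getvalue(), allow_negative=True)
    tree.lengths = np.maximum(tree.lengths, 0.0)
    return tree


def jc_distance_matrix(states: np.ndarray, max_p: float = 0.70) -> np.ndarray:
    """Jukes-Cantor-corrected pairwise distances from a (n, sites) state matrix.

    Observed proportions are capped at ``max_p`` to keep the correction
    finite for saturated pairs.
    """
    states = np.asarray(states)
    n = states.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        p = (states[i] != states[i + 1 :]).mean(axis=1)
        p = np.minimum(p, max_p)
        d[i, i + 1 :] = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    return d + d.T


def random_tree(
    n_taxa: int,
    rng: np.random.Generator,
    mean_branch: float = 0.1,
    labels=None,
) -> Tree:
    """Random topology by sequential pairwise joining, exponential branch lengths."""
    if n_taxa < 2:
        raise TreeError("need at least 2 taxa")
    if labels is None:
        labels = [f"t{i+1}" for i in range(n_taxa)]
    nodes = [lbl for lbl in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        bi, bj = rng.exponential(mean_branch, size=2)
        merged = f"({nodes[i]}:{bi:.8f},{nodes[j]}:{bj:.8f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    bi, bj = rng.exponential(mean_branch, size=2)
    newick = f"({nodes[0]}:{bi:.8f},{nodes[1]}:{bj:.8f});"
    return Tree.from_newick(newick)
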