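"""Rooted phylogenies with branch lengths and the derived trait covariance.

The central object is :class:`Phylogeny`, a light array-backed rooted tree.
Nodes are stored in preorder (every parent precedes its children), which
makes root-to-tip accumulation, trait simulation and covariance assembly
simple vectorised passes.  Newick parsing is delegated to dendropy; writing
is a small recursive serialiser so that branch lengths round-trip at fixed
significant-digit precision.

The phylogenetic variance–covariance matrix C has
``C[i, j] = total branch length shared by the root-to-tip paths of i and j``
(i.e. the depth of their most recent common ancestor) and
``C[i, i] = root-to-tip distance``.  Under Brownian motion with rate sigma^2
the tip values are multivariate normal with covariance ``sigma^2 * C``.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np

from .errors import ParseError, ValidationError


class Phylogeny:
    """Rooted tree; nodes in preorder, node 0 is the root.

    Parameters
    ----------
    parent:
        integer array, ``parent[0] == -1`` and ``parent[i] < i`` otherwise.
    length:
        branch length above each node (``length[0]`` ignored, kept 0).
        May contain NaN for topology-only trees.
    labels:
        node labels; required for tips, optional for internal nodes.
    """

    def __init__(self, parent, length, labels):
        self.parent = np.asarray(parent, dtype=int)
        self.length = np.asarray(length, dtype=float).copy()
        self.labels = list(labels)
        n = len(self.parent)
        if len(self.length) != n or len(self.labels) != n:
            raise ValidationError("parent/length/labels size mismatch")
        if n == 0 or self.parent[0] != -1:
            raise ValidationError("node 0 must be the root")
        if (self.parent[1:] >= np.arange(1, n)).any():
            raise ValidationError("nodes must be in preorder")
        self.length[0] = 0.0
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[self.parent[i]].append(i)
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        tip_idx = np.flatnonzero(self.is_tip)
        self.tip_indices = tip_idx
        self.tip_labels = [self.labels[i] for i in tip_idx]
        if any(lbl is None or lbl == "" for lbl in self.tip_labels):
            raise ValidationError("every tip must be labelled")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValidationError("tip labels must be unique")

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises assorted error classes
            raise ParseError(f"invalid newick: {exc}") from None
        return cls._from_dendropy(dtree)

    @classmethod
    def _from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, length, labels = [], [], []
        for nd in nodes:
            parent.append(-1 if nd.parent_node is None else index[id(nd.parent_node)])
            length.append(np.nan if nd.edge.length is None else float(nd.edge.length))
            if nd.taxon is not None:
                labels.append(nd.taxon.label)
            else:
                labels.append(nd.label)
        return cls(parent, length, labels)

    def to_newick(self, precision: int = 10) -> str:
        """Serialise with branch lengths at ``precision`` significant digits."""

        def fmt(i: int) -> str:
            if self.is_tip[i]:
                core = self.labels[i]
            else:
                core = "(" + ",".join(fmt(c) for c in self.children[i]) + ")"
                if self.labels[i]:
                    core += str(self.labels[i])
            if i != 0 and not math.isnan(self.length[i]):
                core += ":" + f"{self.length[i]:.{precision}g}"
            return core

        return fmt(0) + ";"

    # -------------------------------------------------------------- queries
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    def has_lengths(self) -> bool:
        return not np.isnan(self.length[1:]).any()

    def depths(self) -> np.ndarray:
        """Root-to-node distances (preorder accumulation)."""
        if not self.has_lengths():
            raise ValidationError("tree has missing branch lengths")
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            d[i] = d[self.parent[i]] + self.length[i]
        return d

    @property
    def height(self) -> float:
        return float(self.depths()[self.tip_indices].max())

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        tip_d = self.depths()[self.tip_indices]
        h = tip_d.max()
        if h == 0:
            return True
        return bool((tip_d.max() - tip_d.min()) <= tol * h)

    def is_binary_rooted(self) -> bool:
        return len(self.children[0]) == 2

    def clade_tips(self, node: int) -> list[str]:
        """Labels of all tips descending from (and including) ``node``."""
        out, stack = [], [node]
        while stack:
            i = stack.pop()
            if self.is_tip[i]:
                out.append(self.labels[i])
            else:
                stack.extend(self.children[i])
        return out

    def vcv(self, tip_order: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """Phylogenetic variance–covariance matrix over the tips.

        Returns ``(C, labels)`` with C in the order ``tip_order`` (defaults
        to the tree's own preorder tip order).
        """
        depth = self.depths()
        nt = self.n_tips
        pos = {int(node): k for k, node in enumerate(self.tip_indices)}
        C = np.zeros((nt, nt))
        tipsets: list[list[int] | None] = [None] * self.n_nodes
        for i in range(self.n_nodes - 1, -1, -1):
            if self.is_tip[i]:
                k = pos[i]
                tipsets[i] = [k]
                C[k, k] = depth[i]
            else:
                subsets = [tipsets[c] for c in self.children[i]]
                for a in range(len(subsets)):
                    for b in range(a + 1, len(subsets)):
                        ia, ib = np.ix_(subsets[a], subsets[b])
                        C[ia, ib] = depth[i]
                        C[ib, ia] = depth[i]
                tipsets[i] = [k for s in subsets for k in s]
        labels = list(self.tip_labels)
        if tip_order is not None:
            if sorted(tip_order) != sorted(labels):
                raise ValidationError("tip_order does not match tree tips")
            perm = [labels.index(t) for t in tip_order]
            C = C[np.ix_(perm, perm)]
            labels = list(tip_order)
        return C, labels

    def with_lengths(self, new_lengths) -> "Phylogeny":
        return Phylogeny(self.parent, new_lengths, self.labels)


def read_newick(path) -> Phylogeny:
    """Read a single rooted tree from a Newick file."""
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        from .errors import EmptyInputError

        raise EmptyInputError("empty input", path=path)
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny, path=None, precision: int = 10) -> str:
    """Serialise ``tree``; write to ``path`` when given, always return the text."""
    text = tree.to_newick(precision=precision) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def grafen_branch_lengths(tree: Phylogeny, rho: float = 1.0) -> Phylogeny:
    """Assign Grafen branch lengths to a rooted topology.

    Each node gets height ``((number of descendant tips) - 1) / (n - 1)``
    raised to the power ``rho``; tips sit at height 0 and each branch length
    is the height difference between parent and child.  The result depends
    only on the topology, so it gives a usable time axis for comparative
    methods when real divergence times are unavailable.
    """
    if rho <= 0:
        raise ValidationError("rho must be positive")
    if tree.n_tips < 2:
        raise ValidationError("need at least two tips")
    if len(tree.children[0]) > 2:
        raise ValidationError(
            "root has more than two children; supply a rooted (bifurcating-root) tree"
        )
    n = tree.n_tips
    ntips = np.zeros(tree.n_nodes, dtype=int)
    for i in range(tree.n_nodes - 1, -1, -1):
        if tree.is_tip[i]:
            ntips[i] = 1
        else:
            ntips[i] = sum(ntips[c] for c in tree.children[i])
    h = ((ntips - 1) / (n - 1)) ** rho
    new_len = np.zeros(tree.n_nodes)
    for i in range(1, tree.n_nodes):
        new_len[i] = h[tree.parent[i]] - h[i]
    return tree.with_lengths(new_len)


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (convenience wrapper)."""
    if not text.strip():
        from .errors import EmptyInputError

        raise EmptyInputError("empty input")
    return Phylogeny.from_newick(text)
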