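"""Rooted phylogenies, Newick I/O, and the Brownian-motion covariance matrix.

Every statistical stage of the package conditions on a rooted tree with
branch lengths.  The central quantity derived here is the phylogenetic
variance-covariance matrix ``C`` in which ``C[i, j]`` is the length of the
shared root-to-MRCA path of tips *i* and *j* — the among-species covariance
implied by Brownian-motion trait evolution.  Pagel's lambda rescales the
off-diagonal of ``C`` toward a star phylogeny.

Species order convention: tips are always listed in the order they are
encountered during a post-order traversal (equivalently, left-to-right in
the Newick string), so all matrices built from the same tree are
reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np
import pandas as pd


class NewickError(ValueError):
    """Raised when a Newick string cannot be parsed into a valid tree."""


class TreeError(ValueError):
    """Raised for structurally invalid trees or invalid tree operations."""


class Node:
    """One node of a rooted tree.

    ``length`` is the length of the branch connecting the node to its
    parent (``None`` only for a root with no root edge).
    """

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} length={self.length}>"


class Phylogeny:
    """A rooted phylogeny with branch lengths.

    Invariants enforced on construction: unique tip labels, non-negative
    branch lengths on all non-root edges, exactly one root.  Zero-length
    terminal branches are legal but flagged with a warning (they make the
    GLS covariance singular only if tips are duplicated, which is
    rejected outright).
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        seen: set[str] = set()
        zero_terminals: list[str] = []
        for node in self.postorder():
            if node is not self.root:
                if node.length is None:
                    raise TreeError(
                        f"missing branch length on node {node.label!r}"
                    )
                if node.length < 0:
                    raise TreeError(
                        f"negative branch length {node.length} on node {node.label!r}"
                    )
            if node.is_leaf:
                if not node.label:
                    raise TreeError("unlabeled tip")
                if node.label in seen:
                    raise TreeError(f"duplicate tip label {node.label!r}")
                seen.add(node.label)
                if node.length == 0:
                    zero_terminals.append(node.label)
        if zero_terminals:
            warnings.warn(
                "zero-length terminal branches on tips: "
                + ", ".join(sorted(zero_terminals)),
                stacklevel=3,
            )

    # -- traversal ------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        """Yield nodes in post-order (children before parents)."""
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def tips(self) -> list[Node]:
        """Tips in post-order encounter order (the package-wide species order)."""
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.postorder() if n.is_leaf)

    def internal_nodes(self) -> list[Node]:
        """Internal nodes in post-order (root last)."""
        return [n for n in self.postorder() if not n.is_leaf]

    def is_bifurcating(self) -> bool:
        return all(
            len(n.children) == 2 for n in self.postorder() if not n.is_leaf
        )

    # -- metrics --------------------------------------------------------

    def node_depths(self) -> dict[Node, float]:
        """Root-to-node path lengths (the root edge, if any, is excluded)."""
        depth: dict[Node, float] = {self.root: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            depth[node] = depth[node.parent] + node.length
        return depth

    def depths(self) -> dict[str, float]:
        nd = self.node_depths()
        return {n.label: nd[n] for n in self.tips()}

    @property
    def height(self) -> float:
        return max(self.depths().values())

    def patristic_distance(self, a: str, b: str) -> float:
        """Tip-to-tip path length along the tree."""
        by_label = {n.label: n for n in self.tips()}
        try:
            na, nb = by_label[a], by_label[b]
        except KeyError as err:
            raise TreeError(f"unknown tip label {err.args[0]!r}") from None
        anc_a: dict[Node, float] = {}
        d = 0.0
        node: Node | None = na
        while node is not None:
            anc_a[node] = d
            d += node.length or 0.0
            node = node.parent
        d = 0.0
        node = nb
        while node is not None:
            if node in anc_a:
                return anc_a[node] + d
            d += node.length or 0.0
            node = node.parent
        raise TreeError("disconnected tree")  # pragma: no cover

    def scale_to_height(self, height: float) -> "Phylogeny":
        """Return a copy with all branch lengths rescaled to the given tree height."""
        if height <= 0:
            raise TreeError("height must be positive")
        factor = height / self.height
        new = self.copy()
        for node in new.postorder():
            if node.length is not None:
                node.length *= factor
        return new

    # -- copy / io -------------------------------------------------------

    def copy(self) -> "Phylogeny":
        def clone(node: Node) -> Node:
            c = Node(node.label, node.length)
            for child in node.children:
                c.add_child(clone(child))
            return c

        return Phylogeny(clone(self.root))

    def write_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.label
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    s += node.label
            if node.length is not None:
                s += f":{node.length:.12g}"
            return s

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny with {self.n_tips} tips>"


def node_ids(tree: Phylogeny) -> dict[Node, str]:
    """Deterministic node labels: ``N{i}`` with ``i`` the post-order index.

    Shared by ancestral-state reconstruction outputs and the synthetic
    generator's ground-truth tables so node-level results can be joined.
    """
    return {node: f"N{i}" for i, node in enumerate(tree.postorder())}


def parse_newick(text: str) -> Phylogeny:
    """Parse a single rooted Newick tree with branch lengths.

    All non-root edges must carry branch lengths; the root edge is
    optional.  Unbalanced parentheses, duplicate tip labels, and missing
    branch lengths raise :class:`NewickError` naming the offending token.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as err:  # dendropy raises many exception classes
        raise NewickError(f"Newick parse error: {err}") from None

    def convert(dnode: dendropy.Node) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
        else:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    # enforce branch lengths everywhere except the (optional) root edge
    stack = list(root.children)
    while stack:
        node = stack.pop()
        if node.length is None:
            name = node.label or "(internal node)"
            raise NewickError(f"missing branch length on {name!r}")
        stack.extend(node.children)
    try:
        return Phylogeny(root)
    except TreeError as err:
        raise NewickError(str(err)) from None


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.write_newick() + "\n")


# ---------------------------------------------------------------------------
# Phylogenetic covariance
# ---------------------------------------------------------------------------


@dataclass
class PhyloCovariance:
    """Brownian-motion among-species covariance.

    ``matrix[i, j]`` is the shared root-to-MRCA path length of tips
    ``species[i]`` and ``species[j]``; the diagonal holds root-to-tip
    depths.  ``lam`` records the Pagel's-lambda rescaling applied (``None``
    for the untransformed matrix).
    """

    species: list[str]
    matrix: np.ndarray
    lam: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.species), len(self.species)):
            raise TreeError("covariance shape does not match species list")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.species, columns=self.species)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="species")

    def subset(self, taxa: Sequence[str]) -> "PhyloCovariance":
        idx = [self.species.index(t) for t in taxa]
        return PhyloCovariance(
            species=list(taxa),
            matrix=self.matrix[np.ix_(idx, idx)],
            lam=self.lam,
        )


def vcv_matrix(tree: Phylogeny) -> PhyloCovariance:
    """Phylogenetic variance-covariance matrix in post-order tip order."""
    tips = tree.tips()
    if len(tips) < 2:
        raise TreeError("vcv_matrix requires a tree with at least 2 tips")
    n = len(tips)
    index = {node: i for i, node in enumerate(tips)}
    depth = tree.node_depths()
    C = np.zeros((n, n))
    # tips below each node; cross-pairs between child subtrees share that node
    below: dict[Node, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            i = index[node]
            below[node] = [i]
            C[i, i] = depth[node]
        else:
            merged: list[int] = []
            for a_pos, child_a in enumerate(node.children):
                for child_b in node.children[a_pos + 1 :]:
                    for i in below[child_a]:
                        for j in below[child_b]:
                            C[i, j] = C[j, i] = depth[node]
                merged.extend(below[child_a])
            below[node] = merged
    return PhyloCovariance(species=[t.label for t in tips], matrix=C)


def lambda_transform(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda rescaling: off-diagonals multiplied by ``lam``.

    ``lam`` is restricted to [0, 1]; 1 is the identity, 0 yields a
    diagonal (star-phylogeny) matrix.  Keeping the upper bound at 1
    guarantees positive semidefiniteness for every tree.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    M = C.matrix * lam
    np.fill_diagonal(M, np.diag(C.matrix))
    return PhyloCovariance(species=list(C.species), matrix=M, lam=lam)


def prune_to_taxa(tree: Phylogeny, taxa: Iterable[str]) -> Phylogeny:
    """Induced subtree on ``taxa``; all path lengths between retained tips
    (and from the original root) are preserved exactly.

    The original root is kept so that root-to-tip depths — and hence the
    covariance matrix — subset exactly; internal degree-1 nodes are
    suppressed by summing branch lengths.
    """
    keep = set(taxa)
    present = set(tree.tip_labels)
    missing = sorted(keep - present)
    if missing:
        raise TreeError(f"taxa not in tree: {', '.join(missing)}")
    if len(keep) < 2:
        raise TreeError("pruning must retain at least 2 tips")

    def build(node: Node) -> Node | None:
        if node.is_leaf:
            if node.label in keep:
                return Node(node.label, node.length)
            return None
        kids = [c for c in (build(ch) for ch in node.children) if c is not None]
        if not kids:
            return None
        if len(kids) == 1 and node is not tree.root:
            # splice out degree-1 internal node
            kids[0].length = (kids[0].length or 0.0) + (node.length or 0.0)
            return kids[0]
        new = Node(node.label, node.length)
        for k in kids:
            new.add_child(k)
        return new

    root = build(tree.root)
    assert root is not None
    return Phylogeny(root)
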