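"""Rooted, topology-only trees and their combinatorial quantities.

All downstream statistics in this package (orthogram decomposition,
Abouheif proximity, parsimony reconstructions) consume only the topology
of a rooted tree: clade memberships, direct-descendant counts, node
complexities and tip-to-tip paths.  Branch lengths, if present in the
input Newick, are parsed and then discarded with a logged warning.

Nodes are integers assigned in preorder (root = 0, children visited in
the order they were written).  Internal nodes are indexed, everywhere in
the package, in decreasing order of node complexity ``np`` (the number
of descendant tips), ties broken by preorder rank, so that "basal"
columns come first in every derived matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Tree",
    "NewickError",
    "TreeStructureError",
    "read_newick",
    "write_newick",
    "clade_membership",
    "tip_path_internal_nodes",
    "direct_descendant_count",
    "prune_to_tips",
]


class NewickError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicates, ...)."""


class TreeStructureError(ValueError):
    """A tree violating the structural invariants of this package."""


@dataclass(frozen=True)
class Tree:
    """A rooted tree topology with labelled tips and no branch lengths.

    Parameters
    ----------
    root:
        Identifier of the root node.
    children:
        Map from internal node to the ordered tuple of its children.
        Tips do not appear as keys.
    parent:
        Map from node to its parent; the root maps to ``None``.
    tip_labels:
        Map from tip node to its unique, non-empty label.
    """

    root: int
    children: dict[int, tuple[int, ...]]
    parent: dict[int, int | None]
    tip_labels: dict[int, str]

    def __post_init__(self) -> None:
        nodes = set(self.parent)
        if self.parent.get(self.root, 0) is not None:
            raise TreeStructureError("root must have parent None")
        roots = [n for n, p in self.parent.items() if p is None]
        if roots != [self.root] and set(roots) != {self.root}:
            raise TreeStructureError(f"expected exactly one root, found {roots}")
        for node, kids in self.children.items():
            if len(kids) < 2:
                raise TreeStructureError(
                    f"internal node {node} has {len(kids)} child(ren); "
                    "every internal node must have at least 2"
                )
            for k in kids:
                if self.parent[k] != node:
                    raise TreeStructureError(f"parent/children maps disagree at {k}")
        tips = nodes - set(self.children)
        if tips != set(self.tip_labels):
            raise TreeStructureError("tip_labels must cover exactly the leaf nodes")
        labels = list(self.tip_labels.values())
        if any(not lab for lab in labels):
            raise TreeStructureError("empty tip label")
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeStructureError(f"duplicate tip labels: {dups}")

    # ------------------------------------------------------------------
    # derived structure (cached; the dataclass is frozen so these are safe)
    # ------------------------------------------------------------------

    @cached_property
    def preorder(self) -> tuple[int, ...]:
        """Nodes in preorder: root first, children in written order."""
        out: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(self.children.get(node, ())))
        return tuple(out)

    @cached_property
    def tips(self) -> tuple[int, ...]:
        """Tip nodes in left-to-right (preorder) order."""
        return tuple(n for n in self.preorder if n not in self.children)

    @cached_property
    def tip_order(self) -> tuple[str, ...]:
        """Tip labels in left-to-right order; the canonical trait alignment."""
        return tuple(self.tip_labels[t] for t in self.tips)

    @cached_property
    def tip_of_label(self) -> dict[str, int]:
        return {lab: t for t, lab in self.tip_labels.items()}

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @cached_property
    def node_np(self) -> dict[int, int]:
        """Node complexity np: number of descendant tips (tips have np 1)."""
        np_of: dict[int, int] = {}
        for node in reversed(self.preorder):
            kids = self.children.get(node)
            np_of[node] = 1 if kids is None else sum(np_of[k] for k in kids)
        return np_of

    @cached_property
    def internal_nodes(self) -> tuple[int, ...]:
        """Internal nodes sorted by decreasing np, ties by preorder rank."""
        rank = {n: i for i, n in enumerate(self.preorder)}
        return tuple(
            sorted(self.children, key=lambda v: (-self.node_np[v], rank[v]))
        )

    @cached_property
    def tips_below(self) -> dict[int, tuple[int, ...]]:
        """Map node -> descendant tips, in left-to-right order."""
        below: dict[int, tuple[int, ...]] = {}
        for node in reversed(self.preorder):
            kids = self.children.get(node)
            if kids is None:
                below[node] = (node,)
            else:
                below[node] = tuple(t for k in kids for t in below[k])
        return below

    @cached_property
    def _ancestors(self) -> dict[int, frozenset[int]]:
        """Internal (strict) ancestors of every node, including the root."""
        anc: dict[int, frozenset[int]] = {self.root: frozenset()}
        for node in self.preorder:
            for k in self.children.get(node, ()):
                anc[k] = anc[node] | {node}
        return anc

    def mrca(self, tip_a: int, tip_b: int) -> int:
        shared = (self._ancestors[tip_a] | {tip_a}) & (self._ancestors[tip_b] | {tip_b})
        depth = {n: len(self._ancestors.get(n, ())) for n in shared}
        return max(shared, key=lambda n: depth[n])


# ----------------------------------------------------------------------
# Newick I/O
# ----------------------------------------------------------------------


def read_newick(text: str) -> Tree:
    """Parse a single rooted Newick description into a :class:`Tree`.

    Branch lengths, if present, are dropped with a logged warning: every
    method in this package relies exclusively on topology.  Child order
    is preserved as written.  An unrooted-style basal trifurcation is
    accepted as a rooted tree whose root is the trifurcation.

    Raises
    ------
    NewickError
        On unbalanced parentheses, duplicate tip labels or an empty tree;
        the message names the offending position where the parser can.
    """
    text = text.strip()
    if not text:
        raise NewickError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises many subclasses with positions
        raise NewickError(f"Newick parse error: {exc}") from exc

    if any(nd.edge.length is not None for nd in dtree.preorder_node_iter()):
        logger.warning("branch lengths present in Newick input; ignored (topology-only methods)")

    children: dict[int, tuple[int, ...]] = {}
    parent: dict[int, int | None] = {}
    tip_labels: dict[int, str] = {}
    order = list(dtree.preorder_node_iter())
    ids = {nd: i for i, nd in enumerate(order)}
    for nd, i in ids.items():
        parent[i] = ids[nd.parent_node] if nd.parent_node is not None else None
        kids = nd.child_nodes()
        if kids:
            children[i] = tuple(ids[k] for k in kids)
        else:
            tip_labels[i] = nd.taxon.label if nd.taxon is not None else (nd.label or "")

    if not tip_labels:
        raise NewickError("empty tree: no tips found")
    if len(tip_labels) == 1:
        raise NewickError("tree with a single tip is not a valid topology")
    try:
        return Tree(root=0, children=children, parent=parent, tip_labels=tip_labels)
    except TreeStructureError as exc:
        raise NewickError(str(exc)) from exc


def write_newick(tree: Tree) -> str:
    """Serialize the topology (no branch lengths) back to Newick."""

    def render(node: int) -> str:
        kids = tree.children.get(node)
        if kids is None:
            return tree.tip_labels[node]
        return "(" + ",".join(render(k) for k in kids) + ")"

    return render(tree.root) + ";"


# ----------------------------------------------------------------------
# Combinatorial quantities
# ----------------------------------------------------------------------


def clade_membership(tree: Tree) -> np.ndarray:
    """0/1 matrix, tips x internal nodes: tip i descends from node v.

    Rows follow ``tree.tips`` (left-to-right); columns follow
    ``tree.internal_nodes`` (decreasing np).  The root column is all ones
    and every column sum equals the node's complexity np.
    """
    tip_index = {t: i for i, t in enumerate(tree.tips)}
    out = np.zeros((tree.n_tips, len(tree.internal_nodes)), dtype=int)
    for j, v in enumerate(tree.internal_nodes):
        for t in tree.tips_below[v]:
            out[tip_index[t], j] = 1
    return out


def tip_path_internal_nodes(tree: Tree, tip_a: str, tip_b: str) -> list[int]:
    """Internal nodes on the unique path between two tips, MRCA included.

    Tips are given by label.  The result is the symmetric difference of
    the two tips' ancestor sets plus their most recent common ancestor,
    ordered by decreasing np.
    """
    try:
        a = tree.tip_of_label[tip_a]
        b = tree.tip_of_label[tip_b]
    except KeyError as exc:
        raise KeyError(f"unknown tip label: {exc.args[0]!r}") from exc
    if a == b:
        raise ValueError("tip_a and tip_b must differ")
    anc_a, anc_b = tree._ancestors[a], tree._ancestors[b]
    nodes = (anc_a ^ anc_b) | {tree.mrca(a, b)}
    return sorted(nodes, key=lambda v: -tree.node_np[v])


def prune_to_tips(tree: Tree, labels) -> Tree:
    """Restrict the tree to the given tip labels, collapsing unifurcations.

    Internal nodes left with a single surviving child are removed; the
    relative order of retained tips is preserved.
    """
    keep = set(labels)
    unknown = keep - set(tree.tip_order)
    if unknown:
        raise KeyError(f"labels not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("pruning must retain at least 2 tips")

    def render(node: int) -> str | None:
        kids = tree.children.get(node)
        if kids is None:
            return tree.tip_labels[node] if tree.tip_labels[node] in keep else None
        parts = [r for r in (render(k) for k in kids) if r is not None]
        if not parts:
            return None
        if len(parts) == 1:
            return parts[0]
        return "(" + ",".join(parts) + ")"

    return read_newick(render(tree.root) + ";")


def direct_descendant_count(tree: Tree, node: int) -> int:
    """Number of immediate children of an internal node (dd, >= 2)."""
    if node not in tree.children:
        raise ValueError(f"node {node} is a tip; direct descendants undefined")
    return len(tree.children[node])
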