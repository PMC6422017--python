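"""Shared independent oracles: exhaustive tree enumeration and brute-force paths."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from cladesig.treeio import Tree


def set_partitions(items: list):
    """All partitions of a list into unordered non-empty blocks."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def all_rooted_trees(labels: list[str]):
    """Every rooted multifurcating topology on the labels, as Newick bodies."""
    if len(labels) == 1:
        yield labels[0]
        return
    for part in set_partitions(labels):
        if len(part) < 2:
            continue
        for combo in itertools.product(*(all_rooted_trees(b) for b in part)):
            yield "(" + ",".join(combo) + ")"


def all_rooted_newicks(n: int) -> list[str]:
    labels = [chr(ord("A") + i) for i in range(n)]
    return [body + ";" for body in all_rooted_trees(labels)]


def tree_graph(tree: Tree) -> nx.Graph:
    g = nx.Graph()
    for node, parent in tree.parent.items():
        if parent is not None:
            g.add_edge(parent, node)
    return g


def brute_proximity(tree: Tree) -> np.ndarray:
    """Abouheif proximity via graph shortest paths (independent of treeio paths)."""
    g = tree_graph(tree)
    n = tree.n_tips
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            path = nx.shortest_path(g, tree.tips[i], tree.tips[j])
            internal = [v for v in path if v in tree.children]
            w[i, j] = w[j, i] = np.prod([1.0 / len(tree.children[v]) for v in internal])
    np.fill_diagonal(w, 1.0 - w.sum(axis=1))
    return w


def brute_fitch_steps(tree: Tree, states: dict[str, int]) -> int:
    """Minimum changes over exhaustive internal-state enumeration."""
    internal = list(tree.children)
    tips = {t: states[tree.tip_labels[t]] for t in tree.tips}
    best = np.inf
    for combo in itertools.product((0, 1), repeat=len(internal)):
        assign = dict(zip(internal, combo)) | tips
        cost = sum(
            assign[v] != assign[k] for v in tree.children for k in tree.children[v]
        )
        best = min(best, cost)
    return int(best)
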