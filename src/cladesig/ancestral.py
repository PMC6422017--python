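"""Ancestral reconstruction on a fixed topology.

Continuous landmark configurations at internal nodes are chosen to
minimize the summed ancestor-descendant shape change over all branches
(the tree score).  Under the squared criterion this is squared-change
parsimony with unit branch weights: the optimum makes every internal
node the coordinate-wise mean of its tree neighbours, a sparse linear
system solved exactly.  The linear criterion (summed Frobenius
distances) is minimized by Weiszfeld-style iterations started from the
squared solution.

Discrete binary characters are optimized by Fitch/Hartigan parsimony,
valid on multifurcating trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treeio import Tree

__all__ = [
    "AncestralShapes",
    "DiscreteReconstruction",
    "reconstruct_landmarks",
    "fitch_optimize",
]


@dataclass(frozen=True)
class AncestralShapes:
    node_configs: dict[int, np.ndarray]  # internal node -> (k, 2) (or (k, d))
    tree_score: float
    criterion: str
    iterations: int


@dataclass(frozen=True)
class DiscreteReconstruction:
    state_sets: dict[int, frozenset[int]]
    steps: int
    assignment: dict[int, int]


def _branches(tree: Tree) -> list[tuple[int, int]]:
    return [(v, k) for v in tree.children for k in tree.children[v]]


def _score(tree: Tree, values: dict[int, np.ndarray], criterion: str) -> float:
    total = 0.0
    for a, d in _branches(tree):
        diff = values[a] - values[d]
        sq = float((diff**2).sum())
        total += sq if criterion == "squared" else np.sqrt(sq)
    return total


def reconstruct_landmarks(
    tree: Tree,
    tip_configs: dict[str, np.ndarray],
    criterion: str = "squared",
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> AncestralShapes:
    """Internal-node configurations minimizing total branch-wise change.

    Parameters
    ----------
    tree:
        Topology; all branches weighted equally.
    tip_configs:
        Map tip label -> (k, d) array, already superimposed (GPA output).
        Any d >= 1 is accepted; shape data use d = 2.
    criterion:
        ``"squared"`` (exact, unique optimum via the neighbour-mean
        linear system) or ``"linear"`` (Weiszfeld iterations from the
        squared solution, stopping when the score improves by < tol).
    """
    if criterion not in ("squared", "linear"):
        raise ValueError(f"unknown criterion {criterion!r}")
    missing = [lab for lab in tree.tip_order if lab not in tip_configs]
    if missing:
        raise ValueError(f"missing tip configurations: {missing}")
    shapes = {lab: np.atleast_2d(np.asarray(c, dtype=float)) for lab, c in tip_configs.items()}
    dims = {c.shape for c in shapes.values()}
    if len(dims) > 1:
        raise ValueError(f"inconsistent configuration shapes: {sorted(dims)}")
    shape = dims.pop()

    internal = list(tree.internal_nodes)
    idx = {v: i for i, v in enumerate(internal)}
    m = len(internal)
    tips_flat = {tree.tip_of_label[lab]: c.ravel() for lab, c in shapes.items()}

    # neighbour-mean normal equations: deg(v) X_v - sum_{internal u ~ v} X_u = sum_{tip t ~ v} X_t
    A = np.zeros((m, m))
    rhs = np.zeros((m, shape[0] * shape[1]))
    for v in internal:
        neighbours = list(tree.children[v])
        if tree.parent[v] is not None:
            neighbours.append(tree.parent[v])
        A[idx[v], idx[v]] = len(neighbours)
        for u in neighbours:
            if u in idx:
                A[idx[v], idx[u]] -= 1.0
            else:
                rhs[idx[v]] += tips_flat[u]
    sol = np.linalg.solve(A, rhs)
    values: dict[int, np.ndarray] = dict(tips_flat)
    for v in internal:
        values[v] = sol[idx[v]]

    iterations = 0
    if criterion == "linear":
        score = _score_flat(tree, values)
        for iterations in range(1, max_iter + 1):
            for v in internal:
                neighbours = list(tree.children[v])
                if tree.parent[v] is not None:
                    neighbours.append(tree.parent[v])
                num = np.zeros_like(values[v])
                den = 0.0
                at_neighbour = None
                for u in neighbours:
                    d = np.linalg.norm(values[v] - values[u])
                    if d < 1e-12:
                        at_neighbour = u
                        continue
                    num += values[u] / d
                    den += 1.0 / d
                if den > 0:
                    values[v] = num / den
                elif at_neighbour is not None:
                    values[v] = values[at_neighbour].copy()
            new_score = _score_flat(tree, values)
            if score - new_score < tol:
                score = new_score
                break
            score = new_score

    node_configs = {v: values[v].reshape(shape) for v in internal}
    full = {**{t: c.reshape(shape) for t, c in tips_flat.items()}, **node_configs}
    return AncestralShapes(
        node_configs=node_configs,
        tree_score=_score(tree, full, criterion),
        criterion=criterion,
        iterations=iterations,
    )


def _score_flat(tree: Tree, values: dict[int, np.ndarray]) -> float:
    return sum(
        float(np.linalg.norm(values[a] - values[d])) for a, d in _branches(tree)
    )


def fitch_optimize(tree: Tree, states: dict[str, int]) -> DiscreteReconstruction:
    """Most-parsimonious binary-character optimization (Fitch/Hartigan).

    Bottom-up, each internal node keeps the states attaining the maximal
    count over its children's sets and pays ``(#children - max count)``
    steps; on binary trees this is exactly Fitch's intersection/union
    rule.  Top-down, a node takes its parent's state when available,
    otherwise the smallest state in its set, yielding one
    most-parsimonious assignment.
    """
    missing = [lab for lab in tree.tip_order if lab not in states]
    if missing:
        raise ValueError(f"unscored tips: {missing}")
    bad = {lab: s for lab, s in states.items() if s not in (0, 1)}
    if bad:
        raise ValueError(f"states must be 0/1, got {bad}")

    state_sets: dict[int, frozenset[int]] = {}
    steps = 0
    for node in reversed(tree.preorder):
        kids = tree.children.get(node)
        if kids is None:
            state_sets[node] = frozenset({states[tree.tip_labels[node]]})
            continue
        counts = {s: sum(1 for k in kids if s in state_sets[k]) for s in (0, 1)}
        best = max(counts.values())
        state_sets[node] = frozenset(s for s in (0, 1) if counts[s] == best)
        steps += len(kids) - best

    assignment: dict[int, int] = {}
    for node in tree.preorder:
        options = state_sets[node]
        parent = tree.parent[node]
        if parent is not None and assignment[parent] in options:
            assignment[node] = assignment[parent]
        else:
            assignment[node] = min(options)
    return DiscreteReconstruction(state_sets=state_sets, steps=steps, assignment=assignment)
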