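"""Synthetic trees, traits and landmark datasets with known ground truth.

Every pipeline stage can be exercised end-to-end on data whose
phylogenetic structure is controlled: Yule (pure-birth) tree topologies,
Brownian-motion tip traits (strong phylogenetic signal) versus i.i.d.
Gaussian tip traits (no signal), and landmark configurations whose
coordinates evolve by independent Brownian motion from a base shape.
All edges carry implicit length one, matching the topology-only regime
of the analyses; all generators are deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

from .morphometry import LandmarkConfiguration
from .treeio import Tree

__all__ = [
    "simulate_tree",
    "random_polytomy_tree",
    "simulate_trait",
    "simulate_landmarks",
    "default_base_shape",
]


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_tree(n_tips: int, seed) -> Tree:
    """Yule topology: repeatedly split a uniformly chosen tip.

    Starting from a two-tip root, a uniformly random current tip is
    bifurcated until ``n_tips`` tips exist; labels ``t1..tn`` are then
    assigned to the tips in uniformly random order, so every labelled
    topology of a given shape is equally likely.
    """
    if n_tips < 3:
        raise ValueError(f"n_tips must be >= 3, got {n_tips}")
    rng = _as_rng(seed)
    children: dict[int, tuple[int, ...]] = {0: (1, 2)}
    parent: dict[int, int | None] = {0: None, 1: 0, 2: 0}
    tips = [1, 2]
    next_id = 3
    while len(tips) < n_tips:
        i = rng.integers(len(tips))
        node = tips[i]
        kids = (next_id, next_id + 1)
        children[node] = kids
        for k in kids:
            parent[k] = node
        tips[i] = kids[0]
        tips.append(kids[1])
        next_id += 2
    labels = [f"t{i + 1}" for i in range(n_tips)]
    perm = rng.permutation(n_tips)
    tip_labels = {tip: labels[perm[i]] for i, tip in enumerate(sorted(tips))}
    return Tree(root=0, children=children, parent=parent, tip_labels=tip_labels)


def random_polytomy_tree(n_tips: int, seed, contract_prob: float = 0.3) -> Tree:
    """Yule topology with random internal edges contracted into polytomies."""
    rng = _as_rng(seed)
    tree = simulate_tree(n_tips, rng)
    children = {v: list(k) for v, k in tree.children.items()}
    parent = dict(tree.parent)
    internal_edges = [
        (parent[v], v) for v in tree.children if parent[v] is not None
    ]
    for p, v in internal_edges:
        if rng.random() < contract_prob:
            # merge v into its (possibly already merged) current parent
            q = parent[v]
            pos = children[q].index(v)
            children[q][pos : pos + 1] = children[v]
            for k in children[v]:
                parent[k] = q
            del children[v]
            del parent[v]
    return Tree(
        root=tree.root,
        children={v: tuple(k) for v, k in children.items()},
        parent=parent,
        tip_labels=dict(tree.tip_labels),
    )


def simulate_trait(tree: Tree, trait_model: str, sigma: float, seed) -> np.ndarray:
    """Tip trait vector aligned with ``tree.tip_order``.

    ``brownian``: root value 0, each child adds N(0, sigma^2) per unit
    edge.  ``white_noise``: i.i.d. N(0, sigma^2) per tip, no structure.
    ``sigma = 0`` yields a constant trait, which downstream tests reject
    as degenerate input.
    """
    if trait_model not in ("brownian", "white_noise"):
        raise ValueError(f"unknown trait_model {trait_model!r}")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = _as_rng(seed)
    if trait_model == "white_noise":
        return rng.normal(0.0, sigma, size=tree.n_tips)
    values = {tree.root: 0.0}
    for node in tree.preorder:
        for k in tree.children.get(node, ()):
            values[k] = values[node] + rng.normal(0.0, sigma)
    return np.array([values[t] for t in tree.tips])


def default_base_shape(k_landmarks: int = 8) -> np.ndarray:
    """A non-degenerate base configuration: k points on the unit circle."""
    angles = 2 * np.pi * np.arange(k_landmarks) / k_landmarks
    return np.column_stack([np.cos(angles), np.sin(angles)])


def simulate_landmarks(
    tree: Tree, base_shape: np.ndarray, sigma: float, seed
) -> dict[str, LandmarkConfiguration]:
    """Landmark configurations evolving by per-coordinate Brownian motion.

    Every coordinate of every landmark follows an independent BM from
    the base shape down the tree (unit edges, per-edge sd ``sigma``).
    Returns a map from tip label to configuration; use
    :func:`cladesig.morphometry.write_tps` to persist as TPS.
    """
    base = np.asarray(base_shape, dtype=float)
    if base.ndim != 2 or base.shape[1] != 2 or base.shape[0] < 3:
        raise ValueError(f"base_shape must be (k >= 3, 2), got {base.shape}")
    # collinear landmarks leave rotation unidentifiable in GPA
    centered = base - base.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise ValueError("base_shape is degenerate (collinear landmarks)")
    rng = _as_rng(seed)
    values = {tree.root: base}
    for node in tree.preorder:
        for child in tree.children.get(node, ()):
            values[child] = values[node] + rng.normal(0.0, sigma, size=base.shape)
    return {
        tree.tip_labels[t]: LandmarkConfiguration(
            specimen_id=tree.tip_labels[t], coords=values[t]
        )
        for t in tree.tips
    }
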