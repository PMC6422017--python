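"""Abouheif's C-mean: autocorrelation of a tip trait on a cladogram.

The C-mean is Moran's index computed with a phylogenetic proximity
matrix derived from topology alone.  The proximity between two tips is
the product of the inverses of the direct-descendant counts of every
internal node on the path joining them (their most recent common
ancestor included); the diagonal is filled so each row sums to one,
giving a symmetric bistochastic matrix with a non-null diagonal.  The
null hypothesis (C mean = 0, no autocorrelation) is tested by permuting
trait values across tips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treeio import Tree, tip_path_internal_nodes

__all__ = ["ProximityMatrix", "CmeanResult", "abouheif_proximity", "c_mean", "c_mean_test"]


@dataclass(frozen=True)
class ProximityMatrix:
    """Symmetric tips x tips proximity with rows summing to one."""

    w: np.ndarray
    tip_order: tuple[str, ...]


@dataclass(frozen=True)
class CmeanResult:
    c_mean: float
    pvalue: float
    n_perm: int
    seed: int
    perm_mean: float
    perm_sd: float
    perm_quantiles: dict[str, float]


def abouheif_proximity(tree: Tree) -> ProximityMatrix:
    """Topological proximity matrix (the non-null-diagonal variant).

    ``w_ij = prod over internal nodes v on the i<->j path of 1/dd(v)``
    for ``i != j``, with ``dd`` the direct-descendant count; the
    diagonal is the complement ``1 - sum_j w_ij``, which is provably
    non-negative for any rooted tree under this path definition.
    """
    n = tree.n_tips
    if n < 3:
        raise ValueError(f"proximity requires >= 3 tips, got {n}")
    labels = tree.tip_order
    dd = {v: len(kids) for v, kids in tree.children.items()}
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            path = tip_path_internal_nodes(tree, labels[i], labels[j])
            w[i, j] = w[j, i] = np.prod([1.0 / dd[v] for v in path])
    diag = 1.0 - w.sum(axis=1)
    if np.any(diag < -1e-12):
        raise AssertionError("negative diagonal: path definition violated")
    np.fill_diagonal(w, np.clip(diag, 0.0, None))
    return ProximityMatrix(w=w, tip_order=labels)


def c_mean(x: np.ndarray, w: ProximityMatrix) -> float:
    """C = (z' W z) / (z' z) with z the centered trait."""
    x = np.asarray(x, dtype=float)
    if x.shape != (len(w.tip_order),):
        raise ValueError(f"trait length {x.shape} does not match {len(w.tip_order)} tips")
    z = x - x.mean()
    denom = z @ z
    if denom == 0 or not np.isfinite(denom):
        raise ValueError("trait is constant (zero variance) or non-finite")
    return float(z @ w.w @ z / denom)


def c_mean_test(
    x: np.ndarray, tree: Tree, n_perm: int = 999, seed: int = 0
) -> CmeanResult:
    """Upper-tail permutation test of C mean = 0 (no autocorrelation).

    Phylogenetic signal manifests as positive autocorrelation, so only
    the upper tail is tested; the add-one estimator avoids zero p.
    """
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    w = abouheif_proximity(tree)
    obs = c_mean(x, w)
    rng = np.random.default_rng(seed)
    z = np.asarray(x, dtype=float)
    z = z - z.mean()
    denom = z @ z
    perms = np.array([rng.permutation(z) for _ in range(n_perm)])
    null = np.einsum("ij,jk,ik->i", perms, w.w, perms) / denom
    p = float((1 + np.sum(null >= obs)) / (n_perm + 1))
    qs = np.quantile(null, [0.025, 0.5, 0.975])
    return CmeanResult(
        c_mean=obs,
        pvalue=p,
        n_perm=n_perm,
        seed=seed,
        perm_mean=float(null.mean()),
        perm_sd=float(null.std(ddof=1)),
        perm_quantiles={"2.5%": float(qs[0]), "50%": float(qs[1]), "97.5%": float(qs[2])},
    )
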