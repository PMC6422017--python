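"""Orthonormal decomposition of a tip trait's variance across tree nodes.

The orthogram asks where on a rooted tree the variance of a quantitative
trait is concentrated.  From the topology alone, a basis of ``n - 1``
orthonormal contrast vectors is built, one subspace per internal node
(a node with ``m`` children contributes ``m - 1`` Helmert-style
contrasts between its child clades).  A standardized trait vector is
projected on this basis; the squared coefficients ``R2_k`` sum to one
and measure the share of variance attributable to each node-level
contrast.  Four summary statistics condense the profile:

``R2Max``
    the largest single squared coefficient — variance concentrated at
    one node;
``SkR2k``
    ``sum_k k * R2_k`` with columns ordered from basal (high np) to
    terminal — skewness of the decomposition toward root or tips;
``Dmax``
    the Kolmogorov–Smirnov-style maximal deviation of the cumulative
    decomposition from the uniform diagonal;
``SCE``
    the sum of squared cumulative deviations.

Significance is assessed by Monte-Carlo permutation of trait values
across tips, which is exact under the null of exchangeability (no
phylogenetic autocorrelation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .treeio import Tree

__all__ = [
    "Orthobasis",
    "OrthogramResult",
    "build_orthobasis",
    "decompose_trait",
    "orthogram_statistics",
    "orthogram_test",
    "significant_nodes",
]

STAT_NAMES = ("R2Max", "SkR2k", "Dmax", "SCE")

#: Tail convention per statistic.  R2Max, Dmax and SCE grow with any
#: departure from uniformity, hence upper-tailed; SkR2k can shift either
#: way (variance skewed toward root or toward tips), hence two-sided.
STAT_TAILS = {"R2Max": "upper", "SkR2k": "two-sided", "Dmax": "upper", "SCE": "upper"}


@dataclass(frozen=True)
class Orthobasis:
    """Orthonormal topological contrasts: tips x (n - 1) matrix.

    Column ``j`` belongs to internal node ``node_of_column[j]``; columns
    are ordered by decreasing node complexity ``np_of_column[j]`` (ties
    by preorder), within a node by child index.  ``B.T @ B = I`` and
    every column is orthogonal to the all-ones vector.
    """

    vectors: np.ndarray
    node_of_column: np.ndarray
    np_of_column: np.ndarray
    tip_order: tuple[str, ...]

    @property
    def n_columns(self) -> int:
        return self.vectors.shape[1]


@dataclass(frozen=True)
class OrthogramResult:
    """Observed decomposition plus its Monte-Carlo null summary."""

    r2: np.ndarray
    cumulative: np.ndarray
    stats: dict[str, float]
    pvalues: dict[str, float]
    r2_upper_envelope: np.ndarray
    cumulative_envelope: np.ndarray  # (2, B): lower and upper quantiles
    node_of_column: np.ndarray
    np_of_column: np.ndarray
    n_perm: int
    seed: int
    alpha: float
    tails: dict[str, str] = field(default_factory=lambda: dict(STAT_TAILS))


def build_orthobasis(tree: Tree) -> Orthobasis:
    """Build the n-1 column orthonormal basis from the tree topology.

    For an internal node with ordered children ``c_1 .. c_m``, columns
    ``j = 2 .. m`` contrast the pooled tips of ``c_1 .. c_{j-1}``
    (value ``a``) against the tips of ``c_j`` (value ``b``), zero
    elsewhere, with ``a, b`` fixed by centering and unit norm.  Nested
    supports make all columns exactly orthonormal by construction.
    """
    n = tree.n_tips
    if n < 3:
        raise ValueError(f"orthobasis requires >= 3 tips, got {n}")
    tip_index = {t: i for i, t in enumerate(tree.tips)}
    cols: list[np.ndarray] = []
    node_of: list[int] = []
    for v in tree.internal_nodes:
        kids = tree.children[v]
        left: list[int] = []
        for j in range(1, len(kids)):
            left.extend(tip_index[t] for t in tree.tips_below[kids[j - 1]])
            right = [tip_index[t] for t in tree.tips_below[kids[j]]]
            n1, n2 = len(left), len(right)
            col = np.zeros(n)
            col[left] = np.sqrt(n2 / (n1 * (n1 + n2)))
            col[right] = -np.sqrt(n1 / (n2 * (n1 + n2)))
            cols.append(col)
            node_of.append(v)
    vectors = np.column_stack(cols)
    node_of_column = np.asarray(node_of)
    np_of_column = np.asarray([tree.node_np[v] for v in node_of])
    return Orthobasis(vectors, node_of_column, np_of_column, tree.tip_order)


def _standardize(x: np.ndarray) -> np.ndarray:
    """Center and scale to unit Euclidean norm; reject constant input."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    norm = np.linalg.norm(xc)
    if norm == 0 or not np.isfinite(norm):
        raise ValueError("trait is constant (zero variance) or non-finite")
    return xc / norm


def decompose_trait(x: np.ndarray, basis: Orthobasis) -> np.ndarray:
    """Squared projection coefficients R2_k of the standardized trait.

    ``x`` must be aligned with ``basis.tip_order``.  The returned vector
    is non-negative and sums to one (Parseval: the basis spans the full
    centered subspace).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (len(basis.tip_order),):
        raise ValueError(
            f"trait length {x.shape} does not match {len(basis.tip_order)} tips"
        )
    xs = _standardize(x)
    return (basis.vectors.T @ xs) ** 2


def orthogram_statistics(r2: np.ndarray) -> dict[str, float]:
    """The four orthogram summary statistics of an R2 profile."""
    r2 = np.asarray(r2, dtype=float)
    if abs(r2.sum() - 1.0) > 1e-8:
        raise ValueError(f"R2 profile must sum to 1, got {r2.sum():.6g}")
    return {k: float(v[0]) for k, v in _stats_matrix(r2[None, :]).items()}


def _stats_matrix(r2: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized statistics for a stack of R2 profiles (rows)."""
    B = r2.shape[1]
    k = np.arange(1, B + 1)
    cum = np.cumsum(r2, axis=1)
    uniform = k / B
    dev = cum - uniform
    return {
        "R2Max": r2.max(axis=1),
        "SkR2k": r2 @ k,
        "Dmax": np.abs(dev).max(axis=1),
        "SCE": (dev**2).sum(axis=1),
    }


def _perm_pvalues(
    obs: dict[str, float], null: dict[str, np.ndarray], n_perm: int
) -> dict[str, float]:
    """Add-one permutation p-values under the per-statistic tail rules."""
    pvals: dict[str, float] = {}
    for name in STAT_NAMES:
        upper = (1 + np.sum(null[name] >= obs[name])) / (n_perm + 1)
        if STAT_TAILS[name] == "upper":
            pvals[name] = float(upper)
        else:
            lower = (1 + np.sum(null[name] <= obs[name])) / (n_perm + 1)
            pvals[name] = float(min(1.0, 2.0 * min(upper, lower)))
    return pvals


def orthogram_test(
    x: np.ndarray,
    tree: Tree,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> OrthogramResult:
    """Orthogram decomposition with Monte-Carlo permutation inference.

    Parameters
    ----------
    x:
        Trait values aligned with ``tree.tip_order``.
    n_perm:
        Number of random permutations of ``x`` across tips (>= 99).
    seed:
        Seed for the permutation stream; results are bit-reproducible.
    alpha:
        Level for the pointwise envelopes (upper R2 envelope at
        ``1 - alpha``; bilateral cumulative envelope at
        ``alpha/2, 1 - alpha/2``).
    """
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    basis = build_orthobasis(tree)
    r2 = decompose_trait(x, basis)
    obs = {k: float(v[0]) for k, v in _stats_matrix(r2[None, :]).items()}

    rng = np.random.default_rng(seed)
    xs = _standardize(np.asarray(x, dtype=float))
    perms = np.array([rng.permutation(xs) for _ in range(n_perm)])
    r2_null = (perms @ basis.vectors) ** 2
    null = _stats_matrix(r2_null)
    pvalues = _perm_pvalues(obs, null, n_perm)

    cum_null = np.cumsum(r2_null, axis=1)
    return OrthogramResult(
        r2=r2,
        cumulative=np.cumsum(r2),
        stats=obs,
        pvalues=pvalues,
        r2_upper_envelope=np.quantile(r2_null, 1 - alpha, axis=0),
        cumulative_envelope=np.quantile(cum_null, [alpha / 2, 1 - alpha / 2], axis=0),
        node_of_column=basis.node_of_column,
        np_of_column=basis.np_of_column,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
    )


def significant_nodes(result: OrthogramResult) -> list[tuple[int, float]]:
    """Nodes whose observed R2_k exceeds the pointwise upper envelope.

    Returns ``(node, R2_k)`` pairs sorted by decreasing R2_k; a node
    owning several contrast columns (polytomy) may appear once per
    exceeding column.
    """
    hits = [
        (int(result.node_of_column[k]), float(result.r2[k]))
        for k in np.flatnonzero(result.r2 > result.r2_upper_envelope)
    ]
    return sorted(hits, key=lambda pair: -pair[1])
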