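"""Monte-Carlo calibration and power studies of the signal tests.

These helpers drive the full stack on synthetic datasets: for each
replicate a fresh Yule topology is drawn, a trait (or landmark set) is
simulated under either Brownian motion (signal) or white noise (no
signal), and the permutation tests are run at level ``alpha``.  The
permutation null is exact under exchangeability, so white-noise
rejection rates estimate the realized type-I error and Brownian-motion
rates estimate power.
"""

from __future__ import annotations

import numpy as np

from .abouheif import c_mean_test
from .morphometry import LandmarkConfiguration, gpa, shape_pca
from .orthogram import STAT_NAMES, orthogram_test, significant_nodes
from .pipeline import verdict
from .synthetic import default_base_shape, simulate_landmarks, simulate_trait, simulate_tree

__all__ = ["trait_rejection_rates", "landmark_screen_rates"]


def trait_rejection_rates(
    trait_model: str,
    n_datasets: int = 500,
    n_tips: int = 32,
    n_perm: int = 999,
    alpha: float = 0.05,
    sigma: float = 1.0,
    seed: int = 0,
) -> dict[str, float]:
    """Rejection rate of each orthogram statistic and of the C-mean.

    Each dataset is an independent Yule tree plus a simulated trait;
    returns the fraction of datasets with p < alpha per statistic.
    """
    ss = np.random.SeedSequence(seed)
    rejections = {name: 0 for name in (*STAT_NAMES, "Cmean")}
    for child in ss.spawn(n_datasets):
        rng = np.random.default_rng(child)
        tree = simulate_tree(n_tips, rng)
        x = simulate_trait(tree, trait_model, sigma, rng)
        perm_seed = int(rng.integers(2**31))
        og = orthogram_test(x, tree, n_perm=n_perm, seed=perm_seed, alpha=alpha)
        cm = c_mean_test(x, tree, n_perm=n_perm, seed=perm_seed)
        for name in STAT_NAMES:
            rejections[name] += og.pvalues[name] < alpha
        rejections["Cmean"] += cm.pvalue < alpha
    return {name: count / n_datasets for name, count in rejections.items()}


def landmark_screen_rates(
    trait_model: str,
    n_datasets: int = 100,
    n_tips: int = 32,
    k_landmarks: int = 8,
    n_perm: int = 999,
    alpha: float = 0.05,
    sigma: float = 0.1,
    seed: int = 0,
) -> dict[str, float]:
    """End-to-end screen on simulated landmark data.

    Per replicate: simulate landmarks (Brownian on the tree, or white
    noise around the base shape), run GPA + shape PCA, test PC1 with
    the orthogram and the C-mean, and record the combined verdict.
    Returns the "signal" verdict rate, plus the mean complexity np of
    envelope-exceeding nodes relative to the mean np over all columns
    (values > 1 mean flagged nodes are basal).
    """
    ss = np.random.SeedSequence(seed)
    signal_count = 0
    np_ratio_sum, np_ratio_n = 0.0, 0
    base = default_base_shape(k_landmarks)
    for child in ss.spawn(n_datasets):
        rng = np.random.default_rng(child)
        tree = simulate_tree(n_tips, rng)
        if trait_model == "brownian":
            configs = simulate_landmarks(tree, base, sigma, rng)
        else:
            configs = {
                lab: LandmarkConfiguration(lab, base + rng.normal(0.0, sigma, size=base.shape))
                for lab in tree.tip_order
            }
        aligned = gpa([configs[lab] for lab in tree.tip_order])
        pc1 = shape_pca(aligned).scores[:, 0]
        perm_seed = int(rng.integers(2**31))
        og = orthogram_test(pc1, tree, n_perm=n_perm, seed=perm_seed, alpha=alpha)
        cm = c_mean_test(pc1, tree, n_perm=n_perm, seed=perm_seed)
        if verdict(og, cm, alpha) == "signal":
            signal_count += 1
        flagged = significant_nodes(og)
        if flagged:
            mean_np_flagged = np.mean([_np_of(og, n) for n, _ in flagged])
            np_ratio_sum += mean_np_flagged / og.np_of_column.mean()
            np_ratio_n += 1
    out = {"signal_rate": signal_count / n_datasets}
    out["flagged_np_ratio"] = np_ratio_sum / np_ratio_n if np_ratio_n else float("nan")
    return out


def _np_of(result, node: int) -> int:
    pos = np.flatnonzero(result.node_of_column == node)[0]
    return int(result.np_of_column[pos])
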