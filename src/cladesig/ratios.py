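"""Skull-proportion ratios and nonparametric group comparisons.

The ratio of basicranium length (bsL) to total skull length (stL)
describes the proportional length of the basicranium; differences
between subfamilies are assessed with the Kruskal-Wallis rank test and
pairwise two-sided Wilcoxon rank-sum tests under Holm step-down
adjustment.  Specimens lacking stL (incomplete fossils) are dropped
with a logged count.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["GroupTestResult", "compute_ratios", "kruskal_wallis", "pairwise_wilcoxon"]


@dataclass(frozen=True)
class GroupTestResult:
    kw_h: float
    kw_df: int
    kw_pvalue: float
    pairwise: dict[tuple[str, str], float]
    adjustment: str


def compute_ratios(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-specimen bsL/stL ratios and per-species mean ratios.

    ``table`` needs columns ``specimen_id, species, subfamily, bsL, stL``.
    Rows with missing stL (or bsL) are dropped and counted; nonpositive
    measurements raise, naming the specimen.
    """
    required = {"specimen_id", "species", "subfamily", "bsL", "stL"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"missing columns: {sorted(missing_cols)}")
    df = table.copy()
    complete = df["bsL"].notna() & df["stL"].notna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d incomplete specimens (missing bsL/stL)", n_dropped)
    df = df[complete].copy()
    bad = df[(df["bsL"] <= 0) | (df["stL"] <= 0)]
    if len(bad):
        raise ValueError(
            f"nonpositive measurements for specimens: {sorted(bad['specimen_id'])}"
        )
    over = df[df["bsL"] > df["stL"]]
    if len(over):
        raise ValueError(
            f"bsL exceeds stL for specimens: {sorted(over['specimen_id'])}"
        )
    df["ratio"] = df["bsL"] / df["stL"]
    species_means = (
        df.groupby(["species", "subfamily"], as_index=False)["ratio"]
        .mean()
        .rename(columns={"ratio": "mean_ratio"})
    )
    return df, species_means


def kruskal_wallis(groups: dict[str, np.ndarray]) -> tuple[float, int, float]:
    """Kruskal-Wallis H (tie-corrected), df and chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    sizes = {g: len(v) for g, v in groups.items()}
    small = [g for g, n in sizes.items() if n < 2]
    if small:
        raise ValueError(f"groups with < 2 values: {small}")
    values = [np.asarray(v, dtype=float) for v in groups.values()]
    pooled = np.concatenate(values)
    if np.all(pooled == pooled[0]):
        # all observations tied: no evidence of any difference
        return 0.0, len(groups) - 1, 1.0
    h, p = stats.kruskal(*values)
    return float(h), len(groups) - 1, float(p)


def pairwise_wilcoxon(
    groups: dict[str, np.ndarray], adjustment: str = "holm"
) -> GroupTestResult:
    """Two-sided rank-sum test per unordered pair, multiplicity-adjusted.

    The exact null distribution is used when both groups have <= 12
    observations and the pooled data are tie-free; otherwise the normal
    approximation with tie correction.  Adjusted p-values are clipped
    to be >= raw p-values by construction of the step-down method.
    """
    for g, v in groups.items():
        if len(v) == 0:
            raise ValueError(f"empty group: {g}")
    names = sorted(groups)
    pairs = list(itertools.combinations(names, 2))
    raw = []
    for a, b in pairs:
        xa = np.asarray(groups[a], dtype=float)
        xb = np.asarray(groups[b], dtype=float)
        pooled = np.concatenate([xa, xb])
        if np.all(pooled == pooled[0]):
            raw.append(1.0)
            continue
        exact = len(xa) <= 12 and len(xb) <= 12 and len(np.unique(pooled)) == len(pooled)
        res = stats.mannwhitneyu(
            xa, xb, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        raw.append(min(1.0, float(res.pvalue)))
    adjusted = multipletests(raw, method=adjustment)[1] if pairs else []
    kw = kruskal_wallis(groups)
    return GroupTestResult(
        kw_h=kw[0],
        kw_df=kw[1],
        kw_pvalue=kw[2],
        pairwise={pair: float(p) for pair, p in zip(pairs, adjusted)},
        adjustment=adjustment,
    )
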