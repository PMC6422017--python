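"""Orchestration: signal screen, ancestral reconstruction, ratios, report.

The screen runs, per trait variable, the orthogram decomposition and
the Abouheif C-mean test on the same tree and permutation budget, then
issues a per-variable verdict: "signal" when at least two of the four
orthogram statistics are significant at ``alpha`` or the C-mean is,
"no signal" otherwise.  Individual p-values are always reported so a
different combination rule can be applied downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .abouheif import CmeanResult, c_mean_test
from .ancestral import fitch_optimize, reconstruct_landmarks
from .orthogram import (
    STAT_NAMES,
    OrthogramResult,
    orthogram_test,
    significant_nodes,
)
from .ratios import compute_ratios, pairwise_wilcoxon
from .treeio import Tree, prune_to_tips

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "VariableReport", "run_signal_screen", "run_full", "verdict"]


@dataclass
class PipelineConfig:
    variables: tuple[str, ...] = ("PC1", "PC2", "PC3", "PC4", "PC5", "CS")
    n_perm: int = 999
    alpha: float = 0.05
    seed: int = 0
    criterion: str = "squared"
    adjustment: str = "holm"
    tip_policy: str = "strict"  # or "prune"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_perm < 99:
            raise ValueError(f"n_perm must be >= 99, got {self.n_perm}")
        if self.tip_policy not in ("strict", "prune"):
            raise ValueError(f"unknown tip_policy {self.tip_policy!r}")


@dataclass(frozen=True)
class VariableReport:
    variable: str
    orthogram: OrthogramResult
    cmean: CmeanResult
    significant_nodes: list[tuple[int, float]]
    verdict: str


def verdict(orthogram: OrthogramResult, cmean: CmeanResult, alpha: float) -> str:
    """Combined call: >= 2 significant orthogram statistics OR C-mean."""
    n_sig = sum(orthogram.pvalues[s] < alpha for s in STAT_NAMES)
    return "signal" if (n_sig >= 2 or cmean.pvalue < alpha) else "no signal"


def _reconcile(tree: Tree, traits: pd.DataFrame, policy: str) -> tuple[Tree, pd.DataFrame]:
    tree_tips = set(tree.tip_order)
    table_tips = set(traits.index)
    if tree_tips == table_tips:
        return tree, traits.loc[list(tree.tip_order)]
    if policy == "strict":
        only_tree = sorted(tree_tips - table_tips)
        only_table = sorted(table_tips - tree_tips)
        raise ValueError(
            "tip labels do not match trait table "
            f"(tree-only: {only_tree}; table-only: {only_table})"
        )
    shared = tree_tips & table_tips
    if len(shared) < 3:
        raise ValueError(f"fewer than 3 shared tips after pruning: {sorted(shared)}")
    logger.info(
        "pruned to %d shared tips (dropped from tree: %s; from table: %s)",
        len(shared),
        sorted(tree_tips - shared),
        sorted(table_tips - shared),
    )
    pruned = prune_to_tips(tree, shared)
    return pruned, traits.loc[list(pruned.tip_order)]


def run_signal_screen(
    tree: Tree, traits: pd.DataFrame, config: PipelineConfig
) -> dict[str, VariableReport]:
    """Orthogram + C-mean per variable; traits indexed by tip label.

    Sub-seeds for the per-variable permutation streams are spawned
    deterministically from ``config.seed``.
    """
    missing = [v for v in config.variables if v not in traits.columns]
    if missing:
        raise ValueError(f"variables absent from trait table: {missing}")
    tree, traits = _reconcile(tree, traits, config.tip_policy)
    reports: dict[str, VariableReport] = {}
    for i, var in enumerate(config.variables):
        x = traits[var].to_numpy(dtype=float)
        sub_seed = int((config.seed + 1) * 100_003 + i) % (2**31)
        og = orthogram_test(x, tree, config.n_perm, sub_seed, config.alpha)
        cm = c_mean_test(x, tree, config.n_perm, sub_seed)
        reports[var] = VariableReport(
            variable=var,
            orthogram=og,
            cmean=cm,
            significant_nodes=significant_nodes(og),
            verdict=verdict(og, cm, config.alpha),
        )
    return reports


def summary_table(reports: dict[str, VariableReport]) -> pd.DataFrame:
    """One row per variable: statistics, p-values and the verdict."""
    rows = []
    for var, rep in reports.items():
        row: dict[str, object] = {"variable": var}
        for s in STAT_NAMES:
            row[s] = rep.orthogram.stats[s]
            row[f"p_{s}"] = rep.orthogram.pvalues[s]
        row["Cmean"] = rep.cmean.c_mean
        row["p_Cmean"] = rep.cmean.pvalue
        row["n_significant_nodes"] = len(rep.significant_nodes)
        row["verdict"] = rep.verdict
        rows.append(row)
    return pd.DataFrame(rows)


def run_full(
    tree: Tree,
    traits: pd.DataFrame,
    config: PipelineConfig,
    tip_configs: dict[str, np.ndarray] | None = None,
    habitat: dict[str, int] | None = None,
    ratio_table: pd.DataFrame | None = None,
) -> dict:
    """Signal screen plus optional ancestral, habitat and ratio stages.

    Returns a JSON-serializable report bundle stamped with seed, n_perm
    and package version; stages with absent inputs are skipped and
    marked as such.
    """
    bundle: dict = {
        "software_version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "alpha": config.alpha,
        "criterion": config.criterion,
        "adjustment": config.adjustment,
    }
    reports = run_signal_screen(tree, traits, config)
    bundle["signal"] = {
        var: {
            "stats": rep.orthogram.stats,
            "pvalues": rep.orthogram.pvalues,
            "tails": rep.orthogram.tails,
            "c_mean": rep.cmean.c_mean,
            "p_cmean": rep.cmean.pvalue,
            "significant_nodes": [
                {"node": n, "r2": r, "np": int(_np_of(rep.orthogram, n))}
                for n, r in rep.significant_nodes
            ],
            "verdict": rep.verdict,
        }
        for var, rep in reports.items()
    }

    if tip_configs is not None:
        anc = reconstruct_landmarks(tree, tip_configs, criterion=config.criterion)
        bundle["ancestral"] = {
            "tree_score": anc.tree_score,
            "criterion": anc.criterion,
            "nodes": {str(v): c.tolist() for v, c in anc.node_configs.items()},
        }
    if habitat is not None:
        fitch = fitch_optimize(tree, habitat)
        bundle["habitat"] = {
            "steps": fitch.steps,
            "assignment": {str(n): s for n, s in fitch.assignment.items()},
        }
    if ratio_table is not None:
        per_specimen, species_means = compute_ratios(ratio_table)
        groups = {
            g: sub["ratio"].to_numpy()
            for g, sub in per_specimen.groupby("subfamily")
        }
        gt = pairwise_wilcoxon(groups, adjustment=config.adjustment)
        bundle["ratios"] = {
            "kw_h": gt.kw_h,
            "kw_df": gt.kw_df,
            "kw_pvalue": gt.kw_pvalue,
            "pairwise": {f"{a}|{b}": p for (a, b), p in gt.pairwise.items()},
            "adjustment": gt.adjustment,
            "species_means": {
                r.species: r.mean_ratio for r in species_means.itertuples()
            },
        }
    return bundle


def _np_of(result: OrthogramResult, node: int) -> int:
    pos = np.flatnonzero(result.node_of_column == node)[0]
    return int(result.np_of_column[pos])


def write_report(bundle: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
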