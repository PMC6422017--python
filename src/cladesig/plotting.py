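"""Diagnostic plots: orthogram, cumulative orthogram, null histograms.

All functions take a matplotlib Axes (or create one) and return it, so
they compose into multi-panel figures; file output is left to the
caller or the CLI.
"""

from __future__ import annotations

import numpy as np

from .abouheif import CmeanResult
from .orthogram import OrthogramResult


def orthogram_plot(result: OrthogramResult, ax=None):
    """Bars of R2 per column (basal to terminal) with the upper envelope."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pos = np.arange(1, len(result.r2) + 1)
    ax.bar(pos, result.r2, color="0.6", edgecolor="black")
    ax.step(pos, result.r2_upper_envelope, where="mid", linestyle="--", color="black")
    ax.axhline(1.0 / len(result.r2), color="black", linewidth=0.8)
    ax.set_xlabel("contrast column (decreasing node complexity np)")
    ax.set_ylabel("R²")
    return ax


def cumulative_orthogram_plot(result: OrthogramResult, ax=None):
    """Observed cumulative decomposition against the uniform diagonal."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    B = len(result.r2)
    pos = np.arange(1, B + 1)
    ax.plot([0, B], [0, 1], color="black", linewidth=0.8)
    ax.plot(pos, result.cumulative, "o", color="black", markerfacecolor="white")
    for row in result.cumulative_envelope:
        ax.plot(pos, row, linestyle="--", color="black", linewidth=0.8)
    ax.set_xlabel("contrast column")
    ax.set_ylabel("cumulative R²")
    return ax


def cmean_plot(result: CmeanResult, null_sample=None, ax=None):
    """Observed C-mean against its permutation-null summary."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if null_sample is not None:
        ax.hist(null_sample, bins=30, color="0.8", edgecolor="black")
    ax.axvline(result.c_mean, color="black")
    ax.plot([result.c_mean], [0], "ko")
    ax.set_xlabel("C mean")
    ax.set_title(f"C = {result.c_mean:.3f}, p = {result.pvalue:.3f}")
    return ax


def ratio_boxplot(groups: dict[str, np.ndarray], ax=None):
    """Per-group boxplot (quartile boxes, 1.5-IQR whiskers, outliers)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    names = sorted(groups)
    ax.boxplot([groups[g] for g in names], tick_labels=names, whis=1.5)
    ax.set_ylabel("bsL / stL")
    return ax
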