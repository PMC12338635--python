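"""Superplot rendering: per-focus dots, replicate-mean triangles, grand mean ± SEM."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .quant import ReplicateSummary

__all__ = ["superplot"]


def superplot(
    quant: pd.DataFrame,
    summary: ReplicateSummary,
    value_col: str = "normalized_value",
    ax: plt.Axes | None = None,
    jitter: float = 0.18,
    seed: int = 0,
):
    """Hierarchical dot plot of normalized per-centromere intensities.

    Circles: individual centromere foci (jittered).  Triangles: the mean of
    each biological replicate — the values on which statistics are run.
    Horizontal line and error bar: grand mean ± SEM over replicate means.
    """
    if ax is None:
        fig, ax = plt.subplots(figsize=(1.3 * summary.conditions.shape[0] + 1.5, 4))
    else:
        fig = ax.figure
    rng = np.random.default_rng(seed)
    conditions = list(summary.conditions["condition"])
    cmap = plt.get_cmap("tab10")
    for i, condition in enumerate(conditions):
        sub = quant[quant["condition"] == condition]
        x = i + rng.uniform(-jitter, jitter, size=len(sub))
        ax.scatter(x, sub[value_col], s=8, alpha=0.35, color="#4878a8",
                   linewidths=0, zorder=1)
        reps = summary.replicates
        reps_c = reps[reps["condition"] == condition]
        for j, row in enumerate(reps_c.itertuples(index=False)):
            ax.scatter(i, row.replicate_mean, marker="^", s=60,
                       color=cmap(j % 10), edgecolor="black", zorder=3)
        cond_row = summary.conditions[summary.conditions["condition"] == condition]
        gm = float(cond_row["grand_mean"].iloc[0])
        sem = float(cond_row["sem"].iloc[0])
        ax.hlines(gm, i - 0.3, i + 0.3, color="black", linewidth=1.8, zorder=4)
        ax.errorbar(i, gm, yerr=sem, color="black", capsize=4, zorder=4)
    ax.set_xticks(range(len(conditions)))
    ax.set_xticklabels(conditions, rotation=30, ha="right")
    ax.set_ylabel("normalized centromeric intensity")
    ax.axhline(1.0, color="grey", linewidth=0.6, linestyle="--", zorder=0)
    fig.tight_layout()
    return fig
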