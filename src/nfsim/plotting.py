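"""Figure helpers for session summaries and the hypothesis battery."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_session_summary", "plot_battery_heatmap"]


def plot_session_summary(summary: pd.DataFrame, value: str = "nf_value", ax=None):
    """Per-session means of a summary column, one line per target level."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for tl, group in summary.groupby("target_level"):
        means = group.groupby("session")[value].mean()
        ax.plot(means.index, means.values, marker="o", label=f"TL {tl}")
    if value == "nf_value":
        for y in (6, 9):
            ax.axhline(y, color="grey", lw=0.6, ls="--")
    ax.set_xlabel("session")
    ax.set_ylabel(value)
    ax.set_xticks(sorted(summary["session"].unique()))
    ax.legend()
    return ax


def plot_battery_heatmap(battery: pd.DataFrame, ax=None):
    """Hypotheses x level heat table of posterior probabilities.

    Red below 0.5, white at 0.5, blue toward 1; asterisks mark
    probabilities above 0.95.
    """
    table = battery.pivot(index="hypothesis", columns="level", values="probability")
    cols = ["group"] + [c for c in table.columns if c != "group"]
    table = table[cols]
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * len(cols), 0.4 * len(table) + 1))
    im = ax.imshow(table.values, cmap="RdBu", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(np.arange(len(cols)), labels=[str(c) for c in cols], rotation=45)
    ax.set_yticks(np.arange(len(table)), labels=table.index)
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            v = table.values[i, j]
            mark = "*" if v > 0.95 else ""
            ax.text(j, i, f"{v:.2f}{mark}", ha="center", va="center", fontsize=7)
    plt.colorbar(im, ax=ax, label="posterior probability")
    return ax
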