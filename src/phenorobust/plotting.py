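"""Basic plot exports: robustness bars per function and trade-off scatters.

Deliberately unstyled — these are working plots for inspection, not
publication figures.
"""

from __future__ import annotations

import numpy as np


def plot_robustness_bars(robustness_results, ax=None):
    """Grouped bar chart of R per strain within each function, with SEM
    error bars."""
    import matplotlib.pyplot as plt

    df = robustness_results.table
    if ax is None:
        _, ax = plt.subplots(figsize=(1.6 * df["function"].nunique() + 2, 4))
    functions = list(df["function"].unique())
    strains = list(df["strain"].unique())
    width = 0.8 / max(len(strains), 1)
    for k, strain in enumerate(strains):
        sub = df[df["strain"] == strain].set_index("function").reindex(functions)
        x = np.arange(len(functions)) + k * width
        ax.bar(x, sub["R"], width=width, yerr=sub["sem"], capsize=2, label=strain)
    ax.set_xticks(np.arange(len(functions)) + 0.4 - width / 2)
    ax.set_xticklabels(functions, rotation=30, ha="right")
    ax.set_ylabel(f"robustness R ({df['metric'].iloc[0]})")
    ax.axhline(0, color="k", lw=0.5)
    ax.legend(fontsize="small")
    return ax


def plot_tradeoffs(tradeoff_df, ax=None):
    """Scatter of robustness versus mean performance, one panel-worth of
    points per function (marker) and strain (color)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    markers = "osD^vP*Xh"
    functions = list(tradeoff_df["function"].unique())
    strains = list(tradeoff_df["strain"].unique())
    colors = plt.get_cmap("tab10")
    for fi, function in enumerate(functions):
        for si, strain in enumerate(strains):
            sub = tradeoff_df[
                (tradeoff_df["function"] == function) & (tradeoff_df["strain"] == strain)
            ]
            if sub.empty:
                continue
            ax.errorbar(
                sub["performance"], sub["robustness"],
                xerr=sub["performance_sem"], yerr=sub["robustness_sem"],
                fmt=markers[fi % len(markers)], color=colors(si % 10),
                label=f"{strain} / {function}", ms=5, capsize=2, lw=0.8,
            )
    ax.set_xlabel("mean performance (function units)")
    ax.set_ylabel("robustness R")
    ax.legend(fontsize="x-small", ncols=2)
    return ax
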