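"""Figure export: bracketed strain maps and study-level plots."""

from __future__ import annotations

import numpy as np
from matplotlib import pyplot as plt
from matplotlib.colors import BoundaryNorm, ListedColormap

from .strain import BRACKET_COLORS, DEFAULT_BRACKET_EDGES, StrainField

__all__ = ["plot_strain_map", "plot_condition_boxes", "plot_strain_vs_pressure"]


def plot_strain_map(strain: StrainField, ax=None, brackets: bool = True,
                    edges=DEFAULT_BRACKET_EDGES, point_size: float = 14.0):
    """Scatter the strain magnitude field, bracketed or continuous.

    The five-bracket palette (blue/green/yellow/magenta/red) highlights
    local regions of high strain on absolute plots; ``brackets=False``
    uses a continuous colormap instead.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.2))
    v = strain.valid
    x, y = strain.points[v, 0], strain.points[v, 1]
    s = strain.S_MAG[v]
    if brackets:
        cmap = ListedColormap(BRACKET_COLORS)
        norm = BoundaryNorm(list(edges) + [np.inf], cmap.N)
        sc = ax.scatter(x, y, c=s, cmap=cmap, norm=norm, s=point_size,
                        marker="s", linewidths=0)
        cbar = plt.colorbar(sc, ax=ax, ticks=list(edges))
        cbar.set_label("S_MAG bracket (%)")
        cbar.ax.set_yticklabels([f"{e:g}" for e in edges])
    else:
        sc = ax.scatter(x, y, c=s, cmap="viridis", s=point_size,
                        marker="s", linewidths=0)
        plt.colorbar(sc, ax=ax, label="S_MAG (%)")
    ax.set_aspect("equal")
    ax.set_xlabel("AP (mm)")
    ax.set_ylabel("ML (mm)")
    return ax


def plot_condition_boxes(table, value_col="peak_smag_pct", ax=None):
    """Boxplots of per-participant median regional peaks by condition."""
    import pandas as pd

    per = (table[table.region != "global"]
           .groupby(["region", "condition", "participant"])[value_col]
           .median().reset_index())
    regions = list(dict.fromkeys(per.region))
    conditions = list(dict.fromkeys(per.condition))
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    w = 0.8 / len(conditions)
    for j, cond in enumerate(conditions):
        data = [per[(per.region == r) & (per.condition == cond)][value_col].values
                for r in regions]
        pos = np.arange(len(regions)) + (j - (len(conditions) - 1) / 2) * w
        ax.boxplot(data, positions=pos, widths=w * 0.9,
                   patch_artist=True,
                   boxprops={"facecolor": f"C{j}", "alpha": 0.6},
                   medianprops={"color": "black"})
    ax.set_xticks(np.arange(len(regions)))
    ax.set_xticklabels(regions, rotation=45, ha="right")
    ax.set_ylabel(value_col)
    ax.legend([plt.Rectangle((0, 0), 1, 1, fc=f"C{j}", alpha=0.6)
               for j in range(len(conditions))], conditions)
    return ax


def plot_strain_vs_pressure(table, condition="flat", ax=None):
    """Scatter of repeat-averaged regional peak strain vs peak pressure."""
    sub = table[table.condition == condition]
    m = (sub.groupby(["participant", "region"])[["peak_smag_pct", "ppp_kpa"]]
         .mean().dropna().reset_index())
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for pid, g in m.groupby("participant"):
        ax.scatter(g.peak_smag_pct, g.ppp_kpa, label=pid, s=18)
    ax.set_xlabel("peak S_MAG (%)")
    ax.set_ylabel("PPP (kPa)")
    ax.legend(fontsize=8)
    return ax
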