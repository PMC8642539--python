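"""Figure helpers: stacked KDE depth profiles and per-organoid boxplots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_stacked_kde", "plot_distance_boxes"]


def plot_stacked_kde(grid: np.ndarray, curves: dict, path=None, ax=None):
    """Stack unit-area KDE curves of cell depth, one per organoid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    offset = 0.0
    step = 1.1 * max(c.max() for c in curves.values())
    for name, dens in curves.items():
        ax.fill_between(grid, offset, offset + dens, alpha=0.6, label=str(name))
        offset += step
    ax.set_xlabel("distance to organoid surface (µm)")
    ax.set_ylabel("stacked density")
    ax.set_yticks([])
    ax.legend(fontsize=7, loc="upper right")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_distance_boxes(table: pd.DataFrame, path=None, ax=None,
                        value_col: str = "normalized_distance_um"):
    """Boxplot per organoid (cells as points), grouped by treatment."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    order = table[["organoid_id", "group"]].drop_duplicates()
    data = [table.loc[table["organoid_id"] == oid, value_col].to_numpy()
            for oid in order["organoid_id"]]
    ax.boxplot(data, tick_labels=order["organoid_id"], showfliers=False)
    rng = np.random.default_rng(0)
    for i, vals in enumerate(data, start=1):
        ax.scatter(i + rng.uniform(-0.15, 0.15, len(vals)), vals, s=4,
                   alpha=0.5)
    ax.set_ylabel(f"{value_col.replace('_', ' ')}")
    ax.tick_params(axis="x", rotation=60, labelsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
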