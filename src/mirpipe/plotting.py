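"""Figure helpers: expression heatmap and cross-species correlation grid."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .expression import hierarchical_cluster

__all__ = ["plot_ratio_heatmap", "plot_spearman_grid"]


def plot_ratio_heatmap(ratio_matrix: pd.DataFrame, path: str | Path) -> None:
    """Clustered heatmap of log2 stage-ratio profiles (rows reordered by the
    complete-linkage dendrogram)."""
    if len(ratio_matrix) >= 2:
        order, _ = hierarchical_cluster(ratio_matrix)
        ratio_matrix = ratio_matrix.loc[order]
    fig, ax = plt.subplots(
        figsize=(1.2 + 0.5 * ratio_matrix.shape[1], 1.5 + 0.22 * len(ratio_matrix))
    )
    vmax = max(1.0, np.nanmax(np.abs(ratio_matrix.to_numpy())))
    im = ax.imshow(ratio_matrix.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(ratio_matrix.shape[1]), ratio_matrix.columns,
                  rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(len(ratio_matrix)), ratio_matrix.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="log2 ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_spearman_grid(grid: pd.DataFrame, path: str | Path) -> None:
    """Bubble grid of per-library-pair Spearman rho (size and colour encode
    correlation strength)."""
    libs_a = sorted(grid.library_a.unique())
    libs_b = sorted(grid.library_b.unique())
    fig, ax = plt.subplots(figsize=(1.5 + 0.6 * len(libs_b), 1.5 + 0.6 * len(libs_a)))
    for _, row in grid.iterrows():
        if not row.get("defined", True) or np.isnan(row.rho):
            continue
        x = libs_b.index(row.library_b)
        y = libs_a.index(row.library_a)
        ax.scatter(x, y, s=600 * abs(row.rho), c=[row.rho], cmap="RdBu_r",
                   vmin=-1, vmax=1, edgecolors="k", linewidths=0.3)
    ax.set_xticks(range(len(libs_b)), libs_b, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(len(libs_a)), libs_a, fontsize=7)
    ax.set_xlim(-0.5, len(libs_b) - 0.5)
    ax.set_ylim(len(libs_a) - 0.5, -0.5)
    sm = plt.cm.ScalarMappable(cmap="RdBu_r", norm=plt.Normalize(-1, 1))
    fig.colorbar(sm, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
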