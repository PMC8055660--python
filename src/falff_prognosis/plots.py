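"""Figures for the battery-structure analysis (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster import hierarchy

from .battery import AssociationMatrix, Dendrogram

__all__ = ["plot_tau_heatmap", "plot_dendrogram"]


def plot_tau_heatmap(assoc: AssociationMatrix, path: str | Path) -> None:
    """Shaded correlation matrix: red positive, blue negative tau."""
    p = len(assoc.measures)
    fig, ax = plt.subplots(figsize=(max(6, p * 0.3),) * 2)
    im = ax.imshow(assoc.tau, cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(np.arange(p), assoc.measures, rotation=90, fontsize=7)
    ax.set_yticks(np.arange(p), assoc.measures, fontsize=7)
    fig.colorbar(im, ax=ax, label="Kendall tau-b")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dendrogram(dendro: Dendrogram, path: str | Path) -> None:
    """Association dendrogram with correlation distance as height."""
    fig, ax = plt.subplots(figsize=(max(6, len(dendro.labels) * 0.35), 4))
    hierarchy.dendrogram(dendro.linkage, labels=dendro.labels, ax=ax,
                         leaf_rotation=90, leaf_font_size=7)
    ax.set_ylabel("correlation distance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
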