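"""Cosmetic SVG rendering of correlation heatmaps and dendrograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy.cluster.hierarchy import dendrogram

from cytonet.network import CorrelationMatrix, WardClustering


def plot_correlation_heatmap(corr: CorrelationMatrix, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.markers)), corr.markers, rotation=90, fontsize=7)
    ax.set_yticks(range(len(corr.markers)), corr.markers, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r (log10 scale)")
    title = f"day {corr.day}" if corr.day is not None else "controls"
    ax.set_title(f"Mediator correlations, {title}")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def plot_dendrogram(clustering: WardClustering, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    if len(clustering.markers) >= 2:
        dendrogram(
            clustering.linkage_matrix,
            labels=clustering.markers,
            color_threshold=clustering.cut_height,
            ax=ax,
        )
        ax.axhline(clustering.cut_height, ls="--", c="grey", lw=0.8)
    ax.set_ylabel("Ward height on 1 - r")
    ax.tick_params(axis="x", labelrotation=90, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
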