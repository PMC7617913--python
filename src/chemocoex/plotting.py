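"""Basic inspection plots (correlation heatmap, PCA scatter).

These are convenience renderings for eyeballing a run, not
publication-grade heatmap graphics.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from chemocoex.clustering import PcaResult


def plot_correlation_heatmap(
    corr: pd.DataFrame, order: list[str] | None = None, path: str | Path = "correlation.png"
) -> Path:
    """Render the gene-gene correlation matrix (optionally in dendrogram order)."""
    m = corr.loc[order, order] if order else corr
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(m.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(m)), m.columns, rotation=90, fontsize=4)
    ax.set_yticks(range(len(m)), m.index, fontsize=4)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_pca(pca: PcaResult, labels=None, path: str | Path = "pca.png") -> Path:
    """Scatter genes on PC1/PC2, optionally coloured by cluster label."""
    s = pca.scores
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(s.iloc[:, 0], s.iloc[:, 1], c=labels, cmap="tab10", s=18)
    evr = pca.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)")
    if s.shape[1] > 1:
        ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
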