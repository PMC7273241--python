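"""Optional figure export for study reports (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .models import labels_to_int


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def roc_curve_plot(scores, labels, path: str | Path) -> Path:
    """ROC curve of AF scores (AF positive)."""
    from sklearn.metrics import roc_curve

    plt = _pyplot()
    y = labels_to_int(np.asarray(labels))
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr)
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def decile_bars_plot(decile_df: pd.DataFrame, metric: str, path: str | Path) -> Path:
    """Bar chart of per-decile sensitivity or specificity."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(decile_df["decile"], decile_df[metric])
    ax.set_xlabel("decile")
    ax.set_ylabel(metric)
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def embedding_scatter_plot(embedding: pd.DataFrame, path: str | Path, hue: str = "label") -> Path:
    """2-D feature-embedding scatter colored by label or a statistic."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(4.5, 4))
    if embedding[hue].dtype.kind in "OU":
        for val, grp in embedding.groupby(hue):
            ax.scatter(grp["x"], grp["y"], s=6, label=str(val), alpha=0.7)
        ax.legend(frameon=False)
    else:
        sc = ax.scatter(embedding["x"], embedding["y"], c=embedding[hue], s=6, cmap="viridis")
        fig.colorbar(sc, ax=ax, label=hue)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
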