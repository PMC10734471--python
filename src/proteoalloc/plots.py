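"""Basic figures: PCA scatter of samples and per-class allocation bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .model import SampleDesign
from .ordination import PCAResult

__all__ = ["pca_scatter", "class_allocation_bars"]


def pca_scatter(result: PCAResult, design: SampleDesign, path: str | Path) -> Path:
    """Scatter of the first two PC scores, colored by condition."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4))
    scores = result.scores
    for condition in design.conditions:
        samples = design.samples_for(condition)
        sub = scores.loc[samples]
        ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], label=condition, s=40)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)")
    if scores.shape[1] > 1:
        ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def class_allocation_bars(
    class_table: pd.DataFrame, design: SampleDesign, path: str | Path, top: int = 7
) -> Path:
    """Grouped bars of per-condition mean class mass fractions (top classes)."""
    path = Path(path)
    means = pd.DataFrame(
        {
            cond: class_table[design.samples_for(cond)].mean(axis=1)
            for cond in design.conditions
        }
    )
    means = means.drop(index=[i for i in ("unannotated",) if i in means.index])
    order = means.mean(axis=1).sort_values(ascending=False).index[:top]
    fig, ax = plt.subplots(figsize=(6, 4))
    means.loc[order].plot.bar(ax=ax)
    ax.set_ylabel("proteome mass fraction")
    ax.set_xlabel("KOG class")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
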