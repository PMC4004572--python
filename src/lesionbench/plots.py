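"""Figure rendering: pROC panels, gray-scale agreement heatmaps, weight maps."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .evaluation import AgreementMatrix, ROCCurve


def plot_proc_curves(curves: Mapping[str, ROCCurve], path: str | Path,
                     fpr_max: float = 0.10, title: str = "") -> Path:
    """Partial ROC curves for several methods, chance diagonal for reference."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, c in curves.items():
        ax.plot(c.fpr, c.tpr, label=label, lw=1.2)
    ax.plot([0, fpr_max], [0, fpr_max], "k--", lw=0.8, label="chance")
    ax.set_xlim(0, fpr_max)
    ax.set_ylim(0, 1)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_agreement(matrix: AgreementMatrix, path: str | Path, title: str = "") -> Path:
    """Gray-scale pairwise-Dice heatmap (darker = higher agreement)."""
    t = matrix.table
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(t.to_numpy(), cmap="Greys", vmin=0, vmax=1)
    ax.set_xticks(range(len(t)), t.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(t)), t.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Dice")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_weight_heatmap(weights: pd.DataFrame, path: str | Path, title: str = "") -> Path:
    """Super-learner weights vs training-set size (rows: n_voxels)."""
    pivot = weights.pivot_table(index="n_voxels", columns="learner",
                                values="weight", fill_value=0.0)
    fig, ax = plt.subplots(figsize=(max(6, 0.25 * pivot.shape[1]), 4))
    im = ax.imshow(pivot.to_numpy(), cmap="Greys", aspect="auto", vmin=0)
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(pivot.shape[0]), pivot.index, fontsize=7)
    ax.set_ylabel("training voxels")
    fig.colorbar(im, ax=ax, label="weight")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
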