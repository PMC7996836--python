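"""Optional figure helpers (require matplotlib).

CSV/JSON artifacts are the canonical outputs; these write convenience
images only.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .classify import ImportanceReport
from .rsa import SimilarityMatrix

__all__ = ["plot_similarity_heatmap", "plot_importance_bars"]


def plot_similarity_heatmap(matrix: SimilarityMatrix, path, group_labels=None) -> Path:
    """Participant x participant Pearson-r heatmap, groups delimited."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.r, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(matrix.participant_ids)))
    ax.set_yticks(range(len(matrix.participant_ids)))
    ax.set_xticklabels(matrix.participant_ids, rotation=90, fontsize=6)
    ax.set_yticklabels(matrix.participant_ids, fontsize=6)
    if group_labels is not None:
        labels = [group_labels[p] for p in matrix.participant_ids]
        for i in range(1, len(labels)):
            if labels[i] != labels[i - 1]:
                ax.axhline(i - 0.5, color="k", lw=1)
                ax.axvline(i - 0.5, color="k", lw=1)
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title("CE-profile similarity")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_importance_bars(report: ImportanceReport, path) -> Path:
    """Per-channel permutation importance with mean and bootstrap 95% CI."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    x = np.arange(len(report.channel_names))
    ax.bar(x, report.mean_importance, yerr=report.sd_importance, color="tab:blue")
    ax.axhline(report.overall_mean, color="green", lw=1, label="mean importance")
    ax.axhline(report.ci_low, color="red", lw=1, ls="--", label="95% CI")
    ax.axhline(report.ci_high, color="red", lw=1, ls="--")
    ax.set_xticks(x)
    ax.set_xticklabels(report.channel_names, rotation=90, fontsize=7)
    ax.set_ylabel("LOO accuracy drop")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
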