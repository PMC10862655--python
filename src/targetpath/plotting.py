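"""Plotting helpers: per-disease metric boxplots, PR curves and the
five-criteria target-card heatmap."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import InputError
from .prioritize import CRITERIA, cards_frame

__all__ = ["plot_metric_boxplots", "plot_pr_curves", "plot_card_heatmap"]


def plot_metric_boxplots(results: dict, metric: str = "avep", path=None):
    """Boxplots of a per-disease metric for several methods.

    *results* maps method name -> EvaluationResult.
    """
    if not results:
        raise InputError("results must be non-empty")
    names = list(results)
    data = [results[n].per_disease[metric].values for n in names]
    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(names), 3.2))
    ax.boxplot(data, tick_labels=names)
    ax.set_ylabel(metric)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_pr_curves(curves: dict, path=None):
    """Precision-recall curves; *curves* maps label -> list of
    (recall, precision) points."""
    if not curves:
        raise InputError("curves must be non-empty")
    fig, ax = plt.subplots(figsize=(4, 3.4))
    for label, pts in curves.items():
        rec = [r for r, _p in pts]
        prec = [p for _r, p in pts]
        ax.plot(rec, prec, label=label)
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_card_heatmap(cards, path=None):
    """Heatmap of the five criterion scores, one row per target card
    (higher intensity = higher rating)."""
    frame = cards_frame(cards)
    if frame.empty:
        raise InputError("cards must be non-empty")
    mat = frame[list(CRITERIA)].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(4.2, 0.32 * len(frame) + 1.2))
    im = ax.imshow(mat, vmin=0, vmax=1, cmap="Blues", aspect="auto")
    ax.set_xticks(np.arange(len(CRITERIA)),
                  labels=[c.replace("_", "\n") for c in CRITERIA], fontsize=7)
    ax.set_yticks(np.arange(len(frame)), labels=frame.gene, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
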