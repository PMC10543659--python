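"""Matplotlib figures for histograms, ROC curves, confusion matrices and
selection scores. All functions return the Figure and optionally save it."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .features import RegionHistogram
from .model import EvalReport, SelectionResult

__all__ = [
    "plot_region_histograms",
    "plot_roc",
    "plot_confusion",
    "plot_importance",
]


def _finish(fig, path):
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_region_histograms(histograms: list[RegionHistogram], path=None, title=None):
    """Bar plots of per-region LBP code histograms for one slice."""
    n = len(histograms)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3), squeeze=False)
    for ax, h in zip(axes[0], histograms):
        ax.bar(np.arange(len(h.counts)), h.counts, color="#4878d0")
        ax.set_title(f"region {h.region_index}")
        ax.set_xlabel("riu2 code")
        ax.set_ylabel("count")
    if title:
        fig.suptitle(title)
    return _finish(fig, path)


def plot_roc(report: EvalReport, path=None, label=None):
    fig, ax = plt.subplots(figsize=(4, 4))
    if report.roc_points:
        fpr, tpr = zip(*report.roc_points)
        ax.plot(fpr, tpr, marker="o", label=label or f"AUC = {report.auc_roc:.2f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    return _finish(fig, path)


def plot_confusion(report: EvalReport, path=None):
    mat = np.array([[report.tn, report.fp], [report.fn, report.tp]])
    fig, ax = plt.subplots(figsize=(3.5, 3.2))
    ax.imshow(mat, cmap="Blues")
    for i in range(2):
        for j in range(2):
            ax.text(j, i, str(mat[i, j]), ha="center", va="center")
    ax.set_xticks([0, 1], ["pred healthy", "pred patient"])
    ax.set_yticks([0, 1], ["healthy", "patient"])
    return _finish(fig, path)


def plot_importance(selection: SelectionResult, top: int = 15, path=None):
    """Horizontal bars of the top RFE importance scores (best at top)."""
    frame = selection.frame().head(top)[::-1]
    fig, ax = plt.subplots(figsize=(5, 0.3 * len(frame) + 1.2))
    ax.barh(frame["feature"], frame["importance_score"], color="#4878d0")
    ax.set_xlabel("importance score")
    ax.set_xlim(0, 1.02)
    return _finish(fig, path)
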