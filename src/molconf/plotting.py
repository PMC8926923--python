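"""Evaluation plots: ROC curves, hop plots, Q-Q calibration plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .fdr import RankedHitList, hop_curve, qq_estimated_vs_exact, roc_curve

__all__ = ["plot_roc", "plot_hop", "plot_qq"]


def plot_roc(hits: RankedHitList, path: str | Path | None = None, ax=None):
    fpr, tpr, auc_val = roc_curve(hits)
    ax = ax or plt.figure(figsize=(4, 4)).gca()
    ax.plot(fpr, tpr, label=f"AUC = {auc_val:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8, label="random (AUC 0.5)")
    ax.set_xlabel("false positive rate FP/(FP+TN)")
    ax.set_ylabel("true positive rate TP/(TP+FN)")
    ax.legend(loc="lower right")
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_hop(hits: RankedHitList, path: str | Path | None = None, ax=None):
    """Hop plot: TP/N vs FP/N; the endpoint (x, y) satisfies x + y = 1."""
    x, y = hop_curve(hits)
    ax = ax or plt.figure(figsize=(4, 4)).gca()
    ax.plot(x, y)
    ax.plot([0, x[-1]], [0, y[-1]], ls="--", c="grey", lw=0.8, label="random ordering")
    ax.plot([0, 1], [1, 0], ls=":", c="grey", lw=0.8)
    ax.set_xlabel("incorrect hits / N")
    ax.set_ylabel("correct hits / N")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right")
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_qq(hits: RankedHitList, path: str | Path | None = None, ax=None):
    """Estimated vs exact q values; points above the diagonal are conservative."""
    pairs = qq_estimated_vs_exact(hits)
    ax = ax or plt.figure(figsize=(4, 4)).gca()
    ax.scatter(pairs["q_exact"], pairs["q_estimate"], s=6)
    lim = max(pairs["q_exact"].max(), pairs["q_estimate"].max(), 0.01)
    ax.plot([0, lim], [0, lim], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("exact q value")
    ax.set_ylabel("estimated q value")
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
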