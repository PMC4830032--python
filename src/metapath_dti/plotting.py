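"""Matplotlib helpers for evaluation reports (optional extra).

Requires matplotlib (``pip install metapath-dti[plot]``).
"""

from __future__ import annotations

import numpy as np

from .models import EvalReport, ImportanceReport


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_roc_pr(reports: dict[str, EvalReport], path=None):
    """ROC and PR curves for one or more named evaluation reports."""
    plt = _plt()
    fig, (ax_roc, ax_pr) = plt.subplots(1, 2, figsize=(10, 4.2))
    for name, rep in reports.items():
        fpr, tpr, _ = rep.curves["roc"]
        precision, recall, _ = rep.curves["pr"]
        ax_roc.plot(fpr, tpr, label=f"{name} (AUC {rep.auc_roc:.3f})")
        ax_pr.plot(recall, precision, label=f"{name} (AUC {rep.auc_pr:.3f})")
    ax_roc.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax_roc.set(xlabel="false positive rate", ylabel="true positive rate", title="ROC")
    ax_pr.set(xlabel="recall", ylabel="precision", title="Precision-Recall")
    for ax in (ax_roc, ax_pr):
        ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig


def plot_importance(report: ImportanceReport, top: int = 30, path=None):
    """Dot plot of per-feature MDA (and MDG when available)."""
    plt = _plt()
    order = np.argsort(report.mda)[::-1][:top][::-1]
    names = [report.feature_names[i] for i in order]
    n_panels = 2 if report.mdg is not None else 1
    fig, axes = plt.subplots(1, n_panels, figsize=(4.5 * n_panels, 0.25 * len(order) + 1.5),
                             squeeze=False)
    axes[0][0].plot(report.mda[order], range(len(order)), "o")
    axes[0][0].set_yticks(range(len(order)), names, fontsize=7)
    axes[0][0].set_xlabel("mean decrease in accuracy")
    if report.mdg is not None:
        axes[0][1].plot(report.mdg[order], range(len(order)), "o", color="tab:orange")
        axes[0][1].set_yticks(range(len(order)), names, fontsize=7)
        axes[0][1].set_xlabel("mean decrease in Gini")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig


def plot_stability(stability: dict, top: int = 20, path=None):
    """Box plot of per-feature importance across replicate models."""
    plt = _plt()
    means = stability["mda_mean"]
    order = np.argsort(means)[::-1][:top]
    fig, ax = plt.subplots(figsize=(0.45 * len(order) + 2, 4))
    ax.boxplot(
        [stability["mda_per_model"][:, i] for i in order],
        tick_labels=[stability["feature_names"][i] for i in order],
    )
    ax.set_ylabel("mean decrease in accuracy")
    ax.tick_params(axis="x", labelrotation=90, labelsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig
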