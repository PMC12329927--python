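"""Optional figures: precision-recall scatter and threshold-sweep curves.

Both take the tidy frames produced by the workbench and draw the standard
benchmark layouts — mean ± sd per DATABASE-SOFTWARE-SETTING combination,
one panel per marker/level, and metric-vs-threshold curves for sweeps.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def precision_recall_plot(metrics: pd.DataFrame,
                          out_path: str | Path | None = None):
    """One panel per (marker, level): recall vs precision, error bars = sd."""
    markers = sorted(metrics["marker"].unique())
    levels = sorted(metrics["level"].unique())
    fig, axes = plt.subplots(len(levels), len(markers),
                             figsize=(4 * len(markers), 3.5 * len(levels)),
                             squeeze=False)
    for i, level in enumerate(levels):
        for j, marker in enumerate(markers):
            ax = axes[i][j]
            sub = metrics[(metrics["marker"] == marker)
                          & (metrics["level"] == level)]
            for _, row in sub.iterrows():
                ax.errorbar(row["recall_mean"], row["precision_mean"],
                            xerr=row["recall_sd"], yerr=row["precision_sd"],
                            fmt="o", capsize=2, label=row["combination"])
            ax.set_xlabel("recall (%)")
            ax.set_ylabel("precision (%)")
            ax.set_title(f"{marker} / {level}")
            ax.set_xlim(-5, 105)
            ax.set_ylim(-5, 105)
    axes[0][0].legend(fontsize=6, loc="lower left")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def sweep_plot(sweep: pd.DataFrame, out_path: str | Path | None = None):
    """Precision / recall / F1 against the abundance-filter threshold."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    thr_pct = sweep["threshold"] * 100
    for ax, (col, label, scale) in zip(axes, [
            ("precision_mean", "precision (%)", 1.0),
            ("recall_mean", "recall (%)", 1.0),
            ("f1_mean", "F1", 1.0)]):
        ax.plot(thr_pct, sweep[col] * scale, marker="o", ms=3)
        ax.set_xlabel("abundance threshold (%)")
        ax.set_ylabel(label)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
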