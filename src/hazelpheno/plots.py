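"""Optional matplotlib figures: phase/metric violins and stat heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def violin_figure(groups: dict[str, np.ndarray], out_path=None, ylabel="day of year"):
    """Violin plot of date distributions per group (25/50/75th percentile
    whiskers drawn by matplotlib's quantile option)."""
    labels = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in labels]
    fig, ax = plt.subplots(figsize=(max(6, len(labels)), 4))
    ax.violinplot(data, showmedians=True, quantiles=[[0.25, 0.75]] * len(data))
    ax.set_xticks(range(1, len(labels) + 1), labels, rotation=45, ha="right")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def stat_heatmap(table: pd.DataFrame, value: str = "rmsd_days", out_path=None):
    """Metric x phase heatmap of one comparison statistic, crosses marking
    cells significant at p < 0.05."""
    pivot = table.pivot_table(index="metric", columns="phase", values=value)
    fig, ax = plt.subplots(figsize=(1 + 0.8 * pivot.shape[1], 1 + 0.6 * pivot.shape[0]))
    im = ax.imshow(pivot.to_numpy(), cmap="RdBu_r", aspect="auto")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    fig.colorbar(im, ax=ax, label=value)
    if "significant_05" in table.columns:
        sig = table.pivot_table(
            index="metric", columns="phase", values="significant_05", aggfunc="any"
        ).reindex(index=pivot.index, columns=pivot.columns)
        for i in range(pivot.shape[0]):
            for j in range(pivot.shape[1]):
                if bool(sig.iloc[i, j]) is True:
                    ax.text(j, i, "x", ha="center", va="center")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


__all__ = ["violin_figure", "stat_heatmap"]
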