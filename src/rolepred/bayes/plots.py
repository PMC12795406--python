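"""Optional interval plot of fitted cell means (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["plot_cell_means"]


def plot_cell_means(cell_means: pd.DataFrame, path: str | Path,
                    x: str = "language", facet: str | None = "role") -> None:
    """Mean with 66% and 95% interval bars per cell, one panel per facet level."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    facets = cell_means[facet].unique() if facet else [None]
    fig, axes = plt.subplots(1, len(facets), figsize=(4 * len(facets), 3.5), sharey=True, squeeze=False)
    for ax, level in zip(axes[0], facets):
        sub = cell_means if level is None else cell_means[cell_means[facet] == level]
        xs = range(len(sub))
        ax.vlines(xs, sub["q2.5"], sub["q97.5"], color="steelblue", lw=1.5, alpha=0.6)
        ax.vlines(xs, sub["q17"], sub["q83"], color="steelblue", lw=4, alpha=0.9)
        ax.plot(xs, sub["mean"], "o", color="black", ms=4)
        ax.set_xticks(list(xs))
        ax.set_xticklabels(sub[x], rotation=45, ha="right", fontsize=8)
        ax.set_ylim(0, 1)
        if level is not None:
            ax.set_title(f"{facet} = {level}", fontsize=9)
    axes[0][0].set_ylabel("P(correct role)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
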