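"""Render a D frequency spectrum as the standard bar figure.

Each defined bin is drawn as a vertical bar at derived-allele frequency
k / n whose height is D_k and whose width is proportional to the bin weight
w_k; a dashed horizontal line marks the overall D and a solid line marks
zero.  Undefined bins are omitted.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .dstat import DFSResult

__all__ = ["plot_dfs"]


def plot_dfs(result: DFSResult, ax=None, full_width: float = 0.8,
             color: str = "#c23b22", title: str | None = None):
    """Plot a D frequency spectrum; returns the matplotlib Axes.

    ``full_width`` is the total bar width budget in x-axis units (frequency);
    since the weights sum to 1, the summed bar width equals it.
    """
    defined = result.defined
    if not defined.any():
        raise ValueError("cannot plot a D frequency spectrum with no defined bins")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    widths = result.w * full_width
    ax.axhline(0.0, color="black", lw=0.8)
    ax.bar(result.freq[defined], result.d[defined], width=widths[defined],
           color=color, edgecolor="none", label=r"$D_k$")
    if np.isfinite(result.d_overall):
        ax.axhline(result.d_overall, color="black", ls="--", lw=1.0,
                   label=f"overall D = {result.d_overall:.3f}")
    ax.set_xlabel("derived allele frequency (k / n)")
    ax.set_ylabel(r"$D_k$")
    ax.set_xlim(0, 1 + full_width / result.n)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    return ax


def save_dfs_plot(result: DFSResult, path, **kwargs) -> None:
    ax = plot_dfs(result, **kwargs)
    ax.figure.savefig(path, bbox_inches="tight")
    plt.close(ax.figure)
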