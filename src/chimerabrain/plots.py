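"""Plotting helpers (SVG-friendly, matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .aging import CLASS_ORDER, confidence_interval, fine_bin_order

__all__ = ["plot_class_proportions", "plot_synchrony_matrix"]

_COLORS = {"asynchronous": "#3b6fb6", "chimera": "#e0a73c", "synchronous": "#c23b3b"}
_MARKERS = {"asynchronous": "o", "chimera": "s", "synchronous": "^"}


def plot_class_proportions(patterns: pd.DataFrame, out_path=None, ax=None):
    """Class-proportion-vs-age curves with 95% CI ribbons.

    ``patterns`` needs columns ``age_bin``, ``individual`` and ``cls``.
    Per age bin, each individual contributes one proportion per class;
    the ribbon is the t-based 95% confidence interval across
    individuals.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    bins = (
        ["young", "middle", "old"]
        if set(patterns["age_bin"]) <= {"young", "middle", "old"}
        else fine_bin_order(patterns["age_bin"])
    )
    bins = [b for b in bins if b in set(patterns["age_bin"])]
    x = np.arange(len(bins))
    for cls in CLASS_ORDER:
        means, halves = [], []
        for b in bins:
            grp = patterns[patterns["age_bin"] == b]
            per_indiv = grp.groupby("individual")["cls"].apply(
                lambda s: (s == cls).mean()
            )
            if len(per_indiv) >= 2:
                m, h = confidence_interval(per_indiv)
            else:
                m, h = float(per_indiv.mean()), 0.0
            means.append(m)
            halves.append(h)
        means, halves = np.array(means), np.array(halves)
        ax.plot(x, means, marker=_MARKERS[cls], color=_COLORS[cls], label=cls)
        ax.fill_between(x, means - halves, means + halves,
                        color=_COLORS[cls], alpha=0.2, linewidth=0)
    ax.set_xticks(x, bins)
    ax.set_xlabel("age group")
    ax.set_ylabel("class proportion")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    if out_path is not None:
        ax.figure.savefig(out_path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_synchrony_matrix(matrix, out_path=None, ax=None):
    """Heatmap of a 9 x 9 cognitive-system synchrony matrix."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(matrix.R, vmin=0, vmax=1, cmap="magma")
    ax.set_xticks(range(len(matrix.systems)), matrix.systems, rotation=45)
    ax.set_yticks(range(len(matrix.systems)), matrix.systems)
    ax.figure.colorbar(im, ax=ax, label="synchrony R")
    if out_path is not None:
        ax.figure.savefig(out_path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
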