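"""Figure-style rendering of analysis results.

Non-significant correlation cells are drawn in gray over the r color scale;
correlation traces get their bootstrap-SD envelope; decoding summaries get
the shaded permutation chance band.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_corr_matrix", "plot_corr_trace", "plot_decode",
           "plot_category_fractions"]


def plot_corr_matrix(m, ax=None, cmap="viridis"):
    """Heat map of a time-resolved correlation matrix, gray where p ≥ α."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    shown = np.ma.masked_where(~m.mask, m.r)
    cmap = plt.get_cmap(cmap).copy()
    cmap.set_bad("0.6")
    im = ax.pcolormesh(m.times_b, m.times_a, shown, cmap=cmap, vmin=-1, vmax=1)
    ax.set_xlabel("time, trial B (s)")
    ax.set_ylabel("time, trial A (s)")
    ax.figure.colorbar(im, ax=ax, label="Pearson r (gray: n.s.)")
    return ax


def plot_corr_trace(trace, ax=None, color="purple", label=None):
    """Correlation trace with its bootstrap SD envelope."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.plot(trace.times, trace.values, color=color, label=label)
    if trace.boot_sd is not None:
        ax.fill_between(trace.times, trace.boot_mean - trace.boot_sd,
                        trace.boot_mean + trace.boot_sd, color=color, alpha=0.25,
                        linewidth=0)
    ax.axhline(0, color="k", linewidth=0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("mean r vs reference window")
    return ax


def plot_decode(result, ax=None, color="darkgreen", stim_shade=True):
    """Stimulus-average success vs training time with the chance band."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    t = result.train_times_s
    if result.chance_upper is not None:
        ax.fill_between(t, result.chance_mean, result.chance_upper,
                        color="0.7", label="chance band")
    ax.plot(t, result.stim_avg, color=color, label="stimulus-average success")
    if stim_shade:
        lo, hi = result.eval_window
        ax.axvspan(result.times[lo], result.times[hi - 1], color="0.9", zorder=0)
    ax.set_xlabel("training time (s)")
    ax.set_ylabel("fraction correct")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_category_fractions(fractions, ax=None):
    """Box plot of per-group on/off/prolonged fractions."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    groups = fractions[~fractions.iloc[:, 0].isin(["median", "q1", "q3"])]
    ax.boxplot([groups[c] for c in ("on", "off", "prolonged")],
               tick_labels=["on", "off", "prolonged"])
    ax.set_ylabel("fraction of responding units")
    return ax
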