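"""Matplotlib summaries: attention curves and channel topographies."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .montage import Montage


def plot_attention(report: dict, ax=None):
    """Averaged temporal attention weights against epoch time (ms)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    if report["a_t"] is None:
        raise ValueError("report carries no temporal attention")
    ax.plot(report["times_ms"], report["a_t"], color="tab:red")
    ax.set_xlabel("time after stimulus onset (ms)")
    ax.set_ylabel("mean attention weight")
    ax.set_title("temporal attention")
    return ax


def plot_topography(values: np.ndarray, montage: Montage, ax=None,
                    title: str = "channel weights"):
    """Schematic scalp scatter of per-channel values (nose up)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    pos = montage.positions
    sc = ax.scatter(pos[:, 0], pos[:, 1], c=values, s=120,
                    cmap="RdBu_r", edgecolors="k", linewidths=0.4)
    for (x, y), lab in zip(pos, montage.labels):
        ax.annotate(lab, (x, y), fontsize=4, ha="center", va="center")
    circle = plt.Circle((0, 0), 1.08, fill=False, color="k", lw=0.8)
    ax.add_patch(circle)
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title(title)
    plt.colorbar(sc, ax=ax, shrink=0.7)
    return ax


def plot_grand_average(avg: np.ndarray, times_ms: np.ndarray, ax=None,
                       title: str = "grand average"):
    """Butterfly plot of a (channels, samples) average waveform."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(times_ms, avg.T, color="gray", alpha=0.4, lw=0.6)
    ax.plot(times_ms, avg.mean(axis=0), color="tab:blue", lw=1.5,
            label="channel mean")
    ax.set_xlabel("time after stimulus onset (ms)")
    ax.set_ylabel("amplitude (µV)")
    ax.set_title(title)
    ax.legend(frameon=False)
    return ax
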