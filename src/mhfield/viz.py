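"""Quick-look figures: rate maps, size-sweep curves, deviation curves."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .field import SpikeRecord

__all__ = ["plot_rate_map", "plot_size_sweep", "plot_deviation_curve"]


def plot_rate_map(record: SpikeRecord, window=None, ax=None, cmap="inferno"):
    """Average firing rate per cell (Hz) over the window, as a heatmap."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    if window is None:
        window = (0.0, record.duration)
    counts = record.count_map(window)
    rate = counts / ((window[1] - window[0]) / 1000.0)
    im = ax.imshow(rate.T, origin="lower", cmap=cmap)
    ax.set_xlabel("x (cells)")
    ax.set_ylabel("y (cells)")
    plt.colorbar(im, ax=ax, label="rate (Hz)")
    return ax


def plot_size_sweep(result, ax=None):
    """Cluster count and relative activity against stimulus size."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    t = result.table
    ax.plot(t["size"], t["relative_activity"], "o-", label="relative activity")
    ax.set_xlabel("stimulus size (cells)")
    ax.set_ylabel("activity relative to size 2")
    ax2 = ax.twinx()
    ax2.step(t["size"], t["n_clusters"], where="mid", color="C3",
             alpha=0.6, label="clusters")
    ax2.set_ylabel("n clusters")
    ax.set_title(result.protocol)
    return ax


def plot_deviation_curve(result, ax=None, **plot_kw):
    """Deviation of the near-B cluster against A-B distance; suppressed
    distances are left as gaps, two-cluster outcomes drawn hollow."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    t = result.table
    ax.axhline(0.0, color="grey", lw=0.5)
    one = t["n_clusters"] == 1
    two = t["n_clusters"] >= 2
    ax.plot(t["distance"], t["deviation_x"], "-", alpha=0.5, **plot_kw)
    ax.plot(t["distance"][one], t["deviation_x"][one], "o", color="C0")
    ax.plot(t["distance"][two], t["deviation_x"][two], "o", mfc="none", color="C0")
    ax.set_xlabel("A-B distance (cells)")
    ax.set_ylabel("deviation from B (cells)")
    ax.set_title(result.protocol)
    return ax
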