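"""Summary statistics of simulated activity.

The readout of target selection is the *spiking cluster*: a connected group
of cells that fire and keep firing.  Clusters are 8-connected components of
spiking cells; each is summarised by its spike-count-weighted centre of
gravity, its first spike time, and its steady firing rate over the final
window of the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .field import MembraneTrace, SpikeRecord

__all__ = [
    "Cluster",
    "ClusterReport",
    "DeviationReport",
    "spike_count_map",
    "detect_clusters",
    "relative_activity",
    "deviation_from_B",
    "rise_speed",
    "steady_firing_rate",
    "first_spike_latency",
]


@dataclass(frozen=True)
class Cluster:
    cells: tuple[tuple[int, int], ...]
    n_spikes: int
    cog: tuple[float, float]
    first_spike_time: float


@dataclass(frozen=True)
class ClusterReport:
    clusters: tuple[Cluster, ...]
    total_spikes: int
    discarded_spikes: int          # spikes in components below min_size
    relative_activity: float | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


@dataclass(frozen=True)
class DeviationReport:
    """Offset of the cluster nearest to stimulus B from B's centre.

    ``deviation_x`` is signed along the A-to-B axis: negative values point
    back toward A (attraction), positive away from A (repulsion).  With no
    clusters the run is flagged ``suppressed`` and the deviation is None.
    """

    distance: float
    deviation_x: float | None
    n_clusters: int
    winner_center: tuple[float, float] | None
    suppressed: bool


def spike_count_map(record: SpikeRecord, window: tuple[float, float] | None = None,
                    ) -> np.ndarray:
    """Per-cell spike counts within ``window`` (full run if None)."""
    return record.count_map(window)


def detect_clusters(record: SpikeRecord, min_size: int = 3,
                    window: tuple[float, float] | None = None,
                    connectivity: int = 8) -> ClusterReport:
    """Group spiking cells into connected components.

    Components are taken over the cells with at least one spike inside
    ``window`` (default: the whole run); 8-connectivity keeps rasterised
    circular clusters in one piece.  Components smaller than ``min_size``
    cells are discarded (isolated noise-driven spikers).  Per-cluster spike
    counts, centres of gravity and first-spike times are computed from the
    *full* record of the member cells.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    counts_full = record.count_map(None)
    counts_win = counts_full if window is None else record.count_map(window)
    structure = np.ones((3, 3), dtype=bool) if connectivity == 8 else None
    labels, n_comp = ndimage.label(counts_win > 0, structure=structure)

    # earliest spike per cell, for first-spike times
    first = np.full(record.grid, np.inf)
    if record.n_spikes:
        np.minimum.at(first, (record.xs, record.ys), record.times)

    clusters = []
    discarded = 0
    for lab in range(1, n_comp + 1):
        xs, ys = np.nonzero(labels == lab)
        if xs.size < min_size:
            discarded += int(counts_full[xs, ys].sum())
            continue
        w = counts_full[xs, ys].astype(float)
        total = w.sum()
        cog = (float((xs * w).sum() / total), float((ys * w).sum() / total))
        clusters.append(Cluster(
            cells=tuple(zip(xs.tolist(), ys.tolist())),
            n_spikes=int(total),
            cog=cog,
            first_spike_time=float(first[xs, ys].min()),
        ))
    clusters.sort(key=lambda c: -c.n_spikes)
    return ClusterReport(clusters=tuple(clusters),
                         total_spikes=record.n_spikes,
                         discarded_spikes=discarded)


def relative_activity(record: SpikeRecord, reference: SpikeRecord) -> float:
    """Total spikes of ``record`` relative to a reference run (the smallest
    stimulus size serves as the reference in the size sweeps)."""
    if reference.n_spikes == 0:
        raise ValueError("reference record has no spikes; relative activity undefined")
    return record.n_spikes / reference.n_spikes


def deviation_from_B(report: ClusterReport, B_center: tuple[float, float],
                     A_center: tuple[float, float]) -> DeviationReport:
    """Deviation of the cluster nearest to B from B's centre along the
    A-to-B axis (negative = pulled toward A, positive = pushed away)."""
    distance = float(np.hypot(B_center[0] - A_center[0], B_center[1] - A_center[1]))
    if report.n_clusters == 0:
        return DeviationReport(distance=distance, deviation_x=None, n_clusters=0,
                               winner_center=None, suppressed=True)
    b = np.asarray(B_center, dtype=float)
    cogs = np.array([c.cog for c in report.clusters])
    nearest = report.clusters[int(np.argmin(np.linalg.norm(cogs - b, axis=1)))]
    direction = np.sign(B_center[0] - A_center[0]) or 1.0
    deviation = (nearest.cog[0] - B_center[0]) * direction
    return DeviationReport(distance=distance, deviation_x=float(deviation),
                           n_clusters=report.n_clusters,
                           winner_center=nearest.cog, suppressed=False)


def rise_speed(trace: MembraneTrace, window: tuple[float, float]) -> float:
    """Mean rise speed (mV/s) of the max membrane potential over the tracked
    line within ``window = (t0, t1)`` ms.

    At each sample the maximum V over the tracked cells is taken; the mean
    time-derivative of that curve over the window is its endpoint slope.
    """
    t0, t1 = window
    if t0 >= t1:
        raise ValueError("window must satisfy t0 < t1")
    if t0 < trace.times[0] - 1e-9 or t1 > trace.times[-1] + 1e-9:
        raise ValueError(f"window {window!r} outside trace span "
                         f"[{trace.times[0]}, {trace.times[-1]}]")
    vmax = trace.V.max(axis=0)
    i0 = int(np.argmin(np.abs(trace.times - t0)))
    i1 = int(np.argmin(np.abs(trace.times - t1)))
    dv = vmax[i1] - vmax[i0]
    return float(dv / (trace.times[i1] - trace.times[i0]) * 1000.0)


def steady_firing_rate(record: SpikeRecord, report: ClusterReport,
                       window: tuple[float, float] | None = None) -> list[float]:
    """Mean firing rate (Hz) of each cluster over ``window`` (default: the
    last 50 ms of the run).

    Only cluster members that spike inside the window count as active, so a
    late-onset cluster is not diluted by silent members.
    """
    if window is None:
        window = (record.duration - 50.0, record.duration)
    t0, t1 = window
    if not (0 <= t0 < t1 <= record.duration + 1e-9):
        raise ValueError(f"window {window!r} outside the run")
    counts = record.count_map(window)
    rates = []
    for cluster in report.clusters:
        xs = np.array([c[0] for c in cluster.cells])
        ys = np.array([c[1] for c in cluster.cells])
        c = counts[xs, ys]
        active = c > 0
        if not active.any():
            rates.append(0.0)
            continue
        rates.append(float(c[active].sum() / active.sum() / ((t1 - t0) / 1000.0)))
    return rates


def first_spike_latency(record: SpikeRecord) -> float | None:
    """Time of the earliest spike anywhere on the map (None if spikeless)."""
    if record.n_spikes == 0:
        return None
    return float(record.times.min())
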