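"""Stimulus geometry and deterministic input spike trains.

External drive is delivered by experimenter-controlled input neurons: a
firing-rate curve is converted to a *deterministic* spike train (a spike is
emitted each time the running integral of the rate crosses an integer), and
every input spike increments ``g_e`` of the masked cells by
``alpha_s * w_s``.  This mimics electrical microstimulation rather than a
Poisson process, so runs are reproducible without seeding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RateProfile",
    "gaussian_profile",
    "sustained_profile",
    "StimulusSpec",
    "rate_to_spike_train",
    "line_mask",
    "square_mask",
    "circle_mask",
    "point_pair_masks",
]

#: Default stimulus gain (mV-labelled, applied through the dimensionless
#: gain convention of the engine).
DEFAULT_ALPHA_S = 4000.0


@dataclass(frozen=True)
class RateProfile:
    """Firing-rate curve of an input neuron.

    ``gaussian``: ``peak_rate * exp(-(t - center)^2 / (2 sd^2))`` — a
    transient drive peaking at ``center``.  ``sustained``: constant
    ``peak_rate``.
    """

    kind: str
    peak_rate: float          # Hz
    center: float = 25.0      # ms, gaussian only
    sd: float = 80.0          # ms, gaussian only

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "sustained"):
            raise ValueError(f"unknown rate profile kind {self.kind!r}")
        if not math.isfinite(self.peak_rate) or self.peak_rate < 0:
            raise ValueError("peak_rate must be finite and non-negative")
        if self.kind == "gaussian" and self.sd <= 0:
            raise ValueError("gaussian profile needs sd > 0")

    def rate(self, t) -> np.ndarray:
        """Instantaneous rate in Hz at time(s) ``t`` (ms)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "sustained":
            return np.full_like(t, self.peak_rate)
        return self.peak_rate * np.exp(-((t - self.center) ** 2) / (2.0 * self.sd ** 2))


def gaussian_profile(peak_rate: float = 400.0, center: float = 25.0,
                     sd: float = 80.0) -> RateProfile:
    """The default transient drive: 400 Hz peak at 25 ms, sd 80 ms."""
    return RateProfile("gaussian", peak_rate, center, sd)


def sustained_profile(peak_rate: float = 400.0) -> RateProfile:
    return RateProfile("sustained", peak_rate)


@dataclass(frozen=True)
class StimulusSpec:
    """A spatial mask with per-cell weights, a gain, and a rate profile."""

    cells: tuple[tuple[int, int], ...]
    alpha_s: float = DEFAULT_ALPHA_S
    profile: RateProfile = field(default_factory=gaussian_profile)
    weights: tuple[float, ...] | None = None   # per-cell w_s in [0, 1]; None = all 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple((int(x), int(y)) for x, y in self.cells))
        if self.weights is not None:
            w = tuple(float(v) for v in self.weights)
            if len(w) != len(self.cells):
                raise ValueError("weights must match cells")
            if any(not (0.0 <= v <= 1.0) for v in w):
                raise ValueError("stimulus weights must lie in [0, 1]")
            object.__setattr__(self, "weights", w)
        if self.alpha_s < 0:
            raise ValueError("alpha_s must be non-negative")

    def weight_array(self) -> np.ndarray:
        if self.weights is None:
            return np.ones(len(self.cells))
        return np.asarray(self.weights)

    def validate_on_grid(self, grid: tuple[int, int]) -> None:
        nx, ny = grid
        for x, y in self.cells:
            if not (0 <= x < nx and 0 <= y < ny):
                raise ValueError(f"stimulus cell ({x}, {y}) is off the {nx}x{ny} grid")

    def with_profile(self, profile: RateProfile) -> "StimulusSpec":
        return replace(self, profile=profile)


def rate_to_spike_train(profile: RateProfile, duration: float, dt: float) -> np.ndarray:
    """Deterministic spike times (ms) from a rate curve.

    The rate is integrated on the simulation clock (right-endpoint rule);
    a spike is emitted at the first step where the running integral crosses
    each successive integer.  A sustained 400 Hz profile over 200 ms yields
    exactly 80 spikes, 2.5 ms apart.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    n = round(duration / dt)
    t = dt * np.arange(1, n + 1)
    r = profile.rate(t)
    if np.any(r < 0):
        raise ValueError("rate profile must be non-negative")
    integral = np.cumsum(r * dt / 1000.0)   # Hz * ms -> expected spike count
    total = int(np.floor(integral[-1] + 1e-9))
    if total == 0:
        return np.empty(0)
    # first step index where the integral reaches k, for k = 1 .. total
    idx = np.searchsorted(integral, np.arange(1, total + 1) - 1e-9, side="left")
    return t[idx]


def _centered_span(center: int, size: int) -> range:
    """``size`` consecutive indices; for even size the centre cell pair
    straddles ``center - 0.5`` (e.g. size 2 at centre 50 -> 49, 50)."""
    start = center - size // 2
    return range(start, start + size)


def line_mask(length: int, grid=(100, 100), column: int = 50, center_y: int = 50,
              width: int = 1, **kwargs) -> StimulusSpec:
    """Vertical line stimulus: ``width`` columns starting at ``column``,
    ``length`` cells along Y centred on ``center_y``.

    Lengths follow the single-stimulus protocol (even, 2 to 42); a length
    beyond half the Y extent only warns, since it leaves the tested range
    rather than breaking the geometry.
    """
    nx, ny = grid
    if length < 1:
        raise ValueError("length must be >= 1")
    if length > ny // 2:
        import warnings
        warnings.warn(f"line length {length} exceeds half the Y axis ({ny // 2}); "
                      "outside the tested protocol range", stacklevel=2)
    ys = _centered_span(center_y, length)
    cells = [(column + dx, y) for dx in range(width) for y in ys]
    spec = StimulusSpec(tuple(cells), **kwargs)
    spec.validate_on_grid(grid)
    return spec


def square_mask(side: int, grid=(100, 100), center=(50, 50), **kwargs) -> StimulusSpec:
    """Filled square of ``side`` x ``side`` cells centred on ``center``."""
    if side < 1:
        raise ValueError("side must be >= 1")
    xs = _centered_span(center[0], side)
    ys = _centered_span(center[1], side)
    cells = [(x, y) for x in xs for y in ys]
    spec = StimulusSpec(tuple(cells), **kwargs)
    spec.validate_on_grid(grid)
    return spec


def circle_mask(diameter: int, grid=(100, 100), center=(50, 50), **kwargs) -> StimulusSpec:
    """Filled rasterised disk: cells whose centre lies within ``diameter / 2``
    of the disk centre.

    For even diameters the geometric centre sits between cells (matching the
    even-sided square), so a diameter-2 disk is the four cells of the 2x2
    square.
    """
    if diameter < 1:
        raise ValueError("diameter must be >= 1")
    radius = diameter / 2.0
    # geometric centre of the size-`diameter` centred span on each axis
    xs = _centered_span(center[0], diameter)
    ys = _centered_span(center[1], diameter)
    cx = (xs[0] + xs[-1]) / 2.0
    cy = (ys[0] + ys[-1]) / 2.0
    cells = [(x, y) for x in xs for y in ys
             if (x - cx) ** 2 + (y - cy) ** 2 <= radius ** 2]
    spec = StimulusSpec(tuple(cells), **kwargs)
    spec.validate_on_grid(grid)
    return spec


def point_pair_masks(distance: int, weight_A: float = DEFAULT_ALPHA_S,
                     weight_B: float = DEFAULT_ALPHA_S, grid=(100, 100),
                     anchor=(31, 51), profile: RateProfile | None = None,
                     ) -> tuple[StimulusSpec, StimulusSpec]:
    """Two 2x2 stimulation blocks A and B separated by ``distance`` along X.

    A is anchored (top-left cell) at ``anchor``; B is the same block shifted
    by ``+distance`` in X.  Both share the default transient rate profile.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if profile is None:
        profile = gaussian_profile()
    ax, ay = anchor
    block = [(0, 0), (0, 1), (1, 0), (1, 1)]
    cells_a = tuple((ax + dx, ay + dy) for dx, dy in block)
    cells_b = tuple((ax + distance + dx, ay + dy) for dx, dy in block)
    a = StimulusSpec(cells_a, alpha_s=weight_A, profile=profile)
    b = StimulusSpec(cells_b, alpha_s=weight_B, profile=profile)
    a.validate_on_grid(grid)
    try:
        b.validate_on_grid(grid)
    except ValueError as err:
        raise ValueError(f"stimulus B at distance {distance} falls off the grid") from err
    return a, b


def block_center(spec: StimulusSpec) -> tuple[float, float]:
    """Geometric centre of a stimulus mask in cell coordinates."""
    xs = np.array([c[0] for c in spec.cells], dtype=float)
    ys = np.array([c[1] for c in spec.cells], dtype=float)
    return float(xs.mean()), float(ys.mean())
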