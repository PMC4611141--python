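"""Neuron constants and simulation clocks."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Conversion from the millivolt-labelled synaptic gains (alpha_e = alpha_i
#: = 200 mV, alpha_s up to 4000 mV) to the dimensionless channel increments:
#: gains are read in SI units (volts), the way units-aware simulators store
#: millivolt quantities.  Fixed once by the calibration protocol; see the
#: methods note.
MV_GAIN_SCALE = 1e-3


@dataclass(frozen=True)
class NeuronParams:
    """Constants of the conductance-based integrate-and-fire neuron.

    The membrane relaxes to the rest potential ``V_0`` with time constant
    ``tau_m`` and is pulled toward the excitatory / inhibitory reversal
    potentials ``V_e`` / ``V_i`` in proportion to the dimensionless channel
    variables ``g_e`` / ``g_i``, which decay with ``tau_e`` / ``tau_i``.
    Crossing ``V_t`` emits a spike, resets to ``V_r`` and starts the
    refractory period.
    """

    tau_m: float = 10.0        # ms
    tau_e: float = 3.0         # ms
    tau_i: float = 10.0        # ms
    V_t: float = -50.0         # mV
    V_r: float = -80.0         # mV
    V_0: float = -70.0         # mV
    V_e: float = 0.0           # mV
    V_i: float = -80.0         # mV
    refractory: float = 1.5    # ms

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_e", "tau_i", "refractory"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.V_r <= self.V_i <= self.V_0 < self.V_t < self.V_e):
            raise ValueError("potentials must satisfy V_r <= V_i <= V_0 < V_t < V_e")


@dataclass(frozen=True)
class SimulationConfig:
    """Lattice geometry, clocks and noise for one simulation run.

    ``gain_scale`` is a single dimensionless conversion applied to every
    synaptic gain (lateral ``alpha_e`` / ``alpha_i`` and stimulus
    ``alpha_s``) when weights are deposited onto the channel variables.
    It expresses the millivolt-labelled gains in the dimensionless units
    of ``g_e`` / ``g_i`` and is fixed once by the calibration protocol
    (see the methods note); it is not a per-experiment tuning knob.
    """

    grid: tuple[int, int] = (100, 100)
    dt: float = 0.01           # ms, simulation clock
    record_dt: float = 1.0     # ms, recording clock
    duration: float = 200.0    # ms
    noise_sd: float = 0.0      # mV per record_dt interval; 0 disables noise
    seed: int = 0
    gain_scale: float = MV_GAIN_SCALE
    method: str = "exponential"
    record_cells: tuple[tuple[int, int], ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        nx, ny = self.grid
        if nx <= 0 or ny <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.dt <= 0 or self.record_dt <= 0 or self.duration <= 0:
            raise ValueError("clocks and duration must be positive")
        steps_per_record = self.record_dt / self.dt
        if abs(steps_per_record - round(steps_per_record)) > 1e-9:
            raise ValueError("dt must divide record_dt")
        n_records = self.duration / self.record_dt
        if abs(n_records - round(n_records)) > 1e-9:
            raise ValueError("duration must be a multiple of record_dt")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.gain_scale <= 0:
            raise ValueError("gain_scale must be positive")
        if self.method not in ("euler", "exponential"):
            raise ValueError(f"unknown integration method {self.method!r}")
        if self.record_cells is not None:
            object.__setattr__(self, "record_cells",
                               tuple((int(x), int(y)) for x, y in self.record_cells))
            for x, y in self.record_cells:
                if not (0 <= x < nx and 0 <= y < ny):
                    raise ValueError(f"tracked cell ({x}, {y}) off the grid")

    @property
    def n_steps(self) -> int:
        return round(self.duration / self.dt)

    @property
    def steps_per_record(self) -> int:
        return round(self.record_dt / self.dt)
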