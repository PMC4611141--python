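"""Conductance-based integrate-and-fire dynamics on the 2D lattice.

Each cell obeys

    tau_m dV/dt = -(V - V_0) - g_e (V - V_e) - g_i (V - V_i)

with exponentially decaying channel variables ``g_e`` (tau_e) and ``g_i``
(tau_i).  A spike resets V to ``V_r``, starts a refractory period during
which the cell is clamped and ignores all drive, and deposits
``alpha_e * w_e`` / ``alpha_i * w_i`` onto the neighbours' channels through
the lateral kernel, effective from the next step (one-step synaptic
latency).

The default membrane update is an exponential-Euler step: with the
channels frozen over one dt, the membrane equation is linear in V and is
advanced exactly,

    V  <-  V* + (V - V*) exp(-dt (1 + g_e + g_i) / tau_m),
    V* = (V_0 + g_e V_e + g_i V_i) / (1 + g_e + g_i).

This is unconditionally stable at any synaptic gain; a plain forward-Euler
step (``method="euler"``) is also available and behaves identically in the
calibrated regime, but diverges once the total conductance pushes the
effective membrane time constant tau_m / (1 + g) below the 0.01 ms clock.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import NeuronParams, SimulationConfig
from .kernel import KernelField
from .stimuli import rate_to_spike_train

__all__ = [
    "FieldState",
    "SpikeRecord",
    "MembraneTrace",
    "NumericalDivergenceError",
    "initialize_state",
    "step",
    "run_simulation",
    "probe_column_cells",
]


class NumericalDivergenceError(RuntimeError):
    """Raised when the membrane potential becomes non-finite."""

    def __init__(self, cell: tuple[int, int], time: float):
        self.cell = cell
        self.time = time
        super().__init__(f"non-finite membrane potential at cell {cell}, t = {time:.3f} ms")


@dataclass
class FieldState:
    """Mutable per-cell state of the lattice.

    ``pending_e`` / ``pending_i`` hold the channel increments produced by
    the spikes of the step just completed; they are applied at the start of
    the next step.
    """

    V: np.ndarray
    g_e: np.ndarray
    g_i: np.ndarray
    refractory_remaining: np.ndarray
    pending_e: np.ndarray
    pending_i: np.ndarray
    t: float = 0.0


@dataclass(frozen=True)
class SpikeRecord:
    """All spike events of a run: parallel arrays of times and coordinates."""

    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    grid: tuple[int, int]
    duration: float

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def events(self) -> list[tuple[tuple[int, int], float]]:
        return [((int(x), int(y)), float(t))
                for x, y, t in zip(self.xs, self.ys, self.times)]

    def count_map(self, window: tuple[float, float] | None = None) -> np.ndarray:
        """Per-cell spike counts, optionally restricted to ``[t0, t1]``."""
        if window is None:
            sel = slice(None)
        else:
            t0, t1 = window
            if not (0 <= t0 < t1 <= self.duration + 1e-9):
                raise ValueError(f"invalid window {window!r} for duration {self.duration}")
            sel = (self.times >= t0) & (self.times <= t1)
        counts = np.zeros(self.grid, dtype=np.int64)
        np.add.at(counts, (self.xs[sel], self.ys[sel]), 1)
        return counts

    def cell_times(self, x: int, y: int) -> np.ndarray:
        return self.times[(self.xs == x) & (self.ys == y)]

    def min_isi(self) -> float:
        """Smallest inter-spike interval of any single cell (inf if none)."""
        best = np.inf
        flat = self.xs.astype(np.int64) * self.grid[1] + self.ys
        order = np.lexsort((self.times, flat))
        f, t = flat[order], self.times[order]
        same = f[1:] == f[:-1]
        if same.any():
            best = float(np.min(np.diff(t)[same]))
        return best


@dataclass(frozen=True)
class MembraneTrace:
    """V / g_e / g_i sampled on the recording clock for tracked cells."""

    cells: tuple[tuple[int, int], ...]
    times: np.ndarray                     # ms, multiples of record_dt
    V: np.ndarray                         # (n_cells, n_times)
    g_e: np.ndarray
    g_i: np.ndarray


def initialize_state(config: SimulationConfig, params: NeuronParams) -> FieldState:
    """Rest state: V = V_0 everywhere, channels closed, no refractoriness."""
    shape = config.grid
    return FieldState(
        V=np.full(shape, params.V_0, dtype=float),
        g_e=np.zeros(shape), g_i=np.zeros(shape),
        refractory_remaining=np.zeros(shape),
        pending_e=np.zeros(shape), pending_i=np.zeros(shape),
    )


class _Engine:
    """Precomputed constants for the per-step update."""

    def __init__(self, config: SimulationConfig, params: NeuronParams,
                 kernel: KernelField):
        self.method = config.method
        self.config = config
        self.params = params
        self.nx, self.ny = config.grid
        dt = config.dt
        self.decay_e = float(np.exp(-dt / params.tau_e))
        self.decay_i = float(np.exp(-dt / params.tau_i))
        scale = config.gain_scale
        self.We = scale * kernel.spec.alpha_e * kernel.w_e
        self.Wi = scale * kernel.spec.alpha_i * kernel.w_i
        self.R = kernel.support_radius
        self.noise_step_sd = config.noise_sd * np.sqrt(dt / config.record_dt)

    def deposit(self, xs: np.ndarray, ys: np.ndarray,
                buf_e: np.ndarray, buf_i: np.ndarray) -> None:
        """Add the kernel patch of each spike to the pending buffers.

        Open boundary: contributions falling off the grid are dropped.
        """
        R, nx, ny = self.R, self.nx, self.ny
        for x, y in zip(xs, ys):
            x0, x1 = max(0, x - R), min(nx, x + R + 1)
            y0, y1 = max(0, y - R), min(ny, y + R + 1)
            kx0, ky0 = x0 - (x - R), y0 - (y - R)
            buf_e[x0:x1, y0:y1] += self.We[kx0:kx0 + (x1 - x0), ky0:ky0 + (y1 - y0)]
            buf_i[x0:x1, y0:y1] += self.Wi[kx0:kx0 + (x1 - x0), ky0:ky0 + (y1 - y0)]

    def advance(self, state: FieldState, ext_e: np.ndarray | None,
                rng: np.random.Generator | None) -> np.ndarray:
        """One dt step; returns boolean spike mask for this step."""
        p = self.params
        dt = self.config.dt

        # 1. apply deposits from last step's spikes, plus external input
        if ext_e is not None:
            state.g_e += ext_e
        state.g_e += state.pending_e
        state.g_i += state.pending_i
        state.pending_e.fill(0.0)
        state.pending_i.fill(0.0)

        # 2. membrane update (channels frozen over dt)
        if self.method == "euler":
            dv = (-(state.V - p.V_0) - state.g_e * (state.V - p.V_e)
                  - state.g_i * (state.V - p.V_i)) * (dt / p.tau_m)
            state.V = state.V + dv
        else:
            g_tot = 1.0 + state.g_e + state.g_i
            v_inf = (p.V_0 + state.g_e * p.V_e + state.g_i * p.V_i) / g_tot
            decay = np.exp((-dt / p.tau_m) * g_tot)
            state.V = v_inf + (state.V - v_inf) * decay

        if rng is not None and self.noise_step_sd > 0:
            state.V += rng.normal(0.0, self.noise_step_sd, size=state.V.shape)

        # refractory cells are clamped at V_r and exempt from all drive
        refr = state.refractory_remaining > 0
        state.V[refr] = p.V_r

        # 3. threshold crossing (refractory cells sit at V_r < V_t)
        spiking = state.V > p.V_t
        if spiking.any():
            xs, ys = np.nonzero(spiking)
            state.V[spiking] = p.V_r
            self.deposit(xs, ys, state.pending_e, state.pending_i)

        # 4. refractory bookkeeping: tick down, then arm the new spikes
        np.subtract(state.refractory_remaining, dt, out=state.refractory_remaining)
        np.maximum(state.refractory_remaining, 0.0, out=state.refractory_remaining)
        if spiking.any():
            state.refractory_remaining[spiking] = p.refractory

        # 5. channel decay
        state.g_e *= self.decay_e
        state.g_i *= self.decay_i

        state.t += dt
        return spiking


def step(state: FieldState, kernel: KernelField, external_increments: np.ndarray | None,
         params: NeuronParams, config: SimulationConfig,
         rng: np.random.Generator | None = None) -> tuple[FieldState, np.ndarray]:
    """Advance the field by one dt.

    ``external_increments`` is a per-cell array of non-negative g_e
    increments (input spikes landing on this step), already scaled by
    ``gain_scale * alpha_s * w_s``; pass None for no input.  Returns the
    state and an (n, 2) array of the coordinates that spiked this step.
    """
    if external_increments is not None and np.any(external_increments < 0):
        raise ValueError("external increments must be non-negative")
    engine = _Engine(config, params, kernel)
    spiking = engine.advance(state, external_increments, rng)
    if not np.all(np.isfinite(state.V)):
        bad = np.argwhere(~np.isfinite(state.V))[0]
        raise NumericalDivergenceError((int(bad[0]), int(bad[1])), state.t)
    return state, np.argwhere(spiking)


def _input_schedule(stimuli, config: SimulationConfig):
    """Map step index -> list of (xs, ys, amounts) input deposits."""
    schedule: dict[int, list] = {}
    for stim in stimuli:
        stim.validate_on_grid(config.grid)
        times = rate_to_spike_train(stim.profile, config.duration, config.dt)
        steps = np.round(times / config.dt).astype(int) - 1
        xs = np.array([c[0] for c in stim.cells], dtype=int)
        ys = np.array([c[1] for c in stim.cells], dtype=int)
        amounts = config.gain_scale * stim.alpha_s * stim.weight_array()
        for s in steps:
            schedule.setdefault(int(s), []).append((xs, ys, amounts))
    return schedule


def run_simulation(config: SimulationConfig, params: NeuronParams,
                   kernel: KernelField, stimuli=(),
                   ) -> tuple[SpikeRecord, MembraneTrace | None]:
    """Simulate the full duration and record spikes and membrane traces.

    Deterministic: with ``noise_sd = 0`` the run is bit-reproducible
    regardless of the seed (the noise generator is never drawn from).
    Traces are recorded for ``config.record_cells`` on the recording clock
    (None disables tracing).
    """
    engine = _Engine(config, params, kernel)
    state = initialize_state(config, params)
    schedule = _input_schedule(stimuli, config)
    rng = np.random.default_rng(config.seed) if config.noise_sd > 0 else None

    tracked = config.record_cells
    n_rec = round(config.duration / config.record_dt)
    if tracked:
        tx = np.array([c[0] for c in tracked])
        ty = np.array([c[1] for c in tracked])
        trace_V = np.empty((len(tracked), n_rec + 1))
        trace_ge = np.empty_like(trace_V)
        trace_gi = np.empty_like(trace_V)
        trace_V[:, 0] = state.V[tx, ty]
        trace_ge[:, 0] = state.g_e[tx, ty]
        trace_gi[:, 0] = state.g_i[tx, ty]

    spike_times: list[np.ndarray] = []
    spike_x: list[np.ndarray] = []
    spike_y: list[np.ndarray] = []
    ext = np.zeros(config.grid)
    spr = config.steps_per_record

    for k in range(config.n_steps):
        deposits = schedule.get(k)
        ext_arr = None
        if deposits:
            ext.fill(0.0)
            for xs, ys, amounts in deposits:
                np.add.at(ext, (xs, ys), amounts)
            ext_arr = ext
        spiking = engine.advance(state, ext_arr, rng)
        if spiking.any():
            xs, ys = np.nonzero(spiking)
            spike_x.append(xs.astype(np.int32))
            spike_y.append(ys.astype(np.int32))
            spike_times.append(np.full(xs.size, (k + 1) * config.dt))
        if (k + 1) % spr == 0:
            if not np.all(np.isfinite(state.V)):
                bad = np.argwhere(~np.isfinite(state.V))[0]
                raise NumericalDivergenceError((int(bad[0]), int(bad[1])), state.t)
            if tracked:
                j = (k + 1) // spr
                trace_V[:, j] = state.V[tx, ty]
                trace_ge[:, j] = state.g_e[tx, ty]
                trace_gi[:, j] = state.g_i[tx, ty]

    record = SpikeRecord(
        times=np.concatenate(spike_times) if spike_times else np.empty(0),
        xs=np.concatenate(spike_x) if spike_x else np.empty(0, dtype=np.int32),
        ys=np.concatenate(spike_y) if spike_y else np.empty(0, dtype=np.int32),
        grid=config.grid, duration=config.duration,
    )
    trace = None
    if tracked:
        trace = MembraneTrace(cells=tuple(tracked),
                              times=config.record_dt * np.arange(n_rec + 1),
                              V=trace_V, g_e=trace_ge, g_i=trace_gi)
    return record, trace


def probe_column_cells(grid=(100, 100), column: int = 52) -> tuple[tuple[int, int], ...]:
    """The probe line used for membrane readouts: a full column of cells
    parallel to the line stimulus, two cells away by default (x = 52)."""
    return tuple((column, y) for y in range(grid[1]))
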