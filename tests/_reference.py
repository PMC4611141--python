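"""Independent brute-force oracles used by the tests.

``brute_force_run`` integrates the same neuron equations with explicit
Python loops over every cell and every (spiking cell, target cell) pair —
no kernel patches, no vectorisation — so it checks the engine's lateral
propagation and bookkeeping, not merely its arithmetic.  It is only usable
on tiny grids.
"""

from __future__ import annotations

import numpy as np

from mhfield.config import NeuronParams, SimulationConfig
from mhfield.kernel import KernelField
from mhfield.stimuli import rate_to_spike_train


def brute_force_run(config: SimulationConfig, params: NeuronParams,
                    kernel: KernelField, stimuli=()):
    """Per-event reference simulation; returns a list of (t, x, y) spikes."""
    nx, ny = config.grid
    dt = config.dt
    p = params
    R = kernel.support_radius
    We = config.gain_scale * kernel.spec.alpha_e * kernel.w_e
    Wi = config.gain_scale * kernel.spec.alpha_i * kernel.w_i

    V = [[np.float64(p.V_0) for _ in range(ny)] for _ in range(nx)]
    ge = [[np.float64(0.0) for _ in range(ny)] for _ in range(nx)]
    gi = [[np.float64(0.0) for _ in range(ny)] for _ in range(nx)]
    refr = [[np.float64(0.0) for _ in range(ny)] for _ in range(nx)]
    pend_e = [[np.float64(0.0) for _ in range(ny)] for _ in range(nx)]
    pend_i = [[np.float64(0.0) for _ in range(ny)] for _ in range(nx)]

    # external input schedule: step -> list of (x, y, amount)
    schedule: dict[int, list] = {}
    for stim in stimuli:
        times = rate_to_spike_train(stim.profile, config.duration, dt)
        w = stim.weight_array()
        for t in times:
            k = int(round(t / dt)) - 1
            for (x, y), wv in zip(stim.cells, w):
                schedule.setdefault(k, []).append(
                    (x, y, np.float64(config.gain_scale * stim.alpha_s * wv)))

    decay_e = np.exp(np.float64(-dt / p.tau_e))
    decay_i = np.exp(np.float64(-dt / p.tau_i))
    events = []
    for k in range(config.n_steps):
        for x, y, amount in schedule.get(k, ()):
            ge[x][y] = ge[x][y] + amount
        for x in range(nx):
            for y in range(ny):
                ge[x][y] = ge[x][y] + pend_e[x][y]
                gi[x][y] = gi[x][y] + pend_i[x][y]
                pend_e[x][y] = np.float64(0.0)
                pend_i[x][y] = np.float64(0.0)

        spikes = []
        for x in range(nx):
            for y in range(ny):
                if config.method == "euler":
                    dv = (-(V[x][y] - p.V_0) - ge[x][y] * (V[x][y] - p.V_e)
                          - gi[x][y] * (V[x][y] - p.V_i)) * (dt / p.tau_m)
                    v = V[x][y] + dv
                else:
                    gt = 1.0 + ge[x][y] + gi[x][y]
                    v_inf = (p.V_0 + ge[x][y] * p.V_e + gi[x][y] * p.V_i) / gt
                    v = v_inf + (V[x][y] - v_inf) * np.exp((-dt / p.tau_m) * gt)
                if refr[x][y] > 0:
                    v = np.float64(p.V_r)
                if v > p.V_t:
                    spikes.append((x, y))
                    v = np.float64(p.V_r)
                V[x][y] = v

        for (sx, sy) in spikes:
            events.append(((k + 1) * dt, sx, sy))
            # explicit pair loop: deposit onto every cell in range
            for tx in range(nx):
                for ty in range(ny):
                    dx, dy = tx - sx, ty - sy
                    if abs(dx) <= R and abs(dy) <= R:
                        pend_e[tx][ty] = pend_e[tx][ty] + We[R + dx, R + dy]
                        pend_i[tx][ty] = pend_i[tx][ty] + Wi[R + dx, R + dy]

        for x in range(nx):
            for y in range(ny):
                refr[x][y] = max(refr[x][y] - dt, 0.0)
        for (sx, sy) in spikes:
            refr[sx][sy] = np.float64(p.refractory)
        for x in range(nx):
            for y in range(ny):
                ge[x][y] = ge[x][y] * decay_e
                gi[x][y] = gi[x][y] * decay_i
    return events


def flood_fill_components(binary: np.ndarray, connectivity: int = 8):
    """Connected components of a boolean map by explicit stack flood fill."""
    nx, ny = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    if connectivity == 8:
        neigh = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                 if (dx, dy) != (0, 0)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    comps = []
    for sx in range(nx):
        for sy in range(ny):
            if not binary[sx, sy] or seen[sx, sy]:
                continue
            stack = [(sx, sy)]
            seen[sx, sy] = True
            comp = []
            while stack:
                x, y = stack.pop()
                comp.append((x, y))
                for dx, dy in neigh:
                    tx, ty = x + dx, y + dy
                    if (0 <= tx < nx and 0 <= ty < ny and binary[tx, ty]
                            and not seen[tx, ty]):
                        seen[tx, ty] = True
                        stack.append((tx, ty))
            comps.append(sorted(comp))
    return comps
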