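"""Shared fixtures.

Full-lattice 200 ms runs take a few seconds each, so the ones used by
several tests are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

import mhfield as m


@pytest.fixture(scope="session")
def params() -> m.NeuronParams:
    return m.NeuronParams()


@pytest.fixture(scope="session")
def s1_kernel() -> m.KernelField:
    return m.build_kernel(m.preset("s1", sigma=5.0))


def full_line_run(variant: str, length: int, params, profile=None,
                  with_trace: bool = True):
    """One full protocol condition: 100x100 lattice, 200 ms."""
    cells = m.probe_column_cells() if with_trace else None
    config = m.SimulationConfig(record_cells=cells)
    kernel = m.build_kernel(m.preset(variant, sigma=5.0))
    stim = m.line_mask(length)
    if profile is not None:
        stim = stim.with_profile(profile)
    record, trace = m.run_simulation(config, params, kernel, [stim])
    return record, trace, stim


@pytest.fixture(scope="session")
def s1_line10(params):
    """Reference single-cluster condition (S1 kernel, length-10 line)."""
    return full_line_run("s1", 10, params)


@pytest.fixture(scope="session")
def s1_line20(params):
    """Reference suppressed condition (S1 kernel, length-20 line)."""
    return full_line_run("s1", 20, params)


@pytest.fixture(scope="session")
def s3_line30(params):
    """Delayed two-cluster condition (S3 kernel, length-30 line)."""
    return full_line_run("s3", 30, params)


def synthetic_record(events, grid=(100, 100), duration=200.0) -> m.SpikeRecord:
    """Build a SpikeRecord from a list of (t, x, y) tuples."""
    if events:
        t, x, y = map(np.asarray, zip(*events))
    else:
        t = np.empty(0)
        x = y = np.empty(0, dtype=int)
    return m.SpikeRecord(times=np.asarray(t, dtype=float),
                         xs=np.asarray(x, dtype=np.int32),
                         ys=np.asarray(y, dtype=np.int32),
                         grid=grid, duration=duration)
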