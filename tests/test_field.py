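"""Engine: integration, refractoriness, determinism, symmetry, oracle."""

import numpy as np
import pytest

import mhfield as m
from mhfield.stimuli import StimulusSpec

from _reference import brute_force_run


def small_config(grid=(9, 9), duration=20.0, **kw):
    return m.SimulationConfig(grid=grid, duration=duration, **kw)


def tiny_kernel(grid, sigma=1.5, support=4):
    return m.build_kernel(m.preset("s1", sigma=sigma), grid=grid,
                          support_radius=support)


class TestInitializeState:
    def test_rest_state(self, params):
        state = m.initialize_state(small_config(), params)
        assert np.all(state.V == -70.0)
        assert state.g_e.sum() == 0.0 and state.g_i.sum() == 0.0
        assert np.all(state.refractory_remaining == 0.0)

    def test_grid_shape(self, params):
        state = m.initialize_state(small_config(grid=(3, 3)), params)
        assert state.V.size == 9


class TestStep:
    def test_rest_is_fixed_point(self, params):
        config = small_config()
        kernel = tiny_kernel(config.grid)
        state = m.initialize_state(config, params)
        state, spikes = m.step(state, kernel, None, params, config)
        assert np.all(state.V == -70.0)
        assert spikes.size == 0

    @pytest.mark.parametrize("method", ["exponential", "euler"])
    def test_analytic_membrane_decay(self, params, method):
        """With g = 0, V relaxes as V_0 + (V(0) - V_0) exp(-t / tau_m):
        from -60 mV, V(10 ms) = -70 + 10 e^-1 = -66.321 mV."""
        config = small_config(duration=10.0, method=method)
        kernel = tiny_kernel(config.grid)
        state = m.initialize_state(config, params)
        state.V[:] = -60.0
        for _ in range(config.n_steps):
            state, _ = m.step(state, kernel, None, params, config)
        expected = -70.0 + 10.0 * np.exp(-1.0)
        # Euler carries O(dt) truncation error; the exponential step is exact
        tol = 1e-9 if method == "exponential" else 5e-3
        assert state.V[4, 4] == pytest.approx(expected, abs=tol)

    def test_negative_external_increment_rejected(self, params):
        config = small_config()
        kernel = tiny_kernel(config.grid)
        state = m.initialize_state(config, params)
        bad = np.full(config.grid, -1.0)
        with pytest.raises(ValueError):
            m.step(state, kernel, bad, params, config)

    def test_divergence_error_names_cell_and_time(self, params):
        config = small_config()
        kernel = tiny_kernel(config.grid)
        state = m.initialize_state(config, params)
        state.V[2, 3] = np.nan
        with pytest.raises(m.NumericalDivergenceError) as err:
            m.step(state, kernel, None, params, config)
        assert err.value.cell == (2, 3)


class TestRefractoriness:
    def test_isi_bounded_below_under_strong_drive(self, params):
        """A cell under constant strong excitation fires at the
        refractory-limited rate: every inter-spike interval >= 1.5 ms."""
        config = small_config(grid=(3, 3), duration=50.0)
        kernel = m.build_kernel(
            m.KernelSpec(sigma_x=1, sigma_y=1, K=1.2, beta=6, alpha_e=0, alpha_i=0),
            grid=config.grid, support_radius=1)
        state = m.initialize_state(config, params)
        drive = np.zeros(config.grid)
        drive[1, 1] = 1.0          # per-step top-up; steady g_e is ~300
        spike_times = []
        for k in range(config.n_steps):
            state, spikes = m.step(state, kernel, drive, params, config)
            if spikes.size:
                spike_times.append((k + 1) * config.dt)
        assert len(spike_times) >= 20
        isi = np.diff(spike_times)
        assert np.all(isi >= params.refractory - 1e-9)
        # refractory-limited: close to the 1.5 ms floor
        assert params.refractory <= isi.min() <= 1.56


class TestRunSimulation:
    def test_quiescent_without_input(self, params):
        config = small_config(grid=(15, 15), duration=30.0,
                              record_cells=((7, 7),))
        kernel = tiny_kernel(config.grid)
        record, trace = m.run_simulation(config, params, kernel, [])
        assert record.n_spikes == 0
        assert np.all(trace.V == -70.0)

    def test_trace_clock(self, params):
        config = small_config(grid=(9, 9), duration=10.0, record_cells=((4, 4),))
        kernel = tiny_kernel(config.grid)
        _, trace = m.run_simulation(config, params, kernel, [])
        np.testing.assert_array_equal(trace.times, np.arange(0.0, 11.0))

    def test_bit_reproducible_without_noise(self, params):
        config = small_config(grid=(11, 11), duration=30.0)
        kernel = tiny_kernel(config.grid)
        stim = StimulusSpec(((5, 5), (5, 6)), alpha_s=4000.0)
        rec1, _ = m.run_simulation(config, params, kernel, [stim])
        config2 = m.SimulationConfig(grid=(11, 11), duration=30.0, seed=12345)
        rec2, _ = m.run_simulation(config2, params, kernel, [stim])
        assert rec1.n_spikes > 0
        np.testing.assert_array_equal(rec1.times, rec2.times)
        np.testing.assert_array_equal(rec1.xs, rec2.xs)
        np.testing.assert_array_equal(rec1.ys, rec2.ys)

    def test_noise_is_seeded(self, params):
        config = small_config(grid=(11, 11), duration=20.0, noise_sd=4.0, seed=7)
        kernel = tiny_kernel(config.grid)
        rec1, _ = m.run_simulation(config, params, kernel, [])
        rec2, _ = m.run_simulation(config, params, kernel, [])
        np.testing.assert_array_equal(rec1.times, rec2.times)
        np.testing.assert_array_equal(rec1.xs, rec2.xs)

    def test_conductance_positivity_and_isi_in_driven_run(self, params):
        config = small_config(grid=(15, 15), duration=60.0,
                              record_cells=tuple((x, 7) for x in range(15)))
        kernel = tiny_kernel(config.grid, sigma=1.5, support=8)
        stim = StimulusSpec(((7, 7), (7, 8)), alpha_s=4000.0)
        record, trace = m.run_simulation(config, params, kernel, [stim])
        assert record.n_spikes > 0
        assert (trace.g_e >= 0).all() and (trace.g_i >= 0).all()
        assert record.min_isi() >= params.refractory - 1e-9
        # without noise, V stays within [min(V_r, V_i), V_t] at sample times
        assert trace.V.min() >= -80.0 - 1e-9
        assert trace.V.max() <= -50.0 + 1e-9

    def test_mirror_symmetry(self, params):
        """A stimulus symmetric about the horizontal midline yields an
        exactly mirror-symmetric spike-count map (no noise)."""
        config = small_config(grid=(41, 41), duration=100.0)
        kernel = m.build_kernel(m.preset("s1", sigma=3.0), grid=config.grid)
        # line centred on y = 20: cells y in [18, 22]
        stim = StimulusSpec(tuple((20, y) for y in range(18, 23)), alpha_s=4000.0)
        record, _ = m.run_simulation(config, params, kernel, [stim])
        counts = record.count_map()
        assert record.n_spikes > 0
        np.testing.assert_array_equal(counts, counts[:, ::-1])

    def test_translation_equivariance(self, params):
        """Shifting an interior stimulus shifts the cluster's centre of
        gravity by the same amount (within half a cell)."""
        config = m.SimulationConfig(duration=120.0)
        kernel = m.build_kernel(m.preset("s1", sigma=5.0))
        shift = 6
        base = m.line_mask(6, column=46, center_y=46)
        moved = m.line_mask(6, column=46 + shift, center_y=46 + shift)
        rec_a, _ = m.run_simulation(config, params, kernel, [base])
        rec_b, _ = m.run_simulation(config, params, kernel, [moved])
        cog_a = m.detect_clusters(rec_a).clusters[0].cog
        cog_b = m.detect_clusters(rec_b).clusters[0].cog
        assert cog_b[0] - cog_a[0] == pytest.approx(shift, abs=0.5)
        assert cog_b[1] - cog_a[1] == pytest.approx(shift, abs=0.5)


class TestBruteForceOracle:
    @pytest.mark.parametrize("method", ["exponential", "euler"])
    def test_engine_matches_per_pair_simulator(self, params, method):
        """The vectorised engine and an explicit per-cell, per-pair event
        simulator produce identical spike sets on a small lattice."""
        config = m.SimulationConfig(grid=(11, 11), duration=25.0, method=method)
        kernel = m.build_kernel(m.preset("s1", sigma=1.5), grid=config.grid,
                                support_radius=5)
        stim = StimulusSpec(((5, 4), (5, 5), (5, 6)), alpha_s=4000.0)
        record, _ = m.run_simulation(config, params, kernel, [stim])
        expected = brute_force_run(config, params, kernel, [stim])
        got = [(t, int(x), int(y))
               for t, x, y in zip(record.times, record.xs, record.ys)]
        assert len(expected) > 10
        assert sorted(got) == sorted((t, x, y) for t, x, y in expected)


class TestSpikeRecord:
    def test_count_map_window_and_conservation(self, params):
        rec = m.SpikeRecord(times=np.array([1.0, 2.0, 150.0]),
                            xs=np.array([3, 3, 4]), ys=np.array([4, 4, 9]),
                            grid=(10, 10), duration=200.0)
        full = rec.count_map()
        assert full[3, 4] == 2 and full[4, 9] == 1
        assert full.sum() == rec.n_spikes
        early = rec.count_map((0.0, 10.0))
        assert early.sum() == 2
        with pytest.raises(ValueError):
            rec.count_map((50.0, 10.0))
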