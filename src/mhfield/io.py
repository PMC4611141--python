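"""Serialisation: HDF5 runs, CSV summaries, YAML configuration, NPZ kernels."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .config import NeuronParams, SimulationConfig
from .field import MembraneTrace, SpikeRecord
from .kernel import KernelField, KernelSpec, build_kernel, preset
from .stimuli import (StimulusSpec, circle_mask, gaussian_profile, line_mask,
                      point_pair_masks, square_mask, sustained_profile)

__all__ = [
    "save_run", "load_run", "save_result", "kernel_to_npz",
    "load_config", "build_protocol",
]


def save_run(path, record: SpikeRecord, trace: MembraneTrace | None = None,
             attrs: dict | None = None) -> None:
    """Write a run to HDF5: spike events, optional traces, config echo."""
    with h5py.File(path, "w") as f:
        g = f.create_group("spikes")
        g.create_dataset("times", data=record.times)
        g.create_dataset("x", data=record.xs)
        g.create_dataset("y", data=record.ys)
        f.attrs["grid"] = record.grid
        f.attrs["duration"] = record.duration
        if trace is not None:
            t = f.create_group("trace")
            t.create_dataset("cells", data=np.asarray(trace.cells))
            t.create_dataset("times", data=trace.times)
            t.create_dataset("V", data=trace.V)
            t.create_dataset("g_e", data=trace.g_e)
            t.create_dataset("g_i", data=trace.g_i)
        if attrs:
            f.attrs["config"] = json.dumps(attrs, sort_keys=True, default=str)


def load_run(path) -> tuple[SpikeRecord, MembraneTrace | None]:
    with h5py.File(path, "r") as f:
        record = SpikeRecord(
            times=f["spikes/times"][()], xs=f["spikes/x"][()], ys=f["spikes/y"][()],
            grid=tuple(int(v) for v in f.attrs["grid"]),
            duration=float(f.attrs["duration"]),
        )
        trace = None
        if "trace" in f:
            trace = MembraneTrace(
                cells=tuple((int(x), int(y)) for x, y in f["trace/cells"][()]),
                times=f["trace/times"][()], V=f["trace/V"][()],
                g_e=f["trace/g_e"][()], g_i=f["trace/g_i"][()],
            )
    return record, trace


def save_result(out_dir, result) -> Path:
    """Write an ExperimentResult: summary.csv plus a YAML meta block."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(out / "summary.csv", index=False)
    with open(out / "meta.yaml", "w") as fh:
        yaml.safe_dump(result.meta, fh, sort_keys=True)
    return out / "summary.csv"


def kernel_to_npz(path, field: KernelField) -> None:
    spec = field.spec
    np.savez(path, w_e=field.w_e, w_i=field.w_i, net=field.net,
             support_radius=field.support_radius,
             sigma_x=spec.sigma_x, sigma_y=spec.sigma_y, K=spec.K,
             beta=spec.beta, alpha_e=spec.alpha_e, alpha_i=spec.alpha_i,
             mu_x=spec.mu_x, mu_y=spec.mu_y,
             normalization=spec.normalization)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path!r} must be a YAML mapping")
    return cfg


def _kernel_from_config(cfg: dict) -> KernelField:
    kc = dict(cfg.get("kernel", {}))
    name = kc.pop("preset", "s1")
    grid = tuple(cfg.get("simulation", {}).get("grid", (100, 100)))
    if name == "custom":
        spec = KernelSpec(**kc)
    else:
        spec = preset(name, sigma=float(kc.get("sigma", 5.0)),
                      normalization=kc.get("normalization", "net-split"))
    return build_kernel(spec, grid=grid)


def _profile_from_config(pc) -> "RateProfile":
    if pc in (None, "gaussian"):
        return gaussian_profile()
    if pc == "sustained":
        return sustained_profile()
    kind = pc.pop("kind")
    if kind == "gaussian":
        return gaussian_profile(**pc)
    return sustained_profile(**pc)


def _stimuli_from_config(cfg: dict, grid) -> list[StimulusSpec]:
    sc = dict(cfg.get("stimulus", {}))
    kind = sc.get("kind", "line")
    profile = _profile_from_config(sc.get("profile"))
    alpha = float(sc.get("weight", 4000.0))
    nx, ny = grid
    if kind == "line":
        stim = line_mask(int(sc.get("size", 10)), grid=grid,
                         column=int(sc.get("column", nx // 2)),
                         center_y=int(sc.get("center_y", ny // 2)),
                         width=int(sc.get("width", 1)), alpha_s=alpha)
        return [stim.with_profile(profile)]
    center = tuple(sc.get("center", (nx // 2, ny // 2)))
    if kind == "square":
        return [square_mask(int(sc.get("size", 10)), grid=grid, center=center,
                            alpha_s=alpha).with_profile(profile)]
    if kind == "circle":
        return [circle_mask(int(sc.get("size", 10)), grid=grid, center=center,
                            alpha_s=alpha).with_profile(profile)]
    if kind == "points":
        a, b = point_pair_masks(int(sc.get("distance", 10)),
                                weight_A=float(sc.get("weight_A", 4000.0)),
                                weight_B=float(sc.get("weight_B", 4000.0)),
                                grid=grid, profile=profile)
        return [a, b]
    raise ValueError(f"unknown stimulus kind {kind!r}")


def build_protocol(cfg: dict):
    """Turn a YAML config mapping into (config, params, kernel, stimuli)."""
    sim = dict(cfg.get("simulation", {}))
    if "grid" in sim:
        sim["grid"] = tuple(sim["grid"])
    if "record_cells" in sim and sim["record_cells"] is not None:
        sim["record_cells"] = tuple(tuple(c) for c in sim["record_cells"])
    config = SimulationConfig(**sim)
    params = NeuronParams(**cfg.get("neuron", {}))
    kernel = _kernel_from_config(cfg)
    stimuli = _stimuli_from_config(cfg, config.grid)
    return config, params, kernel, stimuli
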