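"""Deterministic artifact I/O and per-stage seed derivation.

Every CSV/JSON artifact is written with stable column/key ordering and
fixed float precision, so rerunning a command with the same configuration
produces byte-identical files.  One global seed expands into independent
per-stage seeds through :func:`derive_seed`, making each pipeline stage
reproducible in isolation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "derive_seed",
    "write_csv",
    "write_json",
    "read_sweep_csv",
    "sweep_to_frame",
    "save_network",
    "load_network",
]

#: Fixed stage identifiers for seed derivation.
STAGES = {
    "synth": 1,
    "encode_train": 2,
    "encode_test": 3,
    "build": 4,
    "train": 5,
    "sweep": 6,
    "policy": 7,
    "perturb": 8,
    "correlated_clean": 9,
    "correlated_noisy": 10,
    "shuffle": 11,
    "events": 12,
}


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the global seed."""
    if stage not in STAGES:
        raise KeyError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(global_seed), STAGES[stage]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _round_floats(obj, digits=10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(f"{float(obj):.{digits}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), digits)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(results: dict, path) -> Path:
    """JSON report with sorted keys and fixed float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_round_floats(results), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def write_csv(frame: pd.DataFrame, path) -> Path:
    """CSV with fixed column order (as given) and %.10g floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.10g")
    return path


SWEEP_COLUMNS = ["tau_m", "v_th", "accuracy", "mean_rate",
                 "total_spikes", "sop", "in_manifold", "on_boundary"]


def sweep_to_frame(points, result=None) -> pd.DataFrame:
    """Sweep points (+ optional manifold masks) as the canonical CSV table."""
    rows = []
    flat_m = result.membership.ravel() if result is not None else None
    flat_b = result.boundary.ravel() if result is not None else None
    for i, p in enumerate(points):
        rows.append({
            "tau_m": p.tau_m, "v_th": p.v_th, "accuracy": p.accuracy,
            "mean_rate": p.mean_rate, "total_spikes": p.total_spikes,
            "sop": p.sop,
            "in_manifold": bool(flat_m[i]) if flat_m is not None else False,
            "on_boundary": bool(flat_b[i]) if flat_b is not None else False,
        })
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def read_sweep_csv(path):
    """Round-trip a sweep CSV back into SweepPoint objects."""
    from .manifold import SweepPoint

    frame = pd.read_csv(path)
    return [SweepPoint(tau_m=r.tau_m, v_th=r.v_th, accuracy=r.accuracy,
                       mean_rate=r.mean_rate, total_spikes=r.total_spikes,
                       sop=r.sop)
            for r in frame.itertuples()], frame


def save_network(network, path) -> Path:
    """Self-describing checkpoint: architecture + neuron config + weights."""
    from dataclasses import asdict

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, blk in enumerate(network.blocks):
        for name, value in blk.params().items():
            arrays[f"param_{i}_{name}"] = value
        if getattr(blk, "bn", None) is not None:
            arrays[f"bnstat_{i}_mean"] = blk.bn.running_mean
            arrays[f"bnstat_{i}_var"] = blk.bn.running_var
    meta = {
        "spec": asdict(network.spec),
        "neuron": asdict(network.neuron),
        "trained": network.trained,
    }
    arrays["meta"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path


def load_network(path):
    """Rebuild a network from a checkpoint written by :func:`save_network`."""
    from .lif import NeuronConfig
    from .networks import ArchitectureSpec, build_network

    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        spec_d = dict(meta["spec"])
        for key in ("input_shape", "hidden_sizes", "conv_channels"):
            if isinstance(spec_d.get(key), list):
                spec_d[key] = tuple(spec_d[key])
        spec = ArchitectureSpec(**spec_d)
        net = build_network(spec, NeuronConfig(**meta["neuron"]), seed=0)
        for i, blk in enumerate(net.blocks):
            for name in blk.params():
                blk.set_param(name, data[f"param_{i}_{name}"].copy())
            if getattr(blk, "bn", None) is not None:
                blk.bn.running_mean = data[f"bnstat_{i}_mean"].copy()
                blk.bn.running_var = data[f"bnstat_{i}_var"].copy()
        net.trained = bool(meta["trained"])
    return net
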