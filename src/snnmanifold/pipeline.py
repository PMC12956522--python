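"""Configured pipeline stages tying the analysis together.

Each stage is a pure function of a resolved configuration dictionary (one
global seed expands into per-stage seeds) plus artifacts on disk, so the
command-line interface stays a thin wrapper and every stage is equally
usable from Python.  Stage outputs are deterministic: rerunning a stage
with the same configuration writes byte-identical CSV/JSON artifacts.

Default experiment (desk scale): a 4-class 12x12 template task, a small
one-hidden-layer MLP-SNN (144 -> 32 -> 4) at T = 10 steps, a 5x5
(tau_m, v_th) sweep over the standard ranges, BES(lambda = 0.5) /
EAS(beta = 5) scoring, the reset/carry policy curve, and the frame-
permutation drift diagnostics.
"""

from __future__ import annotations

import copy
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, efficiency, reporting
from .encoding import poisson_encode_batch
from .lif import NeuronConfig
from .manifold import (ManifoldSpec, SweepGrid, SweepTask, is_four_connected,
                       membership, run_sweep)
from .networks import (ArchitectureSpec, TrainingConfig, build_network,
                       evaluate, train)
from .policies import class_output_histogram, evaluate_policy_curve
from .synthetic import (SyntheticTaskConfig, make_correlated_spike_trains,
                        make_static_task)

logger = logging.getLogger("snnmanifold")

__all__ = ["DEFAULT_CONFIG", "load_config", "resolve_config", "run_command"]

DEFAULT_CONFIG = {
    "seed": 0,
    "task": {
        "n_classes": 4, "height": 12, "width": 12,
        "n_train_per_class": 50, "n_test_per_class": 25,
        "contrast": 0.5, "noise_std": 0.45,
    },
    "architecture": {"kind": "mlp", "hidden_sizes": [32],
                     "recurrent_last_hidden": False},
    "neuron": {"tau_m": 2.0, "v_th": 1.0, "v_reset": 0.0, "dt": 1.0,
               "t_ref": 0, "reset_mode": "hard"},
    "training": {"T": 10, "epochs": 15, "learning_rate": 1e-3,
                 "batch_size": 32, "surrogate_slope": 2.0, "policy": "reset"},
    "sweep": {"tau_range": [1.001, 5.0], "vth_range": [0.01, 3.0],
              "n_points": 5, "mode": "train_then_eval", "epochs": 10},
    "manifold": {"r_min": 0.01, "r_max": 0.5, "a_thr": 0.9, "relative": True},
    "efficiency": {"lambda": 0.5, "beta": 5.0},
    "policy_eval": {"T_values": [1, 2, 3, 5, 10]},
    "perturbation": {"max_pairs": 2000, "swap_increment": 1, "max_level": 30,
                     "n_test_per_class": 500},
    "correlated": {"n_neurons": 30, "T": 100, "rate": 0.1,
                   "c_clean": 0.0, "c_noisy": 0.5,
                   "n_samples_per_condition": 200},
}


def _deep_update(base: dict, update: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in (update or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    """Resolved configuration: documented defaults overlaid by a YAML file."""
    user = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    return resolve_config(user)


def resolve_config(overrides: dict | None = None) -> dict:
    return _deep_update(DEFAULT_CONFIG, overrides or {})


# ---------------------------------------------------------------------------
# Shared builders
# ---------------------------------------------------------------------------

def _task_config(cfg: dict, seed: int, **overrides) -> SyntheticTaskConfig:
    kw = dict(cfg["task"])
    kw.update(overrides)
    return SyntheticTaskConfig(seed=seed, **kw)


def _arch_spec(cfg: dict) -> ArchitectureSpec:
    a = cfg["architecture"]
    t = cfg["task"]
    if a["kind"] == "mlp":
        input_shape = t["height"] * t["width"]
    else:
        input_shape = (2, t["height"], t["width"])
    return ArchitectureSpec(
        kind=a["kind"], input_shape=input_shape,
        hidden_sizes=tuple(a.get("hidden_sizes", (512, 256, 64))),
        conv_channels=tuple(a.get("conv_channels", (64, 128))),
        head_hidden=a.get("head_hidden", 64),
        n_classes=t["n_classes"],
        recurrent_last_hidden=a.get("recurrent_last_hidden", False))


def _neuron(cfg: dict) -> NeuronConfig:
    return NeuronConfig(**cfg["neuron"])


def _training(cfg: dict, seed: int, **overrides) -> TrainingConfig:
    kw = dict(cfg["training"])
    kw.update(overrides)
    return TrainingConfig(seed=seed, **kw)


def _encoded_splits(cfg: dict, dataset):
    T = cfg["training"]["T"]
    seed = cfg["seed"]
    xtr = poisson_encode_batch(
        dataset.train_x.reshape(len(dataset.train_y), -1),
        T, reporting.derive_seed(seed, "encode_train"))
    xte = poisson_encode_batch(
        dataset.test_x.reshape(len(dataset.test_y), -1),
        T, reporting.derive_seed(seed, "encode_test"))
    return xtr, xte


def _load_dataset(out_dir: Path):
    train_path = out_dir / "dataset_train.csv"
    test_path = out_dir / "dataset_test.csv"
    if not train_path.exists() or not test_path.exists():
        raise FileNotFoundError(
            f"dataset CSVs not found under {out_dir}; run 'synth' first")

    def _read(path):
        frame = pd.read_csv(path)
        labels = frame["label"].to_numpy(np.int64)
        pixels = frame.drop(columns="label").to_numpy(float)
        return pixels, labels

    return _read(train_path), _read(test_path)


def _trained_network(cfg: dict, out_dir: Path):
    ckpt = out_dir / "checkpoint.npz"
    if not ckpt.exists():
        raise FileNotFoundError(f"{ckpt} not found; run 'train' first")
    return reporting.load_network(ckpt)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_synth(cfg: dict, out_dir: Path) -> dict:
    seed = reporting.derive_seed(cfg["seed"], "synth")
    dataset = make_static_task(_task_config(cfg, seed))
    h, w = cfg["task"]["height"], cfg["task"]["width"]
    cols = [f"px_{i}" for i in range(h * w)]

    def _frame(x, y):
        frame = pd.DataFrame(x.reshape(len(y), -1), columns=cols)
        frame.insert(0, "label", y)
        return frame

    reporting.write_csv(_frame(dataset.train_x, dataset.train_y),
                        out_dir / "dataset_train.csv")
    reporting.write_csv(_frame(dataset.test_x, dataset.test_y),
                        out_dir / "dataset_test.csv")
    reporting.write_json({"config": cfg, "stage": "synth",
                          "stage_seed": seed,
                          "n_train": len(dataset.train_y),
                          "n_test": len(dataset.test_y)},
                         out_dir / "synth.json")
    logger.info("synth: wrote %d train / %d test samples",
                len(dataset.train_y), len(dataset.test_y))
    return {"dataset": dataset}


def stage_train(cfg: dict, out_dir: Path) -> dict:
    (train_x, train_y), (test_x, test_y) = _load_dataset(out_dir)

    class _DS:  # minimal view matching the generator's dataset layout
        pass

    ds = _DS()
    ds.train_x, ds.train_y, ds.test_x, ds.test_y = train_x, train_y, test_x, test_y
    xtr, xte = _encoded_splits(cfg, ds)
    net = build_network(_arch_spec(cfg), _neuron(cfg),
                        seed=reporting.derive_seed(cfg["seed"], "build"))
    history = train(net, xtr, train_y,
                    _training(cfg, reporting.derive_seed(cfg["seed"], "train")))
    test_acc = evaluate(net, xte, test_y)
    reporting.write_csv(history, out_dir / "history.csv")
    reporting.save_network(net, out_dir / "checkpoint.npz")
    reporting.write_json({"config": cfg, "stage": "train",
                          "final_train_accuracy": float(history.accuracy.iloc[-1])
                          if len(history) else None,
                          "test_accuracy": float(test_acc)},
                         out_dir / "train.json")
    logger.info("train: test accuracy %.3f", test_acc)
    return {"network": net, "history": history, "test_accuracy": test_acc}


def stage_sweep(cfg: dict, out_dir: Path) -> dict:
    (train_x, train_y), (test_x, test_y) = _load_dataset(out_dir)

    class _DS:
        pass

    ds = _DS()
    ds.train_x, ds.train_y, ds.test_x, ds.test_y = train_x, train_y, test_x, test_y
    xtr, xte = _encoded_splits(cfg, ds)
    sw = cfg["sweep"]
    grid = SweepGrid.uniform(tuple(sw["tau_range"]), tuple(sw["vth_range"]),
                             sw["n_points"])
    base_seed = reporting.derive_seed(cfg["seed"], "sweep")
    task = SweepTask(xtr, train_y, xte, test_y, _arch_spec(cfg),
                     _training(cfg, base_seed, epochs=sw["epochs"]),
                     v_reset=cfg["neuron"]["v_reset"], dt=cfg["neuron"]["dt"],
                     reset_mode=cfg["neuron"]["reset_mode"])
    points = run_sweep(task, grid, mode=sw["mode"], base_seed=base_seed)
    spec = ManifoldSpec(r_min=cfg["manifold"]["r_min"],
                        r_max=cfg["manifold"]["r_max"],
                        a_thr=cfg["manifold"]["a_thr"],
                        relative=cfg["manifold"]["relative"])
    result = membership(points, grid, spec)
    reporting.write_csv(reporting.sweep_to_frame(points, result),
                        out_dir / "sweep.csv")
    reporting.write_json({"config": cfg, "stage": "sweep",
                          "base_seed": base_seed,
                          "grid_shape": list(grid.shape),
                          "resolved_a_thr": result.resolved_a_thr,
                          "manifold_size": int(result.membership.sum()),
                          "boundary_size": int(result.boundary.sum()),
                          "four_connected": is_four_connected(result.membership)},
                         out_dir / "manifold.json")
    logger.info("sweep: %d/%d points in manifold",
                int(result.membership.sum()), len(points))
    return {"points": points, "grid": grid, "result": result}


def stage_score(cfg: dict, out_dir: Path) -> dict:
    sweep_path = out_dir / "sweep.csv"
    if not sweep_path.exists():
        raise FileNotFoundError(f"{sweep_path} not found; run 'sweep' first")
    points, frame = reporting.read_sweep_csv(sweep_path)
    lam, beta = cfg["efficiency"]["lambda"], cfg["efficiency"]["beta"]
    grid = efficiency.score_sweep(points, lam=lam, beta=beta)
    frame["a_norm"] = grid.a_norm
    frame["e_norm"] = grid.e_norm
    frame["bes"] = grid.bes
    frame["eas"] = grid.eas
    frame["pareto"] = [i in grid.pareto_indices for i in range(len(points))]
    reporting.write_csv(frame, out_dir / "sweep_scored.csv")

    def _point(i):
        p = points[i]
        return {"tau_m": p.tau_m, "v_th": p.v_th, "accuracy": p.accuracy,
                "sop": p.sop}

    report = {"config": cfg, "stage": "score", "lambda": lam, "beta": beta,
              "best_bes": _point(grid.best_bes_index),
              "best_eas": _point(grid.best_eas_index),
              "pareto_front": [_point(i) for i in grid.pareto_indices]}
    reporting.write_json(report, out_dir / "efficiency.json")
    logger.info("score: best BES at tau=%.3f vth=%.3f",
                points[grid.best_bes_index].tau_m,
                points[grid.best_bes_index].v_th)
    return {"grid": grid, "report": report}


def stage_policy(cfg: dict, out_dir: Path) -> dict:
    (_, _), (test_x, test_y) = _load_dataset(out_dir)
    net = _trained_network(cfg, out_dir)
    seed = reporting.derive_seed(cfg["seed"], "policy")
    curve = evaluate_policy_curve(net, test_x, test_y,
                                  T_values=tuple(cfg["policy_eval"]["T_values"]),
                                  seed=seed)
    rows = [{"policy": pol, "T": T, "accuracy": acc}
            for pol in curve.accuracy
            for T, acc in zip(curve.T_values, curve.accuracy[pol])]
    reporting.write_csv(pd.DataFrame(rows, columns=["policy", "T", "accuracy"]),
                        out_dir / "policy_curve.csv")
    hist_rows = []
    for pol in curve.accuracy:
        hist = class_output_histogram(net, test_x, test_y, class_label=1,
                                      policy=pol, T=3, seed=seed)
        for t in range(hist.shape[0]):
            for neuron_idx in range(hist.shape[1]):
                hist_rows.append({"policy": pol, "t": t + 1,
                                  "neuron": neuron_idx,
                                  "mean_count": hist[t, neuron_idx]})
    reporting.write_csv(pd.DataFrame(
        hist_rows, columns=["policy", "t", "neuron", "mean_count"]),
        out_dir / "output_histograms.csv")
    reporting.write_json({"config": cfg, "stage": "policy",
                          "order_seed": curve.order_seed},
                         out_dir / "policy.json")
    return {"curve": curve}


def stage_diagnose(cfg: dict, out_dir: Path) -> dict:
    net = _trained_network(cfg, out_dir)
    seed = cfg["seed"]
    pert_seed = reporting.derive_seed(seed, "perturb")
    # a larger evaluation pool so the pair-collection protocol has supply
    pool_cfg = _task_config(cfg, reporting.derive_seed(seed, "synth"),
                            n_test_per_class=cfg["perturbation"]["n_test_per_class"])
    pool = make_static_task(pool_cfg)
    pool_x = poisson_encode_batch(pool.test_x.reshape(len(pool.test_y), -1),
                                  cfg["training"]["T"],
                                  reporting.derive_seed(seed, "encode_test"))
    pcfg = diagnostics.PerturbationConfig(
        max_pairs=cfg["perturbation"]["max_pairs"],
        swap_increment=cfg["perturbation"]["swap_increment"],
        max_level=cfg["perturbation"]["max_level"], seed=pert_seed)
    pairs = diagnostics.collect_pairs(net, pool_x, pool.test_y, pcfg)

    report = {"config": cfg, "stage": "diagnose", "n_pairs": len(pairs)}
    if pairs:
        clean_avg = diagnostics.average_matrices(
            [diagnostics.correlation_matrix(p.clean_activity) for p in pairs])
        noisy_avg = diagnostics.average_matrices(
            [diagnostics.correlation_matrix(p.perturbed_activity) for p in pairs])
        report["pair_summary"] = {
            "clean": diagnostics.summarize_correlations(clean_avg).as_dict(),
            "noisy": diagnostics.summarize_correlations(noisy_avg).as_dict(),
            "mean_flip_level": float(np.mean([p.flip_level for p in pairs])),
        }

    cc = cfg["correlated"]
    clean_seed = reporting.derive_seed(seed, "correlated_clean")
    noisy_seed = reporting.derive_seed(seed, "correlated_noisy")
    acts = {"clean": [make_correlated_spike_trains(
                cc["n_neurons"], cc["T"], cc["rate"], cc["c_clean"],
                seed=clean_seed + i)
                for i in range(cc["n_samples_per_condition"])],
            "noisy": [make_correlated_spike_trains(
                cc["n_neurons"], cc["T"], cc["rate"], cc["c_noisy"],
                seed=noisy_seed + i)
                for i in range(cc["n_samples_per_condition"])]}
    table = diagnostics.feature_table(acts)
    reporting.write_csv(table, out_dir / "features.csv")
    labels = (table["condition"] == "noisy").astype(int).to_numpy()
    feats = table[list(diagnostics.FEATURE_NAMES)]
    mi = diagnostics.mutual_information_scores(feats, labels)
    acc, importances = diagnostics.condition_classifier(feats, labels, seed=seed)
    report["mutual_information_bits"] = mi.to_dict()
    report["classifier_accuracy"] = acc
    report["feature_importances"] = importances.to_dict()
    reporting.write_json(report, out_dir / "diagnostics.json")
    logger.info("diagnose: %d pairs, classifier accuracy %.3f", len(pairs), acc)
    return {"pairs": pairs, "report": report, "table": table}


_COMMANDS = {
    "synth": stage_synth,
    "train": stage_train,
    "sweep": stage_sweep,
    "score": stage_score,
    "policy": stage_policy,
    "diagnose": stage_diagnose,
}


def run_command(name: str, cfg: dict, out_dir) -> dict:
    """Dispatch one pipeline stage; artifacts land under ``out_dir``."""
    if name not in _COMMANDS:
        raise ValueError(f"unknown command {name!r}; "
                         f"choose from {sorted(_COMMANDS)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return _COMMANDS[name](cfg, out_dir)
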