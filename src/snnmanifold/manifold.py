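"""Operational-manifold mapping over the (tau_m, v_th) plane.

For each point theta = (tau_m, v_th) of a uniform grid, a network is
trained (or re-evaluated) and summarised by its test accuracy A(theta) and
mean firing rate

    rbar(theta) = (1/N) * sum_{l,i} (1/T) * sum_t S_{l,i}^t,

averaged over the evaluation set, where N is the total spiking-neuron
count across all spiking layers (output layer included).  The operational
manifold M is the set of grid points whose rate lies inside a balanced
band [r_min, r_max] — excluding silent and saturated regimes — and whose
accuracy clears a floor A_thr.  The boundary dM marks members with at
least one axis-adjacent neighbour outside M; cells on the grid edge count
as boundary because off-grid behaviour is uncertified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import efficiency
from .lif import RESET, NeuronConfig
from .networks import (ArchitectureSpec, Network, TrainingConfig,
                       build_network, evaluate, train)

__all__ = [
    "SweepGrid",
    "SweepPoint",
    "SweepTask",
    "ManifoldSpec",
    "ManifoldResult",
    "mean_firing_rate",
    "rate_from_stats",
    "run_sweep",
    "membership",
    "boundary",
    "is_four_connected",
]


@dataclass(frozen=True)
class SweepGrid:
    """Uniform grid over the two neuron hyperparameters.

    Defaults follow the standard sweep: tau_m in [1.001, 5] ms and v_th in
    [0.01, 3] V, 10 uniformly spaced points each (fully configurable; some
    settings need wider ranges before silent/saturated regimes appear).
    """

    tau_values: tuple = field(default=None)  # type: ignore[assignment]
    vth_values: tuple = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.tau_values is None:
            object.__setattr__(self, "tau_values",
                               tuple(np.linspace(1.001, 5.0, 10)))
        if self.vth_values is None:
            object.__setattr__(self, "vth_values",
                               tuple(np.linspace(0.01, 3.0, 10)))
        for name in ("tau_values", "vth_values"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.ndim != 1 or len(vals) < 1:
                raise ValueError(f"{name} must be a 1-D sequence")
            if len(vals) > 1 and not np.all(np.diff(vals) > 0):
                raise ValueError(f"{name} must be strictly increasing")

    @classmethod
    def uniform(cls, tau_range=(1.001, 5.0), vth_range=(0.01, 3.0),
                n_points: int = 10) -> "SweepGrid":
        return cls(tuple(np.linspace(*tau_range, n_points)),
                   tuple(np.linspace(*vth_range, n_points)))

    @property
    def shape(self) -> tuple:
        return (len(self.tau_values), len(self.vth_values))


@dataclass
class SweepPoint:
    """Measurements at one grid point theta = (tau_m, v_th)."""

    tau_m: float
    v_th: float
    accuracy: float
    mean_rate: float
    total_spikes: float
    sop: float


@dataclass
class SweepTask:
    """Everything a sweep needs: encoded data, architecture and training
    recipe, plus the fixed (non-swept) neuron constants.

    ``network`` is only consulted in ``eval_only`` mode, where a single
    trained network is re-run under each theta instead of retraining.
    """

    train_inputs: np.ndarray
    train_labels: np.ndarray
    test_inputs: np.ndarray
    test_labels: np.ndarray
    arch: ArchitectureSpec
    training: TrainingConfig
    v_reset: float = 0.0
    dt: float = 1.0
    reset_mode: str = "hard"
    network: Network | None = None


@dataclass(frozen=True)
class ManifoldSpec:
    """Membership thresholds.

    ``r_min``/``r_max`` bound the balanced firing band in spikes per neuron
    per timestep.  ``a_thr`` is the accuracy floor; with
    ``relative=True`` (default) it is interpreted as a fraction of the best
    accuracy observed in the sweep.
    """

    r_min: float = 0.01
    r_max: float = 0.5
    a_thr: float = 0.9
    relative: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_min < self.r_max <= 1.0:
            raise ValueError("need 0 <= r_min < r_max <= 1")
        if self.a_thr < 0:
            raise ValueError("a_thr must be >= 0")


@dataclass
class ManifoldResult:
    """Boolean membership mask M and boundary mask dM over the grid."""

    membership: np.ndarray
    boundary: np.ndarray
    resolved_a_thr: float


def mean_firing_rate(records) -> float:
    """Mean spike rate per neuron per timestep from layer-wise spike trains.

    ``records`` is an iterable of samples, each a list of per-layer binary
    [T, ...] tensors covering every spiking layer.  The rate is averaged
    over neurons, time and samples.
    """
    records = list(records)
    if not records:
        raise ValueError("empty record set")
    rates = []
    for layers in records:
        total = 0.0
        n_neurons = 0
        for tensor in layers:
            arr = np.asarray(tensor)
            T = arr.shape[0]
            n = int(np.prod(arr.shape[1:]))
            total += arr.sum() / T
            n_neurons += n
        rates.append(total / n_neurons)
    return float(np.mean(rates))


def rate_from_stats(stats: dict) -> float:
    """Mean firing rate from the aggregated statistics of
    :func:`snnmanifold.networks.evaluate`."""
    total = sum(a.sum() for a in stats["spike_sums"])
    n_neurons = sum(stats["n_neurons"])
    T = len(stats["spike_sums"][0])
    return float(total / (stats["n_samples"] * n_neurons * T))


def run_sweep(task: SweepTask, grid: SweepGrid, mode: str = "train_then_eval",
              base_seed: int = 0) -> list:
    """Measure accuracy, firing rate, spike count and SOP at each theta.

    ``train_then_eval`` (default) trains a fresh network at every grid point
    with the same base seed, so points differ only through theta;
    ``eval_only`` re-evaluates ``task.network`` after swapping its neuron
    constants.  Points are returned in row-major order (tau outer, v_th
    inner).
    """
    if mode not in ("train_then_eval", "eval_only"):
        raise ValueError(f"unknown sweep mode {mode!r}")
    for tau in grid.tau_values:
        if tau <= task.dt:
            raise ValueError(f"grid tau_m {tau} <= dt {task.dt}")
    if mode == "eval_only" and task.network is None:
        raise ValueError("eval_only mode requires task.network")

    points = []
    saved_neuron = task.network.neuron if task.network is not None else None
    for tau in grid.tau_values:
        for vth in grid.vth_values:
            neuron = NeuronConfig(tau_m=tau, v_th=vth, v_reset=task.v_reset,
                                  dt=task.dt, reset_mode=task.reset_mode)
            if mode == "train_then_eval":
                net = build_network(task.arch, neuron, seed=base_seed)
                cfg = task.training
                if cfg.seed != base_seed:
                    cfg = TrainingConfig(**{**cfg.__dict__, "seed": base_seed})
                train(net, task.train_inputs, task.train_labels, cfg)
            else:
                net = task.network
                net.neuron = neuron
                for blk in net.blocks:
                    if getattr(blk, "spiking", False):
                        blk.lif.neuron = neuron
            acc, stats = evaluate(net, task.test_inputs, task.test_labels,
                                  policy=RESET, collect_stats=True)
            fanouts = efficiency.fanout_table(net)
            sop = efficiency.count_sop(stats["in_sums"], fanouts)
            points.append(SweepPoint(tau_m=float(tau), v_th=float(vth),
                                     accuracy=float(acc),
                                     mean_rate=rate_from_stats(stats),
                                     total_spikes=stats["total_spikes"],
                                     sop=float(sop)))
    if saved_neuron is not None:  # leave the provided network as it came
        task.network.neuron = saved_neuron
        for blk in task.network.blocks:
            if getattr(blk, "spiking", False):
                blk.lif.neuron = saved_neuron
    return points


def membership(points, grid: SweepGrid, spec: ManifoldSpec) -> ManifoldResult:
    """Boolean manifold mask: balanced rate band AND accuracy floor."""
    shape = grid.shape
    if len(points) != shape[0] * shape[1]:
        raise ValueError("points do not cover the grid")
    acc = np.array([p.accuracy for p in points]).reshape(shape)
    rate = np.array([p.mean_rate for p in points]).reshape(shape)
    a_thr = spec.a_thr * acc.max() if spec.relative else spec.a_thr
    mask = (rate >= spec.r_min) & (rate <= spec.r_max) & (acc >= a_thr)
    return ManifoldResult(mask, boundary(mask), float(a_thr))


def boundary(mask: np.ndarray) -> np.ndarray:
    """Members with at least one 4-neighbour outside M (off-grid counts as
    outside, so member cells on the grid edge are boundary)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 1:  # a genuine 1-D grid has only left/right neighbours
        padded = np.pad(mask, 1, constant_values=False)
        return mask & ~(padded[:-2] & padded[2:])
    padded = np.pad(mask, 1, constant_values=False)
    all_in = (padded[:-2, 1:-1] & padded[2:, 1:-1]
              & padded[1:-1, :-2] & padded[1:-1, 2:])
    return mask & ~all_in


def is_four_connected(mask: np.ndarray) -> bool:
    """True iff the True cells of the mask form one 4-connected component
    (vacuously true for an empty mask)."""
    mask = np.asarray(mask, dtype=bool)
    seeds = np.argwhere(mask)
    if len(seeds) == 0:
        return True
    seen = np.zeros_like(mask)
    stack = [tuple(seeds[0])]
    seen[tuple(seeds[0])] = True
    while stack:
        i, j = stack.pop()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if (0 <= ni < mask.shape[0] and 0 <= nj < mask.shape[1]
                    and mask[ni, nj] and not seen[ni, nj]):
                seen[ni, nj] = True
                stack.append((ni, nj))
    return bool(seen.sum() == mask.sum())
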