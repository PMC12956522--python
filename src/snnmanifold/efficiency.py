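"""Synaptic-operation energy proxy and composite accuracy-energy scores.

Computational cost is estimated in synaptic operations (SOP): every spike
entering a layer triggers one operation per synapse it fans out to,

    SOP = sum_l sum_t N_in^(l)(t) * f_fanout^(l),

with N_in^(l)(t) the spikes entering layer l at step t and f_fanout^(l)
the layer's synaptic fan-out (dense layer: its output width; 3x3 conv
layer: 9 * out_channels, an interior approximation that ignores image-
boundary truncation — constant across a sweep, so rankings are
unaffected).

Over a sweep, accuracy and SOP are min-max normalised to [0, 1] and
combined into two scalar scores:

    BES_lambda = A_norm - lambda * E_norm                (weighted difference)
    EAS_beta   = (1 + beta^2) * A_norm * (1 - E_norm)
                 / (beta^2 * A_norm + (1 - E_norm))      (F_beta-style)

Low lambda favours accuracy, high lambda energy savings; beta > 1
emphasises accuracy in the harmonic trade-off, beta < 1 energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FanoutTable",
    "EfficiencyGrid",
    "fanout_table",
    "count_sop",
    "min_max_normalize",
    "bes",
    "eas",
    "pareto_front",
    "score_sweep",
]


@dataclass(frozen=True)
class FanoutTable:
    """Per-layer synaptic fan-out: synapses driven by one incoming spike."""

    fanouts: tuple

    def __post_init__(self) -> None:
        if any(f <= 0 or int(f) != f for f in self.fanouts):
            raise ValueError("fan-outs must be positive integers")


@dataclass
class EfficiencyGrid:
    """Normalised grids and both composite scores over a sweep."""

    a_norm: np.ndarray
    e_norm: np.ndarray
    lam: float
    beta: float
    bes: np.ndarray
    eas: np.ndarray
    best_bes_index: int
    best_eas_index: int
    pareto_indices: tuple


def fanout_table(network) -> FanoutTable:
    """Fan-out of every synaptic (spiking) layer of a network, in order."""
    return FanoutTable(tuple(blk.fanout for blk in network.blocks
                             if getattr(blk, "spiking", False)))


def count_sop(incoming_per_layer, fanouts: FanoutTable) -> float:
    """SOP count from per-layer incoming-spike totals.

    ``incoming_per_layer`` holds, for each synaptic layer, the spikes
    entering it per timestep (array [T] or any summable array).
    """
    layers = list(incoming_per_layer)
    if len(layers) != len(fanouts.fanouts):
        raise ValueError(
            f"{len(layers)} layers of spike counts but "
            f"{len(fanouts.fanouts)} fan-out entries")
    total = 0.0
    for counts, f in zip(layers, fanouts.fanouts):
        arr = np.asarray(counts, dtype=float)
        if (arr < 0).any():
            raise ValueError("spike counts must be nonnegative")
        total += arr.sum() * f
    return float(total)


def min_max_normalize(values) -> np.ndarray:
    """(x - min) / (max - min); a flat dimension maps everything to 0."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def bes(a_norm, e_norm, lam: float):
    """Balanced efficiency score A_norm - lambda * E_norm."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    return np.asarray(a_norm, dtype=float) - lam * np.asarray(e_norm, dtype=float)


def eas(a_norm, e_norm, beta: float):
    """F_beta-style efficiency-accuracy score; 0 where the denominator
    vanishes (both arguments zero).

    Accuracy occupies the emphasised (recall) slot of the F_beta form, so
    beta > 1 stresses accuracy and the beta -> infinity ranking converges
    to the accuracy ranking; beta < 1 stresses energy savings.
    """
    if beta <= 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    a = np.asarray(a_norm, dtype=float)
    inv_e = 1.0 - np.asarray(e_norm, dtype=float)
    denom = beta ** 2 * inv_e + a
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (1 + beta ** 2) * a * inv_e
                       / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def pareto_front(a_norm, inv_e_norm) -> tuple:
    """Indices of points not dominated in (A_norm, 1 - E_norm).

    A point is dominated if another is >= in both coordinates and > in at
    least one.  Duplicated optimal points are all kept.
    """
    a = np.asarray(a_norm, dtype=float)
    e = np.asarray(inv_e_norm, dtype=float)
    keep = []
    for i in range(len(a)):
        dominated = np.any((a >= a[i]) & (e >= e[i])
                           & ((a > a[i]) | (e > e[i])))
        if not dominated:
            keep.append(i)
    return tuple(keep)


def score_sweep(points, lam: float = 0.5, beta: float = 5.0) -> EfficiencyGrid:
    """Normalise a sweep's accuracy and SOP, score every point, and report
    the best configuration per score plus the Pareto front."""
    points = list(points)
    if not points:
        raise ValueError("empty sweep")
    acc = np.array([p.accuracy for p in points])
    sop = np.array([p.sop for p in points])
    a_norm = min_max_normalize(acc)
    e_norm = min_max_normalize(sop)
    bes_grid = bes(a_norm, e_norm, lam)
    eas_grid = eas(a_norm, e_norm, beta)
    return EfficiencyGrid(
        a_norm=a_norm, e_norm=e_norm, lam=lam, beta=beta,
        bes=bes_grid, eas=eas_grid,
        best_bes_index=int(np.argmax(bes_grid)),
        best_eas_index=int(np.argmax(eas_grid)),
        pareto_indices=pareto_front(a_norm, 1.0 - e_norm),
    )
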