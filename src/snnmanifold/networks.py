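"""Spiking network construction, simulation and surrogate-gradient training.

Two backbone families are provided, both built from shared LIF dynamics:

* **MLP-SNN** — fully connected hidden layers (default 512-256-64), each as
  Linear -> BatchNorm -> LIF, followed by a Linear -> LIF output layer
  without normalization.
* **ConvSNN** — two Conv(3x3, stride 1, pad 1) -> BatchNorm -> LIF ->
  MaxPool(2x2) blocks (default 64 and 128 channels), global average
  pooling, then a dense head (128 -> 64 -> n_classes).

All spiking layers share a single :class:`~snnmanifold.lif.NeuronConfig`.
Decisions are read out by accumulating output-layer spikes as an average
over the T-step window.  Training unrolls the dynamics over time
(backpropagation through time) and replaces the derivative of the spike
indicator with the arctangent pseudo-derivative

    g(u) = s / (1 + (pi * s * u)^2),   u = v_pre - v_th,

with slope ``s`` (default 2.0).  The same backward code also supports a
*smoothed* forward pass in which the hard indicator is replaced by its
antiderivative-consistent soft counterpart h(u) = 1/2 + arctan(pi*s*u)/pi;
in that mode the computed gradients are exact and can be verified against
finite differences.

The implementation is plain numpy: the experiments in this package are
desk-scale (small networks, T = 10), where an explicit tape is simple,
fast enough, and bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lif import CARRY, RESET, NeuronConfig

__all__ = [
    "ArchitectureSpec",
    "TrainingConfig",
    "ActivityRecord",
    "Network",
    "build_network",
    "forward",
    "predict",
    "train",
    "evaluate",
    "add_recurrence",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureSpec:
    """Architecture description for the two custom SNN families.

    ``input_shape`` is the flat input size for ``kind="mlp"`` or a
    ``(channels, height, width)`` tuple for ``kind="conv"`` (spatial dims
    must be divisible by 4 because of the two 2x2 pooling stages).
    """

    kind: str = "mlp"
    input_shape: tuple | int = 784
    hidden_sizes: tuple = (512, 256, 64)
    conv_channels: tuple = (64, 128)
    head_hidden: int = 64
    n_classes: int = 10
    recurrent_last_hidden: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("mlp", "conv"):
            raise ValueError(f"kind must be 'mlp' or 'conv', got {self.kind!r}")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.kind == "conv":
            c, h, w = self.input_shape
            if h % 4 or w % 4:
                raise ValueError("conv input spatial dims must be divisible by 4")


@dataclass(frozen=True)
class TrainingConfig:
    """Surrogate-gradient training hyperparameters.

    ``policy`` is the between-sample membrane-state policy applied during
    training (reset by default, matching i.i.d. static data).
    """

    T: int = 10
    epochs: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 32
    surrogate_slope: float = 2.0
    policy: str = RESET
    seed: int = 0
    adam_betas: tuple = (0.9, 0.999)
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class ActivityRecord:
    """Per-layer binary spike traces for one sample, plus the outcome."""

    layer_spikes: list            # one [T, ...] int8 array per spiking layer
    layer_names: list
    output_counts: np.ndarray     # per-class mean output spikes
    predicted: int
    true_label: int | None = None
    degenerate: bool = False      # no output spikes at all


# ---------------------------------------------------------------------------
# Primitive forward/backward helpers
# ---------------------------------------------------------------------------

def _conv2d_fwd(x, W, b):
    kh, kw = W.shape[2:]
    xp = np.pad(x, ((0, 0), (0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    out = np.einsum("nchwij,ocij->nohw", win, W, optimize=True)
    return out + b[None, :, None, None], win


def _conv2d_bwd(win, W, dout):
    dW = np.einsum("nchwij,nohw->ocij", win, dout, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    kh, kw = W.shape[2:]
    dp = np.pad(dout, ((0, 0), (0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2)))
    dwin = np.lib.stride_tricks.sliding_window_view(dp, (kh, kw), axis=(2, 3))
    dx = np.einsum("nohwij,ocij->nchw", dwin, W[:, :, ::-1, ::-1], optimize=True)
    return dx, dW, db


def _maxpool_fwd(x):
    n, c, h, w = x.shape
    xr = (x.reshape(n, c, h // 2, 2, w // 2, 2)
           .transpose(0, 1, 2, 4, 3, 5)
           .reshape(n, c, h // 2, w // 2, 4))
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool_bwd(dout, idx, x_shape):
    n, c, h, w = x_shape
    dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=float)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    return (dxr.reshape(n, c, h // 2, w // 2, 2, 2)
               .transpose(0, 1, 2, 4, 3, 5)
               .reshape(n, c, h, w))


def _surrogate(u, slope):
    return slope / (1.0 + (math.pi * slope * u) ** 2)


def _soft_spike(u, slope):
    return 0.5 + np.arctan(math.pi * slope * u) / math.pi


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------

class _BatchNorm:
    """Per-feature batch normalization, statistics shared across timesteps.

    At initialization the transform is the identity (running mean 0,
    variance 1, unit affine), so untrained networks behave analytically.
    """

    def __init__(self, n_features, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, axes, train, update_running, tape):
        # axes: reduction axes; features on the remaining axis
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            if update_running:
                self.running_mean = ((1 - self.momentum) * self.running_mean
                                     + self.momentum * mu)
                self.running_var = ((1 - self.momentum) * self.running_var
                                    + self.momentum * var)
        else:
            mu, var = self.running_mean, self.running_var
        shape = [1] * x.ndim
        feat_axis = [a for a in range(x.ndim) if a not in axes][0]
        shape[feat_axis] = x.shape[feat_axis]
        mu_b = mu.reshape(shape)
        std_b = np.sqrt(var + self.eps).reshape(shape)
        xhat = (x - mu_b) / std_b
        if tape is not None:
            tape["bn_xhat"] = xhat
            tape["bn_std"] = std_b
            tape["bn_axes"] = axes
            tape["bn_shape"] = shape
            tape["bn_train"] = train
        return self.gamma.reshape(shape) * xhat + self.beta.reshape(shape)

    def backward(self, dout, tape, grads):
        xhat, std_b = tape["bn_xhat"], tape["bn_std"]
        axes, shape = tape["bn_axes"], tape["bn_shape"]
        grads["gamma"] = (dout * xhat).sum(axis=axes)
        grads["beta"] = dout.sum(axis=axes)
        g = self.gamma.reshape(shape)
        if not tape["bn_train"]:
            return dout * g / std_b
        m = np.prod([dout.shape[a] for a in axes])
        dxhat = dout * g
        mean_dxhat = dxhat.mean(axis=axes).reshape(shape)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes).reshape(shape)
        return (dxhat - mean_dxhat - xhat * mean_dxhat_xhat) / std_b


class _LIFUnit:
    """Time loop over LIF dynamics for one spiking layer (any feature shape).

    Holds the persistent membrane/spike state used by the between-sample
    policies.  ``t_ref > 0`` is supported at inference; training requires
    ``t_ref == 0`` (the hyperparameter sweeps vary only tau_m and v_th).
    """

    def __init__(self, neuron: NeuronConfig):
        self.neuron = neuron
        self.v = None          # [B, *feat]
        self.s = None
        self.refr = None

    def reset(self, batch, feat_shape):
        self.v = np.full((batch,) + feat_shape, self.neuron.v_reset, dtype=float)
        self.s = np.zeros((batch,) + feat_shape, dtype=float)
        self.refr = np.zeros((batch,) + feat_shape, dtype=np.int64)

    def ensure(self, batch, feat_shape):
        if self.v is None or self.v.shape != (batch,) + feat_shape:
            self.reset(batch, feat_shape)

    def forward(self, Z, wrec=None, smooth=False, slope=2.0, tape=None):
        cfg = self.neuron
        alpha = cfg.alpha
        B, T = Z.shape[:2]
        feat = Z.shape[2:]
        self.ensure(B, feat)
        if cfg.t_ref > 0 and tape is not None:
            raise ValueError("training requires t_ref == 0")
        v, s_prev, refr = self.v, self.s, self.refr
        v_pre_hist = np.empty_like(Z, dtype=float)
        S = np.empty_like(Z, dtype=float)
        s_entry = s_prev
        for t in range(T):
            I = Z[:, t].astype(float)
            if wrec is not None:
                I = I + s_prev @ wrec.T
            active = refr <= 0
            v_pre = (1.0 - alpha) * v + I
            if smooth:
                s = _soft_spike(v_pre - cfg.v_th, slope)
            else:
                s = (active & (v_pre >= cfg.v_th)).astype(float)
            if cfg.reset_mode == "hard":
                v_new = v_pre * (1.0 - s) + cfg.v_reset * s
            else:
                v_new = v_pre - cfg.v_th * s
            if cfg.t_ref > 0:
                v = np.where(active, v_new, v)
                refr = np.where(active, 0, refr - 1)
                refr = np.where(s > 0, cfg.t_ref, refr)
            else:
                v = v_new
            v_pre_hist[:, t] = v_pre
            S[:, t] = s
            s_prev = s
        self.v, self.s, self.refr = v, s_prev, refr
        if tape is not None:
            tape["lif_vpre"] = v_pre_hist
            tape["lif_S"] = S
            tape["lif_s_entry"] = s_entry
            tape["lif_smooth"] = smooth
        return S

    def backward(self, dS, tape, wrec=None, slope=2.0):
        cfg = self.neuron
        alpha = cfg.alpha
        v_pre_hist, S = tape["lif_vpre"], tape["lif_S"]
        s_entry = tape["lif_s_entry"]
        T = dS.shape[1]
        dZ = np.empty_like(dS, dtype=float)
        dv = np.zeros(dS.shape[:1] + dS.shape[2:], dtype=float)
        dwrec = np.zeros_like(wrec) if wrec is not None else None
        ds_rec = 0.0
        for t in reversed(range(T)):
            ds_t = dS[:, t] + ds_rec
            v_pre = v_pre_hist[:, t]
            s = S[:, t]
            g = _surrogate(v_pre - cfg.v_th, slope)
            if cfg.reset_mode == "hard":
                dv_pre = dv * (1.0 - s) + (ds_t + dv * (cfg.v_reset - v_pre)) * g
            else:
                dv_pre = dv + (ds_t - cfg.v_th * dv) * g
            dZ[:, t] = dv_pre
            if wrec is not None:
                s_prev = S[:, t - 1] if t > 0 else s_entry
                dwrec += dv_pre.T @ s_prev
                ds_rec = dv_pre @ wrec
            dv = (1.0 - alpha) * dv_pre
        return dZ, dwrec


class _DenseBlock:
    """Linear -> (BatchNorm) -> LIF, with optional recurrence on its own
    previous-step spikes (current added after normalization)."""

    name = "dense"

    def __init__(self, n_in, n_out, neuron, rng, bn=True):
        bound = 1.0 / math.sqrt(n_in)
        self.W = rng.uniform(-bound, bound, size=(n_out, n_in))
        self.b = rng.uniform(-bound, bound, size=n_out)
        self.bn = _BatchNorm(n_out) if bn else None
        self.Wrec = None
        self.lif = _LIFUnit(neuron)
        self.n_in, self.n_out = n_in, n_out
        self.spiking = True

    @property
    def fanout(self) -> int:
        return self.n_out

    def n_neurons(self, feat_shape=None) -> int:
        return self.n_out

    def params(self):
        p = {"W": self.W, "b": self.b}
        if self.bn is not None:
            p["gamma"], p["beta"] = self.bn.gamma, self.bn.beta
        if self.Wrec is not None:
            p["Wrec"] = self.Wrec
        return p

    def set_param(self, name, value):
        if name in ("gamma", "beta"):
            setattr(self.bn, name, value)
        else:
            setattr(self, name, value)

    def forward(self, x, train, update_running, smooth, slope, tape):
        B, T = x.shape[:2]
        xf = x.reshape(B, T, -1).astype(float)
        C = xf @ self.W.T + self.b
        if tape is not None:
            tape["x"] = xf
        Z = (self.bn.forward(C, (0, 1), train, update_running, tape)
             if self.bn is not None else C)
        S = self.lif.forward(Z, self.Wrec, smooth, slope, tape)
        return S

    def backward(self, dS, tape, slope):
        grads = {}
        dZ, dwrec = self.lif.backward(dS, tape, self.Wrec, slope)
        if dwrec is not None:
            grads["Wrec"] = dwrec
        dC = (self.bn.backward(dZ, tape, grads) if self.bn is not None else dZ)
        xf = tape["x"]
        B, T = xf.shape[:2]
        grads["W"] = np.einsum("bto,bti->oi", dC, xf, optimize=True)
        grads["b"] = dC.sum(axis=(0, 1))
        dx = dC @ self.W
        return dx, grads


class _ConvBlock:
    """Conv(3x3, stride 1, pad 1) -> BatchNorm -> LIF -> MaxPool(2x2)."""

    name = "conv"

    def __init__(self, c_in, c_out, neuron, rng, kernel=3):
        fan_in = c_in * kernel * kernel
        bound = 1.0 / math.sqrt(fan_in)
        self.W = rng.uniform(-bound, bound, size=(c_out, c_in, kernel, kernel))
        self.b = rng.uniform(-bound, bound, size=c_out)
        self.bn = _BatchNorm(c_out)
        self.lif = _LIFUnit(neuron)
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.Wrec = None
        self.spiking = True

    @property
    def fanout(self) -> int:
        # interior approximation: each incoming spike feeds k*k*c_out synapses
        return self.kernel * self.kernel * self.c_out

    def n_neurons(self, feat_shape) -> int:
        return int(np.prod(feat_shape))  # LIF units at conv resolution

    def params(self):
        return {"W": self.W, "b": self.b,
                "gamma": self.bn.gamma, "beta": self.bn.beta}

    def set_param(self, name, value):
        if name in ("gamma", "beta"):
            setattr(self.bn, name, value)
        else:
            setattr(self, name, value)

    def forward(self, x, train, update_running, smooth, slope, tape):
        B, T = x.shape[:2]
        xf = x.reshape((B * T,) + x.shape[2:]).astype(float)
        C, win = _conv2d_fwd(xf, self.W, self.b)
        C = C.reshape((B, T) + C.shape[1:])
        if tape is not None:
            tape["win"] = win
            tape["x_shape"] = xf.shape
        Z = self.bn.forward(C, (0, 1, 3, 4), train, update_running, tape)
        S = self.lif.forward(Z, None, smooth, slope, tape)
        sf = S.reshape((B * T,) + S.shape[2:])
        P, idx = _maxpool_fwd(sf)
        if tape is not None:
            tape["pool_idx"] = idx
            tape["pool_in_shape"] = sf.shape
        return P.reshape((B, T) + P.shape[1:])

    def backward(self, dP, tape, slope):
        grads = {}
        B, T = dP.shape[:2]
        dPf = dP.reshape((B * T,) + dP.shape[2:])
        dS = _maxpool_bwd(dPf, tape["pool_idx"], tape["pool_in_shape"])
        dS = dS.reshape((B, T) + dS.shape[1:])
        dZ, _ = self.lif.backward(dS, tape, None, slope)
        dC = self.bn.backward(dZ, tape, grads)
        dCf = dC.reshape((B * T,) + dC.shape[2:])
        dx, dW, db = _conv2d_bwd(tape["win"], self.W, dCf)
        grads["W"], grads["b"] = dW, db
        return dx.reshape((B, T) + dx.shape[1:]), grads


class _GlobalAvgPool:
    """Spatial global average pool; emits rates, not spikes."""

    name = "gap"
    spiking = False

    def params(self):
        return {}

    def forward(self, x, train, update_running, smooth, slope, tape):
        if tape is not None:
            tape["gap_shape"] = x.shape
        return x.mean(axis=(3, 4))

    def backward(self, dout, tape, slope):
        shape = tape["gap_shape"]
        scale = shape[3] * shape[4]
        dx = np.broadcast_to(dout[..., None, None] / scale, shape)
        return np.ascontiguousarray(dx), {}


class _OutputBlock(_DenseBlock):
    """Linear -> LIF readout layer; no normalization on the output layer."""

    name = "output"

    def __init__(self, n_in, n_out, neuron, rng):
        super().__init__(n_in, n_out, neuron, rng, bn=False)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class Network:
    """A stack of blocks sharing one NeuronConfig, with persistent LIF state."""

    def __init__(self, spec: ArchitectureSpec, neuron: NeuronConfig, blocks):
        self.spec = spec
        self.neuron = neuron
        self.blocks = blocks
        self.trained = False

    # -- state management ---------------------------------------------------
    def reset_state(self) -> None:
        for blk in self.blocks:
            if blk.spiking:
                blk.lif.v = None

    def apply_boundary(self, policy: str) -> None:
        """Between-sample state policy: reset clears LIF state, carry keeps it."""
        if policy not in (RESET, CARRY):
            raise ValueError(f"unknown policy {policy!r}")
        if policy == RESET:
            self.reset_state()

    # -- parameters ---------------------------------------------------------
    def parameters(self):
        out = []
        for i, blk in enumerate(self.blocks):
            for name in blk.params():
                out.append((i, name))
        return out

    def get_param(self, key):
        i, name = key
        return self.blocks[i].params()[name]

    def set_param(self, key, value):
        i, name = key
        self.blocks[i].set_param(name, value)

    # -- forward ------------------------------------------------------------
    def forward_batch(self, x, train=False, update_running=False, smooth=False,
                      slope=2.0, tapes=None, collect=None):
        """Run a [B, T, ...] spike batch through the network.

        Returns per-class output counts [B, n_classes] (mean spikes per
        step).  ``collect`` may be a dict, filled with per-block input spike
        sums, output spike sums and traces for diagnostics.
        """
        B, T = x.shape[:2]
        for blk in self.blocks:
            tape = {} if tapes is not None else None
            if collect is not None and getattr(blk, "spiking", False):
                collect.setdefault("in_sums", []).append(
                    x.reshape(B, T, -1).sum(axis=(0, 2)))
            out = blk.forward(x, train, update_running, smooth, slope, tape)
            if collect is not None and getattr(blk, "spiking", False):
                spikes = tape["lif_S"] if tape is not None else None
                # conv blocks pool after the LIF, so take pre-pool spikes
                if spikes is None:
                    spikes = blk.lif_last_spikes
                collect.setdefault("spike_sums", []).append(
                    spikes.reshape(B, T, -1).sum(axis=(0, 2)))
                collect.setdefault("n_neurons", []).append(
                    spikes.reshape(B, T, -1).shape[2])
                if collect.get("want_traces"):
                    collect.setdefault("traces", []).append(
                        (spikes > 0.5).astype(np.int8))
            if tapes is not None:
                tapes.append(tape)
            x = out
        counts = x.reshape(B, T, -1).mean(axis=1)
        return counts

    # -- persistence hooks for spike traces without a tape -------------------
    # (blocks store their last LIF spikes when asked)


def _attach_spike_capture(blocks):
    """Wrap spiking blocks' LIF forward so the last spike trains are kept
    for diagnostics even when no training tape is in use."""
    for blk in blocks:
        if not getattr(blk, "spiking", False):
            continue
        unit = blk.lif
        original = unit.forward

        def wrapped(Z, wrec=None, smooth=False, slope=2.0, tape=None,
                    _orig=original, _blk=blk):
            S = _orig(Z, wrec, smooth, slope, tape)
            _blk.lif_last_spikes = S
            return S

        unit.forward = wrapped


def build_network(spec: ArchitectureSpec, config: NeuronConfig,
                  seed: int = 0) -> Network:
    """Construct an untrained network with seeded deterministic weights."""
    rng = np.random.default_rng(seed)
    blocks = []
    if spec.kind == "mlp":
        n_in = int(spec.input_shape) if np.isscalar(spec.input_shape) \
            else int(np.prod(spec.input_shape))
        for h in spec.hidden_sizes:
            blocks.append(_DenseBlock(n_in, h, config, rng))
            n_in = h
        blocks.append(_OutputBlock(n_in, spec.n_classes, config, rng))
    else:
        c_in = spec.input_shape[0]
        for c_out in spec.conv_channels:
            blocks.append(_ConvBlock(c_in, c_out, config, rng))
            c_in = c_out
        blocks.append(_GlobalAvgPool())
        blocks.append(_DenseBlock(c_in, spec.head_hidden, config, rng))
        blocks.append(_OutputBlock(spec.head_hidden, spec.n_classes, config, rng))
    _attach_spike_capture(blocks)
    net = Network(spec, config, blocks)
    if spec.recurrent_last_hidden:
        add_recurrence(net, seed=seed + 1)
    return net


def add_recurrence(network: Network, seed: int = 0,
                   init_std: float = 1e-3) -> Network:
    """Give the last hidden dense layer recurrent input from its own
    previous-step spikes; W_rec starts near zero so behaviour is initially
    unchanged."""
    hidden = [b for b in network.blocks
              if isinstance(b, _DenseBlock) and not isinstance(b, _OutputBlock)]
    if not hidden:
        raise ValueError("network has no hidden spiking dense layer")
    blk = hidden[-1]
    rng = np.random.default_rng(seed)
    blk.Wrec = rng.normal(0.0, init_std, size=(blk.n_out, blk.n_out))
    return network


# ---------------------------------------------------------------------------
# Inference API
# ---------------------------------------------------------------------------

def predict(counts: np.ndarray) -> int:
    """Label = argmax of accumulated output counts; ties -> lowest index."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("counts must be a non-empty 1-D vector")
    return int(np.argmax(counts))


def forward(network: Network, input_spikes: np.ndarray, policy: str = RESET,
            record: bool = False, true_label: int | None = None):
    """Run one encoded sample [T, ...] through the network.

    Applies the between-sample state policy first, integrates T steps and
    returns per-class mean output spike counts, plus an
    :class:`ActivityRecord` with binary per-layer traces when ``record``.
    """
    network.apply_boundary(policy)
    x = np.asarray(input_spikes)[None, ...]
    collect = {"want_traces": record} if record else None
    counts = network.forward_batch(x, collect=collect)[0]
    if not record:
        return counts, None
    traces = [t[0] for t in collect["traces"]]
    names = [b.name for b in network.blocks if getattr(b, "spiking", False)]
    rec = ActivityRecord(traces, names, counts, predict(counts), true_label,
                         degenerate=not counts.any())
    return counts, rec


def evaluate(network: Network, inputs: np.ndarray, labels: np.ndarray,
             policy: str = RESET, collect_stats: bool = False,
             batch_size: int = 256):
    """Test-set accuracy under a state policy.

    Under ``reset`` every sample is independent, so the set is evaluated in
    parallel batches.  Under ``carry`` the set is streamed one sample at a
    time in the given order, propagating membrane state across samples.

    With ``collect_stats`` also returns a dict with total spike counts,
    mean firing rate ingredients and per-layer input sums for the SOP proxy.
    """
    n = len(labels)
    correct = 0
    agg = {"in_sums": None, "spike_sums": None, "n_neurons": None}

    def _merge(c):
        for key in ("in_sums", "spike_sums"):
            arrs = c[key]
            if agg[key] is None:
                agg[key] = [a.copy() for a in arrs]
            else:
                for acc, a in zip(agg[key], arrs):
                    acc += a
        agg["n_neurons"] = c["n_neurons"]

    if policy == RESET:
        for start in range(0, n, batch_size):
            x = inputs[start:start + batch_size]
            network.reset_state()
            collect = {} if collect_stats else None
            counts = network.forward_batch(np.asarray(x), collect=collect)
            correct += int((counts.argmax(axis=1)
                            == labels[start:start + batch_size]).sum())
            if collect_stats:
                _merge(collect)
        network.reset_state()
    elif policy == CARRY:
        network.reset_state()  # fresh state at stream start
        for i in range(n):
            collect = {} if collect_stats else None
            counts = network.forward_batch(np.asarray(inputs[i])[None, ...],
                                           collect=collect)
            correct += int(counts.argmax(axis=1)[0] == labels[i])
            if collect_stats:
                _merge(collect)
    else:
        raise ValueError(f"unknown policy {policy!r}")

    accuracy = correct / n
    if not collect_stats:
        return accuracy
    stats = {
        "n_samples": n,
        "in_sums": agg["in_sums"],          # per layer: [T] summed over set
        "spike_sums": agg["spike_sums"],    # per spiking layer: [T]
        "n_neurons": agg["n_neurons"],      # per spiking layer, per sample
        "total_spikes": float(sum(a.sum() for a in agg["spike_sums"])),
    }
    return accuracy, stats


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _softmax_ce(counts, labels):
    z = counts - counts.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = -np.log(p[np.arange(n), labels] + 1e-12).mean()
    dcounts = p.copy()
    dcounts[np.arange(n), labels] -= 1.0
    return loss, dcounts / n


def loss_and_grads(network: Network, x, y, slope=2.0, smooth=False,
                   train_bn=True, update_running=False):
    """Cross-entropy on averaged output counts + BPTT gradients.

    ``smooth=True`` replaces hard spikes with the arctangent soft indicator
    everywhere, making the returned gradients exact derivatives of the
    returned loss (used by the finite-difference check).
    """
    tapes = []
    counts = network.forward_batch(np.asarray(x, dtype=float), train=train_bn,
                                   update_running=update_running,
                                   smooth=smooth, slope=slope, tapes=tapes)
    loss, dcounts = _softmax_ce(counts, y)
    B, T = np.asarray(x).shape[:2]
    dS = np.repeat(dcounts[:, None, :], T, axis=1) / T
    grads = {}
    dx = dS
    for i in reversed(range(len(network.blocks))):
        blk = network.blocks[i]
        dx, g = blk.backward(dx, tapes[i], slope)
        for name, val in g.items():
            grads[(i, name)] = val
    return loss, grads, counts


def train(network: Network, inputs: np.ndarray, labels: np.ndarray,
          config: TrainingConfig) -> pd.DataFrame:
    """Train with BPTT + Adam; returns the (epoch, loss, accuracy) history.

    ``inputs`` are pre-encoded spike tensors [N, T, ...].  The between-
    sample membrane policy of ``config`` is applied between minibatches
    (gradients are truncated at sample boundaries under carry).
    """
    horizon = np.asarray(inputs).shape[1]
    if horizon != config.T:
        raise ValueError(f"input horizon {horizon} != config.T {config.T}")
    rng = np.random.default_rng(config.seed)
    keys = network.parameters()
    m = {k: np.zeros_like(network.get_param(k)) for k in keys}
    v = {k: np.zeros_like(network.get_param(k)) for k in keys}
    b1, b2 = config.adam_betas
    step = 0
    history = []
    n = len(labels)
    bs = min(config.batch_size, n)
    network.reset_state()
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, correct, seen = [], 0, 0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            if config.policy == CARRY and len(idx) < bs:
                continue  # keep lane count constant under carry
            network.apply_boundary(config.policy)
            loss, grads, counts = loss_and_grads(
                network, inputs[idx], labels[idx], slope=config.surrogate_slope,
                update_running=True)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {step}")
            step += 1
            for k in keys:
                g = grads.get(k)
                if g is None:
                    continue
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1 ** step)
                vhat = v[k] / (1 - b2 ** step)
                network.set_param(k, network.get_param(k)
                                  - config.learning_rate * mhat
                                  / (np.sqrt(vhat) + config.adam_eps))
            losses.append(loss)
            correct += int((counts.argmax(axis=1) == labels[idx]).sum())
            seen += len(idx)
        history.append({"epoch": epoch,
                        "loss": float(np.mean(losses)) if losses else np.nan,
                        "accuracy": correct / seen if seen else np.nan})
    network.trained = config.epochs > 0 or network.trained
    network.reset_state()
    return pd.DataFrame(history, columns=["epoch", "loss", "accuracy"])
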