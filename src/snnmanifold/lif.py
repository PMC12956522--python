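"""Discrete-time leaky integrate-and-fire (LIF) neuron dynamics.

The membrane potential of each neuron follows a forward-Euler leak
``v <- (1 - alpha) * v + I`` with per-step leak factor ``alpha = dt / tau_m``.
A spike is emitted whenever the pre-reset potential reaches the firing
threshold ``v_th`` (inclusive).  The reset is applied exactly once per step,
according to the configured mode:

* ``hard`` — the potential of spiking neurons is clamped to ``v_reset``;
* ``soft`` — ``v_th`` is subtracted from the potential of spiking neurons.

An optional absolute refractory period freezes spiking neurons for
``t_ref`` further steps: refractory neurons neither integrate input nor
spike.  Between input samples the membrane state is handled by one of two
policies: ``reset`` reinitialises every neuron to ``v_reset`` (the standard
i.i.d.-benchmark convention), while ``carry`` propagates the final state of
one sample into the next, modelling continuous streaming deployment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NeuronConfig",
    "LayerState",
    "RESET",
    "CARRY",
    "lif_step",
    "init_state",
    "apply_sample_boundary",
]

#: Between-sample membrane-state policies.
RESET = "reset"
CARRY = "carry"
_POLICIES = (RESET, CARRY)
_RESET_MODES = ("hard", "soft")


@dataclass(frozen=True)
class NeuronConfig:
    """Hyperparameters shared by every neuron in a layer (or network).

    Parameters
    ----------
    tau_m:
        Membrane time constant in ms.  Must exceed ``dt`` so that the
        derived leak factor ``alpha = dt / tau_m`` lies in (0, 1).
    v_th:
        Firing threshold in volts; a spike fires when the pre-reset
        potential is ``>= v_th``.
    v_reset:
        Reset potential in volts (default 0).  Must lie below ``v_th``.
    dt:
        Integration step in ms (default 1).
    t_ref:
        Absolute refractory period, in integer steps (default 0).
    reset_mode:
        ``"hard"`` (clamp to ``v_reset``, the default) or ``"soft"``
        (subtract ``v_th``).
    """

    tau_m: float
    v_th: float
    v_reset: float = 0.0
    dt: float = 1.0
    t_ref: int = 0
    reset_mode: str = "hard"

    def __post_init__(self) -> None:
        if not self.tau_m > self.dt:
            raise ValueError(
                f"tau_m ({self.tau_m}) must exceed dt ({self.dt}) so that "
                "alpha = dt/tau_m < 1"
            )
        if not self.v_th > self.v_reset:
            raise ValueError(
                f"v_th ({self.v_th}) must exceed v_reset ({self.v_reset})"
            )
        if self.t_ref < 0 or int(self.t_ref) != self.t_ref:
            raise ValueError(f"t_ref must be a nonnegative integer, got {self.t_ref}")
        if self.reset_mode not in _RESET_MODES:
            raise ValueError(
                f"reset_mode must be one of {_RESET_MODES}, got {self.reset_mode!r}"
            )

    @property
    def alpha(self) -> float:
        """Per-step leak factor ``dt / tau_m``, dimensionless, in (0, 1)."""
        return self.dt / self.tau_m


@dataclass
class LayerState:
    """Mutable per-neuron state of one spiking layer.

    ``v`` is the membrane potential (V), ``refr`` the number of remaining
    refractory steps, and ``last_spikes`` the binary spike indicator of the
    most recent step.  Arrays share a common trailing shape (any leading
    batch dimensions are allowed).
    """

    v: np.ndarray
    refr: np.ndarray = field(default=None)  # type: ignore[assignment]
    last_spikes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.refr is None:
            self.refr = np.zeros(self.v.shape, dtype=np.int64)
        if self.last_spikes is None:
            self.last_spikes = np.zeros(self.v.shape, dtype=np.int8)

    def copy(self) -> "LayerState":
        return LayerState(self.v.copy(), self.refr.copy(), self.last_spikes.copy())


def init_state(n_neurons, config: NeuronConfig, jitter: float = 0.0,
               rng: np.random.Generator | None = None) -> LayerState:
    """Fresh layer state with every membrane at ``v_reset``.

    ``n_neurons`` may be an int or a shape tuple.  ``jitter`` optionally adds
    uniform noise in ``[0, jitter)`` above ``v_reset`` (off by default so
    tests are deterministic).
    """
    shape = (n_neurons,) if np.isscalar(n_neurons) else tuple(n_neurons)
    if any(s < 1 for s in shape):
        raise ValueError(f"n_neurons must be >= 1, got {n_neurons}")
    v = np.full(shape, config.v_reset, dtype=float)
    if jitter:
        if rng is None:
            raise ValueError("jitter > 0 requires an rng")
        v = v + rng.uniform(0.0, jitter, size=shape)
    return LayerState(v)


def lif_step(state: LayerState, input_current: np.ndarray,
             config: NeuronConfig) -> tuple[LayerState, np.ndarray]:
    """Advance one LIF layer by a single timestep.

    Non-refractory neurons integrate ``v_pre = (1 - alpha) * v + I`` and
    spike iff ``v_pre >= v_th``; the reset (hard clamp or soft subtraction)
    is applied once.  Neurons that spike enter the refractory period; neurons
    already refractory do not integrate, cannot spike, and count down.

    Returns the updated state and the binary spike vector.  The input state
    is not modified.
    """
    current = np.asarray(input_current, dtype=float)
    if current.shape != state.v.shape:
        raise ValueError(
            f"input_current shape {current.shape} does not match "
            f"state shape {state.v.shape}"
        )
    if not np.all(np.isfinite(current)):
        raise ValueError("input_current contains non-finite values")

    active = state.refr <= 0
    v_pre = (1.0 - config.alpha) * state.v + current
    spikes = (active & (v_pre >= config.v_th)).astype(np.int8)
    fired = spikes.astype(bool)

    v_new = np.where(active, v_pre, state.v)
    if config.reset_mode == "hard":
        v_new = np.where(fired, config.v_reset, v_new)
    else:
        v_new = np.where(fired, v_pre - config.v_th, v_new)

    refr_new = np.where(active, 0, state.refr - 1).astype(np.int64)
    if config.t_ref > 0:
        refr_new = np.where(fired, config.t_ref, refr_new)

    return LayerState(v_new, refr_new, spikes), spikes


def apply_sample_boundary(state: LayerState, policy: str,
                          config: NeuronConfig) -> LayerState:
    """Apply the between-sample membrane-state policy.

    ``reset`` returns a fresh state (every membrane at ``v_reset``, no
    refractory carry-over, spikes cleared); ``carry`` returns the state
    unchanged.
    """
    if policy not in _POLICIES:
        raise ValueError(f"policy must be one of {_POLICIES}, got {policy!r}")
    if policy == RESET:
        return init_state(state.v.shape, config)
    return state
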