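"""Reset-versus-carry inference comparison.

At deployment time the membrane state between consecutive inputs can be
reinitialised (*reset*) or propagated (*carry*).  On i.i.d. static inputs
carrying state lets residual potentials from the previous sample interfere
with the early integration of the next one; the interference is strongest
for short inference windows T and is progressively overwritten as T grows.
This module measures test accuracy as a function of T for both policies
and the class-conditional output spike histograms that visualise the
interference.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .encoding import poisson_encode_batch
from .lif import CARRY, RESET
from .networks import Network

__all__ = ["PolicyCurve", "evaluate_policy_curve", "class_output_histogram"]


@dataclass
class PolicyCurve:
    """Accuracy per (policy, T)."""

    T_values: tuple
    accuracy: dict          # {policy: [accuracy per T]}
    order_seed: int


def _encode_set(images, T, seed):
    return poisson_encode_batch(images, T, seed)


def _stream_accuracy(network, inputs, labels, policy):
    network.reset_state()  # fresh state at stream start
    correct = 0
    for i in range(len(labels)):
        network.apply_boundary(policy)
        counts = network.forward_batch(np.asarray(inputs[i])[None, ...])
        correct += int(counts.argmax(axis=1)[0] == labels[i])
    return correct / len(labels)


def evaluate_policy_curve(network: Network, images: np.ndarray,
                          labels: np.ndarray, policies=(RESET, CARRY),
                          T_values=(1, 2, 3, 5, 10), seed: int = 0,
                          order_seed: int | None = None) -> PolicyCurve:
    """Accuracy versus inference horizon T under each state policy.

    Each sample's Poisson encoding is re-drawn at every T from ``seed``
    (tied to the sample, not its stream position); the test set is then
    streamed in one fixed shuffle drawn from ``order_seed`` (default:
    ``seed``) and recorded in the result.  Under reset the accuracy is a
    per-sample property and thus invariant to the stream order; under
    carry it generally is not.
    """
    if any(t < 1 for t in T_values):
        raise ValueError("all T values must be >= 1")
    if not network.trained:
        warnings.warn("evaluating an untrained network", stacklevel=2)
    order_seed = seed if order_seed is None else order_seed
    order = np.random.default_rng(order_seed).permutation(len(labels))
    flat = images.reshape(len(labels), -1) if network.spec.kind == "mlp" \
        else images
    accuracy = {p: [] for p in policies}
    for T in T_values:
        encoded = _encode_set(flat, T, seed + 7919 * T)[order]
        for policy in policies:
            accuracy[policy].append(
                _stream_accuracy(network, encoded, labels[order], policy))
    return PolicyCurve(tuple(T_values), accuracy, order_seed)


def class_output_histogram(network: Network, images: np.ndarray,
                           labels: np.ndarray, class_label: int,
                           policy: str = RESET, T: int = 10,
                           seed: int = 0) -> np.ndarray:
    """Mean output-layer spike count per timestep for one class.

    Streams the full set in order (so carry sees realistic preceding
    samples) and averages the output layer's spikes at each step
    1..T over the samples of ``class_label``.  Returns [T, n_outputs].
    """
    labels = np.asarray(labels)
    if class_label not in labels:
        raise ValueError(f"class {class_label} absent from dataset")
    flat = images.reshape(len(labels), -1) if network.spec.kind == "mlp" else images
    encoded = _encode_set(flat, T, seed + 7919 * T)
    network.reset_state()
    sums = None
    n_class = 0
    for i in range(len(labels)):
        network.apply_boundary(policy)
        network.forward_batch(np.asarray(encoded[i])[None, ...])
        out_blk = network.blocks[-1]
        spikes = out_blk.lif_last_spikes[0]     # [T, n_outputs]
        if labels[i] == class_label:
            sums = spikes.astype(float) if sums is None else sums + spikes
            n_class += 1
    return sums / n_class
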