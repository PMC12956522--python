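"""Seeded synthetic task generators.

Every experiment in the package runs on generated data: a template-based
static-image classification task (stands in for small raster benchmarks), a
moving-edge event-stream task (stands in for DVS recordings), and a
common-input model of correlated spike trains used by the drift
diagnostics.  All generators are pure functions of their configuration,
seed included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import EventStream

__all__ = [
    "SyntheticTaskConfig",
    "StaticDataset",
    "EventDataset",
    "make_static_task",
    "make_event_task",
    "make_correlated_spike_trains",
]


@dataclass(frozen=True)
class SyntheticTaskConfig:
    """Static-image task parameters.

    Each class is a distinct oriented-bar template; samples are the template
    at ``contrast`` intensity over a dim background, plus Gaussian pixel
    noise of standard deviation ``noise_std``, clipped to [0, 1].  At zero
    noise the classes have disjoint bright supports and are linearly
    separable.
    """

    n_classes: int = 4
    height: int = 12
    width: int = 12
    n_train_per_class: int = 50
    n_test_per_class: int = 25
    contrast: float = 0.5
    noise_std: float = 0.45
    background: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.height < 4 or self.width < 4:
            raise ValueError("image dimensions must be >= 4")
        if not 0.0 < self.contrast <= 1.0:
            raise ValueError("contrast must lie in (0, 1]")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")


@dataclass
class StaticDataset:
    """Labeled intensity images, shape [n, height, width], labels [n]."""

    train_x: np.ndarray
    train_y: np.ndarray
    test_x: np.ndarray
    test_y: np.ndarray
    config: SyntheticTaskConfig


@dataclass
class EventDataset:
    """Labeled event streams."""

    train_streams: list
    train_y: np.ndarray
    test_streams: list
    test_y: np.ndarray
    height: int
    width: int
    duration: float


def class_templates(config: SyntheticTaskConfig) -> np.ndarray:
    """One spatial template per class: bars of rotating orientation placed at
    distinct offsets so the bright supports never fully overlap."""
    h, w, k = config.height, config.width, config.n_classes
    templates = np.full((k, h, w), config.background)
    thickness = max(1, min(h, w) // 6)
    for c in range(k):
        kind = c % 4
        # offsets walk across the frame so same-orientation classes differ
        off = (c // 4 + 1 + c) % (min(h, w) - thickness)
        if kind == 0:      # horizontal bar
            templates[c, off:off + thickness, :] = config.contrast
        elif kind == 1:    # vertical bar
            templates[c, :, off:off + thickness] = config.contrast
        elif kind == 2:    # main diagonal band
            for d in range(thickness):
                idx = np.arange(min(h, w) - d)
                templates[c, idx + d, idx] = config.contrast
        else:              # anti-diagonal band
            for d in range(thickness):
                idx = np.arange(min(h, w) - d)
                templates[c, idx, w - 1 - idx - d] = config.contrast
    return np.clip(templates, 0.0, 1.0)


def make_static_task(config: SyntheticTaskConfig) -> StaticDataset:
    """Generate the labeled train/test image sets for the static task."""
    templates = class_templates(config)
    rng = np.random.default_rng(config.seed)

    def draw(n_per_class: int):
        xs, ys = [], []
        for c in range(config.n_classes):
            base = templates[c][None, :, :]
            noise = rng.normal(0.0, config.noise_std,
                               size=(n_per_class, config.height, config.width))
            xs.append(np.clip(base + noise, 0.0, 1.0))
            ys.append(np.full(n_per_class, c, dtype=np.int64))
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        order = rng.permutation(len(y))
        return x[order], y[order]

    train_x, train_y = draw(config.n_train_per_class)
    test_x, test_y = draw(config.n_test_per_class)
    return StaticDataset(train_x, train_y, test_x, test_y, config)


def _edge_trajectory(kind: int, duration: float, h: int, w: int,
                     n_events: int, rng: np.random.Generator) -> np.ndarray:
    """Events along a moving edge; ``kind`` selects the sweep direction."""
    t = np.sort(rng.uniform(0.0, duration, n_events))
    frac = t / duration
    jitter = rng.integers(-1, 2, n_events)
    if kind % 4 == 0:    # left -> right vertical edge
        x = np.clip((frac * (w - 1)).astype(int) + jitter, 0, w - 1)
        y = rng.integers(0, h, n_events)
    elif kind % 4 == 1:  # top -> bottom horizontal edge
        x = rng.integers(0, w, n_events)
        y = np.clip((frac * (h - 1)).astype(int) + jitter, 0, h - 1)
    elif kind % 4 == 2:  # main-diagonal sweep
        x = np.clip((frac * (w - 1)).astype(int) + jitter, 0, w - 1)
        y = np.clip((frac * (h - 1)).astype(int) + rng.integers(-1, 2, n_events), 0, h - 1)
    else:                # right -> left vertical edge
        x = np.clip(((1 - frac) * (w - 1)).astype(int) + jitter, 0, w - 1)
        y = rng.integers(0, h, n_events)
    # leading edge brightens (p=1), trailing side darkens (p=0)
    p = (rng.random(n_events) < 0.6).astype(int)
    return np.column_stack([t, x, y, p]).astype(float)


def make_event_task(n_classes: int = 3, duration: float = 1.0,
                    height: int = 12, width: int = 12,
                    events_per_sample: int = 150,
                    n_train_per_class: int = 40, n_test_per_class: int = 15,
                    background_events: int = 15, seed: int = 0) -> EventDataset:
    """Moving-edge event-stream classification task.

    Each class sweeps an edge across the frame in a characteristic
    direction; uniform background noise events of random polarity are
    superimposed.  Reproducible under the seed.
    """
    if events_per_sample < 1:
        raise ValueError("events_per_sample must be >= 1")
    if height < 4 or width < 4:
        raise ValueError("frame dimensions must be >= 4")
    rng = np.random.default_rng(seed)

    def draw(n_per_class: int):
        streams, ys = [], []
        for c in range(n_classes):
            for _ in range(n_per_class):
                recs = _edge_trajectory(c, duration, height, width,
                                        events_per_sample, rng)
                if background_events:
                    bt = rng.uniform(0.0, duration, background_events)
                    bx = rng.integers(0, width, background_events)
                    by = rng.integers(0, height, background_events)
                    bp = rng.integers(0, 2, background_events)
                    recs = np.concatenate(
                        [recs, np.column_stack([bt, bx, by, bp]).astype(float)])
                streams.append(EventStream(recs, duration, height, width))
                ys.append(c)
        order = rng.permutation(len(ys))
        return [streams[i] for i in order], np.asarray(ys, dtype=np.int64)[order]

    train_streams, train_y = draw(n_train_per_class)
    test_streams, test_y = draw(n_test_per_class)
    return EventDataset(train_streams, train_y, test_streams, test_y,
                        height, width, duration)


def make_correlated_spike_trains(n_neurons: int, T: int, rate: float,
                                 common_fraction: float, seed: int) -> np.ndarray:
    """Binary [T, n_neurons] trains from a common-input mixture model.

    At every step each neuron independently either copies a shared source
    train of rate ``rate`` (with probability ``common_fraction``) or draws
    its own Bernoulli(rate) spike.  ``common_fraction = 0`` gives
    independent trains; ``common_fraction = 1`` makes all trains identical
    to the source, so every pairwise correlation is 1.
    """
    if not 0.0 < rate < 1.0:
        raise ValueError(f"rate must lie in (0, 1), got {rate}")
    if not 0.0 <= common_fraction <= 1.0:
        raise ValueError(f"common_fraction must lie in [0, 1], got {common_fraction}")
    rng = np.random.default_rng(seed)
    source = (rng.random(T) < rate).astype(np.int8)
    own = (rng.random((T, n_neurons)) < rate).astype(np.int8)
    copy_mask = rng.random((T, n_neurons)) < common_fraction
    return np.where(copy_mask, source[:, None], own).astype(np.int8)
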