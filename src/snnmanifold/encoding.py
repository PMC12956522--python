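"""Spike encoders: Poisson rate coding for static images and time-binning
for DVS-style event streams.

A *SpikeTensor* is a plain binary numpy array whose first axis is time; the
remaining axes index neurons/channels/pixels.  Static intensities in [0, 1]
are rate-coded as independent per-step Bernoulli draws with success
probability equal to the intensity (the standard discrete-time reading of
"Poisson encoded").  Event streams — lists of (t, x, y, polarity) records —
are discretised into T uniform half-open time bins with the two polarities
separated in a channel dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EventStream", "poisson_encode", "poisson_encode_batch", "bin_events"]


@dataclass
class EventStream:
    """An asynchronous event recording from a dynamic vision sensor.

    ``records`` is a float array of shape [n_events, 4] with columns
    (t, x, y, p): event time in [0, duration), integer pixel coordinates
    and polarity in {0, 1}.
    """

    records: np.ndarray
    duration: float
    height: int
    width: int

    def __post_init__(self) -> None:
        self.records = np.asarray(self.records, dtype=float).reshape(-1, 4)

    @property
    def n_events(self) -> int:
        return self.records.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["t", "x", "y", "p"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, duration: float,
                   height: int, width: int) -> "EventStream":
        return cls(frame[["t", "x", "y", "p"]].to_numpy(float), duration, height, width)


def poisson_encode(image: np.ndarray, T: int, seed: int) -> np.ndarray:
    """Rate-code a static intensity image into a binary [T, *image.shape] tensor.

    Every pixel emits an independent Bernoulli(intensity) draw at each of the
    T steps, so the empirical firing rate converges to the intensity.
    Deterministic given (image, T, seed).
    """
    img = np.asarray(image, dtype=float)
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if img.size and (img.min() < 0.0 or img.max() > 1.0):
        raise ValueError("intensities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    draws = rng.random((T,) + img.shape)
    return (draws < img).astype(np.int8)


def poisson_encode_batch(images: np.ndarray, T: int, seed: int) -> np.ndarray:
    """Rate-code a stack of images [N, ...] into [N, T, ...] with one seed.

    Equivalent to per-image encoding from a single random stream; used when
    a whole train/test split is encoded at a fixed horizon.
    """
    imgs = np.asarray(images, dtype=float)
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if imgs.size and (imgs.min() < 0.0 or imgs.max() > 1.0):
        raise ValueError("intensities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    draws = rng.random((imgs.shape[0], T) + imgs.shape[1:])
    return (draws < imgs[:, None]).astype(np.int8)


def bin_events(stream: EventStream, T: int, height: int | None = None,
               width: int | None = None, binary: bool = True) -> np.ndarray:
    """Discretise an event stream into a [T, 2, height, width] tensor.

    Bin k covers the half-open interval [k*dur/T, (k+1)*dur/T); an event at
    exactly t == duration is mapped to the last bin.  Polarity selects the
    channel.  With ``binary=True`` (default) cells hold occupancy in {0, 1};
    ``binary=False`` keeps raw event counts.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    height = stream.height if height is None else height
    width = stream.width if width is None else width
    if height < 1 or width < 1:
        raise ValueError("frame dimensions must be positive")

    out = np.zeros((T, 2, height, width), dtype=np.int32)
    if stream.n_events == 0:
        return out.astype(np.int8) if binary else out

    t, x, y, p = stream.records.T
    xi, yi, pi = x.astype(int), y.astype(int), p.astype(int)
    bad = (xi < 0) | (xi >= width) | (yi < 0) | (yi >= height) | ~np.isin(pi, (0, 1))
    if bad.any():
        first = np.flatnonzero(bad)[0]
        raise ValueError(
            f"event record {first} out of bounds: "
            f"(t={t[first]}, x={xi[first]}, y={yi[first]}, p={pi[first]}) "
            f"for frame {height}x{width}"
        )
    bins = np.floor(t / stream.duration * T).astype(int)
    bins = np.clip(bins, 0, T - 1)  # final instant -> last bin
    np.add.at(out, (bins, pi, yi, xi), 1)
    if binary:
        return np.clip(out, 0, 1).astype(np.int8)
    return out
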