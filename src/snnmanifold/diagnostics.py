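"""Perturbation collection and correlation-based drift diagnostics.

The robustness probe progressively disorders an input's spike sequence by
randomly transposing whole time-frames, re-evaluating after each
perturbation round until a correctly classified sample flips to an
incorrect prediction; the clean and perturbed activities of the deepest
hidden spiking layer are then stored as a correct-incorrect pair.

Pairwise Pearson correlations between that layer's spike trains carry the
drift signature: driven off its balanced operating regime, a network fires
more synchronously, shifting the distribution of correlation coefficients
upward and fattening its tail.  Eight summary statistics of that
distribution (mean, median, std, skewness, excess kurtosis, the 99th
percentile and the counts of coefficients above 0.75 and 0.9) act as
label-free condition features.  Their diagnostic value is quantified by
per-feature mutual information with the clean/noisy condition label and by
a gradient-boosted tree classifier whose importances reveal which aspects
of the correlation structure discriminate best.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .networks import Network, forward, predict

__all__ = [
    "PerturbationConfig",
    "PerturbationPair",
    "CorrelationSummary",
    "FEATURE_NAMES",
    "permute_frames",
    "collect_pairs",
    "correlation_matrix",
    "average_matrices",
    "summarize_correlations",
    "feature_table",
    "mutual_information_scores",
    "condition_classifier",
]

FEATURE_NAMES = ("mean", "median", "std", "skewness", "kurtosis",
                 "p99", "n_gt_075", "n_gt_090")


@dataclass(frozen=True)
class PerturbationConfig:
    """Perturbation-collection schedule.

    Each round adds ``swap_increment`` frame transpositions (applied fresh
    to the clean input, so round k evaluates clean-plus-k-swaps) up to
    ``max_level`` cumulative swaps; collection stops at ``max_pairs``
    stored pairs or when the dataset is exhausted.
    """

    max_pairs: int = 2000
    swap_increment: int = 1
    max_level: int = 30     # 3 * T at the default horizon T = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_pairs < 1 or self.max_level < 1 or self.swap_increment < 1:
            raise ValueError("max_pairs, max_level, swap_increment must be >= 1")


@dataclass
class PerturbationPair:
    """Clean (correct) and perturbed (incorrect) activities of one sample."""

    clean_activity: np.ndarray      # [T, n] binary, deepest hidden layer
    perturbed_activity: np.ndarray
    label: int
    flip_level: int                 # swaps applied at first misclassification


@dataclass
class CorrelationSummary:
    """Distribution statistics of a set of pairwise correlations."""

    mean: float
    median: float
    std: float
    skewness: float
    kurtosis: float                 # excess kurtosis
    p99: float
    n_gt_075: int
    n_gt_090: int
    n_excluded: int = 0             # pairs dropped for zero variance

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in FEATURE_NAMES}


def permute_frames(x: np.ndarray, n_swaps: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Apply ``n_swaps`` uniform random transpositions of whole time-frames.

    The multiset of frames (and hence the total spike count) is preserved;
    only their order changes.
    """
    x = np.asarray(x)
    T = x.shape[0]
    if T < 2:
        raise ValueError("need at least two frames to permute")
    out = x.copy()
    for _ in range(n_swaps):
        i, j = rng.integers(0, T, 2)
        out[[i, j]] = out[[j, i]]
    return out


def _hidden_activity(record) -> np.ndarray:
    # deepest hidden spiking layer: the output layer is the readout itself
    return record.layer_spikes[-2]


def collect_pairs(network: Network, inputs: np.ndarray, labels: np.ndarray,
                  config: PerturbationConfig) -> list:
    """Collect correct-incorrect activity pairs under frame permutation.

    Each test sample is first evaluated clean (with a state reset);
    misclassified samples are skipped.  The swap count then grows by
    ``swap_increment`` per round, each round re-evaluating a fresh
    permutation of the clean input, until the prediction flips (the pair is
    stored with its flip level) or ``max_level`` is reached (the sample is
    discarded).
    """
    rng = np.random.default_rng(config.seed)
    pairs = []
    for i in range(len(labels)):
        if len(pairs) >= config.max_pairs:
            break
        clean = np.asarray(inputs[i])
        network.reset_state()
        counts, rec = forward(network, clean, policy="reset", record=True,
                              true_label=int(labels[i]))
        if predict(counts) != labels[i]:
            continue
        clean_act = _hidden_activity(rec)
        level = 0
        while level + config.swap_increment <= config.max_level:
            level += config.swap_increment
            perturbed = permute_frames(clean, level, rng)
            network.reset_state()
            counts_p, rec_p = forward(network, perturbed, policy="reset",
                                      record=True, true_label=int(labels[i]))
            if predict(counts_p) != labels[i]:
                pairs.append(PerturbationPair(
                    clean_activity=clean_act,
                    perturbed_activity=_hidden_activity(rec_p),
                    label=int(labels[i]), flip_level=level))
                break
    return pairs


def correlation_matrix(activity: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of binary spike trains [T, n].

    Zero-variance (constant) trains yield undefined coefficients, returned
    as NaN and excluded from downstream summaries; the diagonal is 1 where
    defined.
    """
    arr = np.asarray(activity, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("activity must be [T, n] with n >= 2")
    if arr.shape[0] < 2:
        raise ValueError("need at least two timesteps")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr, rowvar=False)
    return corr


def average_matrices(matrices) -> np.ndarray:
    """Elementwise condition average, ignoring undefined (NaN) entries."""
    stack = np.stack([np.asarray(m, dtype=float) for m in matrices])
    with np.errstate(invalid="ignore"):
        return np.nanmean(stack, axis=0)


def summarize_correlations(matrix: np.ndarray) -> CorrelationSummary:
    """Distribution statistics over the defined upper-triangle coefficients.

    Skewness is the standardised third central moment, kurtosis is excess
    kurtosis, and the 99th percentile uses linear interpolation.
    """
    m = np.asarray(matrix, dtype=float)
    iu = np.triu_indices_from(m, k=1)
    coeffs = m[iu]
    defined = coeffs[np.isfinite(coeffs)]
    n_excluded = int(coeffs.size - defined.size)
    if defined.size == 0:
        raise ValueError("all correlation pairs undefined (degenerate activity)")
    std = float(defined.std())
    # (near-)constant coefficient sets have no shape: skew/kurtosis -> 0
    degenerate = defined.size < 2 or std < 1e-12
    return CorrelationSummary(
        mean=float(defined.mean()),
        median=float(np.median(defined)),
        std=std,
        skewness=0.0 if degenerate else float(sps.skew(defined)),
        kurtosis=0.0 if degenerate else float(sps.kurtosis(defined)),
        p99=float(np.percentile(defined, 99)),
        n_gt_075=int((defined > 0.75).sum()),
        n_gt_090=int((defined > 0.90).sum()),
        n_excluded=n_excluded,
    )


def feature_table(activities_by_condition: dict) -> pd.DataFrame:
    """Per-sample feature rows for the condition classifier.

    ``activities_by_condition`` maps a condition name (e.g. "clean",
    "noisy") to a list of [T, n] activity tensors; each sample contributes
    one row of the eight correlation statistics plus its condition label.
    """
    rows = []
    for condition, activities in activities_by_condition.items():
        for act in activities:
            summary = summarize_correlations(correlation_matrix(act))
            row = summary.as_dict()
            row["condition"] = condition
            rows.append(row)
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES) + ["condition"])


def mutual_information_scores(features: pd.DataFrame, labels,
                              n_bins: int = 10) -> pd.Series:
    """Mutual information (bits) between each quantile-binned feature and
    the binary condition label.  Deterministic and seedless."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both condition labels must be present")
    out = {}
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        uniq = np.unique(x)
        if len(uniq) <= n_bins:   # few distinct values: one bin per value
            binned = np.searchsorted(uniq, x)
        else:
            edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
            binned = np.digitize(x, edges[1:-1])
        mi = 0.0
        n = len(y)
        for b in np.unique(binned):
            for c in classes:
                pxy = np.mean((binned == b) & (y == c))
                if pxy > 0:
                    px = np.mean(binned == b)
                    py = np.mean(y == c)
                    mi += pxy * np.log2(pxy / (px * py))
        out[col] = max(mi, 0.0)
    return pd.Series(out)


def condition_classifier(features: pd.DataFrame, labels, seed: int = 0,
                         test_size: float = 0.2):
    """Gradient-boosted tree classifier of clean-vs-noisy condition.

    Fits XGBoost on the eight correlation statistics with a seeded
    stratified 80/20 split; returns the held-out accuracy and normalised
    per-feature importances (summing to 1).
    """
    from sklearn.model_selection import train_test_split
    from xgboost import XGBClassifier

    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least two samples of each condition")
    y_enc = np.searchsorted(classes, y)
    x = features.to_numpy(dtype=float)
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y_enc, test_size=test_size, random_state=seed, stratify=y_enc)
    if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
        raise ValueError("degenerate train/test split")
    clf = XGBClassifier(n_estimators=100, random_state=seed, n_jobs=1,
                        verbosity=0, eval_metric="logloss")
    clf.fit(x_tr, y_tr)
    accuracy = float((clf.predict(x_te) == y_te).mean())
    raw = np.asarray(clf.feature_importances_, dtype=float)
    importances = raw / raw.sum() if raw.sum() > 0 else \
        np.full(len(raw), 1.0 / len(raw))
    return accuracy, pd.Series(importances, index=list(features.columns))
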