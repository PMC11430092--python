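"""Temporal features of decoded brain-state sequences.

Given a per-sample state label sequence, computes fractional occupancy
(share of samples per state), mean lifetime (mean visit duration),
mean interval (mean gap between the end of one visit and the start of
the next), and the empirical transition-probability matrix including
self-transitions.

Conventions: boundary-truncated first/last visits count toward
lifetimes; features that are undefined for a state (never visited, or
visited once for intervals) are reported as NaN, never zero, and
propagate as missing through downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StateSequence",
    "TemporalFeatures",
    "run_lengths",
    "fractional_occupancy",
    "mean_lifetime",
    "mean_interval",
    "transition_matrix",
    "temporal_features",
]


@dataclass
class StateSequence:
    """Per-sample decoded state labels at sampling rate ``fs``."""

    labels: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a nonempty 1-D integer array")
        if self.labels.min() < 0:
            raise ValueError("state labels must be nonnegative")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


@dataclass
class TemporalFeatures:
    fractional_occupancy: np.ndarray  # length K, sums to 1
    mean_lifetime_s: np.ndarray  # length K, NaN if unvisited
    mean_interval_s: np.ndarray  # length K, NaN if < 2 visits
    transition_probs: np.ndarray  # K x K, NaN rows for unvisited states


def _check_labels(labels: np.ndarray, K: int) -> None:
    if labels.max() >= K:
        raise ValueError(f"label {labels.max()} out of range for K={K}")


def run_lengths(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode: (state of each run, length of each run)."""
    labels = np.asarray(labels, dtype=int)
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return labels[starts], ends - starts


def fractional_occupancy(seq: StateSequence, K: int) -> np.ndarray:
    """Fraction of samples spent in each state; unvisited states get 0."""
    _check_labels(seq.labels, K)
    return np.bincount(seq.labels, minlength=K) / seq.labels.size


def mean_lifetime(seq: StateSequence, K: int) -> np.ndarray:
    """Mean visit duration per state, in seconds (NaN if unvisited)."""
    _check_labels(seq.labels, K)
    states, lengths = run_lengths(seq.labels)
    out = np.full(K, np.nan)
    for k in range(K):
        mask = states == k
        if mask.any():
            out[k] = lengths[mask].mean() / seq.fs
    return out


def mean_interval(seq: StateSequence, K: int) -> np.ndarray:
    """Mean gap between consecutive visits per state, in seconds.

    The gap is end-of-visit to start-of-next-visit (exclusive of the
    visits themselves).  States with fewer than two visits get NaN.
    """
    _check_labels(seq.labels, K)
    states, lengths = run_lengths(seq.labels)
    ends = np.cumsum(lengths)
    starts = ends - lengths
    out = np.full(K, np.nan)
    for k in range(K):
        idx = np.flatnonzero(states == k)
        if idx.size >= 2:
            gaps = starts[idx[1:]] - ends[idx[:-1]]
            out[k] = gaps.mean() / seq.fs
    return out


def transition_matrix(
    seq: StateSequence, K: int, include_self: bool = True
) -> np.ndarray:
    """Empirical transition probabilities from consecutive label pairs.

    Rows are normalized per visited state; rows of unvisited states (or
    states with no outgoing pair) are NaN.  With ``include_self=False``
    the diagonal is dropped and off-diagonal rows renormalized.
    """
    if seq.labels.size < 2:
        raise ValueError("need at least 2 samples for transitions")
    _check_labels(seq.labels, K)
    counts = np.zeros((K, K))
    np.add.at(counts, (seq.labels[:-1], seq.labels[1:]), 1.0)
    if not include_self:
        np.fill_diagonal(counts, 0.0)
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / sums
    probs[sums[:, 0] == 0] = np.nan
    return probs


def temporal_features(seq: StateSequence, K: int) -> TemporalFeatures:
    """All temporal features of one decoded sequence."""
    return TemporalFeatures(
        fractional_occupancy=fractional_occupancy(seq, K),
        mean_lifetime_s=mean_lifetime(seq, K),
        mean_interval_s=mean_interval(seq, K),
        transition_probs=transition_matrix(seq, K),
    )
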