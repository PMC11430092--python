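"""State-wise functional connectivity and its network-level reductions.

The decoded state sequence re-windows the envelope data: each maximal
constant-state run is one window.  Per state, Pearson correlation
matrices are computed per visit (windows shorter than ``min_len``
samples are dropped) and combined as a duration-weighted average.
Per-matrix reductions give the 7 within-network means and the 21
between-network-pair means; transition magnitudes weight the absolute
change of those summaries between states by occupancy and transition
probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import ParcelAtlas
from .temporal import StateSequence

__all__ = [
    "StateWindows",
    "StateFC",
    "NetworkSummary",
    "segment_states",
    "compute_state_fc",
    "network_means",
    "transition_magnitude",
    "subject_connectivity",
    "DEFAULT_MIN_WINDOW",
]

# correlations over < 100 ms of envelope data (25 samples at 250 Hz) are
# too noisy to average in
DEFAULT_MIN_WINDOW = 25


@dataclass
class StateWindows:
    """Maximal constant-state intervals [start, end) partitioning [0, T)."""

    states: np.ndarray
    starts: np.ndarray
    ends: np.ndarray

    @property
    def T(self) -> int:
        return int(self.ends[-1])

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class StateFC:
    """Per-state duration-weighted mean correlation matrices.

    ``matrices[k]`` is NaN-filled when state k has no window of at
    least the minimum length; ``support[k]`` is the total number of
    samples that entered state k's average.
    """

    matrices: np.ndarray  # K x N x N
    support: np.ndarray  # length K, samples


@dataclass
class NetworkSummary:
    """Within/between-network mean connectivity for one matrix."""

    within: dict[str, float]
    between: dict[tuple[str, str], float]

    def as_vector(self, atlas: ParcelAtlas) -> np.ndarray:
        w = [self.within[n] for n in atlas.network_names]
        b = [self.between[p] for p in atlas.network_pairs()]
        return np.array(w + b)


def segment_states(seq: StateSequence) -> StateWindows:
    """Split a label sequence into maximal constant-state runs."""
    labels = seq.labels
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return StateWindows(states=labels[starts], starts=starts, ends=ends)


def compute_state_fc(
    env: np.ndarray,
    windows: StateWindows,
    K: int,
    min_len: int = DEFAULT_MIN_WINDOW,
) -> StateFC:
    """Duration-weighted per-state correlation matrices.

    ``env`` is parcels x time (orthogonalized envelopes).  Each visit of
    length >= ``min_len`` contributes its Pearson matrix weighted by its
    duration.  A parcel that is constant within a visit yields NaN
    correlations for that visit's rows/columns; NaNs are excluded from
    the weighted average entrywise.
    """
    env = np.asarray(env, dtype=float)
    n = env.shape[0]
    if env.shape[1] != windows.T:
        raise ValueError("envelope length does not match windows")
    acc = np.zeros((K, n, n))
    wsum = np.zeros((K, n, n))
    support = np.zeros(K)
    for k, s, e in zip(windows.states, windows.starts, windows.ends):
        length = e - s
        if length < min_len:
            continue
        seg = env[:, s:e]
        sd = seg.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(seg)
        if (sd == 0).any():
            c[sd == 0, :] = np.nan
            c[:, sd == 0] = np.nan
        good = np.isfinite(c)
        acc[k][good] += length * c[good]
        wsum[k][good] += length
        support[k] += length
    with np.errstate(invalid="ignore", divide="ignore"):
        matrices = acc / wsum
    matrices[support == 0] = np.nan
    for k in range(K):
        if support[k] > 0:
            np.fill_diagonal(matrices[k], 1.0)
    return StateFC(matrices=matrices, support=support)


def network_means(fc: np.ndarray, atlas: ParcelAtlas) -> NetworkSummary:
    """Within-network and between-network-pair mean connectivity.

    Within(net) averages the off-diagonal entries among that network's
    parcels; between(a, b) averages all cross pairs.  NaN entries (e.g.
    a missing state matrix) propagate to NaN summaries.
    """
    fc = np.asarray(fc, dtype=float)
    if fc.shape[0] != fc.shape[1] or fc.shape[0] != atlas.n_parcels:
        raise ValueError("matrix does not match atlas parcel count")
    within: dict[str, float] = {}
    for net in atlas.network_names:
        idx = atlas.indices(net)
        block = fc[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        within[net] = float(np.mean(block[iu]))
    between: dict[tuple[str, str], float] = {}
    for a, b in atlas.network_pairs():
        ia, ib = atlas.indices(a), atlas.indices(b)
        between[(a, b)] = float(np.mean(fc[np.ix_(ia, ib)]))
    return NetworkSummary(within=within, between=between)


def transition_magnitude(
    summaries: list[NetworkSummary | None],
    transition_probs: np.ndarray,
    fractional_occupancy: np.ndarray,
    atlas: ParcelAtlas,
) -> NetworkSummary:
    """Occupancy- and transition-weighted mean |change| in network FC.

    For each network (or pair) with per-state summary values m_k,

        TM = sum_{i != j} fo_i p_ij |m_j - m_i| / sum_{i != j} fo_i p_ij,

    restricted to states whose summary is present.  Requires at least
    two present states; TM is zero exactly when all present m_k agree.
    """
    K = len(summaries)
    present = [
        k
        for k in range(K)
        if summaries[k] is not None
        and np.isfinite(list(summaries[k].within.values())).all()
    ]
    if len(present) < 2:
        raise ValueError("transition magnitude needs >= 2 states with summaries")
    fo = np.asarray(fractional_occupancy, dtype=float)
    tp = np.asarray(transition_probs, dtype=float)

    def _tm(values: dict[int, float]) -> float:
        num = den = 0.0
        for i in present:
            for j in present:
                if i == j:
                    continue
                w = fo[i] * tp[i, j]
                if not np.isfinite(w):
                    continue
                num += w * abs(values[j] - values[i])
                den += w
        return num / den if den > 0 else np.nan

    within = {
        net: _tm({k: summaries[k].within[net] for k in present})
        for net in atlas.network_names
    }
    between = {
        pair: _tm({k: summaries[k].between[pair] for k in present})
        for pair in atlas.network_pairs()
    }
    return NetworkSummary(within=within, between=between)


def subject_connectivity(
    state_fc: StateFC,
    fractional_occupancy: np.ndarray,
    atlas: ParcelAtlas,
) -> NetworkSummary:
    """Occupancy-weighted subject-level network connectivity.

    Averages per-state network summaries weighted by fractional
    occupancy, renormalized over states with a defined FC matrix.
    """
    fo = np.asarray(fractional_occupancy, dtype=float)
    K = state_fc.matrices.shape[0]
    present = [k for k in range(K) if state_fc.support[k] > 0]
    if not present:
        raise ValueError("no state has a defined FC matrix")
    weights = fo[present]
    weights = weights / weights.sum()
    summaries = [network_means(state_fc.matrices[k], atlas) for k in present]
    within = {
        net: float(sum(w * s.within[net] for w, s in zip(weights, summaries)))
        for net in atlas.network_names
    }
    between = {
        pair: float(sum(w * s.between[pair] for w, s in zip(weights, summaries)))
        for pair in atlas.network_pairs()
    }
    return NetworkSummary(within=within, between=between)
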