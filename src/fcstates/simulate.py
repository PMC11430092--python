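"""Synthetic cohorts of parcel-level amplitude envelopes.

The generator emulates source-localized, parcel-level EEG amplitude
envelopes with hidden Markov state switching: at each sample a latent
Markov chain selects one of K connectivity states; the envelope vector
is drawn from a correlated multivariate Gaussian mapped through a
documented monotone nonnegativity map with that state's cross-parcel
correlation structure and per-parcel amplitude gain.

Two envelope maps are provided.  The default, ``"lognormal"``, is
env = gain * exp(sigma * z - sigma^2/2) for latent standard normal z;
log-envelopes are then exactly multivariate Gaussian, matching the
right-skewed marginals of empirical M/EEG envelopes, and the induced
envelope correlation c = (exp(sigma^2 rho) - 1)/(exp(sigma^2) - 1) is
inverted in closed form so that target envelope correlations are hit
directly.  The alternative, ``"folded"``, is env = |z| (folded
normal), with its attenuation c(rho) inverted through a precomputed
monotone lookup; note |z| cannot express negative envelope
correlations.

Each state elevates one network's within-network coupling and overall
amplitude, the generative analog of recurrent network-specific
activation states.  Group effects scale all off-diagonal correlation
targets multiplicatively, emulating global connectivity differences
between cohorts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .atlas import ParcelAtlas, default_atlas

__all__ = [
    "GroundTruthModel",
    "SubjectRecording",
    "CohortSpec",
    "default_ground_truth",
    "sample_state_sequence",
    "generate_recording",
    "generate_cohort",
    "folded_corr",
    "lognormal_corr",
    "target_to_latent",
    "write_recording",
    "read_recording",
]

LOGNORMAL_SIGMA = 0.5
_PSD_FLOOR = 1e-10


def folded_corr(rho: np.ndarray) -> np.ndarray:
    """Correlation of |z1|, |z2| for standard bivariate normal corr rho."""
    rho = np.asarray(rho, dtype=float)
    return (np.sqrt(1 - rho**2) + rho * np.arcsin(rho) - 1) / (np.pi / 2 - 1)


def lognormal_corr(rho: np.ndarray, sigma: float = LOGNORMAL_SIGMA) -> np.ndarray:
    """Correlation of exp(sigma z1), exp(sigma z2) for latent corr rho."""
    rho = np.asarray(rho, dtype=float)
    return np.expm1(sigma**2 * rho) / np.expm1(sigma**2)


# monotone lookup for inverting the folded-normal attenuation
_FOLD_GRID = np.linspace(0.0, 0.999999, 4001)
_FOLD_VALS = folded_corr(_FOLD_GRID)


def target_to_latent(
    c: np.ndarray, mode: str = "lognormal", sigma: float = LOGNORMAL_SIGMA
) -> np.ndarray:
    """Invert the envelope map: target envelope corr -> latent Gaussian corr."""
    c = np.asarray(c, dtype=float)
    if mode == "lognormal":
        return np.log1p(c * np.expm1(sigma**2)) / sigma**2
    if mode == "folded":
        if (c < 0).any():
            raise ValueError("folded-normal envelopes cannot be negatively correlated")
        return np.interp(c, _FOLD_VALS, _FOLD_GRID)
    raise ValueError(f"unknown envelope map {mode!r}")


def _nearest_psd(mat: np.ndarray, floor: float = _PSD_FLOOR) -> np.ndarray:
    """Eigenvalue-floored symmetric projection keeping the unit diagonal."""
    sym = (mat + mat.T) / 2
    w, v = np.linalg.eigh(sym)
    if w.min() >= floor:
        return sym
    fixed = (v * np.maximum(w, floor)) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


@dataclass
class GroundTruthModel:
    """Generative parameters for one cohort's hidden-state dynamics.

    ``state_env_corr[k]`` is state k's target envelope correlation
    matrix (unit diagonal); ``state_gains[k]`` its per-parcel amplitude
    gain.  ``group_effect`` multiplies all off-diagonal correlation
    targets for a cohort (1.0 = reference level).
    """

    initial_probs: np.ndarray
    transition_matrix: np.ndarray
    state_env_corr: np.ndarray  # K x N x N, unit diagonal
    state_gains: np.ndarray  # K x N
    envelope_map: str = "lognormal"
    sigma: float = LOGNORMAL_SIGMA
    carrier_freq_hz: float = 10.0
    group_effect: float = 1.0

    def __post_init__(self) -> None:
        self.initial_probs = np.asarray(self.initial_probs, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if abs(self.initial_probs.sum() - 1.0) > 1e-12 or (self.initial_probs < 0).any():
            raise ValueError("initial_probs must be a probability vector")
        rows = self.transition_matrix.sum(axis=1)
        if np.abs(rows - 1.0).max() > 1e-12 or (self.transition_matrix < 0).any():
            raise ValueError("transition rows must be stochastic")
        for k, corr in enumerate(self.state_env_corr):
            if np.abs(np.diag(corr) - 1.0).max() > 1e-9:
                raise ValueError(f"state {k} correlation diagonal must be 1")

    @property
    def K_true(self) -> int:
        return len(self.initial_probs)

    @property
    def n_parcels(self) -> int:
        return self.state_env_corr.shape[1]

    def with_group_effect(self, effect: float) -> "GroundTruthModel":
        """Scale off-diagonal envelope-correlation targets by ``effect``."""
        scaled = self.state_env_corr * effect
        offd = ~np.eye(self.n_parcels, dtype=bool)
        if np.abs(scaled[:, offd]).max() > 0.999:
            raise ValueError("group effect pushes correlation targets past 1")
        for k in range(self.K_true):
            np.fill_diagonal(scaled[k], 1.0)
        return replace(self, state_env_corr=scaled, group_effect=effect)

    def latent_correlations(self) -> np.ndarray:
        """Latent Gaussian correlation matrices (PSD-projected)."""
        out = np.empty_like(self.state_env_corr)
        for k, corr in enumerate(self.state_env_corr):
            latent = target_to_latent(corr, self.envelope_map, self.sigma)
            np.fill_diagonal(latent, 1.0)
            out[k] = _nearest_psd(latent)
        return out


@dataclass
class SubjectRecording:
    """One subject's parcels x time matrix with its generative truth."""

    subject_id: str
    group: str
    fs: float
    parcel_series: np.ndarray
    true_states: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.parcel_series = np.asarray(self.parcel_series, dtype=float)
        if not np.isfinite(self.parcel_series).all():
            raise ValueError("parcel series must be finite")
        if self.parcel_series.shape[1] < self.fs:
            raise ValueError("recording must be at least 1 s long")

    @property
    def n_parcels(self) -> int:
        return self.parcel_series.shape[0]

    @property
    def n_samples(self) -> int:
        return self.parcel_series.shape[1]


def default_ground_truth(
    atlas: ParcelAtlas | None = None,
    K_true: int = 7,
    *,
    within_active: float = 0.35,
    within_base: float = 0.10,
    between: float = 0.05,
    active_gain: float = 1.4,
    stay_prob: float = 0.98,
    envelope_map: str = "lognormal",
) -> GroundTruthModel:
    """Reference generative configuration: one state per network.

    State k elevates network (k mod 7)'s within-network envelope
    correlation to ``within_active`` and its amplitude by
    ``active_gain``; all other within-network blocks sit at
    ``within_base`` and between-network entries at ``between`` (levels
    in the range of empirical envelope-correlation studies).  The
    chain stays in a state with probability ``stay_prob`` per sample
    (mean dwell 200 ms at 250 Hz) and leaves uniformly.
    """
    atlas = atlas or default_atlas()
    n = atlas.n_parcels
    codes = atlas.label_codes()
    corr = np.empty((K_true, n, n))
    gains = np.ones((K_true, n))
    for k in range(K_true):
        active = k % atlas.n_networks
        c = np.full((n, n), between)
        for b in range(atlas.n_networks):
            mask = codes == b
            level = within_active if b == active else within_base
            c[np.ix_(mask, mask)] = level
        np.fill_diagonal(c, 1.0)
        corr[k] = c
        gains[k, codes == active] = active_gain
    trans = np.full((K_true, K_true), (1 - stay_prob) / (K_true - 1))
    np.fill_diagonal(trans, stay_prob)
    return GroundTruthModel(
        initial_probs=np.full(K_true, 1.0 / K_true),
        transition_matrix=trans,
        state_env_corr=corr,
        state_gains=gains,
        envelope_map=envelope_map,
    )


def sample_state_sequence(
    model: GroundTruthModel, T: int, seed: int
) -> np.ndarray:
    """Sample a length-T hidden state path from the Markov chain."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    cum_init = np.cumsum(model.initial_probs)
    cum_trans = np.cumsum(model.transition_matrix, axis=1)
    u = rng.random(T)
    states = np.empty(T, dtype=int)
    states[0] = np.searchsorted(cum_init, u[0])
    for t in range(1, T):
        states[t] = np.searchsorted(cum_trans[states[t - 1]], u[t])
    return states


def generate_recording(
    atlas: ParcelAtlas,
    model: GroundTruthModel,
    duration_s: float,
    fs: float,
    seed: int,
    mode: str = "envelope",
    *,
    subject_id: str = "sim",
    group: str = "SIM",
    smooth_samples: int = 25,
) -> SubjectRecording:
    """Simulate one subject's parcel time series.

    ``mode="envelope"`` returns the nonnegative envelope matrix itself.
    ``mode="oscillatory"`` multiplies a shared carrier sinusoid at the
    model's carrier frequency by a moving-average-smoothed envelope
    (window ``smooth_samples``), so that Hilbert demodulation recovers
    the modulator; smoothing band-limits the otherwise white envelope
    and leaves cross-parcel correlations unchanged.
    """
    if duration_s < 1:
        raise ValueError("duration_s must be >= 1")
    if atlas.n_parcels != model.n_parcels:
        raise ValueError("atlas and model disagree on parcel count")
    if mode not in ("envelope", "oscillatory"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "oscillatory" and fs <= 2 * model.carrier_freq_hz:
        raise ValueError("fs must exceed twice the carrier frequency")
    T = int(round(duration_s * fs))
    states = sample_state_sequence(model, T, seed)
    rng = np.random.default_rng(seed + 1)
    latents = model.latent_correlations()
    chols = np.stack([np.linalg.cholesky(r + _PSD_FLOOR * np.eye(len(r))) for r in latents])
    z = rng.standard_normal((T, model.n_parcels))
    env = np.empty((T, model.n_parcels))
    for k in range(model.K_true):
        mask = states == k
        if not mask.any():
            continue
        zc = z[mask] @ chols[k].T
        if model.envelope_map == "lognormal":
            env[mask] = np.exp(model.sigma * zc - model.sigma**2 / 2)
        else:
            env[mask] = np.abs(zc)
        env[mask] *= model.state_gains[k]
    series = env.T
    if mode == "oscillatory":
        kernel = np.ones(smooth_samples) / smooth_samples
        smooth = np.apply_along_axis(
            lambda v: np.convolve(v, kernel, mode="same"), 1, series
        )
        t = np.arange(T) / fs
        series = smooth * np.sin(2 * np.pi * model.carrier_freq_hz * t)[None, :]
    return SubjectRecording(
        subject_id=subject_id,
        group=group,
        fs=fs,
        parcel_series=series,
        true_states=states,
        seed=seed,
    )


@dataclass
class CohortSpec:
    """Declarative description of a multi-group synthetic cohort.

    ``groups`` maps group label -> (n_subjects, group_effect); the
    reference levels correspond to effect 1.0.  Per-subject seeds are
    ``master_seed + stable hash of the subject id`` so ids, not
    enumeration order, determine each subject's stream.
    """

    atlas: ParcelAtlas = field(default_factory=default_atlas)
    model: GroundTruthModel | None = None
    groups: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {"YAC": (15, 1.15), "OAC": (15, 1.0), "TCOA": (15, 1.3)}
    )
    duration_s: float = 60.0
    fs: float = 250.0
    mode: str = "envelope"
    master_seed: int = 0


def _subject_seed(master_seed: int, subject_id: str) -> int:
    digest = hashlib.sha256(subject_id.encode()).digest()
    return int(master_seed + (int.from_bytes(digest[:4], "big") % 1_000_003))


def generate_cohort(spec: CohortSpec) -> list[SubjectRecording]:
    """Generate all subjects of a cohort specification."""
    model = spec.model or default_ground_truth(spec.atlas)
    recordings: list[SubjectRecording] = []
    seen: set[str] = set()
    for group, (n_subj, effect) in spec.groups.items():
        if n_subj < 2:
            raise ValueError(f"group {group}: need >= 2 subjects")
        group_model = model.with_group_effect(effect)
        for i in range(n_subj):
            sid = f"{group}{i + 1:02d}"
            if sid in seen:
                raise ValueError(f"duplicate subject id {sid}")
            seen.add(sid)
            recordings.append(
                generate_recording(
                    spec.atlas,
                    group_model,
                    spec.duration_s,
                    spec.fs,
                    _subject_seed(spec.master_seed, sid),
                    spec.mode,
                    subject_id=sid,
                    group=group,
                )
            )
    return recordings


def write_recording(rec: SubjectRecording, directory: str | Path) -> None:
    """One delimited-text matrix plus a JSON sidecar per subject."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / f"{rec.subject_id}_series.tsv", rec.parcel_series, delimiter="\t")
    sidecar = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "fs": rec.fs,
        "seed": rec.seed,
        "n_parcels": rec.n_parcels,
        "n_samples": rec.n_samples,
        "true_states": None
        if rec.true_states is None
        else rec.true_states.tolist(),
    }
    (directory / f"{rec.subject_id}.json").write_text(json.dumps(sidecar))


def read_recording(directory: str | Path, subject_id: str) -> SubjectRecording:
    directory = Path(directory)
    meta = json.loads((directory / f"{subject_id}.json").read_text())
    series = np.loadtxt(directory / f"{subject_id}_series.tsv", delimiter="\t")
    true_states = meta["true_states"]
    return SubjectRecording(
        subject_id=meta["subject_id"],
        group=meta["group"],
        fs=meta["fs"],
        parcel_series=series,
        true_states=None if true_states is None else np.asarray(true_states, int),
        seed=meta["seed"],
    )
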