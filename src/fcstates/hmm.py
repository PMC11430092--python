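"""Gaussian hidden Markov modelling of envelope data.

Per-sample brain states are modelled as a K-state HMM with
full-covariance Gaussian emissions on PCA-reduced features.  The state
count is chosen by fitting every K in a candidate range to every
subject and minimizing the across-subject mean of (AIC + BIC)/2; the
final shared model is then fit on the concatenated, per-subject
standardized data so state labels are comparable across subjects.

Envelope features are log-transformed (envelopes are strictly positive
and right-skewed; the log is the standard variance-stabilizing
transform and brings amplitude modulations onto an additive scale)
and standardized per subject before PCA.  Both steps can be disabled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from ._hmm_core import (
    em_step,
    forward_backward,
    gaussian_log_likelihood,
    viterbi_path,
)

from .temporal import StateSequence

__all__ = [
    "HMMConfig",
    "GaussianHMM",
    "ModelSelectionResult",
    "preprocess_features",
    "pca_reduce",
    "fit_hmm",
    "information_criteria",
    "select_n_states",
    "decode",
    "n_parameters",
]


@dataclass
class HMMConfig:
    """Tunable knobs of the state-modelling stage.

    ``K_range`` is inclusive; ``pca_retained`` is the cumulative
    explained-variance fraction to keep and ``pca_max_dim`` an optional
    hard cap on the component count; ``variance_floor_frac`` scales the
    maximum feature variance into the emission-covariance diagonal
    floor; ``log_transform`` applies log() to strictly positive
    envelope features before standardization.
    """

    K_range: tuple[int, int] = (3, 12)
    pca_retained: float = 0.95
    pca_max_dim: int | None = None
    variance_floor_frac: float = 1e-3
    em_max_iter: int = 50
    # absolute log-likelihood tolerance per sample; state-count
    # selection compares attained likelihoods across K, which makes it
    # sensitive to under-convergence, so the default is conservative
    em_tol_per_sample: float = 3.3e-4
    n_restarts: int = 3
    seed: int = 0
    log_transform: bool = True
    standardize: bool = True
    # transition-matrix initialization: brain states persist over many
    # samples, and a sticky prior keeps EM out of the shallow local
    # optima that a temporally unstructured start falls into
    sticky_init: float = 0.9
    # optional temporal decimation of the reduced scores during the
    # state-count search; decimation halves the search cost but also
    # shrinks the likelihood differences the criterion compares, which
    # can bias the selected K downward, so the default is off
    selection_stride: int = 1
    # k-means initialization runs on moving-average-smoothed features:
    # states persist over tens of samples, so smoothing (window in
    # samples, ~100 ms at 250 Hz) separates the state clusters that
    # per-sample noise otherwise blurs, placing EM in the right basin
    init_smooth: int = 25

    def __post_init__(self) -> None:
        if not 0 < self.pca_retained <= 1:
            raise ValueError("pca_retained must be in (0, 1]")
        if self.K_range[0] < 1 or self.K_range[0] > self.K_range[1]:
            raise ValueError("invalid K_range")

    @property
    def K_values(self) -> list[int]:
        return list(range(self.K_range[0], self.K_range[1] + 1))


@dataclass
class GaussianHMM:
    """Fitted K-state full-covariance Gaussian HMM."""

    initial_probs: np.ndarray
    transition_matrix: np.ndarray
    state_means: np.ndarray
    state_covariances: np.ndarray
    log_likelihood: float

    @property
    def K(self) -> int:
        return len(self.initial_probs)

    @property
    def d(self) -> int:
        return self.state_means.shape[1]

    def score(self, X: np.ndarray, lengths: list[int] | None = None) -> float:
        """Log-likelihood of data under the fitted parameters."""
        X = np.asarray(X, dtype=float)
        logb = gaussian_log_likelihood(X, self.state_means, self.state_covariances)
        if lengths is None:
            segments = [(0, X.shape[0])]
        else:
            bounds = np.concatenate([[0], np.cumsum(lengths)])
            segments = list(zip(bounds[:-1], bounds[1:]))
        total = 0.0
        for s, e in segments:
            ll, _, _ = forward_backward(
                logb[s:e], self.initial_probs, self.transition_matrix
            )
            total += ll
        return total

    def to_json(self, path: str | Path) -> None:
        payload = {
            "initial_probs": self.initial_probs.tolist(),
            "transition_matrix": self.transition_matrix.tolist(),
            "state_means": self.state_means.tolist(),
            "state_covariances": self.state_covariances.tolist(),
            "log_likelihood": self.log_likelihood,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GaussianHMM":
        d = json.loads(Path(path).read_text())
        return cls(
            initial_probs=np.asarray(d["initial_probs"]),
            transition_matrix=np.asarray(d["transition_matrix"]),
            state_means=np.asarray(d["state_means"]),
            state_covariances=np.asarray(d["state_covariances"]),
            log_likelihood=float(d["log_likelihood"]),
        )


@dataclass
class ModelSelectionResult:
    """Per-subject, per-K criteria and the selected state count."""

    K_values: list[int]
    aic: np.ndarray  # subjects x K
    bic: np.ndarray  # subjects x K
    mean_criterion: np.ndarray  # length K: across-subject mean of (AIC+BIC)/2
    K_star: int
    warnings: list[str] = field(default_factory=list)


def preprocess_features(X: np.ndarray, cfg: HMMConfig) -> np.ndarray:
    """Log-transform (if positive) and standardize a T x N matrix."""
    X = np.asarray(X, dtype=float)
    if cfg.log_transform:
        if (X <= 0).any():
            raise ValueError(
                "log_transform requires strictly positive features; "
                "disable it for signed inputs"
            )
        X = np.log(X)
    if cfg.standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return X


def pca_reduce(
    X: np.ndarray, retained: float = 0.95, max_dim: int | None = None
) -> tuple[np.ndarray, PCA, int]:
    """Project T x N data onto the fewest PCs reaching ``retained``.

    Returns (scores, fitted PCA, d).  d is the smallest component
    count whose cumulative explained variance ratio reaches
    ``retained``, capped at ``max_dim`` and at the matrix rank.
    """
    X = np.asarray(X, dtype=float)
    t, n = X.shape
    if t <= n:
        raise ValueError("need more samples than features for PCA")
    pca = PCA()
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    d = int(np.searchsorted(cum, retained - 1e-12) + 1)
    d = min(d, np.linalg.matrix_rank(X - X.mean(axis=0)))
    if max_dim is not None:
        d = min(d, max_dim)
    return scores[:, :d], pca, d


def n_parameters(K: int, d: int) -> int:
    """Free parameters of a K-state, d-dim full-covariance Gaussian HMM."""
    return (K - 1) + K * (K - 1) + K * d + K * d * (d + 1) // 2


def fit_hmm(
    X: np.ndarray,
    K: int,
    cfg: HMMConfig,
    lengths: list[int] | None = None,
) -> GaussianHMM:
    """EM fit with restarts; returns the best model by log-likelihood.

    ``X`` is T x d (already reduced); ``lengths`` optionally marks
    per-subject segment boundaries for concatenated fits.  The
    covariance diagonal is floored at
    ``variance_floor_frac * max feature variance``.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 10 * K:
        raise ValueError(f"need T >= 10K samples to fit K={K}")
    floor = cfg.variance_floor_frac * float(X.var(axis=0).max())
    tol = cfg.em_tol_per_sample * X.shape[0]
    best: GaussianHMM | None = None
    best_ll = -np.inf
    errors: list[str] = []
    for r in range(cfg.n_restarts):
        seed = cfg.seed + 9973 * r
        try:
            model = _fit_once(X, K, cfg, floor, tol, seed, lengths)
        except (ValueError, np.linalg.LinAlgError, RuntimeError) as exc:
            errors.append(str(exc))
            continue
        if np.isfinite(model.log_likelihood) and model.log_likelihood > best_ll:
            best, best_ll = model, model.log_likelihood
    if best is None:
        raise RuntimeError(
            f"all {cfg.n_restarts} restarts failed for K={K}: "
            f"{errors[-1] if errors else 'no finite likelihood'}"
        )
    return best


def _fit_once(
    X: np.ndarray,
    K: int,
    cfg: HMMConfig,
    floor: float,
    tol: float,
    seed: int,
    lengths: list[int] | None,
) -> GaussianHMM:
    """Single EM run: smoothed k-means labels, sticky transitions,
    floored covariances."""
    t, d = X.shape
    stay = cfg.sticky_init if K > 1 else 1.0
    trans = np.full((K, K), (1 - stay) / max(K - 1, 1))
    np.fill_diagonal(trans, stay)
    start = np.full(K, 1.0 / K)
    if K == 1:
        labels = np.zeros(t, dtype=int)
    else:
        w = max(int(cfg.init_smooth), 1)
        if w > 1 and t > 2 * w:
            kernel = np.ones(w) / w
            smoothed = np.empty_like(X)
            for j in range(d):
                smoothed[:, j] = np.convolve(X[:, j], kernel, mode="same")
        else:
            smoothed = X
        labels = KMeans(n_clusters=K, random_state=seed, n_init=1).fit(smoothed).labels_
    means = np.empty((K, d))
    covs = np.empty((K, d, d))
    eye = np.eye(d)
    global_cov = np.cov(X.T).reshape(d, d)
    for j in range(K):
        members = X[labels == j]
        if members.shape[0] > d:
            means[j] = members.mean(axis=0)
            covs[j] = np.cov(members.T).reshape(d, d) + floor * eye
        else:  # empty/tiny cluster: fall back to global moments
            means[j] = X.mean(axis=0)
            covs[j] = global_cov + floor * eye
    prev_ll = -np.inf
    ll = -np.inf
    for _ in range(cfg.em_max_iter):
        ll, start, trans, means, covs = em_step(
            X, start, trans, means, covs, floor, lengths
        )
        if not np.isfinite(ll):
            raise RuntimeError(f"EM diverged (non-finite likelihood) at K={K}")
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
    return GaussianHMM(
        initial_probs=start,
        transition_matrix=trans,
        state_means=means,
        state_covariances=covs,
        log_likelihood=float(ll),
    )


def information_criteria(
    model: GaussianHMM, X: np.ndarray, log_likelihood: float | None = None
) -> tuple[float, float]:
    """(AIC, BIC) of a fitted model on the data it was fit to.

    AIC = 2p - 2 lnL and BIC = p ln T - 2 lnL with
    p = (K-1) + K(K-1) + Kd + Kd(d+1)/2.  ``log_likelihood`` skips the
    rescoring pass when the fit's attained value is already at hand.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.d:
        raise ValueError("feature dimension does not match the model")
    p = n_parameters(model.K, model.d)
    lnL = (
        float(log_likelihood) if log_likelihood is not None else model.score(X)
    )
    t = X.shape[0]
    return 2 * p - 2 * lnL, p * np.log(t) - 2 * lnL


def select_n_states(
    datasets: list[np.ndarray], cfg: HMMConfig
) -> ModelSelectionResult:
    """Choose K by the across-subject mean of (AIC + BIC)/2.

    ``datasets`` holds one raw T x N feature matrix per subject; each
    is preprocessed and PCA-reduced independently.  A subject failing
    to fit at some K is excluded from that K's mean with a warning; a
    K failing for more than half the subjects is excluded entirely.
    Ties break toward smaller K.
    """
    if not datasets:
        raise ValueError("need at least one subject")
    K_values = cfg.K_values
    n_subj = len(datasets)
    aic = np.full((n_subj, len(K_values)), np.nan)
    bic = np.full((n_subj, len(K_values)), np.nan)
    warnings: list[str] = []
    reduced = []
    for X in datasets:
        Z = preprocess_features(X, cfg)
        scores, _, _ = pca_reduce(Z, cfg.pca_retained, cfg.pca_max_dim)
        reduced.append(scores[:: max(cfg.selection_stride, 1)])
    for j, K in enumerate(K_values):
        for i, Y in enumerate(reduced):
            sub_cfg = HMMConfig(**{**asdict(cfg), "seed": cfg.seed + 17 * i})
            try:
                model = fit_hmm(Y, K, sub_cfg)
            except (RuntimeError, ValueError) as exc:
                warnings.append(f"subject {i}, K={K}: {exc}")
                continue
            a, b = information_criteria(model, Y, model.log_likelihood)
            aic[i, j], bic[i, j] = a, b
    crit = (aic + bic) / 2.0
    ok_frac = np.isfinite(crit).mean(axis=0)
    mean_crit = np.full(len(K_values), np.nan)
    for j in range(len(K_values)):
        if ok_frac[j] > 0.5:
            mean_crit[j] = np.nanmean(crit[:, j])
        else:
            warnings.append(f"K={K_values[j]} excluded (>50% subjects failed)")
    if not np.isfinite(mean_crit).any():
        raise RuntimeError("model selection failed for every K")
    # argmin with ties toward smaller K (argmin returns the first min)
    j_star = int(np.nanargmin(mean_crit))
    return ModelSelectionResult(
        K_values=K_values,
        aic=aic,
        bic=bic,
        mean_criterion=mean_crit,
        K_star=K_values[j_star],
        warnings=warnings,
    )


def decode(model: GaussianHMM, X: np.ndarray, fs: float) -> StateSequence:
    """Viterbi decoding: the most probable joint state path."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.d:
        raise ValueError("feature dimension does not match the model")
    logb = gaussian_log_likelihood(X, model.state_means, model.state_covariances)
    labels, _ = viterbi_path(logb, model.initial_probs, model.transition_matrix)
    return StateSequence(labels=labels, fs=fs)
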