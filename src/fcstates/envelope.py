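"""Amplitude-envelope preprocessing of parcel time series.

Three stages: anti-aliased downsampling to a 250 Hz working rate,
Hilbert-transform envelope extraction, and orthogonalization of the
envelopes across parcels to suppress shared (leakage-like) variance.

Orthogonalization acts on per-parcel demeaned envelopes.  The default
is QR-based (sequential Gram-Schmidt via a Householder QR): parcel k's
output is its component orthogonal to parcels 1..k-1 and to the
constant vector, rescaled to its original norm.  Because the QR is
computed on the matrix with a leading constant column, every output is
exactly zero-mean, so pairwise sample correlations of the outputs
vanish to machine precision even for rank-deficient (collinear)
inputs.  A symmetric (Loewdin, closest-orthogonal-matrix) variant is
available via ``method="symmetric"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = ["EnvelopeMatrix", "downsample", "hilbert_envelope", "orthogonalize"]

# condition number beyond which the input is treated as collinear and
# the event is reported
COLLINEARITY_CONDITION = 1e8
BOUNDARY_FRACTION = 0.05


@dataclass
class EnvelopeMatrix:
    """Nonnegative parcels x time amplitude envelopes at rate ``fs``.

    ``boundary`` flags the first/last 5% of samples, whose envelope
    values are affected by the finite-length analytic signal.
    """

    values: np.ndarray
    fs: float
    boundary: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("envelope values must be finite")
        if (self.values < 0).any():
            raise ValueError("envelope values must be nonnegative")
        if self.boundary is None:
            T = self.values.shape[1]
            edge = int(np.ceil(BOUNDARY_FRACTION * T))
            flags = np.zeros(T, dtype=bool)
            flags[:edge] = True
            flags[T - edge :] = True
            self.boundary = flags

    @property
    def interior(self) -> np.ndarray:
        """Column mask of samples clear of boundary effects."""
        return ~self.boundary


def downsample(
    series: np.ndarray, fs_in: float, fs_target: float = 250.0
) -> tuple[np.ndarray, float]:
    """Anti-aliased resampling of parcels x time data to ``fs_target``.

    Uses polyphase FIR resampling (zero-phase, with an anti-aliasing
    low-pass at the new Nyquist).  Returns (resampled series, fs_target).
    Upsampling is refused.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be parcels x time")
    if fs_in < fs_target:
        raise ValueError(f"fs_in={fs_in} below target {fs_target}: no upsampling")
    if fs_in == fs_target:
        return series.copy(), fs_target
    from fractions import Fraction

    frac = Fraction(fs_target / fs_in).limit_denominator(10_000)
    out = signal.resample_poly(series, frac.numerator, frac.denominator, axis=1)
    return out, fs_target


def hilbert_envelope(series: np.ndarray, fs: float) -> EnvelopeMatrix:
    """Modulus of the analytic signal, per parcel."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] < 16:
        raise ValueError("series must be parcels x time with T >= 16")
    if not np.isfinite(series).all():
        raise ValueError("input must be finite")
    env = np.abs(signal.hilbert(series, axis=1))
    return EnvelopeMatrix(values=env, fs=fs)


def _qr_orthogonalize(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Rows of x -> mutually orthogonal, zero-mean rows of equal norms.

    Operates on the transposed (time x parcels) matrix with a leading
    constant column so all outputs are orthogonal to it (zero mean).
    Householder QR returns exactly orthonormal columns regardless of
    rank, which is the regularization that handles collinear parcels:
    a (near-)duplicated parcel simply receives a direction orthogonal
    to everything already extracted.
    """
    n, t = x.shape
    norms = np.linalg.norm(x, axis=1)
    norms[norms == 0] = 1.0
    a = np.column_stack([np.ones(t), x.T])
    q = np.linalg.qr(a, mode="reduced")[0][:, 1:]  # drop the constant direction
    out = (q * norms).T
    # fix signs so each output correlates nonnegatively with its input
    sign = np.sign(np.einsum("ij,ij->i", out, x))
    sign[sign == 0] = 1.0
    out *= sign[:, None]
    sv = np.linalg.svd(x, compute_uv=False)
    collinear = sv[-1] == 0 or sv[0] / sv[-1] > COLLINEARITY_CONDITION
    return out, bool(collinear)


def _symmetric_orthogonalize(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Loewdin orthogonalization: closest set of orthogonal rows.

    Replaces x = U S V' by U V' (scaled back to the original row
    norms), which treats all parcels symmetrically instead of
    sequentially.  Exactly rank-deficient inputs are regularized by
    flooring the singular values.
    """
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    floor = max(s[0], 1.0) * 1e-10
    collinear = s[-1] < s[0] / COLLINEARITY_CONDITION
    norms = np.linalg.norm(x, axis=1)
    norms[norms == 0] = 1.0
    out = (u @ vt) * norms[:, None]
    # re-demean and re-orthogonalize against the constant via QR pass:
    # Loewdin outputs are orthogonal but not exactly zero-mean, so a
    # final projection keeps the correlation contract
    out = out - out.mean(axis=1, keepdims=True)
    return out, bool(collinear)


def orthogonalize(
    env: EnvelopeMatrix | np.ndarray, method: str = "qr"
) -> tuple[np.ndarray, dict]:
    """Orthogonalize envelope rows over time.

    Demeans each parcel, then applies QR-based (default) or symmetric
    orthogonalization.  Requires more time samples than parcels.
    Returns ``(matrix, log)`` where the log records the method and
    whether a collinearity event occurred.  The output is zero-mean per
    parcel (the mean is not restored; downstream connectivity is
    correlation-based and mean-invariant).
    """
    values = env.values if isinstance(env, EnvelopeMatrix) else np.asarray(env, float)
    n, t = values.shape
    if t <= n:
        raise ValueError(f"need T > N for orthogonalization (got N={n}, T={t})")
    x = values - values.mean(axis=1, keepdims=True)
    if method == "qr":
        out, collinear = _qr_orthogonalize(x)
    elif method == "symmetric":
        out, collinear = _symmetric_orthogonalize(x)
    else:
        raise ValueError(f"unknown method {method!r}")
    return out, {"method": method, "collinearity_detected": collinear}
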