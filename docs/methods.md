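# Methods

`fcstates` implements a complete analysis of recurrent functional-connectivity
(FC) dynamics in parcel-level electrophysiological amplitude envelopes:
synthetic-cohort simulation with known hidden-state ground truth, envelope
preprocessing, Gaussian hidden-Markov brain-state modelling with data-driven
state-count selection, temporal and network-level spatial state features, an
adaptive disparity-filter graph backbone, and nonparametric two-group
statistics. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic validation does and does not show.

## Synthetic cohort model

Each subject is an N-parcel (default 100, grouped into the 7 canonical
cortical networks VIN/SMN/DAN/VAN/LIN/FPN/DMN) x T-sample envelope matrix.
A K-state Markov chain (default K = 7) switches per sample; given state k,
the envelope vector is

    env_t = g_k * exp(sigma * z_t - sigma^2 / 2),    z_t ~ N(0, R_k),

with sigma = 0.5, per-parcel amplitude gains g_k, and latent correlation
R_k. Log-envelopes are therefore exactly multivariate Gaussian per state —
the standard empirical description of M/EEG envelope marginals
(right-skewed, multiplicative) — and the induced envelope correlation

    c = (exp(sigma^2 rho) - 1) / (exp(sigma^2) - 1)

is monotone in the latent correlation rho and inverted in closed form, so
state correlation *targets* are specified directly on the envelope scale.
A folded-normal map (env = |z|, attenuation inverted through a precomputed
monotone lookup) is available as an option; it cannot express negative
envelope correlations and makes the state model's Gaussian emissions
misspecified, which is why it is not the default.

The reference ground truth assigns one state per network: state k raises
network k's within-network envelope correlation to 0.35 and its amplitude
gain to 1.4, against a background of 0.10 within-network and 0.05
between-network coupling — levels in the range reported for envelope FC.
The chain stays per sample with probability 0.98 (mean dwell 200 ms at
250 Hz) and leaves uniformly. Correlation targets are built as nonnegative
block-constant increments, which guarantees positive semidefiniteness by
construction; an eigenvalue-flooring nearest-PSD projection (floor 1e-10)
guards the inverted latent matrices.

Group effects multiply all off-diagonal correlation targets. The default
cohort mirrors a three-group cross-sectional design, 15 subjects per group,
with effects OAC 1.0, YAC 1.15, TCOA 1.3 — i.e. the older-control group is
the connectivity reference, younger controls are moderately higher, and the
practice group highest. Per-subject seeds are `master_seed + (stable hash
of the subject id)`, so cohorts are reproducible and ids, not enumeration
order, determine each subject's stream.

Oscillatory mode multiplies a 10 Hz carrier by the (moving-average
smoothed, window 25 samples) envelope, so Hilbert demodulation recovers the
modulator; smoothing band-limits the otherwise white envelope and leaves
instantaneous cross-parcel correlations unchanged. What the generator does
*not* emulate: sensor-space mixing and source leakage, 1/f background
spectra, artifacts, or any within-state nonstationarity. Passing tests on
this generator therefore validate the *analysis machinery*, not robustness
to those real-data complications.

## Envelope preprocessing

`downsample` applies polyphase FIR resampling with an anti-aliasing
low-pass to the 250 Hz working rate; `hilbert_envelope` takes the modulus
of the analytic signal, flagging the first/last 5% of samples as
boundary-affected. `orthogonalize` demeans each parcel and, by default,
computes a Householder QR of the time x parcel matrix with a leading
constant column: every output is exactly zero-mean and outputs are mutually
orthogonal to machine precision, so post-hoc pairwise correlations vanish.
Exactly collinear parcels (duplicated channels) are handled by the QR
itself — the duplicated direction receives an orthogonal complement rather
than causing failure — and a condition-number check (cutoff 1e8) reports
the event. A symmetric (Loewdin, closest-orthogonal-matrix) variant is
exposed as an option; it treats parcels symmetrically instead of
sequentially at the cost of slightly looser orthogonality after the final
demeaning. The per-parcel mean is not restored: downstream connectivity is
correlation-based and mean-invariant.

Orthogonalization removes zero-lag shared variance — exactly the leakage
artifact of source reconstruction, but also any genuine instantaneous
coupling. On leakage-free synthetic data it therefore removes most of the
signal of interest: the simulation-based group-effect experiments run with
the orthogonalization stage disabled (`PipelineConfig.orthogonalize`),
while the stage's own contracts are tested directly. Whether
orthogonalization should act on analytic signals or on envelopes is left
open in the source literature; here it acts on envelopes.

## Brain-state model

States are modelled as a K-state hidden Markov model with full-covariance
Gaussian emissions — amplitude-coupling states are *defined* by covariance
structure, which diagonal emissions cannot express. Envelope features are
log-transformed (variance stabilization for strictly positive, right-skewed
amplitudes; exposed as `HMMConfig.log_transform`), standardized per
subject, and PCA-reduced to the smallest dimension reaching 95% cumulative
explained variance, optionally capped (`pca_max_dim`, default 20 in the
pipeline) to keep full covariance estimation tractable.

The EM core (`fcstates._hmm_core`) is the package's own: scaled
forward-backward and Viterbi recursions compiled with numba, emission
likelihoods in whitened GEMM form, and closed-form M-steps with the
covariance diagonal floored at `variance_floor_frac` (default 1e-3) times
the maximum feature variance. Tests verify it against an independent
reference HMM implementation (identical likelihood and Viterbi path for
identical parameters) and against brute-force path enumeration.

Initialization matters more than iteration count. Two measures keep EM out
of shallow local optima: (1) k-means runs on moving-average-smoothed
features (window 25 samples ~ the expected dwell time), which separates
state clusters that per-sample noise blurs and empirically places EM in the
basin of the global optimum in ~4 iterations; (2) the transition matrix is
initialized sticky (self-transition 0.9), reflecting state persistence.
The convergence tolerance is deliberately conservative (3.3e-4 per sample,
~5 log-likelihood units at T = 15,000) because the state-count criterion
compares attained likelihoods across K and is sensitive to differential
under-convergence: looser tolerances measurably bias the selected K upward
(under-converged K = 7 fits losing to K = 8), and temporal decimation of
the selection data biases it downward, so neither shortcut is used.

The state count is selected by fitting every K in 3..12 to every subject
separately and minimizing the across-subject mean of (AIC + BIC)/2, with
the parameter count p = (K-1) + K(K-1) + Kd + Kd(d+1)/2; ties break toward
smaller K. The final model is then fit once on the concatenated
per-subject-standardized data (per-subject segment boundaries respected in
the forward-backward pass) and each subject is decoded with it, so state
labels are comparable across subjects. Decoding uses the Viterbi path.

## Temporal and spatial features

From each decoded sequence: fractional occupancy (sample counts / T), mean
lifetime (mean run length, boundary-truncated first/last runs included —
excluding them would bias short recordings), mean interval (mean gap
between consecutive visits, exclusive of the visits; undefined below two
visits), and the empirical transition matrix including self-transitions.
Undefined features propagate as NaN — never zero — and are dropped
pairwise by the statistics.

Spatially, the decoded sequence re-windows the recording into maximal
constant-state runs. Per visit of at least `min_window` samples (default
25 = 100 ms at 250 Hz; shorter windows give numerically meaningless
envelope correlations), a Pearson matrix is computed; per state the visit
matrices are combined by duration-weighted averaging rather than sample
concatenation, which would splice non-contiguous segments and distort
correlations. Network reductions average off-diagonal entries within each
of the 7 networks and across each of the 21 network pairs. Subject-level
connectivity is the occupancy-weighted average of per-state network means,
renormalized over states with defined matrices. The transition magnitude
for a network (or pair) with per-state values m_k is

    TM = sum_{i != j} fo_i p_ij |m_j - m_i| / sum_{i != j} fo_i p_ij,

an occupancy- and transition-weighted mean absolute FC change between
states: zero exactly when all per-state values agree, linear in the spread
of the m_k, and invariant to never-entered states.

## Disparity-filter backbone

Windowed FC graphs are thresholded adaptively rather than at a fixed edge
weight. All edge weights are pooled across windows; M is the median of
10,000 bootstrap medians of the absolute pooled weights (absolute, because
a signed pool's median can sit near zero and break the normalization).
For a window and threshold alpha, edge (u, v) is retained iff

    s_u(v) = (|w_uv|/M)^2 / sum_k (|w_uk|/M)^2 >= alpha   or   s_v(u) >= alpha,

the inclusive either-endpoint rule (a degree-1 node's only edge has score
exactly 1 and always survives). Retained edges keep their sign — the
filter judges magnitudes only, so retained negative couplings survive.
Useful identities: equal-weight nodes of degree g give s = 1/g exactly,
retention is invariant to jointly rescaling weights and M, and the retained
edge set shrinks monotonically in alpha.

The shared alpha minimizes the mean absolute difference in average retained
connectivity between consecutive windows over [0.001, 0.10], by
golden-section search cross-checked against a 0.001-step grid with local
refinement at a tenth of the grid step around the best points — the
objective is piecewise constant and need not be unimodal, so the
golden-section result alone is not trusted. A flat objective returns the
lower bound with a warning flag.

## Statistics

Two groups are compared per dependent variable with the Mann-Whitney U
test, U counted for the first-listed group so that negative rank-biserial
r = 2U/(n1 n2) - 1 means "first group lower". Two p-value routes are
implemented: the exact tie-free null distribution of U via the counting
recurrence f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u) (validated
against complete arrangement enumeration), and the normal approximation
with continuity and midrank-tie corrections. Applied reports at these
sample sizes conventionally print the continuity-corrected asymptotic
value, so `compare_groups` defaults to it; at n = 15 per group the two can
differ several-fold in the far tail (e.g. U = 13: exact 4.8e-6 vs
asymptotic 4.0e-5). Benjamini-Hochberg FDR adjustment is applied within
explicit families (the 7 within-network variables; the 21 between-network
variables; each temporal feature type) — the family structure is
configurable because pooling silently changes every adjusted value.
Shapiro-Wilk, median-centred Levene, and z-score/IQR outlier flags are
reported as information only; nothing is removed automatically.

## Validation scale and experiment design

The state-count experiment runs 10 replicates of 10 subjects x 60 s x
250 Hz (T = 15,000), K = 3..12, PCA capped at 20 components, one
smoothed-k-means EM run per (subject, K) — problem sizes chosen so the
full experiment completes in minutes on a single core while each subject
still yields ~2,100 samples per state. The group-effect experiments use
15-subject groups at 15 s per subject with the state count fixed at the
generative value (state-count recovery is a separate experiment) and
orthogonalization disabled, for the leakage-free reason above. The
type-I-error calibration pools the 28 FC features from two-group cohorts
with identical effects until 200 p-values are collected.

## Known limitations

- The generator's states differ in amplitude and instantaneous
  correlation only; no spectral (frequency-specific) state structure.
- AIC/BIC state-count selection depends on comparable convergence across
  K; the initialization and tolerance choices above were required to make
  it behave, and looser settings visibly bias the answer.
- The transition-magnitude definition is this package's formalization of a
  verbal description; alternatives (e.g. onset-to-onset intervals,
  concatenated-sample state FC) are noted in the module docstrings where
  they arise.
- Exact Mann-Whitney p-values assume no ties; tied data fall back to the
  tie-corrected normal approximation, flagged in the output.
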