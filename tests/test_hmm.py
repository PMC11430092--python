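"""State modelling: PCA reduction, EM fitting, criteria, decoding.

hmmlearn serves as the independent reference implementation: given the
same parameters it must produce the same likelihood and Viterbi path
as the package's own EM core.
"""

import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.stats import multivariate_normal

from fcstates._hmm_core import (
    em_step,
    forward_backward,
    gaussian_log_likelihood,
    viterbi_path,
)
from fcstates.hmm import (
    GaussianHMM,
    HMMConfig,
    decode,
    fit_hmm,
    information_criteria,
    n_parameters,
    pca_reduce,
    select_n_states,
)


def _three_state_data(rng, T=3000, d=4, sep=3.0):
    means = np.array(
        [[0, 0, 0, 0], [sep, sep, 0, 0], [0, 0, sep, sep]], dtype=float
    )[:, :d]
    A = np.array([[0.95, 0.03, 0.02], [0.02, 0.96, 0.02], [0.03, 0.02, 0.95]])
    s = np.zeros(T, dtype=int)
    for t in range(1, T):
        s[t] = rng.choice(3, p=A[s[t - 1]])
    X = rng.standard_normal((T, d)) + means[s]
    return X, s, A


class TestPcaReduce:
    def test_dominant_direction_forces_d1(self, rng):
        base = rng.standard_normal(500)
        X = np.outer(base, np.ones(5)) + 1e-3 * rng.standard_normal((500, 5))
        _, _, d = pca_reduce(X, retained=0.95)
        assert d == 1

    def test_isotropic_needs_almost_all_components(self, rng):
        X = rng.standard_normal((40_000, 20))
        _, _, d = pca_reduce(X, retained=0.95)
        assert d == 19  # cumulative share of equal variances crosses at 19/20

    def test_reconstruction_error_bounded(self, rng):
        X = rng.standard_normal((300, 10)) @ rng.standard_normal((10, 10))
        scores, pca, d = pca_reduce(X, retained=0.9)
        Xc = X - X.mean(axis=0)
        recon = scores @ pca.components_[:d]
        err = np.sum((Xc - recon) ** 2)
        assert err <= 0.1 * np.sum(Xc**2) + 1e-9

    def test_max_dim_cap(self, rng):
        X = rng.standard_normal((200, 12))
        _, _, d = pca_reduce(X, retained=1.0, max_dim=5)
        assert d == 5


class TestCoreAgainstHmmlearn:
    def test_same_parameters_same_likelihood_and_path(self, rng):
        from hmmlearn.hmm import GaussianHMM as HLGauss

        X, _, _ = _three_state_data(rng)
        model = fit_hmm(X, 3, HMMConfig(n_restarts=1, em_max_iter=20, seed=0))
        hl = HLGauss(3, covariance_type="full")
        hl.startprob_ = model.initial_probs
        hl.transmat_ = model.transition_matrix
        hl.means_ = model.state_means
        hl.covars_ = model.state_covariances
        assert model.score(X) == pytest.approx(hl.score(X), abs=1e-6)
        _, hl_path = hl.decode(X)
        assert np.array_equal(decode(model, X, 250.0).labels, hl_path)

    def test_density_matches_scipy(self, rng):
        X = rng.standard_normal((50, 3))
        means = rng.standard_normal((2, 3))
        covs = np.stack([np.eye(3) * 2.0, np.eye(3) * 0.5])
        logb = gaussian_log_likelihood(X, means, covs)
        for k in range(2):
            ref = multivariate_normal(means[k], covs[k]).logpdf(X)
            np.testing.assert_allclose(logb[:, k], ref, atol=1e-10)


class TestFitHmm:
    def test_k1_equals_sample_moments(self, rng):
        X = rng.standard_normal((500, 3)) * 2.0 + 1.0
        cfg = HMMConfig(n_restarts=1, em_max_iter=10, variance_floor_frac=1e-12)
        m = fit_hmm(X, 1, cfg)
        np.testing.assert_allclose(m.state_means[0], X.mean(axis=0), atol=1e-6)
        np.testing.assert_allclose(
            m.state_covariances[0], np.cov(X.T, bias=True), atol=1e-5
        )

    def test_label_recovery_on_separated_states(self, rng):
        X, s, _ = _three_state_data(rng)
        m = fit_hmm(X, 3, HMMConfig(n_restarts=2, em_max_iter=50, seed=1))
        dec = decode(m, X, 250.0).labels
        conf = np.zeros((3, 3))
        np.add.at(conf, (s, dec), 1)
        r, c = linear_sum_assignment(-conf)
        assert conf[r, c].sum() / len(s) >= 0.95

    def test_transition_matrix_recovery(self, rng):
        X, s, A = _three_state_data(rng, T=20_000)
        m = fit_hmm(X, 3, HMMConfig(n_restarts=2, em_max_iter=60, seed=2))
        dec = decode(m, X, 250.0).labels
        conf = np.zeros((3, 3))
        np.add.at(conf, (s, dec), 1)
        _, perm = linear_sum_assignment(-conf)
        aligned = m.transition_matrix[np.ix_(perm, perm)]
        assert np.abs(aligned - A).max() < 0.05

    def test_determinism(self, rng):
        X, _, _ = _three_state_data(rng)
        cfg = HMMConfig(n_restarts=2, em_max_iter=15, seed=5)
        a = fit_hmm(X, 3, cfg)
        b = fit_hmm(X, 3, cfg)
        assert np.array_equal(a.state_means, b.state_means)
        assert a.log_likelihood == b.log_likelihood

    def test_em_monotone(self, rng):
        X, _, _ = _three_state_data(rng, T=1500)
        start = np.full(3, 1 / 3)
        trans = np.full((3, 3), 1 / 3)
        means = X[rng.choice(len(X), 3, replace=False)]
        covs = np.stack([np.cov(X.T) + 0.1 * np.eye(X.shape[1])] * 3)
        lls = []
        for _ in range(25):
            ll, start, trans, means, covs = em_step(X, start, trans, means, covs, 1e-6)
            lls.append(ll)
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))

    def test_covariance_floor_enforced(self, rng):
        X, _, _ = _three_state_data(rng, T=1200)
        cfg = HMMConfig(n_restarts=1, em_max_iter=20, variance_floor_frac=1e-2)
        m = fit_hmm(X, 3, cfg)
        floor = 1e-2 * X.var(axis=0).max()
        diags = np.stack([np.diag(c) for c in m.state_covariances])
        assert (diags >= floor - 1e-12).all()

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError, match="10K"):
            fit_hmm(rng.standard_normal((25, 2)), 3, HMMConfig())


class TestInformationCriteria:
    def test_parameter_count(self):
        # K=1, d=1: one mean + one variance = 2 free parameters
        assert n_parameters(1, 1) == 2
        assert n_parameters(3, 4) == 2 + 6 + 12 + 30

    def test_k1_d1_closed_form(self, rng):
        x = rng.standard_normal(400)[:, None] * 1.3 + 0.2
        cfg = HMMConfig(n_restarts=1, em_max_iter=30, variance_floor_frac=1e-12)
        m = fit_hmm(x, 1, cfg)
        aic, bic = information_criteria(m, x)
        # closed-form Gaussian log-likelihood at the ML estimates
        mu, var = x.mean(), x.var()
        lnL = -0.5 * len(x) * (np.log(2 * np.pi * var) + 1.0)
        assert aic == pytest.approx(4 - 2 * lnL, rel=1e-6)
        assert bic == pytest.approx(2 * np.log(len(x)) - 2 * lnL, rel=1e-6)

    def test_aic_difference_identity(self, rng):
        X, _, _ = _three_state_data(rng, T=1500)
        cfg = HMMConfig(n_restarts=1, em_max_iter=15, seed=0)
        m2, m3 = fit_hmm(X, 2, cfg), fit_hmm(X, 3, cfg)
        a2, _ = information_criteria(m2, X, m2.log_likelihood)
        a3, _ = information_criteria(m3, X, m3.log_likelihood)
        dp = n_parameters(3, X.shape[1]) - n_parameters(2, X.shape[1])
        dll = m3.log_likelihood - m2.log_likelihood
        assert a3 - a2 == pytest.approx(2 * dp - 2 * dll, rel=1e-10)

    def test_bic_exceeds_aic_for_long_series(self, rng):
        X, _, _ = _three_state_data(rng, T=1500)
        m = fit_hmm(X, 2, HMMConfig(n_restarts=1, em_max_iter=10))
        aic, bic = information_criteria(m, X)
        assert bic > aic  # ln(1500) > 2


class TestSelectNStates:
    def test_single_subject_argmin(self, rng):
        X, _, _ = _three_state_data(rng, T=4000, sep=4.0)
        cfg = HMMConfig(
            K_range=(2, 5), n_restarts=1, em_max_iter=25, seed=0,
            log_transform=False, standardize=True,
        )
        res = select_n_states([X], cfg)
        assert res.K_star == 3

    def test_tie_breaks_toward_smaller_k(self):
        # degenerate white data: criteria increase with K, argmin at floor
        rng = np.random.default_rng(0)
        X = rng.standard_normal((2000, 3))
        cfg = HMMConfig(
            K_range=(1, 3), n_restarts=1, em_max_iter=10,
            log_transform=False,
        )
        res = select_n_states([X], cfg)
        assert res.K_star == 1


class TestDecode:
    def test_k1_all_zero(self, rng):
        X = rng.standard_normal((100, 2))
        m = fit_hmm(X, 1, HMMConfig(n_restarts=1, em_max_iter=5))
        assert (decode(m, X, 1.0).labels == 0).all()

    def test_dominant_likelihood(self):
        m = GaussianHMM(
            initial_probs=np.array([0.5, 0.5]),
            transition_matrix=np.array([[0.9, 0.1], [0.1, 0.9]]),
            state_means=np.array([[0.0], [10.0]]),
            state_covariances=np.array([[[0.01]], [[0.01]]]),
            log_likelihood=0.0,
        )
        X = np.full((50, 1), 10.0)
        assert (decode(m, X, 1.0).labels == 1).all()

    def test_matches_exhaustive_path_enumeration(self, rng):
        K, T, d = 3, 8, 2
        m = GaussianHMM(
            initial_probs=np.array([0.5, 0.3, 0.2]),
            transition_matrix=np.array(
                [[0.6, 0.3, 0.1], [0.2, 0.5, 0.3], [0.3, 0.3, 0.4]]
            ),
            state_means=rng.standard_normal((K, d)),
            state_covariances=np.stack([np.eye(d)] * K),
            log_likelihood=0.0,
        )
        X = rng.standard_normal((T, d))
        logb = gaussian_log_likelihood(X, m.state_means, m.state_covariances)
        best_lp, best_path = -np.inf, None
        for path in itertools.product(range(K), repeat=T):
            lp = np.log(m.initial_probs[path[0]]) + logb[0, path[0]]
            for t in range(1, T):
                lp += np.log(m.transition_matrix[path[t - 1], path[t]])
                lp += logb[t, path[t]]
            if lp > best_lp:
                best_lp, best_path = lp, path
        labels, score = viterbi_path(logb, m.initial_probs, m.transition_matrix)
        assert tuple(labels) == best_path
        assert score == pytest.approx(best_lp)

    def test_decoded_histogram_equals_downstream_occupancy(self, rng):
        from fcstates.temporal import StateSequence, fractional_occupancy

        X, _, _ = _three_state_data(rng)
        m = fit_hmm(X, 3, HMMConfig(n_restarts=1, em_max_iter=20))
        seq = decode(m, X, 250.0)
        fo = fractional_occupancy(seq, 3)
        hist = np.bincount(seq.labels, minlength=3) / len(seq.labels)
        np.testing.assert_array_equal(fo, hist)


def test_model_json_roundtrip(tmp_path, rng):
    X, _, _ = _three_state_data(rng, T=1200)
    m = fit_hmm(X, 2, HMMConfig(n_restarts=1, em_max_iter=10))
    p = tmp_path / "model.json"
    m.to_json(p)
    back = GaussianHMM.from_json(p)
    np.testing.assert_allclose(back.state_means, m.state_means)
    np.testing.assert_allclose(back.transition_matrix, m.transition_matrix)
    assert back.log_likelihood == m.log_likelihood
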