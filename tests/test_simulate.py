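"""Synthetic cohort generator: state dynamics, envelope maps, determinism."""

import numpy as np
import pytest

from fcstates.atlas import default_atlas
from fcstates.simulate import (
    CohortSpec,
    GroundTruthModel,
    default_ground_truth,
    folded_corr,
    generate_cohort,
    generate_recording,
    lognormal_corr,
    read_recording,
    sample_state_sequence,
    target_to_latent,
    write_recording,
)


def _tiny_model(K=2, n=4, A=None):
    A = np.asarray(A if A is not None else [[0.9, 0.1], [0.1, 0.9]], float)
    return GroundTruthModel(
        initial_probs=np.full(K, 1 / K),
        transition_matrix=A,
        state_env_corr=np.stack([np.eye(n)] * K),
        state_gains=np.ones((K, n)),
    )


class TestStateSequence:
    def test_absorbing_states_constant(self):
        model = _tiny_model(A=np.eye(2))
        seq = sample_state_sequence(model, 500, seed=3)
        assert (seq == seq[0]).all()

    def test_same_seed_identical(self):
        model = _tiny_model()
        a = sample_state_sequence(model, 1000, seed=11)
        b = sample_state_sequence(model, 1000, seed=11)
        assert np.array_equal(a, b)

    def test_empirical_transition_frequencies(self):
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        seq = sample_state_sequence(_tiny_model(A=A), 100_000, seed=0)
        for i in range(2):
            mask = seq[:-1] == i
            n_i = mask.sum()
            emp = (seq[1:][mask] == 0).mean()
            se = np.sqrt(A[i, 0] * (1 - A[i, 0]) / n_i)
            assert abs(emp - A[i, 0]) < 3 * se

    def test_occupancy_matches_stationary_distribution(self):
        A = np.array([[0.95, 0.05], [0.10, 0.90]])
        seq = sample_state_sequence(_tiny_model(A=A), 100_000, seed=1)
        evals, evecs = np.linalg.eig(A.T)
        pi = np.real(evecs[:, np.argmax(np.real(evals))])
        pi = pi / pi.sum()
        fo = np.bincount(seq, minlength=2) / seq.size
        # dwell-time correlated samples: allow 3 SE with an effective-n
        # correction for mean dwell ~ 1/(1-a_ii)
        se = np.sqrt(pi[0] * (1 - pi[0]) / (seq.size * 0.05))
        assert abs(fo[0] - pi[0]) < 3 * se

    def test_non_stochastic_rows_rejected(self):
        with pytest.raises(ValueError, match="stochastic"):
            GroundTruthModel(
                initial_probs=np.array([0.5, 0.5]),
                transition_matrix=np.array([[0.9, 0.2], [0.1, 0.9]]),
                state_env_corr=np.stack([np.eye(3)] * 2),
                state_gains=np.ones((2, 3)),
            )


class TestEnvelopeMaps:
    def test_folded_map_matches_monte_carlo(self, rng):
        for rho in (0.3, 0.7):
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=200_000)
            emp = np.corrcoef(np.abs(z).T)[0, 1]
            assert folded_corr(rho) == pytest.approx(emp, abs=0.01)

    def test_lognormal_map_matches_monte_carlo(self, rng):
        for rho in (0.3, 0.7):
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=200_000)
            emp = np.corrcoef(np.exp(0.5 * z).T)[0, 1]
            assert lognormal_corr(rho, 0.5) == pytest.approx(emp, abs=0.01)

    def test_inversion_roundtrip(self):
        c = np.array([0.02, 0.05, 0.2, 0.5])
        assert lognormal_corr(target_to_latent(c, "lognormal")) == pytest.approx(c)
        assert folded_corr(target_to_latent(c, "folded")) == pytest.approx(
            c, abs=1e-4
        )

    def test_folded_rejects_negative_targets(self):
        with pytest.raises(ValueError, match="negatively"):
            target_to_latent(np.array([-0.1]), "folded")


class TestGenerateRecording:
    def test_single_state_identity_correlation_independent(self, atlas):
        model = GroundTruthModel(
            initial_probs=np.array([1.0]),
            transition_matrix=np.array([[1.0]]),
            state_env_corr=np.eye(atlas.n_parcels)[None],
            state_gains=np.ones((1, atlas.n_parcels)),
        )
        rec = generate_recording(atlas, model, 60.0, 250.0, seed=0)
        c = np.corrcoef(rec.parcel_series)
        off = c[~np.eye(atlas.n_parcels, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_state_restricted_windows_hit_target_correlation(self, atlas):
        model = default_ground_truth(atlas, K_true=2)
        rec = generate_recording(atlas, model, 240.0, 250.0, seed=4)
        for k in range(2):
            mask = rec.true_states == k
            seg = rec.parcel_series[:, mask]
            emp = np.corrcoef(seg)
            tgt = model.state_env_corr[k]
            offd = ~np.eye(atlas.n_parcels, dtype=bool)
            err = np.abs(emp - tgt)[offd]
            assert err.mean() < 0.05

    def test_oscillatory_constant_envelope_recovered(self, atlas):
        from fcstates.envelope import hilbert_envelope

        model = _tiny_model(n=atlas.n_parcels)
        model.state_gains[:] = 2.0
        # constant envelope: zero sigma makes exp(sigma z) = 1
        model = GroundTruthModel(
            initial_probs=model.initial_probs,
            transition_matrix=model.transition_matrix,
            state_env_corr=model.state_env_corr,
            state_gains=model.state_gains,
            sigma=1e-12,
        )
        rec = generate_recording(atlas, model, 10.0, 250.0, seed=0, mode="oscillatory")
        env = hilbert_envelope(rec.parcel_series, 250.0)
        interior = env.values[:, env.interior]
        assert np.abs(interior - 2.0).max() / 2.0 < 0.02

    def test_envelope_mode_nonnegative(self, atlas, ground_truth):
        rec = generate_recording(atlas, ground_truth, 2.0, 250.0, seed=9)
        assert (rec.parcel_series >= 0).all()

    def test_doubling_duration_shrinks_monte_carlo_error(self, atlas):
        # SE of the state-restricted correlation estimate ~ 1/sqrt(T)
        model = default_ground_truth(atlas, K_true=2)
        offd = ~np.eye(atlas.n_parcels, dtype=bool)

        def rms_err(duration, seeds):
            errs = []
            for s in seeds:
                rec = generate_recording(atlas, model, duration, 250.0, seed=s)
                mask = rec.true_states == 0
                emp = np.corrcoef(rec.parcel_series[:, mask])
                errs.append(
                    np.sqrt(np.mean((emp - model.state_env_corr[0])[offd] ** 2))
                )
            return np.mean(errs)

        short = rms_err(40.0, range(4))
        long = rms_err(160.0, range(4))
        ratio = short / long
        assert 2.0 / 1.5 < ratio < 2.0 * 1.5


class TestGenerateCohort:
    def test_bookkeeping(self, atlas, ground_truth):
        spec = CohortSpec(
            atlas=atlas,
            model=ground_truth,
            groups={"A": (3, 1.0), "B": (3, 1.0), "C": (3, 1.0)},
            duration_s=1.0,
            master_seed=0,
        )
        recs = generate_cohort(spec)
        assert len(recs) == 9
        assert sorted({r.group for r in recs}) == ["A", "B", "C"]
        assert len({r.subject_id for r in recs}) == 9

    def test_master_seed_reproducible(self, atlas, ground_truth):
        spec = CohortSpec(
            atlas=atlas, model=ground_truth,
            groups={"A": (2, 1.0), "B": (2, 1.2)}, duration_s=1.0, master_seed=5,
        )
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.parcel_series, rb.parcel_series)

    def test_group_effect_scales_envelope_correlation(self, atlas, ground_truth):
        strong = ground_truth.with_group_effect(1.3)
        base = generate_recording(atlas, ground_truth, 60.0, 250.0, seed=2)
        boosted = generate_recording(atlas, strong, 60.0, 250.0, seed=2)
        offd = ~np.eye(atlas.n_parcels, dtype=bool)
        assert (
            np.corrcoef(boosted.parcel_series)[offd].mean()
            > np.corrcoef(base.parcel_series)[offd].mean()
        )


def test_null_cohort_exact_p_uniform_under_repetition(atlas, ground_truth):
    # identical group effects: the exact Mann-Whitney p of a downstream
    # statistic should be (discretely) uniform across repeated cohorts
    from scipy.stats import kstest

    from fcstates.stats import exact_p, mannwhitney_u

    offd = ~np.eye(atlas.n_parcels, dtype=bool)
    pvals = []
    for rep in range(100):
        spec = CohortSpec(
            atlas=atlas, model=ground_truth,
            groups={"A": (8, 1.0), "B": (8, 1.0)},
            duration_s=2.0, master_seed=40_000 + rep,
        )
        stat = {"A": [], "B": []}
        for rec in generate_cohort(spec):
            stat[rec.group].append(np.corrcoef(rec.parcel_series)[offd].mean())
        u, _ = mannwhitney_u(stat["A"], stat["B"])
        pvals.append(exact_p(u, 8, 8))
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_recording_roundtrip(tmp_path, atlas, ground_truth):
    rec = generate_recording(
        atlas, ground_truth, 1.0, 250.0, seed=1, subject_id="s01", group="OAC"
    )
    write_recording(rec, tmp_path)
    back = read_recording(tmp_path, "s01")
    assert np.allclose(back.parcel_series, rec.parcel_series)
    assert np.array_equal(back.true_states, rec.true_states)
    assert back.group == "OAC" and back.fs == 250.0
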