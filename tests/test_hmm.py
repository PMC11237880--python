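"""Exact-inference oracles, VB behaviour and decoding contracts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from restdyn import (
    HMMSpec, fit_vb, forward_backward, free_energy, permute_states,
    standardize_inputs, threshold_activation, viterbi, decode_dataset,
    load_model, save_model,
)
from restdyn.data import Dataset, RunSeries
from restdyn.hmm import _expected_log_lik
from restdyn._kernels import viterbi_path

from _oracles import enumerate_posteriors, enumerate_viterbi
from conftest import make_separated_dataset


def random_instance(rng, k_max=3, t_max=8):
    K = rng.integers(1, k_max + 1)
    T = rng.integers(1, t_max + 1)
    log_b = rng.normal(scale=2.0, size=(T, K))
    A = rng.dirichlet(np.ones(K), size=K)
    pi = rng.dirichlet(np.ones(K))
    return log_b, A, pi


class TestForwardBackward:
    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(100):
            log_b, A, pi = random_instance(rng)
            gamma, xi, log_z = forward_backward(log_b, A, pi)
            g_ref, xi_ref, log_z_ref = enumerate_posteriors(log_b, A, pi)
            worst = max(worst, np.abs(gamma - g_ref).max())
            if xi.size:
                worst = max(worst, np.abs(xi - xi_ref).max())
            worst = max(worst, abs(log_z - log_z_ref))
        assert worst < 1e-10

    def test_single_state_reduces_to_loglik_sum(self):
        log_b = np.array([[-1.0], [-2.5], [0.3]])
        gamma, _, log_z = forward_backward(log_b, np.ones((1, 1)), np.ones(1))
        assert np.allclose(gamma, 1.0)
        assert log_z == pytest.approx(log_b.sum())

    def test_full_symmetry_gives_uniform_gamma(self):
        K, T = 3, 5
        gamma, _, _ = forward_backward(
            np.zeros((T, K)), np.full((K, K), 1 / K), np.full(K, 1 / K))
        assert np.allclose(gamma, 1 / K)

    def test_posterior_normalization_and_marginal_consistency(self):
        rng = np.random.default_rng(7)
        log_b, A, pi = rng.normal(size=(6, 3)), rng.dirichlet(np.ones(3), 3), rng.dirichlet(np.ones(3))
        gamma, xi, _ = forward_backward(log_b, A, pi)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(xi.sum(axis=(1, 2)), 1.0, atol=1e-9)
        assert np.allclose(xi.sum(axis=2), gamma[:-1], atol=1e-9)

    def test_rejects_non_finite_input(self):
        with pytest.raises(ValueError, match="finite"):
            forward_backward(np.array([[np.nan, 0.0]]), np.eye(2), np.ones(2) / 2)


class TestViterbi:
    def test_matches_enumeration_score(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            log_b, A, pi = random_instance(rng, k_max=2)
            path, score = viterbi_path(log_b, np.log(A), np.log(pi))
            ref_path, ref_score = enumerate_viterbi(log_b, np.log(A), np.log(pi))
            assert score == pytest.approx(ref_score, abs=1e-10)
            assert np.array_equal(path, ref_path)

    def test_uniform_transitions_factorize_to_argmax(self):
        rng = np.random.default_rng(3)
        log_b = rng.normal(size=(20, 3))
        K = 3
        path, _ = viterbi_path(log_b, np.log(np.full((K, K), 1 / K)),
                               np.log(np.full(K, 1 / K)))
        assert np.array_equal(path, log_b.argmax(axis=1))

    def test_identity_transition_locks_initial_state(self):
        rng = np.random.default_rng(4)
        log_b = rng.normal(size=(10, 2))
        with np.errstate(divide="ignore"):
            log_a = np.log(np.eye(2))
        path, _ = viterbi_path(log_b, log_a, np.log(np.ones(2) / 2))
        assert np.all(path == path[0])

    def test_ties_break_toward_lower_state_index(self):
        K = 3
        path, _ = viterbi_path(np.zeros((4, K)), np.log(np.full((K, K), 1 / K)),
                               np.log(np.full(K, 1 / K)))
        assert np.all(path == 0)

    def test_empty_run_rejected(self, two_state_fit):
        run = two_state_fit["dataset"][0]
        empty = RunSeries(data=np.empty((0, run.n_channels)),
                          sampling_period=2.0, condition="EO", subject="x",
                          run_index=0, modality="fmri")
        with pytest.raises(ValueError, match="empty"):
            viterbi(two_state_fit["model"], empty)


class TestStandardize:
    def test_moments_and_idempotence(self):
        ds, _, _ = make_separated_dataset(seed=2, n_runs=3)
        std = standardize_inputs(ds)
        for run in std:
            assert np.abs(run.data.mean(axis=0)).max() < 1e-10
            assert np.abs(run.data.std(axis=0) - 1).max() < 1e-10
        again = standardize_inputs(std)
        for a, b in zip(std, again):
            assert np.allclose(a.data, b.data, atol=1e-12)

    def test_constant_channel_raises_with_names(self):
        run = RunSeries(data=np.column_stack([np.ones(10), np.arange(10.0)]),
                        sampling_period=1.0, condition="EO", subject="s07",
                        run_index=2, modality="fmri", channels=("flat", "ramp"))
        with pytest.raises(ValueError, match=r"flat.*\('s07', 2\)|\('s07', 2\).*flat"):
            standardize_inputs(Dataset([run]))

    def test_per_subject_pooling(self):
        ds, _, _ = make_separated_dataset(seed=3, n_runs=4)
        std = standardize_inputs(ds, per="subject")
        pooled = np.concatenate([r.data for r in std], axis=0)
        assert np.abs(pooled.mean(axis=0)).max() < 1e-10


class TestFitVB:
    def test_two_state_recovery(self, two_state_fit):
        model = two_state_fit["model"]
        chains = two_state_fit["chains"]
        # the two fitted states must be well separated on channel 1
        assert np.abs(np.diff(model.state_means[:, 1])) > 1.0
        paths = decode_dataset(model, two_state_fit["dataset"])
        concat_dec = np.concatenate([p.states for p in paths])
        concat_true = np.concatenate(chains)
        acc = max(np.mean(concat_dec == concat_true),
                  np.mean(1 - concat_dec == concat_true))
        assert acc > 0.98

    def test_free_energy_trace_monotone(self, two_state_fit):
        trace = two_state_fit["model"].free_energy_trace
        assert np.all(np.diff(trace) <= 1e-8 * np.abs(trace[:-1]))

    def test_gamma_rows_and_transition_rows_normalized(self, two_state_fit):
        model = two_state_fit["model"]
        for g in model.gamma:
            assert np.allclose(g.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(model.transition.sum(axis=1), 1.0, atol=1e-9)
        assert model.initial.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_state_recovers_standardized_moments(self):
        ds, _, _ = make_separated_dataset(n_states=1, sep=0.0, n_runs=4, seed=9)
        std = standardize_inputs(ds)
        model = fit_vb(std, HMMSpec(n_states=1, seed=0))
        assert np.abs(model.state_means).max() < 0.02
        assert np.abs(model.state_covs[0] - np.eye(2)).max() < 0.02

    def test_k_larger_than_samples_rejected(self):
        ds, _, _ = make_separated_dataset(n_runs=1, n_samples=5, seed=1)
        with pytest.raises(ValueError, match="exceeds"):
            fit_vb(ds, HMMSpec(n_states=10, seed=0))

    def test_run_order_invariance(self):
        ds, _, _ = make_separated_dataset(seed=21, n_runs=6, n_samples=150)
        std = standardize_inputs(ds)
        spec = HMMSpec(n_states=2, seed=3)
        a = fit_vb(std, spec)
        reversed_ds = Dataset(list(std.runs)[::-1])
        b = fit_vb(reversed_ds, spec)
        assert np.abs(a.state_means - b.state_means).max() < 1e-6
        assert np.abs(a.transition - b.transition).max() < 1e-6

    def test_label_permutation_equivariance(self, two_state_fit):
        model = two_state_fit["model"]
        flipped = permute_states(model, [1, 0])
        assert np.allclose(flipped.state_means[::-1], model.state_means)
        assert np.allclose(flipped.transition[::-1][:, ::-1], model.transition)
        for g0, g1 in zip(model.gamma, flipped.gamma):
            assert np.allclose(g0, g1[:, ::-1])
        run = two_state_fit["dataset"][0]
        p0 = viterbi(model, run).states
        p1 = viterbi(flipped, run).states
        assert np.array_equal(p0, 1 - p1)


class TestFreeEnergy:
    def test_matches_final_trace_entry(self, two_state_fit):
        model, ds = two_state_fit["model"], two_state_fit["dataset"]
        f = free_energy(model, ds)
        assert f == pytest.approx(model.free_energy_final, rel=1e-6)

    def test_data_term_additive_over_duplicated_runs(self, two_state_fit):
        model, ds = two_state_fit["model"], two_state_fit["dataset"]
        _, data_term, _ = free_energy(model, ds, return_parts=True)
        doubled = Dataset(list(ds.runs) + [
            RunSeries(data=r.data, sampling_period=r.sampling_period,
                      condition=r.condition, subject=r.subject + "_copy",
                      run_index=r.run_index, modality=r.modality,
                      channels=r.channels)
            for r in ds.runs
        ])
        _, data_term2, _ = free_energy(model, doubled, return_parts=True)
        assert data_term2 == pytest.approx(2 * data_term, rel=1e-6)

    def test_richer_model_fits_structured_data_better(self):
        ds, _, _ = make_separated_dataset(n_states=4, n_channels=4, sep=4.0,
                                          n_runs=8, n_samples=250, seed=33)
        std = standardize_inputs(ds)
        f2 = fit_vb(std, HMMSpec(n_states=2, seed=0)).free_energy_final
        f4 = fit_vb(std, HMMSpec(n_states=4, seed=0)).free_energy_final
        assert f4 < f2

    def test_channel_mismatch_rejected(self, two_state_fit):
        bad, _, _ = make_separated_dataset(n_channels=3, n_runs=2, seed=0)
        with pytest.raises(ValueError, match="channel mismatch"):
            free_energy(two_state_fit["model"], bad)


class TestEMCrossCheck:
    def test_vb_means_match_ml_em_reference(self, two_state_fit):
        """Independent EM fit (hmmlearn) agrees with the VB posterior means."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        ds = two_state_fit["dataset"]
        X = ds.concatenated()
        em = hmmlearn.GaussianHMM(n_components=2, covariance_type="full",
                                  n_iter=100, random_state=0)
        em.fit(X, lengths=ds.run_lengths().tolist())
        vb_means = two_state_fit["model"].state_means
        em_means = em.means_
        # match by first-channel sign, then correlate concatenated means
        vb = vb_means[np.argsort(vb_means[:, 0])].ravel()
        ref = em_means[np.argsort(em_means[:, 0])].ravel()
        r = np.corrcoef(vb, ref)[0, 1]
        assert r > 0.99


class TestThresholdActivation:
    @pytest.mark.parametrize("row,expected", [
        ((0.9, 0.1), (True, False)),
        ((0.5, 0.5), (False, False)),
        ((0.79, 0.21), (False, False)),
    ])
    def test_default_threshold_examples(self, row, expected):
        assert tuple(threshold_activation(np.array([row]))[0]) == expected

    def test_majority_threshold_matches_argmax(self):
        rng = np.random.default_rng(0)
        g = rng.dirichlet(np.ones(2), size=50)
        act = threshold_activation(g, threshold=0.5)
        decisive = g.max(axis=1) > 0.5
        assert np.array_equal(act[decisive].argmax(axis=1),
                              g[decisive].argmax(axis=1))

    @given(st.floats(min_value=0.5, max_value=0.99))
    def test_at_most_one_active_per_row(self, thr):
        rng = np.random.default_rng(1)
        g = rng.dirichlet(np.ones(4), size=30)
        assert threshold_activation(g, thr).sum(axis=1).max() <= 1

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_activation(np.ones((1, 2)), threshold=1.0)


def test_model_json_roundtrip(two_state_fit, tmp_path):
    model = two_state_fit["model"]
    path = tmp_path / "model.json"
    save_model(model, path)
    loaded = load_model(path)
    assert np.allclose(loaded.state_means, model.state_means)
    assert np.allclose(loaded.transition, model.transition)
    run = two_state_fit["dataset"][0]
    assert np.array_equal(viterbi(loaded, run).states,
                          viterbi(model, run).states)


def test_expected_loglik_finite_and_shaped(two_state_fit):
    model = two_state_fit["model"]
    X = two_state_fit["dataset"][0].data
    ll = _expected_log_lik(X, model._post)
    assert ll.shape == (X.shape[0], 2)
    assert np.all(np.isfinite(ll))
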