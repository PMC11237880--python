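"""Generator contracts: chains, emissions, shared grids, reproducibility."""

import numpy as np
import pytest
from scipy.signal import hilbert

from restdyn import (
    build_regressor, double_gamma_hrf, mixture_transition, shifted_occupancy,
    simulate_chain, simulate_chain_mixture, simulate_eeg_run,
    simulate_fmri_run, simulate_voxel_bold, subseed,
)
from restdyn.features import bandpass_alpha
from restdyn.synth import (
    GroundTruth, StudyManifest, default_ground_truth, make_study,
    null_profile, paperlike_profile,
)


class TestSimulateChain:
    def test_absorbing_identity_chain(self):
        path = simulate_chain(np.eye(2), np.array([1.0, 0.0]), 5, seed=0)
        assert np.array_equal(path, np.zeros(5))

    def test_same_seed_reproduces_exactly(self):
        A = mixture_transition(np.array([0.3, 0.7]), 0.5)
        a = simulate_chain(A, np.array([0.5, 0.5]), 1000, seed=42)
        b = simulate_chain(A, np.array([0.5, 0.5]), 1000, seed=42)
        assert np.array_equal(a, b)

    def test_symmetric_chain_occupancy_near_half(self):
        A = np.array([[0.5, 0.5], [0.5, 0.5]])
        path = simulate_chain(A, np.array([0.5, 0.5]), 100_000, seed=1)
        assert np.mean(path == 0) == pytest.approx(0.5, abs=0.01)

    @pytest.mark.parametrize("bad_call", [
        lambda: simulate_chain(np.array([[0.5, 0.4], [0.5, 0.5]]),
                               np.array([0.5, 0.5]), 10, seed=0),
        lambda: simulate_chain(np.eye(2), np.array([0.5, 0.5]), 0, seed=0),
    ])
    def test_invalid_parameters_rejected(self, bad_call):
        with pytest.raises(ValueError):
            bad_call()

    def test_mixture_chain_ramp_inflates_early_occupancy(self):
        pi = np.full(3, 1 / 3)
        reps = [
            simulate_chain_mixture(pi, 0.95, 4000, seed=subseed(5, r),
                                   ramp=(2, 0.6, 2.0), rate=100.0)
            for r in range(40)
        ]
        early = np.mean([np.mean(c[:200] == 2) for c in reps])
        late = np.mean([np.mean(c[-200:] == 2) for c in reps])
        assert early > late + 0.1


@pytest.fixture(scope="module")
def truth():
    return default_ground_truth(paperlike_profile(), StudyManifest(), seed=0)


class TestSimulateFmri:
    def test_noiseless_limit_reproduces_state_means(self, truth):
        quiet = GroundTruth(
            n_states=truth.n_states,
            transition_by_condition=truth.transition_by_condition,
            initial_dist=truth.initial_dist,
            state_means=truth.state_means,
            state_covs=truth.state_covs * 1e-12,
            state_alpha_amplitudes=truth.state_alpha_amplitudes,
        )
        chain = np.array([0, 1, 2, 3, 0])
        run = simulate_fmri_run(chain, quiet, seed=0)
        assert np.abs(run.data - truth.state_means[chain]).max() < 1e-4

    def test_noiseless_nearest_mean_decode_recovers_chain(self, truth):
        quiet = GroundTruth(
            n_states=truth.n_states,
            transition_by_condition=truth.transition_by_condition,
            initial_dist=truth.initial_dist,
            state_means=truth.state_means,
            state_covs=truth.state_covs * 1e-12,
            state_alpha_amplitudes=truth.state_alpha_amplitudes,
        )
        chain = simulate_chain(truth.transition_by_condition["EO"],
                               truth.initial_dist, 500, seed=3)
        run = simulate_fmri_run(chain, quiet, seed=1)
        d = np.linalg.norm(run.data[:, None, :] - truth.state_means[None], axis=2)
        assert np.array_equal(d.argmin(axis=1), chain)

    def test_empirical_state_means_within_three_se(self, truth):
        rng = np.random.default_rng(0)
        chain = rng.integers(0, truth.n_states, size=10_000)
        run = simulate_fmri_run(chain, truth, seed=7)
        for k in range(truth.n_states):
            sel = run.data[chain == k]
            se = np.sqrt(np.diag(truth.state_covs[k]) / sel.shape[0])
            assert np.all(np.abs(sel.mean(axis=0) - truth.state_means[k]) < 3.5 * se)

    def test_run_duration_arithmetic(self, truth):
        run = simulate_fmri_run(np.zeros(300, int), truth, seed=0,
                                sampling_period=2.0)
        assert run.duration == pytest.approx(600.0)

    def test_non_spd_covariance_rejected(self, truth):
        with pytest.raises(ValueError):
            GroundTruth(
                n_states=truth.n_states,
                transition_by_condition=truth.transition_by_condition,
                initial_dist=truth.initial_dist,
                state_means=truth.state_means,
                state_covs=np.zeros_like(truth.state_covs),
                state_alpha_amplitudes=truth.state_alpha_amplitudes,
            )


class TestSimulateEeg:
    def test_pure_tone_envelope_matches_amplitude(self):
        amp = 1.7
        chain = np.zeros(4000, int)
        run = simulate_eeg_run(chain, np.full((1, 6), amp), carrier_freq=10.0,
                               raw_rate=200.0, noise_sd=0.0, seed=0)
        env = np.abs(hilbert(bandpass_alpha(run).data, axis=0))
        interior = env[400:-400]
        assert np.abs(interior / amp - 1.0).max() < 0.02

    def test_zero_amplitude_noise_has_no_state_effect(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        chain = rng.integers(0, 2, size=2000)
        run = simulate_eeg_run(chain, np.zeros((2, 6)), carrier_freq=10.0,
                               raw_rate=200.0, noise_sd=1.0, seed=1)
        env = np.abs(hilbert(bandpass_alpha(run).data[:, 0]))
        interior = slice(200, -200)
        t, p = stats.ttest_ind(env[interior][chain[interior] == 0],
                               env[interior][chain[interior] == 1])
        assert p > 0.01

    def test_sample_count_follows_rate(self):
        run = simulate_eeg_run(np.zeros(200 * 30, int), np.ones((1, 6)),
                               carrier_freq=10.0, raw_rate=200.0,
                               noise_sd=0.1, seed=0)
        assert run.n_samples == 6000 and run.duration == pytest.approx(30.0)

    def test_carrier_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_eeg_run(np.zeros(10, int), np.ones((1, 6)),
                             carrier_freq=100.0, raw_rate=200.0,
                             noise_sd=0.0, seed=0)


class TestSimulateVoxelBold:
    def test_zero_betas_zero_noise_gives_zeros(self):
        hrf = double_gamma_hrf(step=2.0)
        out = simulate_voxel_bold(np.zeros(100, int), np.zeros((5, 2)),
                                  hrf.values, (0.0, 0.0), seed=0)
        assert np.all(out == 0)

    def test_single_state_reduces_to_regressor(self):
        hrf = double_gamma_hrf(step=2.0)
        course = np.ones(100)
        out = simulate_voxel_bold(np.zeros(100, int), np.array([[1.0, 0.0]]),
                                  hrf.values, (0.0, 0.0), seed=0)
        reg = build_regressor(course, rate=0.5, tr=2.0, hrf=hrf, n_out=100)
        assert np.allclose(out[0], reg, atol=1e-12)

    def test_kernel_longer_than_run_rejected(self):
        hrf = double_gamma_hrf(step=0.1)
        with pytest.raises(ValueError, match="longer"):
            simulate_voxel_bold(np.zeros(10, int), np.ones((1, 1)),
                                hrf.values, (0.0, 0.0), seed=0)

    def test_ar1_bound_enforced(self):
        hrf = double_gamma_hrf(step=2.0)
        with pytest.raises(ValueError, match="AR"):
            simulate_voxel_bold(np.zeros(100, int), np.ones((1, 1)),
                                hrf.values, (1.0, 1.0), seed=0)


class TestMakeStudy:
    def test_default_manifest_matches_study_design(self):
        m = StudyManifest()
        assert len(m.subjects) == 21
        assert m.runs_per_subject == ("EO", "EC", "EO", "EC")
        assert m.fmri_samples_per_run == 300
        assert m.fmri_sampling_period == 2.0
        assert len(m.fmri_channels) == 13
        assert m.eeg_channels == ("Oz", "O1", "O2", "POz", "PO3", "PO4")

    def test_shapes_and_shared_chain(self, tiny_study):
        study = tiny_study
        assert len(study.fmri) == 4 * 4
        for run in study.fmri:
            assert run.data.shape == (100, 13)
        for run in study.eeg:
            assert run.n_samples == int(100 * 2.0 * 200.0)
        # fMRI chain is an exact index-decimation of the EEG-grid chain
        key = ("s01", 1)
        raw = study.truth.chain_paths[key]
        tr_chain = study.truth.chain_at(key, 2.0)
        assert np.array_equal(tr_chain, raw[::400])

    def test_reproducibility(self):
        m = StudyManifest(subjects=("a", "b"), fmri_samples_per_run=50)
        s1 = make_study(m, paperlike_profile(), seed=9, include_voxels=False)
        s2 = make_study(m, paperlike_profile(), seed=9, include_voxels=False)
        for r1, r2 in zip(s1.fmri, s2.fmri):
            assert np.array_equal(r1.data, r2.data)
        for r1, r2 in zip(s1.eeg, s2.eeg):
            assert np.array_equal(r1.data, r2.data)

    def test_ec_stay_probability_raise_shifts_true_occupancy(self):
        """Raising one state's EC self-transition raises its EC occupancy
        for every subject (computed from the stored true chains)."""
        K = 2
        eo_stay, ec_stay = 0.90, 0.97
        A_eo = np.array([[eo_stay, 1 - eo_stay], [1 - eo_stay, eo_stay]])
        A_ec = np.array([[ec_stay, 1 - ec_stay], [1 - eo_stay, eo_stay]])
        init = np.array([0.5, 0.5])
        diffs = []
        for s in range(10):
            fo = {}
            for cond, A in (("EO", A_eo), ("EC", A_ec)):
                chains = [simulate_chain(A, init, 2000, seed=subseed(77, s, i, 0 if cond == "EO" else 1))
                          for i in range(2)]
                fo[cond] = np.mean([np.mean(c == 0) for c in chains])
            diffs.append(fo["EC"] - fo["EO"])
        assert all(d > 0 for d in diffs)

    def test_null_profile_has_no_condition_effect(self):
        p = null_profile()
        assert np.array_equal(p.stationary_eo, p.stationary_ec)
        assert p.ec_amp_scale == 1.0 and p.ramp_boost is None


def test_shifted_occupancy_moves_exactly_one_state():
    base = np.full(4, 0.25)
    out = shifted_occupancy(base, 1, 0.1)
    assert out[1] == pytest.approx(0.35)
    assert out.sum() == pytest.approx(1.0)
    rest = np.delete(out, 1)
    assert np.allclose(rest, rest[0])


def test_save_study_roundtrip(tmp_path):
    from restdyn.data import load_dataset
    from restdyn.synth import save_study

    study = make_study(
        StudyManifest(subjects=("a", "b"), fmri_samples_per_run=30),
        paperlike_profile(), seed=2, include_eeg=False, include_voxels=False,
    )
    out = save_study(study, tmp_path / "study")
    loaded = load_dataset(out / "fmri_manifest.json")
    assert len(loaded) == len(study.fmri)
    orig = study.fmri[0]
    match = [r for r in loaded if r.key() == orig.key()][0]
    assert np.allclose(match.data, orig.data, atol=1e-8)
    assert match.condition == orig.condition
    assert (out / "ground_truth.json").exists()
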