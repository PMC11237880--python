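"""Alpha-band feature extraction: filter, envelope, epochs, Welch power."""

import numpy as np
import pytest

from restdyn import (
    alpha_condition_test, alpha_power_course, bandpass_alpha,
    epoch_and_downsample, hilbert_envelope, normalize_regressor,
    simulate_eeg_run, welch_alpha_power,
)
from restdyn.data import RunSeries
from restdyn.features import AlphaPowerCourse, POSTERIOR_CHANNELS, envelope_edge_mask

RATE = 200.0


def tone_run(freq, amp=1.0, seconds=60.0, rate=RATE, **kw):
    t = np.arange(int(seconds * rate)) / rate
    x = amp * np.sin(2 * np.pi * freq * t)
    defaults = dict(condition="EO", subject="s01", run_index=0)
    defaults.update(kw)
    return RunSeries(data=np.tile(x[:, None], (1, 6)), sampling_period=1 / rate,
                     modality="eeg", channels=POSTERIOR_CHANNELS, **defaults)


class TestBandpass:
    def test_passband_center_preserved(self):
        out = bandpass_alpha(tone_run(10.0))
        amp = np.abs(out.data[2000:-2000, 0]).max()
        assert amp == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("freq,limit", [(2.0, 0.01), (20.0, 0.05)])
    def test_stopband_attenuation(self, freq, limit):
        out = bandpass_alpha(tone_run(freq))
        assert np.abs(out.data[2000:-2000, 0]).max() < limit

    def test_dc_offset_removed(self):
        run = tone_run(10.0)
        shifted = run.with_data(run.data + 5.0)
        out = bandpass_alpha(shifted)
        # interior samples: the zero-phase filter has edge transients
        assert abs(out.data[2000:-2000].mean()) < 1e-6 * 5.0

    def test_nyquist_violation_rejected(self):
        run = tone_run(3.0, rate=20.0)
        with pytest.raises(ValueError, match="Hz"):
            bandpass_alpha(run)


class TestEnvelope:
    def test_tone_envelope_equals_amplitude(self):
        env = hilbert_envelope(tone_run(10.0, amp=1.3))
        interior = env.data[200:-200, 0]
        assert np.abs(interior / 1.3 - 1).max() < 0.02

    def test_zero_input_zero_envelope(self):
        run = tone_run(10.0, amp=0.0)
        assert np.all(hilbert_envelope(run).data == 0)

    def test_amplitude_step_detected_quickly(self):
        rate = RATE
        t = np.arange(int(20 * rate)) / rate
        amp = np.where(t < 10.0, 1.0, 2.0)
        x = amp * np.sin(2 * np.pi * 10.0 * t)
        run = tone_run(10.0).with_data(np.tile(x[:, None], (1, 6)))
        env = hilbert_envelope(run).data[:, 0]
        crossing = np.flatnonzero(env > 1.5)[0] / rate
        assert abs(crossing - 10.0) < 0.25

    def test_edge_mask_flags_half_second(self):
        mask = envelope_edge_mask(1000, RATE)
        assert mask[:100].all() and mask[-100:].all()
        assert not mask[100:-100].any()


class TestEpoching:
    def test_epoch_sample_count(self):
        epochs, _ = epoch_and_downsample(tone_run(10.0, seconds=60.0),
                                         tr=2.0, target_rate=40.0)
        assert epochs.shape[1] == 80     # 2 s x 40 Hz

    def test_ten_minute_run_gives_300_epochs(self):
        epochs, _ = epoch_and_downsample(tone_run(10.0, seconds=600.0),
                                         tr=2.0, target_rate=40.0)
        assert epochs.shape[0] == 300

    def test_concatenated_epochs_reconstruct_series(self):
        epochs, ds = epoch_and_downsample(tone_run(10.0, seconds=10.0),
                                          tr=2.0, target_rate=40.0)
        flat = epochs.reshape(-1, epochs.shape[2])
        assert np.array_equal(flat, ds.data[: flat.shape[0]])

    def test_run_shorter_than_tr_rejected(self):
        with pytest.raises(ValueError, match="TR"):
            epoch_and_downsample(tone_run(10.0, seconds=1.0), tr=2.0)


class TestWelchPower:
    def _epochs(self, freq, amp=1.0, seconds=60.0):
        return epoch_and_downsample(tone_run(freq, amp=amp, seconds=seconds),
                                    tr=2.0, target_rate=40.0)[0]

    def test_unit_tone_band_power_half(self):
        p = welch_alpha_power(self._epochs(10.0), 40.0, POSTERIOR_CHANNELS)
        assert p.mean() == pytest.approx(0.5, rel=0.10)

    def test_zero_signal_zero_power(self):
        p = welch_alpha_power(self._epochs(10.0, amp=0.0), 40.0, POSTERIOR_CHANNELS)
        assert np.allclose(p, 0.0)

    def test_quadratic_amplitude_scaling(self):
        p1 = welch_alpha_power(self._epochs(10.0, amp=1.0), 40.0, POSTERIOR_CHANNELS)
        p2 = welch_alpha_power(self._epochs(10.0, amp=2.0), 40.0, POSTERIOR_CHANNELS)
        assert (p2.mean() / p1.mean()) == pytest.approx(4.0, rel=0.05)

    def test_missing_channel_named(self):
        epochs = self._epochs(10.0)
        with pytest.raises(ValueError, match="POz"):
            welch_alpha_power(epochs, 40.0, ("Oz", "O1", "O2", "PO3", "PO4", "Fz"))

    def test_envelope_power_agrees_with_welch(self):
        """Two independent band-power estimators (envelope^2/2 and Welch)
        agree for an in-band tone."""
        run = tone_run(10.0, amp=1.4, seconds=30.0)
        filtered = bandpass_alpha(run)
        epochs, ds = epoch_and_downsample(filtered, tr=2.0, target_rate=40.0)
        welch = welch_alpha_power(epochs, 40.0, POSTERIOR_CHANNELS)
        env = hilbert_envelope(ds).data[:, 0] ** 2 / 2
        n = epochs.shape[0]
        env_epoch = env[: n * 80].reshape(n, 80).mean(axis=1)
        ratio = env_epoch[2:-2] / welch[2:-2]
        assert np.abs(ratio.mean() - 1.0) < 0.10


class TestRegressorAndCondition:
    def _course(self, values, **kw):
        defaults = dict(tr=2.0, condition="EO", subject="s01", run_index=0,
                        channels=POSTERIOR_CHANNELS)
        defaults.update(kw)
        return AlphaPowerCourse(values=np.asarray(values, float), **defaults)

    def test_normalized_moments(self):
        rng = np.random.default_rng(0)
        c = normalize_regressor(self._course(rng.random(100)))
        assert abs(c.values.mean()) < 1e-10
        assert abs(c.values.std() - 1) < 1e-10
        assert c.normalized

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(1)
        x = rng.random(50)
        base = normalize_regressor(self._course(x)).values
        pos = normalize_regressor(self._course(3.0 * x + 7.0)).values
        neg = normalize_regressor(self._course(-2.0 * x)).values
        assert np.allclose(pos, base, atol=1e-10)
        assert np.allclose(neg, -base, atol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            normalize_regressor(self._course(np.ones(10)))

    def test_condition_test_closed_form(self):
        courses = []
        eo_vals, ec_vals = [5.0, 9.0], [3.0, 5.0]
        for s in range(2):
            courses.append(self._course([eo_vals[s]] * 4, subject=f"s{s}",
                                        condition="EO"))
            courses.append(self._course([ec_vals[s]] * 4, subject=f"s{s}",
                                        condition="EC", run_index=1))
        res = alpha_condition_test(courses)
        assert res.t == pytest.approx(3.0)

    def test_ec_amplitude_scaling_detected(self):
        """EC alpha amplitude x1.5 in the generator yields a significant
        EC > EO paired test (desk-scale replicates)."""
        amps = np.full((1, 6), 1.0)
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            courses = []
            for s in range(6):
                for ri, cond in enumerate(("EO", "EC", "EO", "EC")):
                    scale = 1.5 if cond == "EC" else 1.0
                    run = simulate_eeg_run(
                        np.zeros(int(30 * RATE), int), amps * scale, 10.0,
                        RATE, noise_sd=0.5, seed=rep * 100 + s * 10 + ri,
                        condition=cond, subject=f"s{s}", run_index=ri)
                    courses.append(alpha_power_course(run))
            res = alpha_condition_test(courses)
            if res.p < 0.05 and res.mean_diff < 0:  # EO - EC negative
                hits += 1
        assert hits >= n_rep - 1

    def test_power_monotone_in_generator_amplitude(self):
        powers = []
        for amp in (0.5, 1.0, 2.0):
            run = simulate_eeg_run(np.zeros(int(30 * RATE), int),
                                   np.full((1, 6), amp), 10.0, RATE,
                                   noise_sd=0.2, seed=3)
            powers.append(alpha_power_course(run).values.mean())
        assert powers[0] < powers[1] < powers[2]

    def test_course_length_matches_paired_fmri_grid(self):
        run = tone_run(10.0, seconds=600.0)
        course = alpha_power_course(run)
        assert len(course) == 300
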