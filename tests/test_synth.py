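import numpy as np
import pytest
from scipy.fft import rfft, rfftfreq

import swallowsound as ss
from swallowsound.synth import SynthesisError


class TestCrackleBurst:
    def test_zero_amplitude_is_silence(self):
        burst = ss.synth_crackle(ss.CrackleSpec(amplitude=0.0))
        assert np.all(burst == 0.0)

    def test_default_length_is_441_samples(self):
        burst = ss.synth_crackle(ss.CrackleSpec(), rate=44_100)
        assert burst.shape[0] == round(0.010 * 44_100) == 441

    def test_spectral_peak_at_center_frequency(self):
        """FFT oracle: the burst's power spectrum peaks near 650 Hz."""
        rate = 44_100
        burst = ss.synth_crackle(ss.CrackleSpec(), rate=rate)
        spec = np.abs(rfft(burst, n=8_192)) ** 2
        peak = rfftfreq(8_192, 1 / rate)[np.argmax(spec)]
        # a 4-ms damped sinusoid has ~40 Hz half-width; allow one width
        assert abs(peak - 650.0) < 80.0

    def test_aliasing_rate_rejected(self):
        with pytest.raises(SynthesisError, match="aliasing"):
            ss.synth_crackle(ss.CrackleSpec(center_freq=650.0), rate=1_000)

    def test_invalid_spec_rejected(self):
        with pytest.raises(SynthesisError):
            ss.CrackleSpec(burst_dur=0.001, damping_tau=0.004)


class TestRecording:
    def test_zero_burst_rate_gives_all_negative_labels(self):
        rec = ss.synth_recording(ss.SwallowScenario(burst_rate=0.0, seed=1))
        assert rec.burst_intervals == ()
        assert np.all(rec.frame_labels() == 0)

    def test_same_seed_bitwise_identical(self):
        a = ss.synth_recording(ss.SwallowScenario(seed=5))
        b = ss.synth_recording(ss.SwallowScenario(seed=5))
        np.testing.assert_array_equal(a.recording.samples, b.recording.samples)
        np.testing.assert_array_equal(a.frame_labels(), b.frame_labels())
        c = ss.synth_recording(ss.SwallowScenario(seed=6))
        assert not np.array_equal(a.recording.samples, c.recording.samples)

    def test_realized_snr_within_1_db(self):
        for seed in (1, 2, 3):
            rec = ss.synth_recording(ss.SwallowScenario(snr_db=10.0, seed=seed))
            assert rec.realized_snr_db() == pytest.approx(10.0, abs=1.0)

    def test_labels_and_bursts_mutually_consistent(self, extractor):
        """Every labelled frame overlaps a burst; every burst touches >=1 frame."""
        rec = ss.synth_recording(ss.SwallowScenario(seed=9))
        labels = rec.frame_labels(extractor)
        section = ss.trim_auscultation(rec.recording)
        grid = ss.make_grid(section)
        starts = section.start_s + grid.frame_start_times()
        ends = starts + grid.window_samples / grid.rate
        for k in np.flatnonzero(labels):
            assert any(starts[k] < b1 and ends[k] > b0 for b0, b1 in rec.burst_intervals)
        for b0, b1 in rec.burst_intervals:
            assert labels[(starts < b1) & (ends > b0)].any()

    def test_window_outside_trimmed_region_rejected(self):
        with pytest.raises(SynthesisError, match="window"):
            ss.SwallowScenario(duration_s=2.0, swallow_window=(0.0, 1.9))

    def test_zero_noise_with_bursts_rejected(self):
        with pytest.raises(SynthesisError, match="SNR"):
            ss.SwallowScenario(noise_rms=0.0, burst_rate=5.0)

    def test_pink_noise_tilts_spectrum_low(self):
        """1/f background concentrates power below 1 kHz relative to white."""
        white = ss.synth_recording(ss.SwallowScenario(burst_rate=0.0, seed=2))
        pink = ss.synth_recording(
            ss.SwallowScenario(burst_rate=0.0, noise_color="pink", seed=2)
        )
        rate = white.recording.rate
        freqs = rfftfreq(white.recording.n_samples, 1 / rate)
        low = freqs < 1_000

        def low_fraction(rec):
            p = np.abs(rfft(rec.recording.samples)) ** 2
            return p[low].sum() / p.sum()

        assert low_fraction(pink) > 2 * low_fraction(white)
        assert np.std(pink.recording.samples) == pytest.approx(0.02, rel=0.05)


class TestTeacherSet:
    def test_default_class_balance(self):
        ts = ss.synth_teacher_set(n_clips=50, pos_fraction=0.5, seed=3, clip_dur_s=0.3)
        pos = [c for c in ts.clips if c.clip_id.startswith("pos")]
        neg = [c for c in ts.clips if c.clip_id.startswith("neg")]
        assert len(pos) == 25 and len(neg) == 25
        for c in pos:
            assert c.labels.sum() > 0
        for c in neg:
            assert c.labels.sum() == 0  # noise-only clips carry no positive frames

    def test_seed_reproducibility(self):
        a = ss.synth_teacher_set(n_clips=6, seed=4, clip_dur_s=0.3)
        b = ss.synth_teacher_set(n_clips=6, seed=4, clip_dur_s=0.3)
        for ca, cb in zip(a.clips, b.clips):
            np.testing.assert_array_equal(ca.recording.samples, cb.recording.samples)
            np.testing.assert_array_equal(ca.labels, cb.labels)

    @pytest.mark.parametrize("bad", [0.0, 1.0])
    def test_single_class_fraction_rejected(self, bad):
        with pytest.raises(SynthesisError, match="pos_fraction"):
            ss.synth_teacher_set(n_clips=10, pos_fraction=bad)


class TestCohort:
    def test_zero_noise_single_covariate_exact_linearity(self):
        spec = ss.SyntheticCohortSpec(
            n_patients=50, betas={"tongue_pressure": 0.004},
            intercept=0.1, sigma=1e-12, seed=2,
        )
        cohort, truth = ss.synth_cohort(spec)
        expected = 0.1 + 0.004 * cohort["tongue_pressure"]
        np.testing.assert_allclose(cohort["index"], np.clip(expected, 0, 1), atol=1e-9)
        assert truth["betas"] == {"tongue_pressure": 0.004}

    def test_seed_reproducibility(self):
        a, _ = ss.synth_cohort(ss.SyntheticCohortSpec(seed=11))
        b, _ = ss.synth_cohort(ss.SyntheticCohortSpec(seed=11))
        assert a.equals(b)

    def test_bulbar_score_mean_recovered_at_large_n(self):
        """Monte-Carlo: the sample mean of the (truncated, rounded) bulbar
        score sits within 3 standard errors of its empirical expectation."""
        spec = ss.SyntheticCohortSpec(n_patients=1_000, seed=13)
        cohort, _ = ss.synth_cohort(spec)
        cov = spec.covariates["alsfrs_r_bulbar"]
        # oracle: direct large-sample simulation of the same truncated draw
        rng = np.random.default_rng(999)
        ref = np.round(np.clip(rng.normal(cov.mean, cov.sd, 200_000), cov.lo, cov.hi))
        se = cohort["alsfrs_r_bulbar"].std() / np.sqrt(len(cohort))
        assert abs(cohort["alsfrs_r_bulbar"].mean() - ref.mean()) < 3 * se

    def test_index_stays_in_unit_interval(self):
        cohort, _ = ss.synth_cohort(ss.SyntheticCohortSpec(n_patients=500, sigma=0.3, seed=1))
        assert cohort["index"].between(0, 1).all()

    def test_too_few_patients_rejected(self):
        with pytest.raises(SynthesisError):
            ss.SyntheticCohortSpec(n_patients=2)

    def test_unknown_beta_rejected(self):
        with pytest.raises(SynthesisError, match="unknown covariate"):
            ss.SyntheticCohortSpec(betas={"grip_strength": 0.01})
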