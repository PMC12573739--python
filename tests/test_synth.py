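"""Generator contracts: spectra, apportionment, SNR, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pitchcode.arp import ACCENT_CLASSES
from pitchcode.synth import (
    F0Model,
    SyllableStimulusSpec,
    SyntheticARPSpec,
    gen_arps,
    gen_continuous_eeg,
    gen_continuous_stimulus,
    gen_ffr_epochs,
    gen_syllable,
    largest_remainder,
    make_trf_kernel,
    pink_noise,
)


class TestSyllable:
    def test_silent_before_voicing_onset_and_f0_peak(self):
        spec = SyllableStimulusSpec()  # 100 Hz, 170 ms, onset 10 ms, 20 kHz
        w = gen_syllable(spec)
        n_onset = int(0.010 * spec.sample_rate_hz)
        assert np.all(w[:n_onset] == 0)
        spec_mag = np.abs(np.fft.rfft(w * np.hanning(len(w))))
        freqs = np.fft.rfftfreq(len(w), 1 / spec.sample_rate_hz)
        peak = freqs[np.argmax(spec_mag)]
        assert abs(peak - 100.0) < 6.0  # one DFT bin at 170 ms

    def test_single_harmonic_is_pure_sinusoid(self):
        spec = SyllableStimulusSpec(harmonics=((1, 1.0),), voicing_onset_ms=0.0)
        w = gen_syllable(spec)
        t = np.arange(len(w)) / spec.sample_rate_hz
        ideal = np.sin(2 * np.pi * 100.0 * t)
        # ignore the 2 ms onset ramp
        n0 = int(0.002 * spec.sample_rate_hz) + 1
        assert np.corrcoef(w[n0:], ideal[n0:])[0, 1] > 0.9999

    def test_autocorrelation_period_200_samples_at_20khz(self):
        w = gen_syllable(SyllableStimulusSpec())
        voiced = w[int(0.012 * 20000):]
        # independent oracle: argmax of the full autocorrelation
        ac = np.correlate(voiced, voiced, mode="full")[len(voiced) - 1:]
        lag = 100 + np.argmax(ac[100:300])
        assert lag == 200

    def test_aliasing_rejected(self):
        spec = SyllableStimulusSpec(sample_rate_hz=2000.0)  # 4x800 Hz > 2 kHz
        with pytest.raises(ValueError):
            gen_syllable(spec)


class TestApportionment:
    def test_audiobook_proportions_200_tokens(self):
        counts = largest_remainder(np.array([1610, 318, 1188, 322]), 200)
        assert counts.sum() == 200
        # independent oracle: floor quotas + largest fractional remainders
        quota = 200 * np.array([1610, 318, 1188, 322]) / 3438
        assert np.all(np.abs(counts - quota) < 1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        props=st.lists(st.integers(0, 1000), min_size=4, max_size=4).filter(
            lambda p: sum(p) > 0
        ),
        total=st.integers(0, 500),
    )
    def test_counts_always_sum_to_total(self, props, total):
        counts = largest_remainder(np.array(props, float), total)
        assert counts.sum() == total
        assert np.all(counts >= 0)


class TestContinuousStimulus:
    def test_deterministic_given_seed(self):
        a = gen_continuous_stimulus(6.0, seed=3)
        b = gen_continuous_stimulus(6.0, seed=3)
        assert np.array_equal(a.audio, b.audio)
        assert np.array_equal(a.f0_true, b.f0_true)
        assert a.annotations == b.annotations

    def test_f0_in_range_and_silences_silent(self):
        stim = gen_continuous_stimulus(8.0, seed=4)
        nz = stim.f0_true[stim.f0_true > 0]
        assert nz.min() >= 60.0 and nz.max() <= 400.0
        assert np.all(stim.audio[stim.f0_true == 0] == 0)

    def test_annotations_fall_in_voiced_spans_with_requested_counts(self):
        stim = gen_continuous_stimulus(30.0, seed=5, n_tokens=20)
        assert len(stim.annotations) == 20
        fs = stim.sample_rate_hz
        for onset, label in stim.annotations:
            assert label in ACCENT_CLASSES
            assert stim.f0_true[int(onset * fs)] > 0
        labels = [lab for _, lab in stim.annotations]
        counts = np.array([labels.count(c) for c in ACCENT_CLASSES])
        expected = largest_remainder(np.array([1610, 318, 1188, 322]), 20)
        assert np.array_equal(np.sort(counts), np.sort(expected))

    def test_too_many_tokens_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            gen_continuous_stimulus(2.0, seed=0, n_tokens=500)

    def test_constant_f0_when_model_degenerate(self):
        model = F0Model(mean_hz=100.0, sd_hz=0.0, excursion_hz=0.0)
        stim = gen_continuous_stimulus(5.0, f0_model_params=model, seed=1, n_tokens=2)
        voiced = stim.f0_true[stim.f0_true > 0]
        assert np.allclose(voiced, 100.0)


class TestFFREpochs:
    def test_balanced_polarities_1500(self):
        s = gen_ffr_epochs(snr=1.0, n_epochs=1500, eeg_rate_hz=2000.0, seed=0)
        assert (s.polarity == 1).sum() == 750
        assert (s.polarity == -1).sum() == 750

    def test_odd_epoch_count_rejected(self):
        with pytest.raises(ValueError):
            gen_ffr_epochs(snr=1.0, n_epochs=9, seed=0)

    @pytest.mark.parametrize("snr", [0.25, 1.0, 4.0])
    def test_empirical_snr_within_10_percent(self, snr):
        s = gen_ffr_epochs(snr=snr, n_epochs=60, eeg_rate_hz=4000.0, seed=8)
        ref = gen_ffr_epochs(snr=np.inf, n_epochs=60, eeg_rate_hz=4000.0, seed=8)
        signal = ref.epochs
        noise = s.epochs - signal
        ratio = np.mean(signal**2) / np.mean(noise**2)
        assert abs(ratio - snr) / snr < 0.10


class TestContinuousEEG:
    def test_mastoids_signal_free_and_deterministic(self):
        rng = np.random.default_rng(0)
        sig = rng.standard_normal(4000)
        kernel, _ = make_trf_kernel(3, seed=1)
        a = gen_continuous_eeg(sig, kernel, snr=np.inf, n_channels=3, seed=2)
        b = gen_continuous_eeg(sig, kernel, snr=np.inf, n_channels=3, seed=2)
        assert np.array_equal(a.data, b.data)
        assert np.all(a.data[-2:] == 0)  # mastoids carry no signal
        assert a.channel_names[-2:] == ["M1", "M2"]

    def test_convolution_matches_direct_lagged_sum(self):
        sig = np.random.default_rng(1).standard_normal(500)
        lags = np.arange(-5, 11)
        kernel = np.zeros((1, len(lags)))
        kernel[0, 7] = 2.0  # lag +2 samples at 1000 Hz
        eeg = gen_continuous_eeg(
            sig, kernel, snr=np.inf, n_channels=1, seed=0, lags_ms=(-5.0, 10.0)
        )
        expected = np.zeros_like(sig)
        expected[2:] = 2.0 * sig[:-2]
        assert np.allclose(eeg.data[0], expected)


class TestARPGeneration:
    def test_shapes_and_balance(self):
        ds = gen_arps(SyntheticARPSpec(n_subjects_per_group=20), seed=0)
        assert len(ds) == 80
        _, y = ds.to_arrays()
        assert np.all(np.bincount(y) == 20)
        assert ds.is_balanced()

    def test_zero_noise_gives_identical_within_class(self):
        spec = SyntheticARPSpec(
            n_subjects_per_group=3, subject_noise_sd=0.0, separation=2.0,
            n_channels=8, n_samples=32,
        )
        ds = gen_arps(spec, seed=1)
        X, y = ds.to_arrays()
        for c in range(4):
            grp = X[y == c]
            assert np.allclose(grp, grp[0])

    def test_zero_separation_removes_class_information(self):
        spec = SyntheticARPSpec(
            n_subjects_per_group=4, separation=0.0, n_channels=8, n_samples=32
        )
        ds = gen_arps(spec, seed=2)
        X, y = ds.to_arrays()
        class_means = np.stack([X[y == c].mean(axis=0) for c in range(4)])
        # template contribution vanished: class means differ only by noise
        assert class_means.std(axis=0).mean() < X.std() / 2


def test_pink_noise_spectrum_slope(rng):
    x = pink_noise(rng, (8, 16384))
    spec = np.mean(np.abs(np.fft.rfft(x, axis=-1)) ** 2, axis=0)
    f = np.fft.rfftfreq(16384)
    lo = spec[(f > 0.001) & (f < 0.01)].mean()
    hi = spec[(f > 0.1) & (f < 0.5)].mean()
    assert lo / hi > 20  # strongly low-frequency weighted (1/f power)
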