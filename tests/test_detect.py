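"""Filtering, noise estimation and threshold detection."""

import numpy as np
import pytest
from scipy import signal as sps

from meanet import (RawRecording, SpikeDetector, SpikeMatrix, ValidationError,
                    bandpass, default_waveform, detect_spikes, estimate_noise,
                    synth_raw)

FS = 25000.0


def designed_gain(freq_hz, low=600.0, high=8000.0, order=3, fs=FS):
    """Oracle: squared magnitude of the designed filter (zero-phase doubles it)."""
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]) ** 2)


def sine_recording(freq_hz, duration_s=1.0, fs=FS):
    t = np.arange(int(duration_s * fs)) / fs
    return RawRecording(np.sin(2 * np.pi * freq_hz * t)[None, :], fs)


def mid_amplitude(x):
    n = x.size
    seg = x[n // 4: 3 * n // 4]
    return np.sqrt(2.0) * np.sqrt(np.mean(seg ** 2))


class TestBandpass:
    def test_dc_fully_rejected(self):
        rec = RawRecording(np.full((1, 25000), 3.3), FS)
        out = bandpass(rec).signal[0]
        assert np.max(np.abs(out[2500:-2500])) < 1e-6

    @pytest.mark.parametrize("freq", [50.0, 3000.0, 12000.0])
    def test_sinusoid_gain_matches_designed_response(self, freq):
        out = bandpass(sine_recording(freq)).signal[0]
        expect = designed_gain(freq)
        assert mid_amplitude(out) == pytest.approx(expect, rel=0.01, abs=1e-4)

    def test_50hz_strongly_attenuated(self):
        out = bandpass(sine_recording(50.0)).signal[0]
        assert mid_amplitude(out) < 1e-3

    def test_band_edge_at_nyquist_rejected(self):
        rec = sine_recording(1000.0, duration_s=0.1)
        with pytest.raises(ValidationError):
            bandpass(rec, band_high_hz=12500.0)

    def test_length_preserved(self):
        rec = sine_recording(3000.0, duration_s=0.2)
        assert bandpass(rec).n_samples == rec.n_samples


class TestNoiseEstimate:
    def test_robust_recovers_gaussian_sd(self, rng):
        x = rng.normal(0, 1.0, 1_000_000)
        assert estimate_noise(x, "robust") == pytest.approx(1.0, rel=0.01)

    def test_plain_is_sample_sd(self, rng):
        x = rng.normal(0, 2.0, 100_000)
        assert estimate_noise(x, "plain") == pytest.approx(np.std(x))

    def test_zero_channel_gives_zero(self):
        assert estimate_noise(np.zeros(1000)) == 0.0

    def test_robust_resists_spikes_plain_inflates(self, rng):
        """Sparse 10-sigma spikes: robust stays within 5%, plain inflates."""
        x = rng.normal(0, 1.0, 200_000)
        idx = rng.choice(x.size, size=x.size // 200, replace=False)  # 0.5%
        x[idx] -= 10.0
        robust = estimate_noise(x, "robust")
        plain = estimate_noise(x, "plain")
        assert abs(robust - 1.0) < 0.05
        assert plain > robust + 0.1

    def test_unknown_estimator_rejected(self):
        with pytest.raises(ValidationError):
            estimate_noise(np.ones(10), "mad")


class TestDetectSpikes:
    def test_zero_channel_zero_sigma_empty(self):
        tr = detect_spikes(np.zeros(1000), 0.0, sampling_rate_hz=FS)
        assert tr.n_spikes == 0

    def test_refractory_shorter_than_sample_rejected(self):
        with pytest.raises(ValidationError):
            detect_spikes(np.zeros(10), 1.0, refractory_ms=0.01,
                          sampling_rate_hz=1000.0)

    def test_event_time_is_local_extremum(self):
        x = np.zeros(1000)
        x[500:505] = [-4, -6, -9, -5, -4]  # excursion, extremum at 502
        tr = detect_spikes(x, 1.0, threshold_k=3.0, sampling_rate_hz=1000.0)
        assert np.array_equal(tr.times, [0.502])

    def test_two_events_inside_refractory_collapse_to_one(self):
        # events 1.0 ms apart with a 1.5 ms refractory period
        x = np.zeros(2500)
        x[1000] = -10.0
        x[1025] = -10.0  # 25 samples = 1.0 ms at 25 kHz
        tr = detect_spikes(x, 1.0, sampling_rate_hz=FS)
        assert tr.n_spikes == 1
        assert tr.times[0] == pytest.approx(1000 / FS)

    def test_refractory_invariant_on_noise(self, rng):
        x = rng.normal(0, 1.0, int(FS))
        tr = detect_spikes(x, 1.0, threshold_k=2.0, sampling_rate_hz=FS)
        assert tr.n_spikes > 0
        assert np.all(np.diff(tr.times) >= 1.5e-3 - 1e-12)

    def test_scale_invariance(self, rng):
        """Rescaling signal and sigma together leaves spike times unchanged."""
        x = rng.normal(0, 1.0, 50_000)
        x[10_000] = -8.0
        a = detect_spikes(x, 1.0, sampling_rate_hz=FS)
        b = detect_spikes(17.3 * x, 17.3, sampling_rate_hz=FS)
        assert np.array_equal(a.times, b.times)

    def test_positive_and_both_polarity(self):
        x = np.zeros(1000)
        x[100] = 8.0
        x[600] = -8.0
        fs = 1000.0
        assert detect_spikes(x, 1.0, polarity="positive",
                             sampling_rate_hz=fs).times.tolist() == [0.1]
        assert detect_spikes(x, 1.0, polarity="both",
                             sampling_rate_hz=fs).n_spikes == 2
        with pytest.raises(ValidationError):
            detect_spikes(x, 1.0, polarity="down", sampling_rate_hz=fs)

    def test_false_positive_rate_decreases_in_k(self, rng):
        """On pure Gaussian noise the FP count falls monotonically with k."""
        sos = sps.butter(3, [600, 8000], btype="bandpass", fs=FS, output="sos")
        x = sps.sosfiltfilt(sos, rng.normal(0, 1.0, int(10 * FS)))
        sigma = estimate_noise(x, "robust")
        counts = [detect_spikes(x, sigma, threshold_k=k,
                                sampling_rate_hz=FS).n_spikes
                  for k in (3.0, 4.0, 5.0)]
        assert counts[0] > counts[1] > counts[2] or counts[2] == counts[1] == 0
        assert counts[2] <= 1


class TestSpikeDetector:
    def test_recovers_injected_spikes(self):
        """20 well-separated 10-sigma spikes recovered at the right times."""
        fs = FS
        times = 0.05 + np.arange(20) * 0.03
        sm = SpikeMatrix.from_times([times], duration_s=0.7)
        wf = default_waveform(fs, amplitude=10.0)
        rec, _ = synth_raw(sm, fs, waveform=wf, noise_sd=1.0, seed=11)
        det = SpikeDetector(threshold_k=5.0).fit_transform(rec)
        found = det.spike_matrix[0].times
        assert found.size == 20
        matched = np.min(np.abs(found[:, None] - times[None, :]), axis=1)
        assert np.all(matched <= 0.5e-3)

    def test_fitted_attributes_and_params(self):
        rec = RawRecording(np.random.default_rng(0).normal(0, 1, (2, 25000)), FS)
        det = SpikeDetector()
        det.fit(rec)
        assert det.noise_sd_per_channel_.shape == (2,)
        assert np.allclose(det.threshold_per_channel_,
                           3.0 * det.noise_sd_per_channel_)
        assert det.get_params()["band_low_hz"] == 600.0

    def test_transform_rejects_channel_mismatch(self):
        rng = np.random.default_rng(0)
        det = SpikeDetector().fit(RawRecording(rng.normal(0, 1, (2, 25000)), FS))
        with pytest.raises(ValidationError):
            det.transform(RawRecording(rng.normal(0, 1, (3, 25000)), FS))
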