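"""Preprocessing: rereferencing, filtering, epoching, baseline z-scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gonogo_ecog.containers import EpochSet, RecordingSession
from gonogo_ecog.preprocess import (band_envelope, bandpass, epoch,
                                    notch_line_noise,
                                    rereference_common_average,
                                    z_normalize_to_baseline)

FS = 1200.0


def _session(signal, events=None):
    n_ch = signal.shape[0]
    channels = pd.DataFrame({"name": [f"c{i}" for i in range(n_ch)],
                             "roi": ["other"] * n_ch,
                             "hemisphere": ["right"] * n_ch})
    if events is None:
        events = pd.DataFrame({"onset_sample": [], "cue_type": [],
                               "response": [], "latency_s": []})
    return RecordingSession(signal, FS, channels, events)


class TestCommonAverage:
    def test_constant_channels_become_zero(self):
        s = _session(np.full((4, 100), 3.7))
        out = rereference_common_average(s)
        np.testing.assert_allclose(out.signal, 0.0, atol=1e-12)

    def test_zero_mean_pair_unchanged(self, rng):
        x = rng.standard_normal(500)
        s = _session(np.stack([x, -x]))
        out = rereference_common_average(s)
        np.testing.assert_allclose(out.signal, s.signal, atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(2, 12), st.integers(0, 2**31 - 1))
    def test_zero_mean_and_idempotent(self, n_ch, seed):
        x = np.random.default_rng(seed).normal(5, 10, size=(n_ch, 200))
        once = rereference_common_average(_session(x))
        assert np.abs(once.signal.mean(axis=0)).max() < 1e-10
        twice = rereference_common_average(once)
        np.testing.assert_allclose(twice.signal, once.signal, atol=1e-10)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match=">= 2 channels"):
            rereference_common_average(_session(np.zeros((1, 10))))


class TestNotch:
    def test_line_tone_attenuated_20db(self, rng):
        t = np.arange(int(5 * FS)) / FS
        tone = np.sin(2 * np.pi * 60 * t)
        out = notch_line_noise(_session(tone[None, :]))
        assert out.signal.std() <= 0.1 * tone.std()

    def test_passband_tone_attenuated_less_than_1db(self):
        t = np.arange(int(5 * FS)) / FS
        for f0 in (10.0, 100.0):
            tone = np.sin(2 * np.pi * f0 * t)
            out = notch_line_noise(_session(tone[None, :]))
            mid = slice(1200, -1200)
            ratio = out.signal[0, mid].std() / tone[mid].std()
            assert ratio > 10 ** (-1 / 20)  # < 1 dB loss
            assert ratio <= 1.001

    def test_dc_unchanged(self):
        s = _session(np.full((2, 2000), 4.0))
        out = notch_line_noise(s)
        np.testing.assert_allclose(out.signal, 4.0, atol=1e-6)

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            notch_line_noise(_session(np.zeros((2, 100))), freqs=(700.0,))


class TestBandEnvelope:
    def test_tone_in_band_gives_flat_envelope_at_amplitude(self):
        t = np.arange(int(4 * FS)) / FS
        x = 2.5 * np.sin(2 * np.pi * 100 * t)
        env = band_envelope(x, FS, (70, 200))
        mid = env[1200:-1200]
        np.testing.assert_allclose(mid, 2.5, rtol=0.02)

    def test_stopband_tone_suppressed(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t)
        env = band_envelope(x, FS, (70, 200))
        assert env[1200:-1200].max() < 0.01

    def test_am_modulator_recovered(self):
        t = np.arange(int(4 * FS)) / FS
        a = 1 + 0.5 * np.cos(2 * np.pi * 4 * t)
        x = a * np.sin(2 * np.pi * 100 * t)
        env = band_envelope(x, FS, (70, 200))
        mid = slice(1200, -1200)
        assert np.max(np.abs(env[mid] - a[mid]) / a[mid]) < 0.05

    def test_zero_phase_no_lag(self, rng):
        # cross-correlation between band-limited input and its filtered
        # output must peak at zero lag
        x = bandpass(rng.standard_normal(int(4 * FS)), FS, (20, 60))
        y = bandpass(x, FS, (10, 80))
        lags = np.arange(-50, 51)
        xc = [np.dot(x[50:-50], y[50 + k:len(y) - 50 + k]) for k in lags]
        assert lags[np.argmax(xc)] == 0

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            band_envelope(np.zeros(1000), FS, (200, 70))


class TestEpoching:
    def _events(self, onsets, cues=None):
        n = len(onsets)
        return pd.DataFrame({
            "onset_sample": onsets,
            "cue_type": cues if cues is not None else ["go"] * n,
            "response": [True] * n,
            "latency_s": [0.4] * n,
        })

    def test_all_events_epoched_with_correct_axis(self, rng):
        onsets = 2400 + 2400 * np.arange(5)
        s = _session(rng.standard_normal((3, 20000)), self._events(onsets))
        ep = epoch(s)
        assert ep.data.shape == (5, 3, 2400)
        assert ep.times[0] == -1.0
        assert ep.times[1200] == 0.0
        assert ep.times[-1] < 1.0  # half-open window

    def test_edge_trial_dropped_with_warning(self, rng, caplog):
        onsets = [100, 5000]
        s = _session(rng.standard_normal((2, 10000)), self._events(onsets))
        with caplog.at_level("WARNING"):
            ep = epoch(s)
        assert ep.n_trials == 1
        assert "dropping trial" in caplog.text

    def test_epoch_values_match_slices(self, rng):
        x = rng.standard_normal((1, 8000))
        s = _session(x, self._events([3000]))
        ep = epoch(s)
        np.testing.assert_array_equal(ep.data[0, 0], x[0, 1800:4200])

    def test_labels_follow_events(self, rng):
        onsets = [2000, 4500, 7000]
        ev = self._events(onsets, cues=["go", "nogo", "go"])
        s = _session(rng.standard_normal((2, 10000)), ev)
        ep = epoch(s)
        assert list(ep.labels["cue_type"]) == ["go", "nogo", "go"]


class TestBaselineNormalization:
    def _epochs(self, data):
        n_tr, n_ch, n_t = data.shape
        times = np.arange(-n_t // 2, n_t // 2) / FS
        labels = pd.DataFrame({"cue_type": ["go"] * n_tr})
        channels = pd.DataFrame({"name": [f"c{i}" for i in range(n_ch)],
                                 "roi": ["other"] * n_ch,
                                 "hemisphere": ["right"] * n_ch})
        return EpochSet(data, times, FS, labels, channels,
                        window=(times[0], times[-1] + 1 / FS))

    def test_pooled_baseline_standardized(self, rng):
        data = rng.normal(5.0, 2.0, size=(49, 2, 2400))
        z = z_normalize_to_baseline(self._epochs(data))
        base = z.data[..., z.baseline_mask]
        assert np.abs(base.mean(axis=(0, 2))).max() < 0.05
        np.testing.assert_allclose(base.std(axis=(0, 2)), 1.0, rtol=0.05)

    def test_value_at_baseline_mean_maps_to_zero(self, rng):
        data = rng.normal(3.0, 1.0, size=(20, 1, 1200))
        mu = data[..., :600].mean()
        z = z_normalize_to_baseline(self._epochs(data))
        sd = data[..., :600].std()
        # a raw value equal to the baseline mean normalizes to 0
        np.testing.assert_allclose((data - mu) / sd, z.data, rtol=1e-10)

    def test_constant_envelope_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            z_normalize_to_baseline(self._epochs(np.ones((5, 1, 1000))))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.floats(0.01, 1e4), st.integers(0, 2**31 - 1))
    def test_affine_invariance_under_positive_scaling(self, k, seed):
        data = np.random.default_rng(seed).normal(1, 2, size=(6, 1, 600))
        a = z_normalize_to_baseline(self._epochs(data))
        b = z_normalize_to_baseline(self._epochs(k * data))
        np.testing.assert_allclose(a.data, b.data, rtol=1e-8, atol=1e-8)

    def test_double_normalization_rejected(self, rng):
        z = z_normalize_to_baseline(
            self._epochs(rng.normal(0, 1, size=(5, 1, 600))))
        with pytest.raises(ValueError, match="already normalized"):
            z_normalize_to_baseline(z)
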