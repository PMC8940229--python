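"""Time-frequency power: ERSP, STFT band peaks, No-Go/Go power ratio."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gonogo_ecog.activation import classify_trials
from gonogo_ecog.config import PipelineConfig
from gonogo_ecog.containers import EpochSet
from gonogo_ecog.pipeline import preprocess_session
from gonogo_ecog.preprocess import epoch
from gonogo_ecog.simulate import SimConfig, SubjectProfile, TaskConfig, simulate_session
from gonogo_ecog.spectral import (band_frame_power, morlet_ersp, power_ratio,
                                  stft_band_peaks)

FS = 1200.0


@pytest.fixture(scope="module")
def null_wide_epochs():
    """49-trial session with no injected responses, wide epochs for ERSP."""
    prof = SubjectProfile("n", 10, "right", ("left",), 1.0)
    sim = SimConfig(n_channels=4,
                    channel_rois=("motor", "ifg", "other", "other"),
                    band_gains_ifg=(("theta", (0, 0)), ("beta", (0, 0)),
                                    ("hg", (0, 0))),
                    hg_burst_gain_motor=0.0, pac_depth=(0, 0))
    session, _ = simulate_session(prof, TaskConfig(), sim, seed=42)
    session = preprocess_session(session, PipelineConfig())
    ep = epoch(session, (-2.5, 2.5))
    return ep.copy_with(labels=classify_trials(ep.labels))


@pytest.fixture(scope="module")
def wide_epochs(preprocessed_run):
    session, truth = preprocessed_run
    ep = epoch(session, (-2.5, 2.5))
    return ep.copy_with(labels=classify_trials(ep.labels)), truth


class TestERSP:
    def test_trial_weighted_baseline_is_zero(self, null_wide_epochs):
        # pooled z-scoring fixes the across-trials baseline mean per row to
        # zero, so the trial-count-weighted average of the two condition
        # ERSPs has (near-)zero baseline rows
        go = morlet_ersp(null_wide_epochs, 1, "go_correct")
        ng = morlet_ersp(null_wide_epochs, 1, "nogo_correct")
        pooled = (go.values * go.n_trials + ng.values * ng.n_trials) \
            / (go.n_trials + ng.n_trials)
        base = pooled[:, go.times < 0]
        assert np.abs(base.mean(axis=1)).max() < 1e-9

    def test_null_session_post_cue_near_zero(self, null_wide_epochs):
        go = morlet_ersp(null_wide_epochs, 1, "go_correct")
        post = go.values[:, go.times >= 0]
        assert abs(post.mean()) < 0.2

    def test_injected_burst_localizes_to_high_gamma_rows(self, wide_epochs):
        ep, truth = wide_epochs
        ersp = morlet_ersp(ep, truth.ci_channel, "nogo_correct")
        post = ersp.values[:, ersp.times >= 0]
        # strongest post-cue high-frequency response sits in 70-200 Hz
        hi = ersp.freqs >= 70
        lo_gamma = (ersp.freqs >= 40) & (ersp.freqs < 70)
        assert post[hi].max() > post[lo_gamma].max()

    def test_affine_invariance(self, null_wide_epochs):
        doubled = null_wide_epochs.copy_with(data=2.0 * null_wide_epochs.data)
        a = morlet_ersp(null_wide_epochs, 0, "go_correct")
        b = morlet_ersp(doubled, 0, "go_correct")
        np.testing.assert_allclose(a.values, b.values, rtol=1e-6)

    def test_narrow_window_rejected(self, preprocessed_run):
        session, _ = preprocessed_run
        ep = epoch(session, (-1.0, 1.0))
        ep = ep.copy_with(labels=classify_trials(ep.labels))
        with pytest.raises(ValueError, match="wavelet"):
            morlet_ersp(ep, 0, "go_correct")


def _tone_epochs(amp_pre, amp_post, f0=100.0, n_trials=3):
    t = np.arange(-1200, 1200) / FS
    x = np.where(t < 0, amp_pre, amp_post) * np.cos(2 * np.pi * f0 * t)
    data = np.tile(x, (n_trials, 1, 1))
    labels = pd.DataFrame({"cue_type": ["go"] * n_trials,
                           "outcome": ["go_correct"] * n_trials})
    channels = pd.DataFrame({"name": ["c0"], "roi": ["ifg"],
                             "hemisphere": ["right"]})
    return EpochSet(data, t, FS, labels, channels)


class TestBandPeaks:
    def test_200_frames_in_post_cue_second(self):
        x = np.zeros(2400)
        _, t0 = band_frame_power(x, FS, {"hg": (70, 200)})
        t_rel = t0 - 1.0
        assert ((t_rel >= 0) & (t_rel < 1)).sum() == 200

    def test_tone_band_power_matches_windowed_dft(self):
        # aligned 100 Hz tone under a periodic Hann window: |X[k0]| = AN/4
        # and |X[k0 +- 1]| = AN/8 exactly, so the band-mean power is known
        A, N = 2.0, 600
        t = np.arange(int(3 * FS)) / FS
        x = A * np.cos(2 * np.pi * 100 * t)  # 100 Hz = bin 50 of 600 @ 1200 Hz
        powers, times = band_frame_power(x, FS, {"hg": (70, 200)})
        mid = np.argmin(np.abs(times - 1.5))
        n_rows = np.count_nonzero(
            (np.fft.rfftfreq(N, 1 / FS) >= 70) & (np.fft.rfftfreq(N, 1 / FS) <= 200))
        expected = ((A * N / 4) ** 2 + 2 * (A * N / 8) ** 2) / n_rows
        assert powers["hg"][mid] == pytest.approx(expected, rel=0.01)

    def test_power_step_yields_large_hg_peak(self):
        ep = _tone_epochs(1.0, np.sqrt(3.0))   # 3x power step post-cue
        with_noise = ep.copy_with(
            data=ep.data + 0.05 * np.random.default_rng(0).standard_normal(ep.data.shape))
        peaks = stft_band_peaks(with_noise, 0)
        assert (peaks["hg"] > peaks["theta"]).all()
        assert (peaks["hg"] > 3).all()

    def test_band_above_nyquist_rejected(self):
        ep = _tone_epochs(1.0, 1.0)
        with pytest.raises(ValueError, match="Nyquist"):
            stft_band_peaks(ep, 0, bands={"bad": (500.0, 700.0)})

    def test_peak_monotone_under_added_power(self, rng):
        ep = _tone_epochs(1.0, 1.0)
        noisy = ep.copy_with(data=ep.data + 0.1 * rng.standard_normal(ep.data.shape))
        base_peaks = stft_band_peaks(noisy, 0)
        t = noisy.times
        boost = np.where((t >= 0.2) & (t < 0.6),
                         np.cos(2 * np.pi * 100 * t), 0.0)
        boosted = noisy.copy_with(data=noisy.data + boost)
        new_peaks = stft_band_peaks(boosted, 0)
        assert (new_peaks["hg"] >= base_peaks["hg"] - 1e-9).all()


class TestPowerRatio:
    def _peaks(self, values):
        return pd.DataFrame({"theta": values})

    def test_direct_substitution(self):
        r = power_ratio(self._peaks([2.0, 2.0]), self._peaks([1.0, 1.0]),
                        bands=("theta",), n_bootstrap=50)
        assert r.loc["theta", "ratio"] == pytest.approx(2.0)

    def test_identical_distributions_near_one(self, rng):
        x = rng.normal(5, 1, 400)
        r = power_ratio(self._peaks(x), self._peaks(x), bands=("theta",),
                        n_bootstrap=100)
        assert r.loc["theta", "ratio"] == pytest.approx(1.0)
        assert r.loc["theta", "ci_low"] < 1.0 < r.loc["theta", "ci_high"]

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.floats(0.1, 50))
    def test_scaling_nogo_peaks_scales_ratio(self, k):
        base = np.array([1.0, 2.0, 3.0])
        r1 = power_ratio(self._peaks(base), self._peaks(base),
                         bands=("theta",), n_bootstrap=10)
        rk = power_ratio(self._peaks(k * base), self._peaks(base),
                         bands=("theta",), n_bootstrap=10)
        assert rk.loc["theta", "ratio"] == pytest.approx(
            k * r1.loc["theta", "ratio"])

    def test_go_mean_below_floor_flagged_undefined(self):
        r = power_ratio(self._peaks([1.0, 1.0]), self._peaks([0.01, -0.01]),
                        bands=("theta",), n_bootstrap=10)
        assert not r.loc["theta", "defined"]
        assert np.isnan(r.loc["theta", "ratio"])

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            power_ratio(self._peaks([]), self._peaks([1.0]), bands=("theta",))
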