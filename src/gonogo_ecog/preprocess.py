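"""Continuous-recording preprocessing and epoching.

Pipeline order: common-average rereference within the grid, notch filtering
of line noise (60/120/180 Hz), band-limited Hilbert envelopes (e.g. the
70-200 Hz high-gamma envelope), cue-locked epoching from 1 s before to 1 s
after the visual cue, and z-normalization to the pre-cue baseline second.

All filters are zero-phase (forward-backward) so that envelope and power
estimates are not delayed relative to the cue.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.fft import next_fast_len

from .containers import EpochSet, RecordingSession

logger = logging.getLogger(__name__)

__all__ = [
    "rereference_common_average",
    "notch_line_noise",
    "bandpass",
    "band_envelope",
    "epoch",
    "z_normalize_to_baseline",
    "zscore_by_baseline",
    "hg_epochs",
]


def rereference_common_average(session: RecordingSession) -> RecordingSession:
    """Subtract the instantaneous mean across the grid's channels.

    After rereferencing, the per-sample mean over channels is zero.  A
    single-channel grid has no defined common average and raises.
    """
    if session.n_channels < 2:
        raise ValueError("common-average reference requires >= 2 channels")
    car = session.signal.mean(axis=0, keepdims=True)
    return session.copy_with(signal=session.signal - car)


def notch_line_noise(session: RecordingSession,
                     freqs: tuple[float, ...] = (60.0, 120.0, 180.0),
                     quality: float = 30.0) -> RecordingSession:
    """Zero-phase IIR notch at each line-noise frequency (Q = 30)."""
    nyq = session.sampling_rate / 2.0
    for f0 in freqs:
        if f0 >= nyq:
            raise ValueError(f"notch frequency {f0} Hz >= Nyquist ({nyq} Hz)")
    x = session.signal
    for f0 in freqs:
        b, a = sps.iirnotch(f0, quality, fs=session.sampling_rate)
        x = sps.filtfilt(b, a, x, axis=-1)
    return session.copy_with(signal=x)


def _butter_sos(band: tuple[float, float], fs: float, order: int = 4):
    low, high = band
    nyq = fs / 2.0
    if not 0.0 < low < high < nyq:
        raise ValueError(f"band {band} must satisfy 0 < low < high < Nyquist ({nyq})")
    return sps.butter(order, band, btype="bandpass", fs=fs, output="sos")


def bandpass(x: np.ndarray, fs: float, band: tuple[float, float],
             order: int = 4) -> np.ndarray:
    """Zero-phase 4th-order Butterworth bandpass along the last axis."""
    return sps.sosfiltfilt(_butter_sos(band, fs, order), x, axis=-1)


def _hilbert(x: np.ndarray) -> np.ndarray:
    """Analytic signal via FFT padded to a fast length (truncated back)."""
    n = x.shape[-1]
    return sps.hilbert(x, N=next_fast_len(n), axis=-1)[..., :n]


def band_envelope(x: np.ndarray, fs: float, band: tuple[float, float],
                  order: int = 4) -> np.ndarray:
    """Band-limited amplitude envelope: |Hilbert| of the Butterworth-filtered
    signal.  Nonnegative, same length as the input."""
    return np.abs(_hilbert(bandpass(x, fs, band, order)))


def band_phase(x: np.ndarray, fs: float, band: tuple[float, float],
               order: int = 4) -> np.ndarray:
    """Instantaneous phase (radians) of the band-limited signal."""
    return np.angle(_hilbert(bandpass(x, fs, band, order)))


def epoch(session: RecordingSession,
          window: tuple[float, float] = (-1.0, 1.0),
          signal: np.ndarray | None = None) -> EpochSet:
    """Cut one epoch per event from the continuous signal.

    The window is half-open ``[window[0], window[1])`` in seconds relative
    to the cue; the cue sample belongs to the post-cue side.  Trials whose
    window exceeds the recording are dropped with a logged warning.
    """
    fs = session.sampling_rate
    data = session.signal if signal is None else np.asarray(signal, float)
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[-1] != session.n_samples:
        raise ValueError("signal override must match the session length")
    i_lo = int(round(window[0] * fs))
    i_hi = int(round(window[1] * fs))
    n_times = i_hi - i_lo
    keep, trials = [], []
    for row in session.events.itertuples(index=True):
        start = row.onset_sample + i_lo
        stop = row.onset_sample + i_hi
        if start < 0 or stop > data.shape[-1]:
            logger.warning(
                "dropping trial %s: window [%d, %d) outside recording",
                row.Index, start, stop)
            continue
        keep.append(row.Index)
        trials.append(data[:, start:stop])
    times = (np.arange(i_lo, i_hi)) / fs
    labels = session.events.loc[keep].reset_index(drop=True)
    return EpochSet(
        data=np.stack(trials) if trials else np.empty((0, data.shape[0], n_times)),
        times=times,
        sampling_rate=fs,
        labels=labels,
        channels=session.channels,
        window=window,
    )


def zscore_by_baseline(data: np.ndarray, baseline_mask: np.ndarray,
                       per_trial: bool = False) -> np.ndarray:
    """Z-score an epoched array against its pre-cue baseline.

    ``data`` has shape (trials, ..., time).  By default the baseline mean
    and SD are pooled over all trials and baseline samples, separately for
    every intermediate index (channel, frequency, ...); ``per_trial=True``
    normalizes each trial by its own baseline instead.
    """
    base = data[..., baseline_mask]
    if per_trial:
        mu = base.mean(axis=-1, keepdims=True)
        sd = base.std(axis=-1, keepdims=True)
    else:
        mu = base.mean(axis=(0, -1), keepdims=True)
        sd = base.std(axis=(0, -1), keepdims=True)
    if np.any(sd == 0):
        raise ValueError("degenerate baseline: zero variance")
    return (data - mu) / sd


def z_normalize_to_baseline(epochs: EpochSet,
                            per_trial: bool = False) -> EpochSet:
    """Z-normalize epochs to the pre-cue second (pooled across trials).

    After normalization the pooled baseline samples of every channel have
    mean 0 and SD 1.  Scaling the raw signal by any k > 0 leaves the
    result unchanged.
    """
    if epochs.normalized:
        raise ValueError("epochs are already normalized")
    z = zscore_by_baseline(epochs.data, epochs.baseline_mask, per_trial)
    return epochs.copy_with(data=z, normalized=True)


def hg_epochs(session: RecordingSession,
              band: tuple[float, float] = (70.0, 200.0),
              window: tuple[float, float] = (-1.0, 1.0),
              per_trial_baseline: bool = False) -> EpochSet:
    """High-gamma envelope epochs, baseline z-normalized (convenience)."""
    env = band_envelope(session.signal, session.sampling_rate, band)
    return z_normalize_to_baseline(epoch(session, window, signal=env),
                                   per_trial=per_trial_baseline)
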