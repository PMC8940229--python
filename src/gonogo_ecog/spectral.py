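"""Time-frequency power analysis of the selected electrodes.

Three pieces: a broadband Morlet event-related spectral perturbation
(ERSP, 2-200 Hz in 3 Hz steps, z-scored per frequency against the pre-cue
baseline), short-time-Fourier band-power peak extraction (theta 4-8,
beta 12-40, high-gamma 70-200 Hz; 5 ms frame hop), and the No-Go/Go power
ratio

    power_ratio = mean(No-Go/Correct peaks) / mean(Go/Correct peaks)

computed per band with a bootstrap confidence interval.

The 5 ms figure is read as the *hop* between analysis frames; the frame
itself is 500 ms (Hann), since a literal 5 ms window cannot resolve theta.
Both are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

from .containers import EpochSet
from .preprocess import zscore_by_baseline

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_BANDS", "ERSPMatrix", "morlet_ersp", "band_frame_power",
           "stft_band_peaks", "power_ratio"]

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "beta": (12.0, 40.0),
    "hg": (70.0, 200.0),
}


@dataclass
class ERSPMatrix:
    """Condition-averaged, baseline-z-scored time-frequency power."""
    values: np.ndarray          # freqs x times
    freqs: np.ndarray
    times: np.ndarray
    condition: str
    channel: int
    n_trials: int


def morlet_ersp(epochs: EpochSet, channel: int, condition: str,
                freqs: np.ndarray | None = None,
                n_cycles: float = 6.0,
                crop: tuple[float, float] = (-1.0, 1.0)) -> ERSPMatrix:
    """Morlet-wavelet ERSP of one electrode for one outcome condition.

    Epochs must be raw (un-normalized) and cut wider than the analysis
    window so the longest wavelet (6 cycles at 2 Hz spans ~4.8 s at 5 SD)
    fits; cut with ``epoch(session, window=(-2.5, 2.5))``.  Power is
    z-scored per frequency
    against the pooled pre-cue baseline of all correct trials, then
    averaged over the requested condition's trials.
    """
    from mne.time_frequency import tfr_array_morlet

    if epochs.normalized:
        raise ValueError("morlet_ersp expects raw epochs")
    if freqs is None:
        freqs = np.arange(2.0, 201.0, 3.0)
    # mne builds wavelets with 5 SD support: sigma_t = n_cycles/(2 pi f)
    need = 5.0 * n_cycles / (np.pi * freqs.min())
    have = epochs.window[1] - epochs.window[0]
    if have < need:
        raise ValueError(
            f"epoch window {have:.2f}s shorter than the longest wavelet "
            f"({need:.2f}s); cut wider epochs (e.g. window=(-2.5, 2.5))")

    correct = np.concatenate([epochs.trials_of("go_correct"),
                              epochs.trials_of("nogo_correct")])
    correct = np.sort(correct)
    cond_idx = epochs.trials_of(condition)
    if cond_idx.size == 0:
        raise ValueError(f"no correct trials for condition {condition!r}")
    data = epochs.data[correct][:, [channel], :]
    power = tfr_array_morlet(data, sfreq=epochs.sampling_rate,
                             freqs=freqs, n_cycles=n_cycles,
                             output="power", zero_mean=True)[:, 0]
    keep = (epochs.times >= crop[0]) & (epochs.times < crop[1])
    power = power[..., keep]
    times = epochs.times[keep]
    z = zscore_by_baseline(power, times < 0.0)
    # map condition trials into the 'correct' subset ordering
    pos = {t: i for i, t in enumerate(correct)}
    sel = [pos[t] for t in cond_idx]
    return ERSPMatrix(values=z[sel].mean(axis=0), freqs=freqs, times=times,
                      condition=condition, channel=channel,
                      n_trials=len(sel))


def band_frame_power(x: np.ndarray, fs: float,
                     bands: dict[str, tuple[float, float]],
                     window_s: float = 0.5,
                     hop_s: float = 0.005) -> tuple[dict, np.ndarray]:
    """Raw STFT band power per frame (Hann window, |S|^2 averaged over the
    band's frequency rows).

    ``x`` has shape (..., time).  Returns ``(powers, frame_times)`` where
    ``powers[name]`` has shape (..., n_frames) and frame times are seconds
    from the first sample.
    """
    nyq = fs / 2.0
    for name, (lo, hi) in bands.items():
        if hi > nyq:
            raise ValueError(f"band {name} {lo}-{hi} Hz exceeds Nyquist {nyq}")
    n_win = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    sft = ShortTimeFFT(hann(n_win, sym=False), hop=hop, fs=fs,
                       fft_mode="onesided")
    S = sft.stft(np.asarray(x, float), axis=-1)
    p = (np.abs(S) ** 2).swapaxes(-2, -1)      # ... x frames x freq
    powers = {}
    for name, (lo, hi) in bands.items():
        rows = (sft.f >= lo) & (sft.f <= hi)
        powers[name] = p[..., rows].mean(axis=-1)
    return powers, sft.t(np.asarray(x).shape[-1])


def stft_band_peaks(epochs: EpochSet, channel: int,
                    bands: dict[str, tuple[float, float]] | None = None,
                    window_s: float = 0.5, hop_s: float = 0.005,
                    correct_only: bool = True) -> pd.DataFrame:
    """Per-trial post-cue band-power peaks from a short-time Fourier
    transform.

    Band power per frame is z-scored against the pooled pre-cue baseline
    frames of the same band; the peak is the maximum over the frames whose
    centers fall in the post-cue second [0, 1 s).  Returns one row per
    trial with one column per band plus the trial labels.
    """
    if bands is None:
        bands = DEFAULT_BANDS
    fs = epochs.sampling_rate
    powers, t0 = band_frame_power(epochs.data[:, channel, :], fs, bands,
                                  window_s, hop_s)
    t_frames = t0 + epochs.times[0]            # frame centers, rel cue
    # frames fully inside the epoch (avoid zero-padded edges)
    valid_lo = epochs.times[0] + window_s / 2.0
    base = (t_frames >= valid_lo) & (t_frames < 0.0)
    post = (t_frames >= 0.0) & (t_frames < 1.0)
    if not post.any():
        raise ValueError("post-cue window is empty")

    out = {}
    for name in bands:
        bp = powers[name]                      # trials x frames
        mu = bp[:, base].mean()
        sd = bp[:, base].std()
        if sd == 0:
            raise ValueError(f"degenerate baseline power in band {name}")
        out[name] = ((bp - mu) / sd)[:, post].max(axis=-1)
    peaks = pd.DataFrame(out)
    for col in ("cue_type", "outcome"):
        if col in epochs.labels.columns:
            peaks[col] = epochs.labels[col].to_numpy()
    if correct_only and "outcome" in peaks.columns:
        peaks = peaks[peaks["outcome"].isin(["go_correct", "nogo_correct"])]
        peaks = peaks.reset_index(drop=True)
    return peaks


def power_ratio(peaks_nogo: pd.DataFrame, peaks_go: pd.DataFrame,
                bands: tuple[str, ...] | None = None,
                n_bootstrap: int = 2000, go_floor: float = 0.05,
                seed: int = 0) -> pd.DataFrame:
    """No-Go/Go ratio of mean band-power peaks, with a bootstrap 95% CI.

    The ratio is the ratio of condition means (not the mean of per-trial
    ratios).  Because the peaks are z-scores the Go mean can be near zero
    or negative; bands whose Go mean is below ``go_floor`` are flagged
    undefined (ratio NaN) rather than reported as unstable numbers.
    """
    if bands is None:
        bands = tuple(k for k in DEFAULT_BANDS if k in peaks_nogo.columns)
    if len(peaks_nogo) == 0 or len(peaks_go) == 0:
        raise ValueError("both condition peak sets must be nonempty")
    rng = np.random.default_rng(seed)
    rows = []
    for band in bands:
        x_n = peaks_nogo[band].to_numpy(float)
        x_g = peaks_go[band].to_numpy(float)
        mean_n, mean_g = x_n.mean(), x_g.mean()
        defined = mean_g > go_floor
        if not defined:
            logger.warning("band %s: Go mean %.3f below floor %.3f — ratio "
                           "undefined", band, mean_g, go_floor)
            rows.append(dict(band=band, ratio=np.nan, ci_low=np.nan,
                             ci_high=np.nan, mean_nogo=mean_n,
                             mean_go=mean_g, n_nogo=x_n.size, n_go=x_g.size,
                             defined=False))
            continue
        boots = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            bn = x_n[rng.integers(x_n.size, size=x_n.size)].mean()
            bg = x_g[rng.integers(x_g.size, size=x_g.size)].mean()
            boots[b] = bn / bg if bg > go_floor else np.nan
        lo, hi = np.nanpercentile(boots, [2.5, 97.5])
        rows.append(dict(band=band, ratio=mean_n / mean_g, ci_low=lo,
                         ci_high=hi, mean_nogo=mean_n, mean_go=mean_g,
                         n_nogo=x_n.size, n_go=x_g.size, defined=True))
    return pd.DataFrame(rows).set_index("band")
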