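"""In-memory containers shared across the pipeline stages.

A :class:`RecordingSession` holds a continuous multichannel intracranial
recording together with per-channel anatomy (region-of-interest label and
hemisphere) and the behavioral event table of one Go/No-Go run.  An
:class:`EpochSet` holds the cue-locked trials x channels x time array cut
around the visual cues, with per-trial condition/outcome labels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: canonical cue types
GO = "go"
NOGO = "nogo"

#: the four behavioral outcome categories
OUTCOMES = ("go_correct", "go_wrong", "nogo_correct", "nogo_wrong")

#: event-table columns required by the pipeline
EVENT_COLUMNS = ("onset_sample", "cue_type", "response", "latency_s")

#: channel-metadata columns required by the pipeline
CHANNEL_COLUMNS = ("name", "roi", "hemisphere")


@dataclass
class RecordingSession:
    """Continuous multichannel recording with channel metadata and events.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Voltage trace in microvolts.
    sampling_rate : float
        Sampling rate in Hz.
    channels : DataFrame
        One row per channel with at least ``name``, ``roi`` (one of
        ``{"ifg", "motor", "other"}``) and ``hemisphere`` (``{"left",
        "right"}``).
    events : DataFrame
        One row per trial with at least ``onset_sample`` (cue onset, in
        samples), ``cue_type`` (``go``/``nogo``), ``response`` (bool) and
        ``latency_s`` (seconds, NaN when no response).
    """

    signal: np.ndarray
    sampling_rate: float
    channels: pd.DataFrame
    events: pd.DataFrame

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if not np.isfinite(self.signal).all():
            raise ValueError("signal contains NaN/Inf samples")
        if len(self.channels) != self.signal.shape[0]:
            raise ValueError(
                f"channel metadata has {len(self.channels)} rows for "
                f"{self.signal.shape[0]} signal channels"
            )
        missing = [c for c in CHANNEL_COLUMNS if c not in self.channels.columns]
        if missing:
            raise ValueError(f"channel metadata missing columns: {missing}")
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.sampling_rate

    def copy_with(self, **kwargs) -> "RecordingSession":
        """Return a shallow-copied session with some fields replaced."""
        return replace(self, **kwargs)


@dataclass
class EpochSet:
    """Cue-locked trials cut from a continuous recording.

    ``data`` has shape (n_trials, n_channels, n_times); ``times`` is the
    common time axis in seconds relative to the cue (cue at 0, baseline =
    [window[0], 0)).  ``labels`` carries one row per retained trial with the
    cue type and, once classified, the outcome category.
    """

    data: np.ndarray
    times: np.ndarray
    sampling_rate: float
    labels: pd.DataFrame
    channels: pd.DataFrame
    window: tuple[float, float] = (-1.0, 1.0)
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials x channels x time)")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis length does not match data")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("labels must have one row per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def baseline_mask(self) -> np.ndarray:
        """Boolean mask of baseline samples (t < 0)."""
        return self.times < 0.0

    @property
    def postcue_mask(self) -> np.ndarray:
        """Boolean mask of the first post-cue second (0 <= t < 1)."""
        return (self.times >= 0.0) & (self.times < 1.0)

    def trials_of(self, outcome: str) -> np.ndarray:
        """Indices of trials with the given outcome label."""
        if "outcome" not in self.labels.columns:
            raise ValueError("trials are not classified yet (no 'outcome' column)")
        return np.flatnonzero((self.labels["outcome"] == outcome).to_numpy())

    def copy_with(self, **kwargs) -> "EpochSet":
        return replace(self, **kwargs)
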