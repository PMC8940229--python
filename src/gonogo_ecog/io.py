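"""Readers and writers: HDF5 sessions/epochs, BIDS-style events TSV.

HDF5 is the lossless session container (signal in microvolts + channel
metadata + sampling rate); events travel as a tab-separated file with
columns ``onset_sample, cue_type, response, latency_s`` (plus ``outcome``
once classified).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import CHANNEL_COLUMNS, EVENT_COLUMNS, EpochSet, RecordingSession

__all__ = ["write_events_tsv", "read_events_tsv", "write_session",
           "read_session", "write_epochs", "read_epochs"]


def write_events_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t", na_values=["n/a"])
    missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
    if missing:
        raise ValueError(f"events file {path} missing columns: {missing}")
    ev["response"] = ev["response"].astype(bool)
    return ev


def _write_str_dataset(grp: h5py.Group, name: str, values) -> None:
    grp.create_dataset(name, data=np.asarray(values, dtype=object),
                       dtype=h5py.string_dtype())


def write_session(session: RecordingSession, signal_path, events_path=None) -> None:
    """Write the continuous signal + channel metadata to HDF5 (and the
    event table to TSV when ``events_path`` is given)."""
    with h5py.File(signal_path, "w") as f:
        f.create_dataset("signal", data=session.signal)
        f.attrs["sampling_rate"] = session.sampling_rate
        g = f.create_group("channels")
        for col in CHANNEL_COLUMNS:
            _write_str_dataset(g, col, session.channels[col].astype(str))
    if events_path is not None:
        write_events_tsv(session.events, events_path)


def read_session(signal_path, events_path, margin_s: float = 1.0) -> RecordingSession:
    """Load and validate a session from HDF5 + events TSV.

    Validation: channel metadata complete, no NaNs in the signal, and every
    cue onset at least ``margin_s`` away from both recording edges (the
    epoch window must fit).  Violations raise with the offending row named.
    """
    with h5py.File(signal_path, "r") as f:
        signal = f["signal"][()]
        fs = float(f.attrs["sampling_rate"])
        cols = {}
        for col in CHANNEL_COLUMNS:
            if col not in f["channels"]:
                raise ValueError(f"channel metadata missing field '{col}'")
            cols[col] = [v.decode() if isinstance(v, bytes) else str(v)
                         for v in f["channels"][col][()]]
    channels = pd.DataFrame(cols)
    events = read_events_tsv(events_path)
    margin = int(margin_s * fs)
    n = signal.shape[1]
    bad = events.index[(events["onset_sample"] < margin) |
                       (events["onset_sample"] > n - margin)]
    if len(bad):
        raise ValueError(
            f"event rows {list(bad)} have onsets outside the valid range "
            f"[{margin}, {n - margin}] of {signal_path}")
    return RecordingSession(signal, fs, channels, events)


def write_epochs(epochs: EpochSet, path) -> None:
    """Write an EpochSet (data + axes + labels) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.attrs["sampling_rate"] = epochs.sampling_rate
        f.attrs["normalized"] = epochs.normalized
        f.attrs["window"] = epochs.window
        g = f.create_group("channels")
        for col in CHANNEL_COLUMNS:
            _write_str_dataset(g, col, epochs.channels[col].astype(str))
        g = f.create_group("labels")
        for col in epochs.labels.columns:
            vals = epochs.labels[col]
            if vals.dtype == object:
                _write_str_dataset(g, col, vals.astype(str))
            else:
                g.create_dataset(col, data=vals.to_numpy())


def read_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        times = f["times"][()]
        fs = float(f.attrs["sampling_rate"])
        normalized = bool(f.attrs["normalized"])
        window = tuple(float(w) for w in f.attrs["window"])
        channels = pd.DataFrame({
            col: [v.decode() if isinstance(v, bytes) else str(v)
                  for v in f["channels"][col][()]]
            for col in f["channels"]})
        labels = {}
        for col in f["labels"]:
            v = f["labels"][col][()]
            if v.dtype.kind in ("S", "O"):
                v = [s.decode() if isinstance(s, bytes) else str(s) for s in v]
            labels[col] = v
    return EpochSet(data=data, times=times, sampling_rate=fs,
                    labels=pd.DataFrame(labels), channels=channels,
                    window=window, normalized=normalized)
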