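"""Run-level configuration with YAML round-trip.

Every default matches the recording/analysis parameters of the protocol
the package implements: 1.2 kHz sampling, notches at 60/120/180 Hz,
4th-order zero-phase Butterworth bands, 2 s epochs around the cue, 3 Hz
wavelet steps, 5 ms STFT hop, 1,000 permutation shuffles at alpha 0.05.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["PipelineConfig"]


def _as_tuple(v):
    if isinstance(v, (list, tuple)):
        return tuple(_as_tuple(x) for x in v)
    return v


@dataclass(frozen=True)
class PipelineConfig:
    sampling_rate: float = 1200.0
    notch_freqs: tuple = (60.0, 120.0, 180.0)
    notch_q: float = 30.0
    hg_band: tuple = (70.0, 200.0)
    bands: tuple = (("theta", (4.0, 8.0)),
                    ("beta", (12.0, 40.0)),
                    ("hg", (70.0, 200.0)))
    epoch_window: tuple = (-1.0, 1.0)
    ersp_window: tuple = (-2.5, 2.5)
    wavelet_freqs: tuple = (2.0, 200.0, 3.0)   # (min, max, step)
    wavelet_cycles: float = 6.0
    stft_window_s: float = 0.5
    stft_hop_s: float = 0.005
    pac_phase: tuple = (2.0, 20.0, 3.0)        # (min center, max center, step)
    pac_amp: tuple = (40.0, 200.0, 20.0, 10.0)  # (min, max, width, hop)
    n_shuffles: int = 1000
    alpha: float = 0.05
    n_bootstrap: int = 2000
    go_mean_floor: float = 0.05
    seed: int = 0

    def bands_dict(self) -> dict:
        return {name: tuple(b) for name, b in self.bands}

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: _to_plain(v) for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: _as_tuple(v) for k, v in d.items()})

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        try:
            text = open(source).read()
        except (OSError, TypeError):
            text = source
        return cls.from_dict(yaml.safe_load(text))


def _to_plain(v):
    if isinstance(v, tuple):
        return [_to_plain(x) for x in v]
    return v
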