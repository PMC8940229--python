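"""Trial classification, high-gamma activation mapping, electrode selection.

The activation map screens electrodes: for every channel the per-trial
maximum of the z-normalized high-gamma envelope in the post-cue second is
averaged over the correct trials of each condition.  The most activated
motor channel in Go/Correct defines Cm; the most activated IFG channel in
No-Go/Correct defines Ci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GO, NOGO, EpochSet

logger = logging.getLogger(__name__)

__all__ = ["classify_trials", "hg_activation_map", "select_electrodes",
           "SelectedElectrodes"]

CONDITIONS = ("go_correct", "nogo_correct")


def classify_trials(events: pd.DataFrame) -> pd.DataFrame:
    """Assign each trial one of the four outcome categories.

    Go with a reaction -> go_correct; Go without -> go_wrong; No-Go without
    a reaction -> nogo_correct; No-Go with -> nogo_wrong.  Adds an
    ``accuracy`` attribute-style column-free scalar via ``.attrs``.
    """
    if "response" not in events.columns or events["response"].isna().any():
        raise ValueError("every event needs a response flag")
    out = events.copy()
    is_go = out["cue_type"] == GO
    resp = out["response"].astype(bool)
    outcome = np.where(
        is_go, np.where(resp, "go_correct", "go_wrong"),
        np.where(resp, "nogo_wrong", "nogo_correct"))
    out["outcome"] = outcome
    correct = np.char.endswith(outcome.astype(str), "_correct")
    out.attrs["accuracy"] = float(correct.mean())
    return out


def hg_activation_map(epochs: EpochSet) -> pd.DataFrame:
    """Per-electrode, per-condition activation scalars.

    ``activation[e, c]`` = mean over the correct trials of condition c of
    the maximum of the z-normalized high-gamma envelope over the post-cue
    second [0, 1 s).  Conditions with zero correct trials yield NaN.
    """
    if not epochs.normalized:
        raise ValueError("activation mapping expects z-normalized envelopes")
    post = epochs.data[..., epochs.postcue_mask]  # trials x ch x t
    peaks = post.max(axis=-1)                     # trials x ch
    out = {"name": epochs.channels["name"].to_numpy(),
           "roi": epochs.channels["roi"].to_numpy(),
           "hemisphere": epochs.channels["hemisphere"].to_numpy()}
    for cond in CONDITIONS:
        idx = epochs.trials_of(cond)
        if idx.size == 0:
            logger.warning("no correct trials for condition %s", cond)
            out[cond] = np.full(epochs.channels.shape[0], np.nan)
        else:
            out[cond] = peaks[idx].mean(axis=0)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class SelectedElectrodes:
    """Indices (rows of the activation map) of the representative motor
    (Cm) and IFG (Ci) electrodes."""
    cm: int
    ci: int


def _argmax_roi(amap: pd.DataFrame, roi: str, condition: str) -> int:
    rows = amap.index[amap["roi"] == roi]
    if rows.empty:
        raise ValueError(f"no channels labeled '{roi}' — cannot select an "
                         f"electrode for that region")
    vals = amap.loc[rows, condition]
    if vals.isna().all():
        raise ValueError(f"activation undefined for all '{roi}' channels")
    best = vals.max()
    winners = rows[(vals == best).to_numpy()]
    if len(winners) > 1:
        logger.warning("activation tie in roi=%s (%s); choosing lowest "
                       "channel index %d", roi, list(winners), winners[0])
    return int(winners[0])


def select_electrodes(amap: pd.DataFrame) -> SelectedElectrodes:
    """Cm = most Go/Correct-activated motor channel; Ci = most
    No-Go/Correct-activated IFG channel.  Ties go to the lowest index."""
    return SelectedElectrodes(
        cm=_argmax_roi(amap, "motor", "go_correct"),
        ci=_argmax_roi(amap, "ifg", "nogo_correct"),
    )
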