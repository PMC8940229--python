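"""Simple per-electrode and comodulogram plots (no brain surface)."""

from __future__ import annotations

import numpy as np


def activation_bars(amap, ax=None):
    """Grouped bar plot of Go/Correct and No-Go/Correct activation per
    electrode, annotated by ROI."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    x = np.arange(len(amap))
    ax.bar(x - 0.2, amap["go_correct"], width=0.4, label="Go/Correct")
    ax.bar(x + 0.2, amap["nogo_correct"], width=0.4, label="No-Go/Correct")
    ax.set_xticks(x)
    ax.set_xticklabels([f"{n}\n{r}" for n, r in zip(amap["name"], amap["roi"])],
                       fontsize=7)
    ax.set_ylabel("HG activation (z)")
    ax.legend(frameon=False)
    return ax


def comodulogram(grid, ax=None, zeroed: bool = False):
    """Heat map of a PAC grid (phase bins x amplitude bins)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    vals = grid.zeroed if zeroed else grid.values
    pc = [0.5 * (a + b) for a, b in grid.phase_bins]
    ac = [0.5 * (a + b) for a, b in grid.amp_bins]
    im = ax.pcolormesh(pc, ac, vals.T, shading="nearest", cmap="viridis")
    ax.set_xlabel("phase frequency (Hz)")
    ax.set_ylabel("amplitude frequency (Hz)")
    ax.set_title(f"MI — {grid.condition}")
    ax.figure.colorbar(im, ax=ax, label="modulation index")
    return ax


def ersp_map(ersp, ax=None, vmax=None):
    """Heat map of an ERSP matrix (frequency x time, z-scored power)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    vmax = vmax or np.nanmax(np.abs(ersp.values))
    im = ax.pcolormesh(ersp.times, ersp.freqs, ersp.values, cmap="RdBu_r",
                       vmin=-vmax, vmax=vmax, shading="nearest")
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("time from cue (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(f"ERSP — {ersp.condition}")
    ax.figure.colorbar(im, ax=ax, label="power (z)")
    return ax
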