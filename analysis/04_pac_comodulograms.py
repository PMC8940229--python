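#!/usr/bin/env python
"""Theta-gamma phase-amplitude coupling on Ci for one representative
subject.

Computes the modulation-index comodulogram (phase 2-20 Hz every 3 Hz,
amplitude 40-200 Hz in 20 Hz bins) for Go/Correct and No-Go/Correct,
masks it with a 200-shuffle trial-permutation test at alpha = 0.05, and
forms the No-Go/Go ratio map over defined cells.  Writes
results/pac_bins.tsv and a comodulogram figure to scratch/.
"""

from pathlib import Path

import matplotlib
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from gonogo_ecog.config import PipelineConfig
from gonogo_ecog.pipeline import analyze_session
from gonogo_ecog.plots import comodulogram
from gonogo_ecog.simulate import SimConfig, SubjectProfile, TaskConfig, simulate_session

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = PipelineConfig(n_shuffles=200)
    profile = SubjectProfile("s1", 11, "right", ("left",), 0.93)
    session, truth = simulate_session(profile, TaskConfig(), SimConfig(), SEED)
    res = analyze_session(session, cfg, seed=SEED, run_pac=True)
    grids = res["pac_grids"]
    ratio = res["pac_ratio"]

    rows = []
    for i, pb in enumerate(ratio.phase_bins):
        for j, ab in enumerate(ratio.amp_bins):
            rows.append(dict(
                phase_lo=pb[0], phase_hi=pb[1], amp_lo=ab[0], amp_hi=ab[1],
                mi_go=grids["go_correct"].values[i, j],
                mi_nogo=grids["nogo_correct"].values[i, j],
                sig_go=bool(grids["go_correct"].mask[i, j]),
                sig_nogo=bool(grids["nogo_correct"].mask[i, j]),
                ratio=ratio.values[i, j]))
    pd.DataFrame(rows).to_csv(ROOT / "results" / "pac_bins.tsv", sep="\t",
                              index=False, float_format="%.5g")

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, cond in zip(axes, ("go_correct", "nogo_correct")):
        comodulogram(grids[cond], ax=ax, zeroed=True)
    fig.tight_layout()
    fig.savefig(ROOT / "scratch" / "comodulograms.png", dpi=120)

    n_sig = {c: int(g.mask.sum()) for c, g in grids.items()}
    print(f"significant bins: Go {n_sig['go_correct']}/105, "
          f"No-Go {n_sig['nogo_correct']}/105 — most bins are zeroed, as "
          "expected under sparse coupling.")
    print(f"defined-cell median No-Go/Go MI ratio: "
          f"{ratio.median_defined:.2f} (> 1: coupling deeper when the "
          "response is withheld; injected depths were 0.6 vs 0.2).")


if __name__ == "__main__":
    main()
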