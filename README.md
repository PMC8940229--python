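# gonogo-ecog

Analysis pipeline for pediatric Go/No-Go motor-inhibition experiments
recorded with subdural electrocorticography (ECoG), together with a
synthetic cohort generator that makes every stage testable against known
ground truth.

Response inhibition — withholding a prepotent action on a rare No-Go cue —
engages the inferior frontal gyrus (IFG). In children, this engagement is
bilateral and shifts toward the right IFG with age. The pipeline
quantifies that picture from continuous multichannel recordings of a
Go/No-Go task (49 trials per run at a 1:6 No-Go:Go ratio, 1.2 kHz):

1. **Preprocessing** — common-average rereference within the grid, notch
   filters at 60/120/180 Hz, high-gamma (HG, 70–200 Hz) Hilbert envelopes
   from 4th-order zero-phase Butterworth filters, epochs from 1 s before
   to 1 s after each visual cue, z-normalized to the pre-cue baseline.
2. **Activation mapping** — trials are classified Go-correct / Go-wrong /
   No-Go-correct / No-Go-wrong; each electrode gets an activation scalar
   (mean over correct trials of the per-trial post-cue envelope maximum);
   the most Go-activated motor electrode (*Cm*) and most No-Go-activated
   IFG electrode (*Ci*) are selected.
3. **Spectral power** — Morlet-wavelet event-related spectral perturbation
   (2–200 Hz in 3 Hz steps) and STFT band-power peaks (theta 4–8, beta
   12–40, HG 70–200 Hz; 500 ms Hann frames hopped every 5 ms), summarized
   per band as the power ratio

   ```
   power ratio = mean(No-Go/Correct peaks) / mean(Go/Correct peaks)
   ```

4. **Phase–amplitude coupling (PAC)** — the composite-signal modulation
   index over *Ci*,

   ```
   MI = | <A_high(t) · exp(i·φ_low(t))> |
   ```

   on a comodulogram of low-frequency phase (2–20 Hz, every 3 Hz) by
   high-frequency amplitude bins (40–200 Hz), with a trial-permutation
   significance test (1,000 shuffles, α = 0.05); non-significant bins are
   zeroed and conditions compared as an elementwise No-Go/Go ratio map.
   For an envelope `A = 1 + m·cos(φ)` the MI equals `m/2`, which anchors
   the estimator tests.
5. **Group statistics** — No-Go vs Go band-power comparison per hemisphere
   with Tukey–Kramer correction (group sizes are unequal by design), and
   Spearman rank correlations of per-subject ratios against age.

Clinical recordings of this kind are not publicly distributable, so the
package ships a first-class generator (`gonogo_ecog.simulate`) producing
1/f background plus line noise, movement-locked motor HG bursts for the
contralateral hand, condition-dependent theta/beta/HG responses on IFG
channels, theta-phase-modulated HG amplitude with a larger modulation
depth in No-Go, and a logistic age-dependent laterality weight that fades
the left-IFG No-Go excess. Every injected value is returned as
`GroundTruth` for recovery tests.

## Worked example

```python
from gonogo_ecog.config import PipelineConfig
from gonogo_ecog.pipeline import analyze_session
from gonogo_ecog.simulate import SimConfig, SubjectProfile, TaskConfig, simulate_session

profile = SubjectProfile("s1", age=11, grid_side="right",
                         hands_tested=("left",), behavioral_accuracy=0.93)
session, truth = simulate_session(profile, TaskConfig(), SimConfig(), seed=1)
res = analyze_session(session, PipelineConfig(n_shuffles=200), seed=1)
print(res["power_ratios"]["ratio"])
print(f"PAC ratio median: {res['pac_ratio'].median_defined:.2f}")
```

prints

```
band
theta    3.752631
beta     3.822155
hg       4.273283
Name: ratio, dtype: float64
PAC ratio median: 2.16
```

All three band ratios exceed 1 — the No-Go responses injected on the IFG
channel (twice the Go gains in this run) are recovered through electrode
selection and the z-scored STFT peaks — and the defined-cell median of
the masked PAC ratio map is ≈ 2, reflecting the deeper injected No-Go
coupling (0.6 vs 0.2).

The numbered scripts under `analysis/` walk the full study on the default
8-subject cohort (simulation → activation mapping → band-power ratios →
PAC → group statistics) and write their tables under `results/`. On the
default cohort the right-IFG theta and HG No-Go excesses are significant
after Tukey–Kramer correction, while the left-IFG HG and PAC ratios
decline monotonically with age (Spearman ρ = −1.0 and −0.95) — the
bilateral-to-right developmental pattern the generator encodes.

A CLI mirrors the stages: `gonogo-ecog simulate | preprocess | activate |
power | pac | group | run-all` (see `--help`).

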