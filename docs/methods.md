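# Methods

This note records the models, estimators and numerical choices behind the
package, what the synthetic cohort does and does not emulate, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Task and recording model

A run is 49 trials at a 1:6 No-Go:Go ratio. Cue order is a uniform random
permutation; the intertrial interval is Uniform(0.75 s, 1.25 s) — a
symmetric, bounded reading of a "1 s jittered" interval — and the cue is
displayed for 1 s, so consecutive cues are 1.75–2.25 s apart. Responses
are Bernoulli per cue type with the subject's accuracy; latencies are
Normal(0.45 s, 0.1 s) clipped to [0.15, 0.95] s, so every response falls
inside the 1 s post-cue analysis window. Outcomes follow the four-way
classification (Go-correct = cue + reaction, No-Go-correct = cue + no
reaction, and their complements).

Signals are synthesized at 1.2 kHz on a 16-channel strip (2 motor-labeled
and 2 IFG-labeled channels by default; one primary injection site per
region plus a 0.4-weight secondary site so that electrode *selection*,
not just region labeling, is tested).

### Signal components

* **Background**: Gaussian 1/f^α noise (α = 2 by default) via spectral
  shaping, scaled to 5 µV RMS. The shaping is normalized by the
  *expected* (Parseval) standard deviation rather than each
  realization's: with a steep spectrum the realized total variance is
  dominated by the lowest one or two frequency bins, and normalizing by
  it would multiply every other band by a ±40% random factor per channel,
  which in turn makes baseline z-scores channel-dependent for no
  physiological reason.
* **Line noise**: sinusoids at 60/120/180 Hz (2/1/0.5 µV) with random
  phase per channel.
* **Motor burst**: on Go trials with an executed response and only when
  the tested hand is contralateral to the grid, band-limited 70–200 Hz
  noise (8 µV RMS, Tukey window, 0.15–0.75 s post-cue) on motor channels.
* **IFG response**: on every trial, scaled by condition — a coherent
  6 Hz theta oscillation (carrying the coupling phase), beta band noise
  (12–40 Hz), and a 100–120 Hz high-gamma carrier whose envelope is
  modulated as `A(t) = gain · (1 + m·cos φ_theta(t))` with the
  condition's coupling depth m (defaults 0.2 Go, 0.6 No-Go). Default
  band gains (µV RMS, Go → No-Go): theta 3 → 6, beta 1.5 → 1.8
  (deliberately small, mirroring the observation that the beta contrast
  is weak), HG 1.5 → 3.
* **Burst support**: IFG components span 0–0.75 s post-cue with smooth
  Tukey(α = 0.5) ramps. Both numbers matter. The burst must end by
  +0.75 s because the next trial's pre-cue baseline can begin there at
  the shortest intertrial interval; a burst that bleeds into baselines
  inflates each channel's baseline SD in proportion to its own gain,
  which cancels the gain out of the z-scored activation map. Sharp ramps
  are avoided because an envelope transient is itself a broadband,
  trial-locked event: with short ramps we measured genuine (structured,
  up to 25% per-bin rejection) phase–amplitude dependence at the burst
  bins even with zero injected coupling — the familiar evoked-response
  PAC confound, here visible with ground truth.
* **Laterality**: a logistic weight w(age) centered at 12 years with a
  2-year slope multiplies the *left*-IFG No-Go excess (band gains and
  coupling depth) by (1 − w); right-IFG effects are age-independent.
  The center/slope are free parameters of the generator; the source
  observations are qualitative (a bilateral-to-right shift over ages
  7–16), so the default places the midpoint inside that range.

What the generator does **not** emulate: cortical geometry and volume
conduction, epileptiform activity, eye/EMG artifacts, behavioral
response variability beyond Bernoulli accuracy, and any coupling between
neighboring channels beyond the common-average reference. Passing tests
therefore demonstrate correctness of the estimators under the stated
statistical structure, not robustness to clinical artifacts.

## Preprocessing

Order is common-average reference, then notch. CAR is the per-sample mean
across the grid; notch filters are second-order IIR (Q = 30) applied
forward–backward at 60/120/180 Hz. Band filters are 4th-order Butterworth
applied with `sosfiltfilt` (zero-phase, default odd-reflection padding);
envelopes and phases come from the Hilbert analytic signal computed at an
FFT-fast length. Epochs are half-open [−1, +1) s around the cue (the cue
sample belongs to the post-cue side); trials whose window exceeds the
recording are dropped with a logged warning.

Baseline z-normalization pools the mean and SD over all trials' pre-cue
seconds per channel (and per frequency for spectral data). Pooling keeps
σ stable with only 7 No-Go trials per run; a per-trial mode exists behind
a flag. A degenerate (zero-variance) baseline raises rather than returns
infinities.

## Activation mapping and electrode selection

Activation is computed only from correct trials: per electrode and
condition, the mean over trials of the maximum z-scored HG envelope in
[0, 1) s. Motor electrodes are ranked by Go/Correct, IFG electrodes by
No-Go/Correct (the pairing implied by how the screening is used); ties
break to the lowest channel index with a logged warning; an absent ROI
raises an error naming the region. The spatial Gaussian smoothing used in
brain-surface figures is visualization-only and intentionally not part of
selection; the package plots simple per-electrode bars instead.

## Spectral power

The ERSP uses 6-cycle Morlet wavelets (mne's `tfr_array_morlet`) at 2–200
Hz in 3 Hz steps. The 2 Hz wavelet spans ~4.8 s at mne's 5-SD support, so
ERSP epochs are cut at ±2.5 s and cropped to ±1 s after the transform;
power is z-scored per frequency against the pooled baseline of all
correct trials (one common reference for both conditions), then averaged
within condition.

Band power uses an STFT with a 500 ms Hann window hopped every 5 ms. The
5 ms figure is read as the hop: a literal 5 ms analysis window cannot
resolve 4–8 Hz theta. Both window and hop are configurable. Frames are
z-scored per band against pooled baseline frames whose centers lie fully
inside the epoch; the per-trial statistic is the maximum over the 200
frames centered in [0, 1) s.

The power ratio is the ratio of condition means (not a mean of ratios),
with a 2,000-resample percentile bootstrap CI. Because peaks are
z-scores, the Go mean can approach zero; ratios with a Go mean below a
0.05 floor are flagged undefined instead of reported.

## Phase–amplitude coupling

The modulation index is the modulus of the time-averaged composite signal
`A_high(t)·e^{iφ_low(t)}`, with the envelope normalized by its own window
mean so MI reads as a relative modulation depth (a raw-envelope mode is
available). For sinusoidal modulation of depth m the analytic value is
m/2; the estimator is validated against that closed form at m ∈ {0, 0.2,
0.4, 0.5, 1} on 100 s traces.

Two estimator-level choices deserve emphasis, both adopted after
measuring the alternatives on ground-truth data:

* **Modulus after the cross-trial average.** z(t) is averaged over each
  trial's post-cue second; the per-trial complex means are averaged
  across trials and the modulus is taken last (equivalently, the
  composite-signal estimator on the pooled task samples). Averaging
  per-trial *magnitudes* instead is provably invariant under any time
  shift of a periodically modulated envelope, which leaves a shift-based
  or re-pairing-based surrogate test with no power at exactly the
  coupled bins.
* **Trial-permutation surrogates.** Each of the 1,000 shuffles re-pairs
  the trials' phase windows with a random permutation of the trials'
  amplitude windows. Every surrogate window is therefore still
  cue-locked, so the null reproduces the evoked envelope nonstationarity
  of the observed statistic exactly, and the test is exact under trial
  exchangeability. Surrogates that slide the envelope to arbitrary
  recording positions understate the variance of cue-locked windows and
  mis-size the test on event-locked data (measured directly: spurious
  Go-condition detections at evoked-envelope bins). Significance uses
  the exact empirical p-value (1 + #{null ≥ obs})/(S + 1) ≤ α, which
  avoids the anticonservatism of an interpolated 95th percentile at a
  few hundred shuffles.

The comodulogram covers phase bins centered 2–20 Hz every 3 Hz (each
3 Hz wide; the slowest bin is floored at 0.25 Hz) by amplitude bins
40–200 Hz, 20 Hz wide with a 10 Hz hop — the amplitude-bin geometry is a
package choice at modest resolution and fully configurable. Low-frequency
filtering is done once on the continuous channel (a 1 s epoch cannot
support a 0.5 Hz band edge) and cut into post-cue windows afterwards.
Non-significant bins are zeroed; the condition contrast is the
elementwise No-Go/Go ratio of the zeroed grids, with cells undefined
where the Go grid is zero. Interpretation caveats: the slowest phase bin
holds under two cycles per window and carries a visible finite-sample
bias (the permutation null absorbs it), and the strong injected theta
leaks through filter skirts into adjacent phase bins, so coupling
detected in a neighboring bin of the true one is expected behavior.

## Group statistics

For the cross-patient comparison, trials are pooled across patients
within (hemisphere × band × condition); all such cells form one one-way
layout with pooled within-group variance (MSE, df = N − k), and each
No-Go-vs-Go pair is referred to the studentized range with the family's
group count — the Tukey–Kramer procedure, valid for the unequal group
sizes the 1:6 design guarantees. The implementation is cross-checked in
the tests against statsmodels' `pairwise_tukeyhsd` on the same layout,
and a plain Welch t-test is reported alongside. A per-patient-mean
pooling mode was considered and rejected as the default because 7 No-Go
trials per patient make patient means unstable; the pooled mode matches
how the cross-patient box plots are constructed.

Age trends are quantified as Spearman rank correlations of per-patient
ratios against age — a deliberate quantification of a qualitative
observation, chosen because it is rank-based and meaningful at n = 8
(n = 4 per hemisphere); it requires at least 4 patients and flags
constant inputs rather than dividing by zero.

## Pipeline, formats, reproducibility

Sessions travel as HDF5 (float64 signal in µV, sampling rate, channel
name/ROI/hemisphere) plus a BIDS-style tab-separated event file
(`onset_sample, cue_type, response, latency_s, outcome`); epochs as HDF5
with axis metadata. EDF export is out of scope for this implementation.
The YAML run configuration round-trips losslessly and its defaults are
the protocol values (1.2 kHz, 60/120/180 Hz notches, 4th-order
Butterworth, ±1 s epochs, 3 Hz wavelet steps, 5 ms hop, 1,000 shuffles,
α = 0.05). `run_pipeline` derives all per-subject seeds from one master
seed and writes a manifest (config hash, seeds, library versions, output
hashes); identical (config, seed, cohort) runs produce byte-identical
tables.

## Validation problem sizes

The end-to-end suite runs on one CPU with deliberately compact problem
sizes: band-ratio and PAC-ratio checks on single 49-trial sessions at
200 permutation shuffles; permutation calibration pooled over 20
background-only sessions × 2 conditions × 105 bins; the group pattern on
the full 8-subject cohort; electrode-recovery over 30 seeds of 28-trial,
6-channel sessions; the left-IFG age trend over 20 seeds of 8-subject,
35-trial, 4-channel left-grid cohorts. Rate thresholds (≥95% recovery,
≥90% negative trends, α plus a session-level Monte-Carlo margin) are
asserted at these sizes.

## Known limitations

* The permutation test treats trials as exchangeable; slow drifts that
  correlate neighboring trials would make it anticonservative.
* Evoked-response PAC is a genuine property of event-locked data that
  the test will (correctly) flag; distinguishing it from oscillatory
  coupling requires designs outside this package's scope.
* The Morlet ERSP inherits edge effects below ~4 Hz even with ±2.5 s
  padding.
* With 7 No-Go trials per run, all No-Go-side estimates are noisy by
  construction; the defaults compensate with strong injected effects,
  so absolute power at weaker, more realistic effect sizes should be
  established separately before interpreting null results.
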