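"""Synthetic Go/No-Go ECoG cohort generator.

Builds task runs, behavioral responses and multichannel surface recordings
carrying the statistical structure the downstream analysis assumes:

* 1/f^alpha background noise plus 60/120/180 Hz line interference,
* a high-gamma burst on the motor-strip channel contralateral to the hand
  used, on Go trials with an executed response,
* condition-dependent theta / beta / high-gamma responses on inferior
  frontal gyrus (IFG) channels, larger for No-Go than Go,
* theta-phase-modulated high-gamma amplitude (phase-amplitude coupling)
  on the IFG channels, with a larger modulation depth in No-Go trials,
* an age-dependent laterality weight that fades the *left*-IFG No-Go
  excess with age while the right-IFG effect persists, emulating the
  bilateral-to-right developmental shift of response inhibition.

Every injected quantity is recorded in a :class:`GroundTruth` object so
recovery tests can compare estimates against what was put in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import GO, NOGO, RecordingSession

__all__ = [
    "TaskConfig",
    "SubjectProfile",
    "SimConfig",
    "GroundTruth",
    "generate_task_sequence",
    "simulate_behavior",
    "simulate_session",
    "simulate_cohort",
    "default_cohort_profiles",
    "generate_pac_trace",
    "laterality_weight",
    "one_over_f_noise",
]


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskConfig:
    """Go/No-Go run structure.

    Defaults follow the pediatric-optimized paradigm: 49 trials per run at
    a 1:6 No-Go:Go ratio with a 1 s jittered intertrial interval.  The
    jitter is Uniform(iti_mean - halfwidth, iti_mean + halfwidth).
    """

    n_trials: int = 49
    nogo_go_ratio: tuple[int, int] = (1, 6)
    cue_duration: float = 1.0
    iti_mean: float = 1.0
    iti_jitter_halfwidth: float = 0.25
    allow_rounding: bool = False

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if min(self.nogo_go_ratio) <= 0:
            raise ValueError("ratio counts must be positive")
        if self.iti_mean - self.iti_jitter_halfwidth <= 0:
            raise ValueError("iti_mean - jitter halfwidth must be positive")

    def trial_counts(self) -> tuple[int, int]:
        """(n_nogo, n_go) implied by the ratio; error when indivisible."""
        r_nogo, r_go = self.nogo_go_ratio
        total = r_nogo + r_go
        if self.n_trials % total:
            if not self.allow_rounding:
                raise ValueError(
                    f"{self.n_trials} trials are not divisible by the "
                    f"{r_nogo}:{r_go} ratio; set allow_rounding=True to round"
                )
            n_nogo = int(round(self.n_trials * r_nogo / total))
        else:
            n_nogo = self.n_trials * r_nogo // total
        return n_nogo, self.n_trials - n_nogo


@dataclass(frozen=True)
class SubjectProfile:
    """One synthetic patient: age, implanted side, hands tested, accuracy.

    ``behavioral_accuracy`` is the probability of a correct outcome per cue
    type; a single float applies to both cue types.
    """

    subject_id: str
    age: float
    grid_side: str = "right"
    hands_tested: tuple[str, ...] = ("right",)
    behavioral_accuracy: float | dict = 0.9

    def __post_init__(self) -> None:
        if self.grid_side not in ("left", "right"):
            raise ValueError("grid_side must be 'left' or 'right'")
        acc = self.accuracy_by_cue()
        for cue, p in acc.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"accuracy for {cue} outside [0, 1]")

    def accuracy_by_cue(self) -> dict:
        if isinstance(self.behavioral_accuracy, dict):
            return {GO: float(self.behavioral_accuracy[GO]),
                    NOGO: float(self.behavioral_accuracy[NOGO])}
        p = float(self.behavioral_accuracy)
        return {GO: p, NOGO: p}


def _default_rois(n_channels: int) -> tuple[str, ...]:
    """2 x 8 strip layout: two motor, two IFG, the rest unlabeled cortex."""
    rois = ["other"] * n_channels
    rois[0], rois[1] = "motor", "motor"
    rois[2], rois[3] = "ifg", "ifg"
    return tuple(rois)


def _default_weights(n_channels: int) -> tuple[float, ...]:
    """Injection weight per channel; the first channel of each ROI is the
    primary (ground-truth Cm/Ci) site, the second a weaker secondary site."""
    w = [0.0] * n_channels
    w[0], w[1] = 1.0, 0.4
    w[2], w[3] = 1.0, 0.4
    return tuple(w)


@dataclass(frozen=True)
class SimConfig:
    """Signal-generation parameters.

    Band gains are RMS amplitudes in microvolts of the injected burst
    components; ``pac_depth`` is the sinusoidal modulation depth m in
    [0, 1] of the high-gamma envelope by theta phase, per condition.
    The laterality weight w(age) (logistic, centered at
    ``laterality_age_center``) scales the *left*-IFG No-Go excess by
    (1 - w): at w = 1 the left IFG No-Go response equals the Go baseline
    while the right IFG keeps the full effect.
    """

    sampling_rate: float = 1200.0
    n_channels: int = 16
    channel_rois: tuple[str, ...] | None = None
    roi_weights: tuple[float, ...] | None = None
    noise_exponent: float = 2.0
    noise_rms: float = 5.0
    line_noise_amplitudes: tuple[tuple[float, float], ...] = (
        (60.0, 2.0), (120.0, 1.0), (180.0, 0.5))
    hg_burst_gain_motor: float = 8.0
    band_gains_ifg: tuple[tuple[str, tuple[float, float]], ...] = (
        # band -> (Go gain, No-Go gain), microvolt RMS
        ("theta", (3.0, 6.0)),
        ("beta", (1.5, 1.8)),
        ("hg", (1.5, 3.0)),
    )
    pac_depth: tuple[float, float] = (0.2, 0.6)  # (Go, No-Go)
    # carrier centered on 110 Hz; wide enough that the coupling spans
    # several 20 Hz analysis bins, narrow enough to keep per-bin depth high
    pac_carrier_band: tuple[float, float] = (100.0, 120.0)
    theta_freq: float = 6.0
    beta_band: tuple[float, float] = (12.0, 40.0)
    motor_hg_band: tuple[float, float] = (70.0, 200.0)
    laterality_age_center: float = 12.0
    laterality_slope: float = 2.0

    def __post_init__(self) -> None:
        for m in self.pac_depth:
            if not 0.0 <= m <= 1.0:
                raise ValueError("pac_depth must lie in [0, 1]")
        if self.channel_rois is not None and len(self.channel_rois) != self.n_channels:
            raise ValueError("channel_rois length must equal n_channels")
        if self.roi_weights is not None and len(self.roi_weights) != self.n_channels:
            raise ValueError("roi_weights length must equal n_channels")

    def rois(self) -> tuple[str, ...]:
        return self.channel_rois if self.channel_rois is not None else _default_rois(self.n_channels)

    def weights(self) -> tuple[float, ...]:
        if self.roi_weights is not None:
            return self.roi_weights
        if self.channel_rois is not None:
            # first channel of each labeled ROI is the primary site
            w, seen = [], set()
            for roi in self.channel_rois:
                if roi == "other":
                    w.append(0.0)
                elif roi not in seen:
                    w.append(1.0)
                    seen.add(roi)
                else:
                    w.append(0.4)
            return tuple(w)
        return _default_weights(self.n_channels)

    def band_gains(self) -> dict:
        return {band: {GO: g[0], NOGO: g[1]} for band, g in self.band_gains_ifg}

    def pac_depths(self) -> dict:
        return {GO: self.pac_depth[0], NOGO: self.pac_depth[1]}


@dataclass
class GroundTruth:
    """Everything injected into one simulated session."""

    subject_id: str
    seed: int
    hand: str
    laterality_weight: float
    band_gains_effective: dict      # band -> condition -> microvolt RMS
    pac_depth_effective: dict       # condition -> modulation depth
    cm_channel: int                 # primary motor site (index)
    ci_channel: int                 # primary IFG site (index)
    theta_freq: float
    pac_carrier_band: tuple[float, float]
    events: pd.DataFrame = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# task schedule and behavior
# ---------------------------------------------------------------------------

def generate_task_sequence(task: TaskConfig, seed: int,
                           sampling_rate: float = 1200.0,
                           start_pad: float = 2.5) -> pd.DataFrame:
    """Randomized cue schedule for one run.

    Returns an event table with cue onsets (sample indices and seconds),
    randomized cue types honoring the No-Go:Go ratio, and intertrial
    intervals drawn uniformly from the configured jitter interval.
    """
    rng = np.random.default_rng(seed)
    n_nogo, n_go = task.trial_counts()
    cues = np.array([NOGO] * n_nogo + [GO] * n_go)
    rng.shuffle(cues)
    lo = task.iti_mean - task.iti_jitter_halfwidth
    hi = task.iti_mean + task.iti_jitter_halfwidth
    itis = rng.uniform(lo, hi, size=task.n_trials)
    onsets_s = start_pad + np.concatenate(
        [[0.0], np.cumsum(task.cue_duration + itis[:-1])])
    return pd.DataFrame({
        "trial": np.arange(task.n_trials),
        "onset_sample": np.round(onsets_s * sampling_rate).astype(int),
        "onset_s": onsets_s,
        "cue_type": cues,
        "iti_s": itis,
    })


def simulate_behavior(events: pd.DataFrame, profile: SubjectProfile,
                      seed: int) -> pd.DataFrame:
    """Attach responses, latencies and outcome labels to a cue schedule.

    Each trial is correct with probability ``behavioral_accuracy`` for its
    cue type.  Correct Go and wrong No-Go trials carry a button press with
    a latency drawn from a clipped normal around 450 ms.
    """
    if "cue_type" not in events.columns:
        raise ValueError("events must have cue types assigned")
    rng = np.random.default_rng(seed)
    acc = profile.accuracy_by_cue()
    out = events.copy()
    p = out["cue_type"].map(acc).to_numpy(dtype=float)
    correct = rng.random(len(out)) < p
    is_go = (out["cue_type"] == GO).to_numpy()
    responded = np.where(is_go, correct, ~correct)
    latency = np.clip(rng.normal(0.45, 0.1, size=len(out)), 0.15, 0.95)
    out["response"] = responded
    out["latency_s"] = np.where(responded, latency, np.nan)
    outcome = np.empty(len(out), dtype=object)
    outcome[is_go & responded] = "go_correct"
    outcome[is_go & ~responded] = "go_wrong"
    outcome[~is_go & ~responded] = "nogo_correct"
    outcome[~is_go & responded] = "nogo_wrong"
    out["outcome"] = outcome
    return out


# ---------------------------------------------------------------------------
# signal components
# ---------------------------------------------------------------------------

def one_over_f_noise(n_samples: int, exponent: float, sampling_rate: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Unit-expected-RMS Gaussian noise with power spectrum ~ 1/f^exponent.

    Synthesized by spectral shaping: white Gaussian noise is filtered in
    the frequency domain by f^(-exponent/2) (DC removed).  The output is
    scaled by the *expected* standard deviation (Parseval), not the
    realized one: with a steep spectrum the realized total variance is
    dominated by the few lowest-frequency bins, and dividing by it would
    rescale every other band by a large random factor per realization.
    """
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n_samples)
    # E[Var(x)] for unit-variance white input via Parseval on the rfft grid
    weights = np.full(freqs.size, 2.0)
    weights[0] = 1.0
    if n_samples % 2 == 0:
        weights[-1] = 1.0
    expected_sd = np.sqrt((weights * shape**2).sum() / n_samples)
    return x / expected_sd


def _band_noise(n_samples: int, band: tuple[float, float],
                sampling_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (4th-order Butterworth)."""
    sos = sps.butter(4, band, btype="bandpass", fs=sampling_rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n_samples))
    return x / x.std()


def laterality_weight(age: float, center: float = 12.0,
                      slope: float = 2.0) -> float:
    """Logistic right-lateralization weight in [0, 1], non-decreasing in age."""
    return float(1.0 / (1.0 + np.exp(-(age - center) / slope)))


def _effective_gains(sim: SimConfig, hemisphere: str, w: float) -> dict:
    """Per-band condition gains after applying the laterality weight.

    Right IFG keeps the full No-Go gain; left IFG has its No-Go excess over
    the Go baseline scaled by (1 - w).
    """
    gains = sim.band_gains()
    eff = {}
    for band, g in gains.items():
        go, nogo = g[GO], g[NOGO]
        if hemisphere == "left":
            nogo = go + (nogo - go) * (1.0 - w)
        eff[band] = {GO: go, NOGO: nogo}
    return eff


def _effective_depths(sim: SimConfig, hemisphere: str, w: float) -> dict:
    d = sim.pac_depths()
    if hemisphere == "left":
        d = {GO: d[GO], NOGO: d[GO] + (d[NOGO] - d[GO]) * (1.0 - w)}
    return d


def simulate_session(profile: SubjectProfile, task: TaskConfig,
                     sim: SimConfig, seed: int,
                     hand: str | None = None,
                     end_pad: float = 2.5):
    """Simulate one Go/No-Go run; returns ``(RecordingSession, GroundTruth)``.

    The continuous signal is 1/f background + line noise + cue-locked
    components.  The motor channels (contralateral hand only) receive a
    high-gamma burst on Go trials with an executed response; the IFG
    channels receive theta/beta/high-gamma bursts on every trial with
    condition-dependent gains, the high-gamma carrier amplitude being
    modulated by the theta phase with the condition's coupling depth.
    """
    if hand is None:
        hand = profile.hands_tested[0]
    rois = sim.rois()
    if "ifg" not in rois or "motor" not in rois:
        raise ValueError("channel metadata must label at least one 'ifg' "
                         "and one 'motor' channel")
    weights = sim.weights()
    fs = sim.sampling_rate

    rng = np.random.default_rng(seed)
    seed_task, seed_behav = rng.integers(2**31, size=2)
    events = generate_task_sequence(task, int(seed_task), fs)
    events = simulate_behavior(events, profile, int(seed_behav))

    last = events["onset_sample"].iloc[-1]
    n_samples = int(last + (task.cue_duration + end_pad) * fs)

    n_ch = sim.n_channels
    sig = np.empty((n_ch, n_samples))
    t = np.arange(n_samples) / fs
    for ch in range(n_ch):
        sig[ch] = sim.noise_rms * one_over_f_noise(
            n_samples, sim.noise_exponent, fs, rng)
        for f0, amp in sim.line_noise_amplitudes:
            sig[ch] += amp * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))

    w_lat = laterality_weight(profile.age, sim.laterality_age_center,
                              sim.laterality_slope)
    hemi = profile.grid_side
    gains = _effective_gains(sim, hemi, w_lat)
    depths = _effective_depths(sim, hemi, w_lat)

    # motor burst: movement-locked, mid-window, clearly tapered
    m_i0 = int(0.15 * fs)
    n_m = int(0.75 * fs) - m_i0
    taper_m = sps.windows.tukey(n_m, alpha=0.5)
    # IFG response: cue-locked with gentle ramps (a sharp burst bump would
    # itself couple to the slowest phase bins), ending at 0.75 s post-cue —
    # the earliest possible start of the next trial's pre-cue baseline —
    # so responses never contaminate the baseline used for z-scoring
    f_i0 = 0
    n_f = int(0.75 * fs)
    taper_f = sps.windows.tukey(n_f, alpha=0.5)

    onsets = events["onset_sample"].to_numpy()
    cues = events["cue_type"].to_numpy()
    responded = events["response"].to_numpy()

    motor_contra = hand != hemi  # tested hand contralateral to the grid
    for ch in range(n_ch):
        roi, w_ch = rois[ch], weights[ch]
        if roi == "other" or w_ch == 0.0:
            continue
        for k in range(len(events)):
            if roi == "motor":
                if cues[k] == GO and responded[k] and motor_contra:
                    s0 = onsets[k] + m_i0
                    if s0 + n_m > n_samples:
                        continue
                    burst = _band_noise(n_m, sim.motor_hg_band, fs, rng)
                    sig[ch, s0:s0 + n_m] += (sim.hg_burst_gain_motor * w_ch
                                             * taper_m * burst)
            elif roi == "ifg":
                s0 = onsets[k] + f_i0
                if s0 + n_f > n_samples:
                    continue
                sl = slice(s0, s0 + n_f)
                cond = cues[k]
                phase = (2 * np.pi * sim.theta_freq * np.arange(n_f) / fs
                         + rng.uniform(0, 2 * np.pi))
                # theta component: coherent oscillation carrying the phase
                sig[ch, sl] += (gains["theta"][cond] * w_ch * np.sqrt(2.0)
                                * taper_f * np.cos(phase))
                # beta component: band noise
                sig[ch, sl] += (gains["beta"][cond] * w_ch * taper_f
                                * _band_noise(n_f, sim.beta_band, fs, rng))
                # high-gamma carrier, theta-phase modulated
                m = depths[cond]
                carrier = _band_noise(n_f, sim.pac_carrier_band, fs, rng)
                sig[ch, sl] += (gains["hg"][cond] * w_ch * taper_f
                                * (1.0 + m * np.cos(phase)) * carrier)

    channels = pd.DataFrame({
        "name": [f"ch{ch:02d}" for ch in range(n_ch)],
        "roi": list(rois),
        "hemisphere": [hemi] * n_ch,
    })
    session = RecordingSession(sig, fs, channels, events)

    primary = {roi: int(np.argmax([w if r == roi else -1.0
                                   for r, w in zip(rois, weights)]))
               for roi in ("motor", "ifg")}
    truth = GroundTruth(
        subject_id=profile.subject_id,
        seed=seed,
        hand=hand,
        laterality_weight=w_lat,
        band_gains_effective=gains,
        pac_depth_effective=depths,
        cm_channel=primary["motor"],
        ci_channel=primary["ifg"],
        theta_freq=sim.theta_freq,
        pac_carrier_band=sim.pac_carrier_band,
        events=events,
    )
    return session, truth


# ---------------------------------------------------------------------------
# cohort helpers
# ---------------------------------------------------------------------------

def default_cohort_profiles() -> list[SubjectProfile]:
    """Eight pediatric subjects mirroring the study demographics
    (ages 7-16, four right- and four left-sided grids, accuracies 64-98%)."""
    rows = [
        ("p1", 7, "right", ("right",), 0.642),
        ("p2", 8, "left", ("right",), 0.939),
        ("p3", 9, "left", ("right", "left"), 0.745),
        ("p4", 11, "right", ("right", "left"), 0.959),
        ("p5", 11, "left", ("right", "left"), 0.750),
        ("p6", 12, "right", ("right", "left"), 0.929),
        ("p7", 15, "right", ("right", "left"), 0.663),
        ("p8", 16, "left", ("right",), 0.979),
    ]
    return [SubjectProfile(sid, age, side, hands, acc)
            for sid, age, side, hands, acc in rows]


def simulate_cohort(profiles: list[SubjectProfile], task: TaskConfig,
                    sim: SimConfig, master_seed: int,
                    hand: str | None = None):
    """Simulate one run per subject with per-subject seeds derived from the
    master seed; returns a list of ``(profile, session, truth)`` tuples."""
    rng = np.random.default_rng(master_seed)
    seeds = rng.integers(2**31, size=len(profiles))
    out = []
    for profile, s in zip(profiles, seeds):
        # contralateral hand preferred so the motor burst is expressed
        h = hand
        if h is None:
            contra = "left" if profile.grid_side == "right" else "right"
            h = contra if contra in profile.hands_tested else profile.hands_tested[0]
        session, truth = simulate_session(profile, task, sim, int(s), hand=h)
        out.append((profile, session, truth))
    return out


def generate_pac_trace(duration: float, depth: float,
                       sampling_rate: float = 1200.0,
                       phase_freq: float = 6.0,
                       carrier_freq: float = 110.0,
                       carrier_gain: float = 1.0,
                       noise_rms: float = 0.0,
                       seed: int = 0) -> np.ndarray:
    """Long stationary trace with known sinusoidal phase-amplitude coupling.

    The composite-signal modulation index of such a trace has the analytic
    value depth/2 (expectation of (1 + m cos phi) e^{i phi} over uniform
    phase).  The carrier is a pure tone so that the modulation sidebands
    at carrier_freq +- phase_freq stay inside the analysis amplitude band;
    used as the oracle for the estimator.
    """
    rng = np.random.default_rng(seed)
    n = int(duration * sampling_rate)
    t = np.arange(n) / sampling_rate
    phase = 2 * np.pi * phase_freq * t
    carrier = np.cos(2 * np.pi * carrier_freq * t + rng.uniform(0, 2 * np.pi))
    x = np.cos(phase) + carrier_gain * (1.0 + depth * np.cos(phase)) * carrier
    if noise_rms > 0:
        x = x + noise_rms * one_over_f_noise(n, 2.0, sampling_rate, rng)
    return x
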