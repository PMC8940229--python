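"""Canonical synthetic study conditions and validation experiments.

Each function here sets up one of the package's reference experiments —
fixed generator parameters, runs the relevant pipeline stages from
scratch, and returns the measured quantity.  They are used by the test
suite and by ``scripts/acceptance.py``, and double as worked examples of
the library API.
"""

from __future__ import annotations

import numpy as np

from .activation import classify_trials, hg_activation_map, select_electrodes
from .config import PipelineConfig
from .pac import PACAnalyzer, pac_ratio
from .pipeline import analyze_session, preprocess_session, run_pipeline
from .preprocess import epoch, hg_epochs
from .simulate import (SimConfig, SubjectProfile, TaskConfig,
                       default_cohort_profiles, simulate_cohort,
                       simulate_session)
from .spectral import power_ratio, stft_band_peaks
from .stats import age_trend

__all__ = [
    "band_ratio_study", "pac_ratio_study", "null_pac_fpr_study",
    "group_significance_study", "electrode_recovery_rate",
    "left_ifg_hg_trend_rate",
]

#: representative single subject (age 11, right grid, left hand tested)
_SUBJECT = SubjectProfile("s1", 11, "right", ("left",), 0.93)

#: compact montage for repeated-seed experiments: 2 motor, 2 IFG, 2 other
_SMALL_MONTAGE = dict(
    n_channels=6,
    channel_rois=("motor", "motor", "ifg", "ifg", "other", "other"),
)


def _select_ci_peaks(session, config: PipelineConfig):
    """Preprocess, classify, select electrodes, return Ci band peaks."""
    session = preprocess_session(session, config)
    session = session.copy_with(events=classify_trials(session.events))
    env = hg_epochs(session, config.hg_band, config.epoch_window)
    sel = select_electrodes(hg_activation_map(env))
    raw = epoch(session, config.epoch_window)
    raw = raw.copy_with(labels=classify_trials(raw.labels))
    peaks = stft_band_peaks(raw, sel.ci, config.bands_dict(),
                            config.stft_window_s, config.stft_hop_s)
    return session, sel, peaks


def band_ratio_study(seed: int) -> dict:
    """No-Go/Go band-power ratios on the selected IFG electrode of one
    49-trial session whose No-Go gains are twice the Go gains in every
    band.  Returns {'theta': r, 'beta': r, 'hg': r}."""
    config = PipelineConfig()
    sim = SimConfig(band_gains_ifg=(("theta", (3.0, 6.0)),
                                    ("beta", (1.5, 3.0)),
                                    ("hg", (1.5, 3.0))))
    session, _ = simulate_session(_SUBJECT, TaskConfig(), sim, seed)
    _, _, peaks = _select_ci_peaks(session, config)
    ratios = power_ratio(peaks[peaks["outcome"] == "nogo_correct"],
                         peaks[peaks["outcome"] == "go_correct"],
                         n_bootstrap=200, seed=seed)
    return {band: float(ratios.loc[band, "ratio"]) for band in ratios.index}


def pac_ratio_study(seed: int, n_shuffles: int = 200) -> float:
    """Median over defined cells of the No-Go/Go PAC ratio map on the
    selected IFG electrode (coupling depth 0.6 No-Go vs 0.2 Go, the
    generator defaults)."""
    config = PipelineConfig(n_shuffles=n_shuffles)
    session, _ = simulate_session(_SUBJECT, TaskConfig(), SimConfig(), seed)
    res = analyze_session(session, config, seed=seed, run_pac=True)
    return float(res["pac_ratio"].median_defined)


def null_pac_fpr_study(seed: int, n_sessions: int = 20,
                       n_shuffles: int = 200,
                       alpha: float = 0.05) -> dict:
    """Empirical false-positive rate of the PAC permutation test.

    Simulates sessions with zero injected coupling — and zero evoked
    responses altogether, since a trial-locked burst envelope is itself a
    genuine phase-amplitude dependence that the test should detect —
    then runs the comodulogram + permutation mask on the primary IFG
    channel for both conditions and pools the per-bin significance
    indicators.  Returns the pooled rate plus a session-level 95%
    Monte-Carlo margin (bins within a grid are correlated, so the margin
    treats each grid's fraction as one observation).
    """
    rng = np.random.default_rng(seed)
    sim = SimConfig(pac_depth=(0.0, 0.0),
                    band_gains_ifg=(("theta", (0.0, 0.0)),
                                    ("beta", (0.0, 0.0)),
                                    ("hg", (0.0, 0.0))),
                    hg_burst_gain_motor=0.0)
    config = PipelineConfig()
    fracs = []
    for _ in range(n_sessions):
        s = int(rng.integers(2**31))
        session, truth = simulate_session(_SUBJECT, TaskConfig(), sim, s)
        session = preprocess_session(session, config)
        an = PACAnalyzer(session, truth.ci_channel)
        for cond in ("go_correct", "nogo_correct"):
            g = an.permutation_mask(an.grid(cond), n_shuffles, alpha,
                                    int(rng.integers(2**31)))
            fracs.append(g.mask.mean())
    fracs = np.asarray(fracs)
    margin = 1.645 * fracs.std(ddof=1) / np.sqrt(fracs.size)
    return dict(rate=float(fracs.mean()), margin=float(margin),
                n_grids=int(fracs.size), alpha=alpha)


def group_significance_study(seed: int, run_pac: bool = True,
                             n_shuffles: int = 200,
                             out_dir=None) -> dict:
    """Right-IFG No-Go-vs-Go corrected p-values on the default 8-subject
    cohort (right-lateralized theta and HG No-Go effects injected).

    Runs the full pipeline; returns the Tukey-Kramer corrected p for
    right-IFG theta and HG (and the rest of the comparison table).
    """
    import tempfile

    config = PipelineConfig(n_shuffles=n_shuffles, seed=seed)
    if out_dir is None:
        out_dir = tempfile.mkdtemp(prefix="gonogo_group_")
    res = run_pipeline(config, out_dir, seed=seed, run_pac=run_pac)
    comp = res["comparison"].set_index(["hemisphere", "band"])
    return dict(
        p_right_theta=float(comp.loc[("right", "theta"), "p_tukey"]),
        p_right_hg=float(comp.loc[("right", "hg"), "p_tukey"]),
        comparison=res["comparison"],
        trends=res["trends"],
    )


def electrode_recovery_rate(seed: int, n_seeds: int = 30) -> float:
    """Fraction of seeds on which electrode selection recovers both the
    injected primary motor channel (Cm) and the injected primary IFG
    channel (Ci) on compact 28-trial sessions."""
    rng = np.random.default_rng(seed)
    config = PipelineConfig()
    task = TaskConfig(n_trials=28)
    sim = SimConfig(**_SMALL_MONTAGE)
    hits = 0
    for _ in range(n_seeds):
        s = int(rng.integers(2**31))
        session, truth = simulate_session(_SUBJECT, task, sim, s)
        _, sel, _ = _select_ci_peaks(session, config)
        hits += (sel.ci == truth.ci_channel) and (sel.cm == truth.cm_channel)
    return hits / n_seeds


def left_ifg_hg_trend_rate(seed: int, n_seeds: int = 20,
                           n_subjects: int = 8) -> float:
    """Fraction of seeds with a negative left-IFG high-gamma ratio age
    trend (Spearman rho < 0) on compact left-grid cohorts.

    Each cohort has ``n_subjects`` left-grid subjects with ages spread
    over 7-16 years so the logistic laterality model fades the No-Go
    excess across the cohort.
    """
    rng = np.random.default_rng(seed)
    config = PipelineConfig()
    task = TaskConfig(n_trials=35)
    sim = SimConfig(n_channels=4, channel_rois=("motor", "ifg", "other", "other"))
    ages = np.linspace(7, 16, n_subjects)
    profiles = [SubjectProfile(f"s{i}", float(a), "left", ("right",), 0.93)
                for i, a in enumerate(ages)]
    neg = 0
    for _ in range(n_seeds):
        master = int(rng.integers(2**31))
        cohort = simulate_cohort(profiles, task, sim, master)
        ratios = []
        for profile, session, _truth in cohort:
            _, _, peaks = _select_ci_peaks(session, config)
            r = power_ratio(peaks[peaks["outcome"] == "nogo_correct"],
                            peaks[peaks["outcome"] == "go_correct"],
                            n_bootstrap=10, seed=master)
            ratios.append(float(r.loc["hg", "ratio"]))
        tr = age_trend(ages, ratios)
        neg += (tr.rho < 0)
    return neg / n_seeds
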