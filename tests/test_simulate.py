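"""Synthetic cohort generator: schedules, behavior, signal statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from gonogo_ecog.containers import GO, NOGO
from gonogo_ecog.simulate import (SimConfig, SubjectProfile, TaskConfig,
                                  generate_task_sequence, laterality_weight,
                                  one_over_f_noise, simulate_behavior,
                                  simulate_cohort, simulate_session,
                                  default_cohort_profiles)


class TestTaskSequence:
    def test_default_run_counts(self):
        ev = generate_task_sequence(TaskConfig(), seed=0)
        assert len(ev) == 49
        assert (ev["cue_type"] == NOGO).sum() == 7
        assert (ev["cue_type"] == GO).sum() == 42

    def test_itis_within_jitter_interval(self):
        task = TaskConfig(iti_mean=1.0, iti_jitter_halfwidth=0.25)
        ev = generate_task_sequence(task, seed=3)
        assert ev["iti_s"].between(0.75, 1.25).all()
        # onsets advance by cue duration + previous ITI
        gaps = np.diff(ev["onset_s"].to_numpy())
        np.testing.assert_allclose(gaps, 1.0 + ev["iti_s"].to_numpy()[:-1])

    def test_deterministic_under_seed(self):
        a = generate_task_sequence(TaskConfig(), seed=7)
        b = generate_task_sequence(TaskConfig(), seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_indivisible_ratio_raises_without_flag(self):
        with pytest.raises(ValueError, match="not divisible"):
            generate_task_sequence(TaskConfig(n_trials=50), seed=0)
        ev = generate_task_sequence(
            TaskConfig(n_trials=50, allow_rounding=True), seed=0)
        assert len(ev) == 50

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TaskConfig(n_trials=0)
        with pytest.raises(ValueError):
            TaskConfig(iti_mean=0.2, iti_jitter_halfwidth=0.25)


class TestBehavior:
    @pytest.mark.parametrize("acc,outcomes", [
        (1.0, {"go_correct", "nogo_correct"}),
        (0.0, {"go_wrong", "nogo_wrong"}),
    ])
    def test_degenerate_accuracy(self, acc, outcomes):
        prof = SubjectProfile("p", 10, behavioral_accuracy=acc)
        ev = generate_task_sequence(TaskConfig(), seed=1)
        ev = simulate_behavior(ev, prof, seed=2)
        assert set(ev["outcome"]) == outcomes

    def test_empirical_accuracy_matches_table_value(self):
        # representative subject accuracy 93.9%; binomial 95% CI half-width
        # at n = 9996 is ~0.47%, well inside the 1% tolerance
        prof = SubjectProfile("p", 8, behavioral_accuracy=0.939)
        ev = generate_task_sequence(TaskConfig(n_trials=9996), seed=1)
        ev = simulate_behavior(ev, prof, seed=3)
        acc = ev["outcome"].str.endswith("_correct").mean()
        assert abs(acc - 0.939) < 0.01

    def test_responses_consistent_with_outcomes(self):
        prof = SubjectProfile("p", 10, behavioral_accuracy=0.8)
        ev = simulate_behavior(generate_task_sequence(TaskConfig(), 0), prof, 1)
        responded = ev["response"]
        assert (ev.loc[responded, "latency_s"].between(0.15, 0.95)).all()
        assert ev.loc[~responded, "latency_s"].isna().all()


class TestSignal:
    def test_determinism(self, profile):
        a, _ = simulate_session(profile, TaskConfig(), SimConfig(), seed=5)
        b, _ = simulate_session(profile, TaskConfig(), SimConfig(), seed=5)
        np.testing.assert_array_equal(a.signal, b.signal)
        pd.testing.assert_frame_equal(a.events, b.events)

    def test_spectral_slope_recovered_with_zero_gains(self, profile):
        sim = SimConfig(band_gains_ifg=(("theta", (0, 0)), ("beta", (0, 0)),
                                        ("hg", (0, 0))),
                        hg_burst_gain_motor=0.0, pac_depth=(0, 0),
                        noise_exponent=2.0)
        session, _ = simulate_session(profile, TaskConfig(), sim, seed=6)
        f, p = sps.welch(session.signal, fs=session.sampling_rate,
                         nperseg=4096)
        p = np.median(p, axis=0)
        keep = (f >= 2) & (f <= 200)
        for f0 in (60, 120, 180):           # exclude line-noise peaks
            keep &= np.abs(f - f0) > 4
        slope = np.polyfit(np.log(f[keep]), np.log(p[keep]), 1)[0]
        assert abs(slope - (-2.0)) < 0.15

    def test_missing_roi_label_raises(self, profile):
        sim = SimConfig(n_channels=4,
                        channel_rois=("motor", "other", "other", "other"))
        with pytest.raises(ValueError, match="ifg"):
            simulate_session(profile, TaskConfig(), sim, seed=0)

    def test_ground_truth_records_laterality_and_sites(self, default_run):
        session, truth = default_run
        assert truth.cm_channel == 0 and truth.ci_channel == 2
        assert truth.laterality_weight == pytest.approx(
            laterality_weight(11), abs=1e-12)
        assert truth.pac_depth_effective[NOGO] == 0.6  # right grid: full depth

    def test_left_grid_nogo_effect_fades_with_age(self):
        task, sim = TaskConfig(), SimConfig()
        old = SubjectProfile("o", 30, "left")   # w ~ 1
        _, truth = simulate_session(old, task, sim, seed=0)
        gains = truth.band_gains_effective
        for band in gains:
            assert gains[band][NOGO] == pytest.approx(gains[band][GO],
                                                      rel=1e-3)
        young = SubjectProfile("y", 7, "left")
        _, truth_y = simulate_session(young, task, sim, seed=0)
        assert truth_y.band_gains_effective["hg"][NOGO] > gains["hg"][NOGO]

    def test_laterality_weight_monotone_in_unit_interval(self):
        ages = np.linspace(0, 40, 50)
        w = np.array([laterality_weight(a) for a in ages])
        assert np.all(np.diff(w) >= 0)
        assert np.all((w >= 0) & (w <= 1))


def test_one_over_f_noise_unit_expected_rms_and_stable_band_power(rng):
    # the deterministic (Parseval) normalization gives unit variance in
    # expectation, and -- crucially -- near-constant band-limited power
    # across realizations (a realized-std normalization would rescale the
    # high-frequency content by the luck of the lowest-frequency bins)
    variances, band_rms = [], []
    from scipy import signal as sps
    sos = sps.butter(4, (70, 200), btype="bandpass", fs=1200.0, output="sos")
    for _ in range(20):
        x = one_over_f_noise(50_000, 2.0, 1200.0, rng)
        variances.append(x.var())
        band_rms.append(sps.sosfiltfilt(sos, x).std())
    assert np.mean(variances) == pytest.approx(1.0, rel=0.2)
    band_rms = np.asarray(band_rms)
    assert band_rms.std() / band_rms.mean() < 0.05


def test_cohort_mirrors_study_demographics():
    profiles = default_cohort_profiles()
    assert len(profiles) == 8
    sides = [p.grid_side for p in profiles]
    assert sides.count("left") == 4 and sides.count("right") == 4
    assert min(p.age for p in profiles) == 7
    assert max(p.age for p in profiles) == 16


def test_cohort_seed_derivation_is_stable():
    profiles = default_cohort_profiles()[:2]
    task = TaskConfig(n_trials=7)
    sim = SimConfig(n_channels=4,
                    channel_rois=("motor", "ifg", "other", "other"))
    a = simulate_cohort(profiles, task, sim, master_seed=9)
    b = simulate_cohort(profiles, task, sim, master_seed=9)
    for (_, sa, _), (_, sb, _) in zip(a, b):
        np.testing.assert_array_equal(sa.signal, sb.signal)
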