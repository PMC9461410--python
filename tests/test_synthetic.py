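from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import vaxwatch as vw
from vaxwatch.exceptions import ConfigurationError
from vaxwatch.preprocessing import hourly_average
from vaxwatch.questionnaire import SEVERE_SYMPTOMS, SeverityTier, classify_reaction, dedupe_daily, split_entries
from vaxwatch.synthetic import (
    SEVERITIES,
    ReportingModel,
    TierReporting,
    participant_rng,
    response_curve,
)


# ------------------------------------------------------------ generate_cohort
def test_cohort_size_and_age_range():
    config = vw.SimulationConfig(n_participants=100, severity_mix=(0.5, 0.35, 0.15), seed=7)
    cohort = vw.generate_cohort(config)
    assert len(cohort) == 100
    assert all(18 <= p.age <= 88 for p in cohort)


def test_severity_draw_matches_independent_reseeded_draw():
    config = vw.SimulationConfig(n_participants=100, severity_mix=(0.5, 0.35, 0.15), seed=7)
    cohort = vw.generate_cohort(config)
    for p in cohort:
        rng = participant_rng(7, p.index, 0)
        expected = SEVERITIES[rng.choice(3, p=[0.5, 0.35, 0.15])]
        assert p.true_severity == expected
    counts = pd.Series([p.true_severity for p in cohort]).value_counts()
    # within 4 sigma of the multinomial expectation
    for tier, prob in zip(SEVERITIES, (0.5, 0.35, 0.15)):
        sigma = np.sqrt(100 * prob * (1 - prob))
        assert abs(counts.get(tier, 0) - 100 * prob) < 4 * sigma


def test_degenerate_mixture_gives_single_tier():
    config = vw.SimulationConfig(n_participants=1, severity_mix=(1, 0, 0), seed=0)
    assert vw.generate_cohort(config)[0].true_severity == "none"


def test_third_dose_mix_accepted():
    config = vw.SimulationConfig(n_participants=5, severity_mix=(0.55, 0.35, 0.10))
    assert vw.generate_cohort(config)[0] is not None


def test_invalid_probability_vector_rejected():
    with pytest.raises((ConfigurationError, ValueError)):
        vw.SimulationConfig(n_participants=5, severity_mix=(0.9, 0.3, 0.1))


def test_cohort_growth_preserves_existing_participants():
    small = vw.generate_cohort(vw.SimulationConfig(n_participants=5, seed=13))
    large = vw.generate_cohort(vw.SimulationConfig(n_participants=12, seed=13))
    assert large[:5] == small


def test_fixed_seed_reproducible():
    config = vw.SimulationConfig(n_participants=4, seed=21, gap_rate=0.4)
    a = vw.simulate_dataset(config, channels=("stress",))
    b = vw.simulate_dataset(config, channels=("stress",))
    for frame_a, frame_b in zip(a, b):
        pd.testing.assert_frame_equal(frame_a, frame_b)


# ------------------------------------------------------------ response curve
def test_curve_zero_before_and_peak_at_peak_time():
    params = vw.ResponseCurveParams(peak_elevation=8.91, peak_time=24.0)
    assert response_curve(-5.0, params) == 0.0
    assert response_curve(0.0, params) == 0.0
    assert response_curve(24.0, params) == pytest.approx(8.91)
    t = np.linspace(0.5, 335, 2000)
    assert response_curve(t, params).max() <= 8.91 + 1e-12
    assert response_curve(2000.0, params) == pytest.approx(0.0, abs=1e-3)


def test_undershoot_goes_below_zero_then_recovers():
    params = vw.ResponseCurveParams(
        peak_elevation=5.0, peak_time=24.0, undershoot_depth=4.0, undershoot_recovery=96.0
    )
    t = np.linspace(0.5, 335, 3000)
    values = response_curve(t, params)
    assert values.min() < 0.0
    assert abs(response_curve(3000.0, params)) < 1e-2


# ------------------------------------------------------------ simulate_stream
def test_sample_cadence():
    config = vw.SimulationConfig(n_participants=1, seed=1)
    p = vw.generate_cohort(config)[0]
    hr = vw.simulate_stream(p, "heart_rate", config.curve_for("heart_rate", "none"), config)
    stress = vw.simulate_stream(p, "stress", config.curve_for("stress", "none"), config)
    hr_steps = hr["timestamp"].diff().dropna().unique()
    stress_steps = stress["timestamp"].diff().dropna().unique()
    assert list(hr_steps) == [pd.Timedelta(seconds=15)]
    assert list(stress_steps) == [pd.Timedelta(minutes=3)]
    assert len(hr) == 21 * 86400 // 15
    span = hr["timestamp"].iloc[0], hr["timestamp"].iloc[-1]
    assert span[0] == p.vaccination_time - pd.Timedelta(days=7)
    assert span[1] < p.vaccination_time + pd.Timedelta(days=14)


def test_unknown_channel_rejected():
    config = vw.SimulationConfig(n_participants=1)
    p = vw.generate_cohort(config)[0]
    with pytest.raises(ConfigurationError):
        vw.simulate_stream(p, "spo2", config.curve_for("heart_rate", "none"), config)


def test_stress_clipped_to_scale():
    config = vw.SimulationConfig(n_participants=1, seed=2)
    config.channels["stress"].noise_sd = 60.0
    p = vw.generate_cohort(config)[0]
    stream = vw.simulate_stream(p, "stress", config.curve_for("stress", "severe"), config)
    assert stream["value"].min() >= 1.0
    assert stream["value"].max() <= 100.0


def test_null_curve_hourly_means_match_baseline_week(rng):
    config = vw.SimulationConfig(n_participants=1, seed=6, gap_rate=0, force_long_gap=False)
    config.channels["heart_rate"].noise_sd = 2.0
    p = vw.generate_cohort(config)[0]
    null_curve = vw.ResponseCurveParams(peak_elevation=0.0)
    stream = vw.simulate_stream(p, "heart_rate", null_curve, config)
    series = hourly_average(stream, p.vaccination_time)
    post = series.slice(0, 336).values
    base = np.tile(series.slice(-168, 0).values, 2)
    diffs = post - base
    tol = 6 * 2.0 / np.sqrt(240)  # 6 sigma of an hourly-mean difference
    assert np.nanmax(np.abs(diffs[1:-1])) < tol * np.sqrt(2)


def test_noise_free_hourly_means_equal_analytic_values():
    config = vw.SimulationConfig(n_participants=1, seed=5, gap_rate=0, force_long_gap=False)
    ch = config.channels["heart_rate"]
    ch.noise_sd = 0.0
    ch.participant_sd = 0.0
    ch.circadian_amplitude = 0.0
    p = vw.generate_cohort(config)[0]
    curve = config.curve_for("heart_rate", "severe")
    stream = vw.simulate_stream(p, "heart_rate", curve, config)
    series = hourly_average(stream, p.vaccination_time)
    ts = stream["timestamp"].to_numpy("datetime64[ns]")
    rel_h = (ts - p.vaccination_time.to_datetime64()) / np.timedelta64(1, "h")
    origin_h = p.vaccination_time.floor("h").to_datetime64()
    offsets = ((ts - origin_h) // np.timedelta64(1, "h")).astype(int)
    expected_signal = ch.circadian_mean + response_curve(rel_h, curve)
    for h in range(series.start, series.stop):
        sel = offsets == h
        if sel.any():
            assert series.values[h - series.start] == pytest.approx(
                expected_signal[sel].mean(), abs=1e-9
            )


def test_severe_curve_anchored_near_nine_bpm():
    config = vw.SimulationConfig(n_participants=1)
    curve = config.curve_for("heart_rate", "severe")
    assert curve.peak_time == 24.0
    assert response_curve(24.0, curve) == pytest.approx(9.0)


# ---------------------------------------------------------------- inject_gaps
def test_zero_gap_rate_is_identity():
    config = vw.SimulationConfig(n_participants=1, seed=4)
    p = vw.generate_cohort(config)[0]
    stream = vw.simulate_stream(p, "stress", config.curve_for("stress", "none"), config)
    out = vw.inject_gaps(stream, 0.0, 2.0, np.random.default_rng(0))
    pd.testing.assert_frame_equal(out, stream)


def test_negative_gap_rate_rejected():
    config = vw.SimulationConfig(n_participants=1, seed=4)
    p = vw.generate_cohort(config)[0]
    stream = vw.simulate_stream(p, "stress", config.curve_for("stress", "none"), config)
    with pytest.raises(ConfigurationError):
        vw.inject_gaps(stream, -1.0, 2.0, np.random.default_rng(0))


def test_empty_samples_rejected():
    with pytest.raises(ValueError):
        vw.inject_gaps(
            pd.DataFrame(columns=["participant_id", "channel", "timestamp", "value"]),
            0.5, 2.0, np.random.default_rng(0),
        )


def test_removed_runs_are_contiguous():
    config = vw.SimulationConfig(n_participants=1, seed=4)
    p = vw.generate_cohort(config)[0]
    stream = vw.simulate_stream(p, "stress", config.curve_for("stress", "none"), config)
    out = vw.inject_gaps(stream, 0.0, 0.0, np.random.default_rng(1), forced_gaps_h=[(10.0, 2.0)])
    steps = out["timestamp"].diff().dropna()
    big = steps[steps > pd.Timedelta(minutes=3)]
    assert len(big) == 1  # one contiguous hole
    assert pd.Timedelta(hours=2) <= big.iloc[0] <= pd.Timedelta(hours=2, minutes=3)


def test_dataset_contains_a_long_gap_for_exclusion_path():
    config = vw.SimulationConfig(n_participants=2, seed=8, gap_rate=0.0, force_long_gap=True)
    _, wearable, _ = vw.simulate_dataset(config, channels=("stress",))
    p0 = wearable[wearable["participant_id"] == "P00000"]
    ts = pd.to_datetime(p0["timestamp"])
    assert ts.diff().max() >= pd.Timedelta(hours=8)


# -------------------------------------------------- generate_questionnaires
def test_zero_reporting_probability_gives_empty_symptoms_and_none_tier():
    config = vw.SimulationConfig(n_participants=1, severity_mix=(0, 0, 1), seed=10)
    p = vw.generate_cohort(config)[0]
    model = ReportingModel(severe=TierReporting(post_probs={}))
    entries = vw.generate_questionnaires(p, model, seed=10)
    assert all(not e.symptoms for e in entries)
    deduped = dedupe_daily(entries)
    baseline, post = split_entries(deduped, p.vaccination_time)
    assert classify_reaction(post, baseline) is SeverityTier.NONE


def test_certain_chills_reporting_gives_severe_tier():
    config = vw.SimulationConfig(n_participants=1, severity_mix=(0, 0, 1), seed=11)
    p = vw.generate_cohort(config)[0]
    model = ReportingModel(
        severe=TierReporting(post_probs={"chills": 1.0}, baseline_probs={})
    )
    entries = vw.generate_questionnaires(p, model, seed=11)
    baseline, post = split_entries(dedupe_daily(entries), p.vaccination_time)
    assert "chills" in SEVERE_SYMPTOMS
    assert classify_reaction(post, baseline) is SeverityTier.SEVERE


def test_reporting_fraction_within_binomial_interval():
    p_report = 0.4
    config = vw.SimulationConfig(n_participants=1000, severity_mix=(0, 1, 0), seed=12)
    model = ReportingModel(mild=TierReporting(post_probs={"headache": p_report}))
    cohort = vw.generate_cohort(config)
    reported = 0
    total = 0
    for participant in cohort:
        entries = vw.generate_questionnaires(participant, model, seed=12)
        for e in entries:
            if e.submitted_at >= participant.vaccination_time.normalize():
                total += 1
                reported += "headache" in e.symptoms
    phat = reported / total
    se = np.sqrt(p_report * (1 - p_report) / total)
    assert abs(phat - p_report) < 4 * se


def test_invalid_reporting_probability_rejected():
    with pytest.raises(ValueError):
        TierReporting(post_probs={"headache": 1.4})


def test_questionnaires_cover_baseline_and_post_days():
    config = vw.SimulationConfig(n_participants=1, seed=14)
    p = vw.generate_cohort(config)[0]
    entries = vw.generate_questionnaires(p, config.reporting_model, seed=14)
    assert len(entries) == 11  # 7 baseline + 4 post days at submit_prob 1
    days = sorted((e.submitted_at.normalize() - p.vaccination_time.normalize()).days
                  for e in entries)
    assert days == list(range(-7, 4))
    assert all(18 <= e.submitted_at.hour <= 23 for e in entries)
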