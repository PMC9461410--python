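"""Synthetic cohort generator.

Emulates the data structure the analysis assumes: per-participant circadian
physiology sampled at device cadence (heart rate every 15 s, stress every
3 min), a severity-scaled post-vaccination elevation peaking near 24 h,
participant-level random intercepts, charging gaps, and probabilistic daily
symptom reporting — all with known ground truth and bit-reproducible under a
fixed seed.

Random streams are split per participant from the master seed (spawn key =
participant index), so growing the cohort never reshuffles existing
participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .exceptions import ConfigurationError
from .questionnaire import MILD_SYMPTOMS, SEVERE_SYMPTOMS, QuestionnaireEntry, SeverityTier

SEVERITIES = ("none", "mild", "severe")

# rng sub-stream codes, so each purpose gets an independent stream
_DEMOGRAPHICS = 0
_STREAM_CODE = {"heart_rate": 1, "stress": 2}
_GAP_CODE = {"heart_rate": 3, "stress": 4}
_QUESTIONNAIRE = 5

STEP_SECONDS = {"heart_rate": 15, "stress": 180}


def participant_rng(seed: int, index: int, purpose: int) -> np.random.Generator:
    """Per-participant, per-purpose random stream from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index, purpose)))


@dataclass(frozen=True)
class Participant:
    """Roster record; the unit of random effects."""

    participant_id: str
    index: int
    age: int
    sex: str
    underlying_condition: bool
    dose: int
    vaccination_time: pd.Timestamp
    true_severity: Optional[str] = None

    def __post_init__(self):
        if self.age < 18:
            raise ValueError("participants are adults (age >= 18)")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be female or male, got {self.sex!r}")


class ResponseCurveParams(BaseModel):
    """Shape of the post-vaccination elevation: a log-normal pulse in time.

    The pulse is 0 at t <= 0, reaches ``peak_elevation`` at ``peak_time``
    hours and decays back to 0; an optional negative undershoot centered at
    ``peak_time + undershoot_recovery`` emulates the below-baseline phase
    seen in the severe stress response.
    """

    peak_elevation: float
    peak_time: float = Field(24.0, gt=0)
    rise_time: float = Field(12.0, gt=0)
    decay_time: float = Field(36.0, gt=0)
    undershoot_depth: float = Field(0.0, ge=0)
    undershoot_recovery: float = Field(96.0, gt=0)


def response_curve(t_hours, params: ResponseCurveParams) -> np.ndarray:
    """Evaluate the elevation curve at hours post-vaccination (vectorized)."""
    t = np.asarray(t_hours, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    x = np.log(tp / params.peak_time)
    sig_rise = np.log1p(params.rise_time / params.peak_time)
    sig_decay = np.log1p(params.decay_time / params.peak_time)
    sig = np.where(x < 0, sig_rise, sig_decay)
    out[pos] = params.peak_elevation * np.exp(-0.5 * (x / sig) ** 2)
    if params.undershoot_depth > 0:
        center = params.peak_time + params.undershoot_recovery
        xu = np.log(tp / center)
        out[pos] -= params.undershoot_depth * np.exp(-0.5 * (xu / np.log(2.0)) ** 2)
    return float(out[0]) if scalar else out


class ChannelParams(BaseModel):
    """Per-channel simulation scales and severity anchors."""

    circadian_mean: float
    circadian_amplitude: float = Field(ge=0)
    participant_sd: float = Field(ge=0)
    noise_sd: float = Field(ge=0)
    floor: float
    ceil: Optional[float] = None
    # peak elevations per severity tier; defaults anchored to the magnitudes
    # reported for the third dose (heart rate ~2.8/5/9 bpm, stress ~6/10/21)
    peak_by_severity: dict[str, float]
    undershoot_by_severity: dict[str, float] = {}
    peak_time: float = 24.0
    rise_time: float = 12.0
    decay_time: float = 36.0
    undershoot_recovery: float = 96.0


def default_channel_params() -> dict[str, ChannelParams]:
    return {
        "heart_rate": ChannelParams(
            circadian_mean=65.0,
            circadian_amplitude=6.0,
            participant_sd=6.0,
            noise_sd=5.0,
            floor=30.0,
            ceil=None,
            peak_by_severity={"none": 2.8, "mild": 5.0, "severe": 9.0},
        ),
        "stress": ChannelParams(
            circadian_mean=30.0,
            circadian_amplitude=10.0,
            participant_sd=8.0,
            noise_sd=12.0,
            floor=1.0,
            ceil=100.0,
            peak_by_severity={"none": 6.0, "mild": 10.0, "severe": 21.0},
            undershoot_by_severity={"severe": 4.0},
        ),
    }


class TierReporting(BaseModel):
    """Reporting probabilities for one true-severity tier."""

    post_probs: dict[str, float] = {}
    baseline_probs: dict[str, float] = {}
    submit_prob: float = Field(1.0, ge=0, le=1)
    fever_prob: float = Field(0.0, ge=0, le=1)

    @field_validator("post_probs", "baseline_probs")
    @classmethod
    def _check_probs(cls, v):
        for symptom, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {symptom!r} outside [0, 1]: {p}")
        return v


class ReportingModel(BaseModel):
    """Per-tier daily symptom reporting probabilities (days 0-3 post, baseline days)."""

    none: TierReporting = TierReporting()
    mild: TierReporting = TierReporting(
        post_probs={"headache": 0.6, "muscle pain": 0.5, "weakness": 0.4}
    )
    severe: TierReporting = TierReporting(
        post_probs={
            "chills": 0.7,
            "fever": 0.2,
            "feeling hot": 0.3,
            "headache": 0.5,
            "muscle pain": 0.5,
        },
        fever_prob=0.5,
    )

    def for_tier(self, severity: str) -> TierReporting:
        return getattr(self, severity)


class SimulationConfig(BaseModel):
    """Full cohort simulation configuration.

    Channel scales are nested per channel because heart rate and stress live
    on different scales; ``severity_mix`` orders probabilities as
    (none, mild, severe).
    """

    n_participants: int = Field(ge=1)
    severity_mix: tuple[float, float, float] = (0.55, 0.35, 0.10)
    dose: int = 3
    channels: dict[str, ChannelParams] = Field(default_factory=default_channel_params)
    gap_rate: float = 0.5  # expected charging gaps per day
    gap_length_mean_h: float = 2.0
    force_long_gap: bool = True  # guarantee one >5 h gap somewhere in the cohort
    reporting_model: ReportingModel = ReportingModel()
    start_date: str = "2021-08-02"  # a Monday; vaccinations spread over two weeks
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        mix = np.asarray(self.severity_mix, dtype=float)
        if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"severity_mix must be non-negative and sum to 1, got {self.severity_mix}"
            )
        if self.gap_rate < 0:
            raise ConfigurationError(f"gap_rate must be >= 0, got {self.gap_rate}")
        if self.gap_length_mean_h < 0:
            raise ConfigurationError("gap_length_mean_h must be >= 0")
        return self

    def curve_for(self, channel: str, severity: str) -> ResponseCurveParams:
        ch = self.channels[channel]
        return ResponseCurveParams(
            peak_elevation=ch.peak_by_severity.get(severity, 0.0),
            peak_time=ch.peak_time,
            rise_time=ch.rise_time,
            decay_time=ch.decay_time,
            undershoot_depth=ch.undershoot_by_severity.get(severity, 0.0),
            undershoot_recovery=ch.undershoot_recovery,
        )


def generate_cohort(config: SimulationConfig) -> list[Participant]:
    """Draw the participant roster: demographics, vaccination times, true tiers."""
    base = pd.Timestamp(config.start_date)
    participants = []
    for i in range(config.n_participants):
        rng = participant_rng(config.seed, i, _DEMOGRAPHICS)
        severity = SEVERITIES[rng.choice(3, p=list(config.severity_mix))]
        age = int(rng.integers(18, 89))
        sex = "female" if rng.random() < 0.57 else "male"
        condition = bool(rng.random() < 0.35)
        day = int(rng.integers(0, 14))
        hour = int(rng.integers(8, 20))
        minute = int(rng.integers(0, 60))
        vacc = base + pd.Timedelta(days=day, hours=hour, minutes=minute)
        participants.append(
            Participant(
                participant_id=f"P{i:05d}",
                index=i,
                age=age,
                sex=sex,
                underlying_condition=condition,
                dose=config.dose,
                vaccination_time=vacc,
                true_severity=severity,
            )
        )
    return participants


def circadian_term(time_of_day_h: np.ndarray, amplitude: float) -> np.ndarray:
    """24-h sinusoid with trough at 04:00 local time."""
    return -amplitude * np.cos(2.0 * np.pi * (time_of_day_h - 4.0) / 24.0)


def simulate_stream(
    participant: Participant,
    channel: str,
    curve: ResponseCurveParams,
    config: SimulationConfig,
    *,
    days_before: int = 7,
    days_after: int = 14,
) -> pd.DataFrame:
    """Simulate one raw device stream spanning the baseline week and post fortnight.

    value = participant baseline + circadian sinusoid + response curve + noise,
    clipped to the channel's physiological range.
    """
    if channel not in STEP_SECONDS:
        raise ConfigurationError(f"unknown channel {channel!r}")
    ch = config.channels[channel]
    step = STEP_SECONDS[channel]
    vacc = participant.vaccination_time.to_datetime64().astype("datetime64[s]")
    t0 = vacc - np.timedelta64(days_before * 86400, "s")
    n = (days_before + days_after) * 86400 // step
    times = t0 + (np.arange(n) * step).astype("timedelta64[s]")

    rel_h = (times - vacc).astype("timedelta64[s]").astype(np.int64) / 3600.0
    tod_h = (times.astype("datetime64[s]").astype(np.int64) % 86400) / 3600.0

    rng = participant_rng(config.seed, participant.index, _STREAM_CODE[channel])
    baseline = ch.circadian_mean + rng.normal(0.0, ch.participant_sd)
    values = (
        baseline
        + circadian_term(tod_h, ch.circadian_amplitude)
        + response_curve(rel_h, curve)
    )
    if ch.noise_sd > 0:
        values = values + rng.normal(0.0, ch.noise_sd, size=n)
    values = np.clip(values, ch.floor, ch.ceil if ch.ceil is not None else np.inf)

    return pd.DataFrame(
        {
            "participant_id": participant.participant_id,
            "channel": channel,
            "timestamp": pd.DatetimeIndex(times),
            "value": values,
        }
    )


def inject_gaps(
    samples: pd.DataFrame,
    gap_rate: float,
    gap_length_mean_h: float,
    rng: np.random.Generator,
    *,
    forced_gaps_h: Sequence[tuple[float, float]] = (),
) -> pd.DataFrame:
    """Remove contiguous runs of samples to emulate device-charging gaps.

    ``gap_rate`` is the expected number of gaps per day; gap lengths are
    exponential with mean ``gap_length_mean_h`` hours.  ``forced_gaps_h``
    adds deterministic (start_offset_h, length_h) gaps measured from the
    first sample, used to guarantee a >5 h masked run in a cohort.
    """
    if gap_rate < 0:
        raise ConfigurationError(f"gap_rate must be >= 0, got {gap_rate}")
    if len(samples) == 0:
        raise ValueError("samples must be non-empty")
    if gap_rate == 0 and not forced_gaps_h:
        return samples
    ts = samples["timestamp"].to_numpy(dtype="datetime64[ns]")
    span_h = (ts[-1] - ts[0]) / np.timedelta64(1, "h")
    n_gaps = rng.poisson(gap_rate * span_h / 24.0)
    starts = rng.uniform(0.0, span_h, size=n_gaps)
    lengths = rng.exponential(gap_length_mean_h, size=n_gaps) if n_gaps else np.array([])
    gaps = list(zip(starts, lengths)) + list(forced_gaps_h)
    keep = np.ones(len(samples), dtype=bool)
    rel_h = (ts - ts[0]) / np.timedelta64(1, "h")
    for start, length in gaps:
        keep &= ~((rel_h >= start) & (rel_h < start + length))
    return samples.loc[keep].reset_index(drop=True)


def generate_questionnaires(
    participant: Participant,
    reporting_model: ReportingModel,
    seed: int,
    *,
    baseline_days: int = 7,
    post_days: int = 4,
) -> list[QuestionnaireEntry]:
    """Daily questionnaire submissions for one participant.

    One potential submission per day over the baseline week and post days
    0..post_days-1, placed in the evening (the within-day timing is a free
    choice; it only matters for the last-entry-per-day rule).  Symptoms are
    Bernoulli draws from the tier's per-day probabilities.
    """
    tier = reporting_model.for_tier(participant.true_severity or "none")
    rng = participant_rng(seed, participant.index, _QUESTIONNAIRE)
    vacc_day = participant.vaccination_time.normalize()
    entries = []
    for day in range(-baseline_days, post_days):
        if rng.random() > tier.submit_prob:
            continue
        probs = tier.baseline_probs if day < 0 else tier.post_probs
        symptoms = frozenset(s for s, p in probs.items() if rng.random() < p)
        temperature = None
        if "feeling hot" in symptoms:
            if rng.random() < tier.fever_prob:
                temperature = float(np.clip(rng.normal(39.4, 0.3), 39.0, 41.0))
            else:
                temperature = float(np.clip(rng.normal(37.8, 0.4), 36.5, 38.9))
        submitted = vacc_day + pd.Timedelta(days=day, hours=18) + pd.Timedelta(
            minutes=int(rng.integers(0, 300))
        )
        if day == 0 and submitted <= participant.vaccination_time:
            # the day-0 report describes the post-vaccination state
            submitted = participant.vaccination_time + pd.Timedelta(
                minutes=30 + int(rng.integers(0, 120))
            )
        entries.append(
            QuestionnaireEntry(
                participant_id=participant.participant_id,
                submitted_at=submitted,
                symptoms=symptoms,
                temperature_c=temperature,
            )
        )
    return entries


def roster_frame(participants: Sequence[Participant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in participants],
            "age": [p.age for p in participants],
            "sex": [p.sex for p in participants],
            "underlying_condition": [p.underlying_condition for p in participants],
            "dose": [p.dose for p in participants],
            "vaccination_time": [p.vaccination_time.isoformat() for p in participants],
            "true_severity": [p.true_severity for p in participants],
        }
    )


def questionnaire_frame(entries: Sequence[QuestionnaireEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [e.participant_id for e in entries],
            "timestamp": [e.submitted_at.isoformat() for e in entries],
            "symptoms": [";".join(sorted(e.symptoms)) for e in entries],
            "temperature_c": [
                "" if e.temperature_c is None else f"{e.temperature_c:.1f}" for e in entries
            ],
        }
    )


def simulate_dataset(
    config: SimulationConfig,
    out_dir: Optional[Path] = None,
    channels: Sequence[str] = ("heart_rate", "stress"),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (roster, wearable, questionnaire) frames; optionally write CSVs.

    If gaps are enabled, participant 0 receives one deterministic 8 h gap so
    the long-gap exclusion path is always exercised.
    """
    participants = generate_cohort(config)
    wearable_parts = []
    q_entries = []
    for p in participants:
        for channel in channels:
            curve = config.curve_for(channel, p.true_severity or "none")
            stream = simulate_stream(p, channel, curve, config)
            forced = []
            if config.force_long_gap and p.index == 0 and (
                config.gap_rate > 0 or config.force_long_gap
            ):
                forced = [(30.0, 8.0)]  # 8 h gap starting 30 h into the stream
            gap_rng = participant_rng(config.seed, p.index, _GAP_CODE[channel])
            stream = inject_gaps(
                stream,
                config.gap_rate,
                config.gap_length_mean_h,
                gap_rng,
                forced_gaps_h=forced,
            )
            wearable_parts.append(stream)
        q_entries.extend(generate_questionnaires(p, config.reporting_model, config.seed))

    roster = roster_frame(participants)
    wearable = pd.concat(wearable_parts, ignore_index=True)
    wearable["timestamp"] = wearable["timestamp"].map(lambda t: t.isoformat())
    questionnaires = questionnaire_frame(q_entries)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        roster.to_csv(out_dir / "roster.csv", index=False)
        wearable.to_csv(out_dir / "wearable.csv", index=False)
        questionnaires.to_csv(out_dir / "questionnaire.csv", index=False)
    return roster, wearable, questionnaires


def simulate_panel(
    n_participants: int,
    seed: int,
    *,
    n_hours: int = 336,
    beta0: float = 30.0,
    beta_post: float = 0.7,
    beta_lag: float = 0.5,
    beta_age: float = -0.15,
    beta_no_condition: float = -1.5,
    beta_male: float = -3.0,
    sigma_u: float = 0.3,
    sigma_e: float = 1.0,
    window: tuple[int, int] = (0, 72),
) -> pd.DataFrame:
    """Directly simulate a participant-hour panel from the regression's own model.

    y_{i,t} = b0 + b1*post + b2*y_{t-1} + b3*age + b4*no_condition + b5*male
              + u_i + e_{i,t}, with u_i ~ N(0, sigma_u^2), e ~ N(0, sigma_e^2).
    Hours run over [-n_hours/2, n_hours/2); the first hour has no lag and is
    dropped, so each participant contributes n_hours - 1 rows.  This is the
    ground-truth generator for parameter-recovery tests, independent of the
    stream-simulation path.
    """
    rng = np.random.default_rng(seed)
    half = n_hours // 2
    hours = np.arange(-half, n_hours - half)
    post = ((hours >= window[0]) & (hours < window[1])).astype(float)

    age = rng.integers(18, 89, size=n_participants).astype(float)
    male = (rng.random(n_participants) < 0.43).astype(float)
    no_condition = (rng.random(n_participants) < 0.65).astype(float)
    u = rng.normal(0.0, sigma_u, size=n_participants)

    fixed = beta0 + beta_age * age + beta_no_condition * no_condition + beta_male * male + u
    y = np.empty((n_participants, n_hours))
    # stationary start (pre-vaccination, post = 0)
    y[:, 0] = fixed / (1.0 - beta_lag) + rng.normal(
        0.0, sigma_e / np.sqrt(1.0 - beta_lag**2), size=n_participants
    )
    eps = rng.normal(0.0, sigma_e, size=(n_participants, n_hours))
    for t in range(1, n_hours):
        y[:, t] = fixed + beta_post * post[t] + beta_lag * y[:, t - 1] + eps[:, t]

    pid = np.repeat([f"P{i:05d}" for i in range(n_participants)], n_hours - 1)
    t_idx = np.tile(hours[1:], n_participants)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "t": t_idx,
            "y": y[:, 1:].ravel(),
            "y_lag": y[:, :-1].ravel(),
            "post": np.tile(post[1:], n_participants),
            "age": np.repeat(age, n_hours - 1),
            "no_condition": np.repeat(no_condition, n_hours - 1),
            "male": np.repeat(male, n_hours - 1),
        }
    )
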