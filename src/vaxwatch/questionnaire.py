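"""Questionnaire analysis: deduplication, severity tiering and reporting proportions.

Symptoms come from a controlled vocabulary split into a mild and a severe
list.  "feeling hot" is special-cased: together with a recorded body
temperature strictly above ``FEVER_THRESHOLD_C`` it counts as fever (severe),
otherwise it stays mild.  A participant's reaction tier is the maximum
severity over the *new* symptoms (not present in the last baseline entry)
reported within 72 h of vaccination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import IntEnum
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats

from .exceptions import ExclusionSignal, VocabularyError

logger = logging.getLogger(__name__)

MILD_SYMPTOMS = frozenset(
    {
        "abdominal pain",
        "feeling hot",
        "back or neck pain",
        "feeling cold",
        "muscle pain",
        "weakness",
        "headache",
        "dizziness",
        "vomiting",
        "sore throat",
        "diarrhea",
        "cough",
        "leg pain",
        "ear pain",
        "loss of taste and smell",
        "swelling of the lymph nodes",
        "fast heartbeat",
        "hypertension",
    }
)

SEVERE_SYMPTOMS = frozenset(
    {
        "chest pain",
        "dyspnea",
        "fever",
        "confusion",
        "chills",
    }
)

VOCABULARY = MILD_SYMPTOMS | SEVERE_SYMPTOMS

#: Body temperature strictly above this value turns "feeling hot" into fever.
FEVER_THRESHOLD_C = 38.9


class SeverityTier(IntEnum):
    """Reaction severity with total order none < mild < severe."""

    NONE = 0
    MILD = 1
    SEVERE = 2

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "SeverityTier":
        try:
            return cls[label.upper()]
        except KeyError:
            raise ValueError(f"unknown severity tier {label!r}") from None


@dataclass(frozen=True)
class QuestionnaireEntry:
    """One questionnaire submission."""

    participant_id: str
    submitted_at: pd.Timestamp
    symptoms: frozenset[str] = field(default_factory=frozenset)
    temperature_c: Optional[float] = None

    def __post_init__(self):
        if self.temperature_c is not None and not 34.0 <= self.temperature_c <= 43.0:
            raise ValueError(
                f"temperature_c={self.temperature_c} outside the plausible range [34, 43]"
            )


@dataclass(frozen=True)
class ProportionEstimate:
    """A reporting proportion with a beta-distribution confidence interval."""

    k: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float


def dedupe_daily(entries: Sequence[QuestionnaireEntry]) -> list[QuestionnaireEntry]:
    """Keep only the last entry per local calendar day for one participant.

    Returns entries sorted by submission time.  Idempotent; empty input gives
    an empty list.
    """
    if not entries:
        return []
    pids = {e.participant_id for e in entries}
    if len(pids) > 1:
        raise ValueError(f"dedupe_daily expects a single participant, got {sorted(pids)}")
    latest: dict = {}
    for entry in entries:
        day = entry.submitted_at.date()
        prev = latest.get(day)
        if prev is None or entry.submitted_at >= prev.submitted_at:
            latest[day] = entry
    return sorted(latest.values(), key=lambda e: e.submitted_at)


def classify_symptom(symptom: str, temperature_c: Optional[float] = None) -> SeverityTier:
    """Map one symptom token (plus optional temperature) to mild or severe."""
    if symptom == "feeling hot":
        if temperature_c is not None and temperature_c > FEVER_THRESHOLD_C:
            return SeverityTier.SEVERE
        return SeverityTier.MILD
    if symptom in SEVERE_SYMPTOMS:
        return SeverityTier.SEVERE
    if symptom in MILD_SYMPTOMS:
        return SeverityTier.MILD
    raise VocabularyError(f"unknown symptom token {symptom!r}")


def classify_reaction(
    post_entries: Sequence[QuestionnaireEntry],
    baseline_entry: Optional[QuestionnaireEntry],
    *,
    ignore_unknown: bool = True,
) -> SeverityTier:
    """Tier a participant from deduped post-vaccination entries.

    Symptoms present in the baseline entry are subtracted before tiering:
    only new symptoms count.  Free-text tokens outside the vocabulary are
    skipped with a warning (they carry no severity mapping) unless
    ``ignore_unknown`` is False.
    """
    if not post_entries:
        raise ExclusionSignal("no questionnaire entries in the post-vaccination window")
    baseline_symptoms = baseline_entry.symptoms if baseline_entry is not None else frozenset()
    tier = SeverityTier.NONE
    for entry in post_entries:
        for symptom in entry.symptoms - baseline_symptoms:
            try:
                sev = classify_symptom(symptom, entry.temperature_c)
            except VocabularyError:
                if not ignore_unknown:
                    raise
                logger.warning(
                    "ignoring free-text symptom %r from participant %s",
                    symptom,
                    entry.participant_id,
                )
                continue
            tier = max(tier, sev)
    return tier


def symptom_proportion(k: int, n: int, level: float = 0.95) -> ProportionEstimate:
    """Proportion k/n with a Beta(k, n-k) equal-tailed confidence interval.

    The degenerate ends collapse to point intervals: k=0 gives [0, 0] and
    k=n gives [1, 1], the one-sided limits of the stated interval.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n < 1:
        raise ValueError("n must be >= 1")
    p = k / n
    tail = (1.0 - level) / 2.0
    if k == 0:
        lo, hi = 0.0, 0.0
    elif k == n:
        lo, hi = 1.0, 1.0
    else:
        dist = stats.beta(k, n - k)
        lo, hi = float(dist.ppf(tail)), float(dist.ppf(1.0 - tail))
    return ProportionEstimate(k=k, n=n, proportion=p, ci_low=lo, ci_high=hi)


def cohort_symptom_proportions(
    new_symptoms_by_participant: dict[str, frozenset[str]],
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-symptom reporting proportions over a cohort.

    ``new_symptoms_by_participant`` maps participant id to the baseline-
    subtracted symptom set observed in the post window.
    """
    n = len(new_symptoms_by_participant)
    rows = []
    for symptom in sorted(VOCABULARY):
        k = sum(1 for s in new_symptoms_by_participant.values() if symptom in s)
        est = symptom_proportion(k, n, level) if n else ProportionEstimate(0, 0, 0.0, 0.0, 0.0)
        rows.append(
            {
                "symptom": symptom,
                "k": k,
                "n": n,
                "proportion": est.proportion,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    return pd.DataFrame(rows)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, the convention used for reported percentages."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _stratum_row(name: str, value: str, tiers: pd.Series) -> dict:
    counts = {t: int((tiers == t.label).sum()) for t in SeverityTier}
    total = int(tiers.shape[0])
    row = {"stratum_type": name, "stratum": value, "total": total}
    for t in SeverityTier:
        row[f"n_{t.label}"] = counts[t]
        row[f"pct_{t.label}"] = round_half_up(100.0 * counts[t] / total) if total else float("nan")
    any_k = counts[SeverityTier.MILD] + counts[SeverityTier.SEVERE]
    row["pct_any"] = round_half_up(100.0 * any_k / total) if total else float("nan")
    return row


def tier_crosstab(table: pd.DataFrame, age_cut: int = 55) -> pd.DataFrame:
    """Stratified tier counts and percentages.

    ``table`` needs columns participant_id, tier, sex, age,
    underlying_condition.  Strata: overall, sex, age (18..age_cut vs
    >age_cut), underlying condition.  Percentages are within-stratum,
    rounded half-up to one decimal.
    """
    required = {"participant_id", "tier", "sex", "age", "underlying_condition"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"tier_crosstab missing columns: {sorted(missing)}")
    rows = [_stratum_row("all", "all", table["tier"])]
    for sex in ("female", "male"):
        rows.append(_stratum_row("sex", sex, table.loc[table["sex"] == sex, "tier"]))
    young = table["age"] <= age_cut
    rows.append(_stratum_row("age", f"18-{age_cut}", table.loc[young, "tier"]))
    rows.append(_stratum_row("age", f">{age_cut}", table.loc[~young, "tier"]))
    cond = table["underlying_condition"].astype(bool)
    rows.append(_stratum_row("condition", "yes", table.loc[cond, "tier"]))
    rows.append(_stratum_row("condition", "no", table.loc[~cond, "tier"]))
    return pd.DataFrame(rows)


def split_entries(
    entries: Iterable[QuestionnaireEntry],
    vaccination_time: pd.Timestamp,
    baseline_days: int = 7,
    post_hours: int = 72,
) -> tuple[Optional[QuestionnaireEntry], list[QuestionnaireEntry]]:
    """Split deduped entries into (last baseline entry, post-window entries).

    The baseline window is the ``baseline_days`` days before the vaccination
    timestamp; the post window is the ``post_hours`` hours after it.
    """
    start = vaccination_time - pd.Timedelta(days=baseline_days)
    post_end = vaccination_time + pd.Timedelta(hours=post_hours)
    baseline = [e for e in entries if start <= e.submitted_at < vaccination_time]
    post = [e for e in entries if vaccination_time <= e.submitted_at <= post_end]
    last_baseline = max(baseline, key=lambda e: e.submitted_at) if baseline else None
    return last_baseline, post
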