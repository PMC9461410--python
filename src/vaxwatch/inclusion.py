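"""Participant inclusion criteria with auditable exclusion reasons.

A participant-dose is included when they (1) submitted a questionnaire in
the baseline week, (2) submitted one within 72 h post-vaccination, and
(3) have wearable data at matching day-of-week/hour-of-day slots in both
periods.  Data confined to a single calendar day in a period excludes the
participant unless the matched-single-day carve-out applies (a matching
day in each period is enough).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .preprocessing import BASELINE_H, POST_H, STATUS_MISSING, HourlySeries
from .questionnaire import QuestionnaireEntry
from .synthetic import Participant

REASON_NO_BASELINE_Q = "no_baseline_questionnaire"
REASON_NO_POST_Q = "no_post72_questionnaire"
REASON_NO_MATCHED_WEARABLE = "no_matched_wearable"
REASON_SINGLE_DAY = "single_day_only"


@dataclass(frozen=True)
class InclusionDecision:
    participant_id: str
    dose: int
    included: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.included != (len(self.reasons) == 0):
            raise ValueError("included must hold exactly when reasons is empty")


def _observed_dates(series: HourlySeries, lo: int, hi: int) -> set:
    """Calendar dates of non-missing cells with hour offsets in [lo, hi)."""
    window = series.slice(lo, hi)
    dates = set()
    for offset in window.hours[window.status != STATUS_MISSING]:
        dates.add(window.cell_timestamp(int(offset)).date())
    return dates


def matched_pair_count(series: HourlySeries) -> int:
    """Number of post hours whose baseline counterpart is also non-missing."""
    base = series.slice(-BASELINE_H, 0)
    post = series.slice(0, POST_H)
    base_ok = base.status != STATUS_MISSING
    post_ok = post.status != STATUS_MISSING
    tiled = np.tile(base_ok, POST_H // BASELINE_H)
    return int((post_ok & tiled).sum())


def apply_inclusion(
    participant: Participant,
    deduped_entries: Sequence[QuestionnaireEntry],
    series_by_channel: dict[str, HourlySeries],
    *,
    baseline_days: int = 7,
    post_hours: int = 72,
) -> InclusionDecision:
    """Evaluate the three inclusion criteria for one participant-dose.

    ``series_by_channel`` holds interpolated hourly series; criterion (3)
    holds if any channel has at least one matched non-missing pair.
    """
    vacc = participant.vaccination_time
    start = vacc - pd.Timedelta(days=baseline_days)
    post_end = vacc + pd.Timedelta(hours=post_hours)

    reasons: list[str] = []
    has_baseline_q = any(start <= e.submitted_at < vacc for e in deduped_entries)
    has_post_q = any(vacc <= e.submitted_at <= post_end for e in deduped_entries)
    if not has_baseline_q:
        reasons.append(REASON_NO_BASELINE_Q)
    if not has_post_q:
        reasons.append(REASON_NO_POST_Q)

    matched = max(
        (matched_pair_count(s) for s in series_by_channel.values()), default=0
    )
    if matched == 0:
        single_day = False
        for series in series_by_channel.values():
            base_dates = _observed_dates(series, -BASELINE_H, 0)
            post_dates = _observed_dates(series, 0, POST_H)
            if (base_dates and len(base_dates) == 1) or (post_dates and len(post_dates) == 1):
                single_day = True
        reasons.append(REASON_NO_MATCHED_WEARABLE)
        if single_day:
            reasons.append(REASON_SINGLE_DAY)

    return InclusionDecision(
        participant_id=participant.participant_id,
        dose=participant.dose,
        included=not reasons,
        reasons=tuple(reasons),
    )


def inclusion_frame(decisions: Sequence[InclusionDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [d.participant_id for d in decisions],
            "dose": [d.dose for d in decisions],
            "included": [d.included for d in decisions],
            "reasons": ["|".join(d.reasons) for d in decisions],
        }
    )
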