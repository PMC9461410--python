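"""CSV schemas, readers/writers and input validation.

All pipeline interchange happens through plain CSV files with fixed
headers; timestamps are ISO-8601 local-clock strings (no timezone, no DST
adjustment).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .preprocessing import (
    CHANNELS,
    STATUS_INTERPOLATED,
    STATUS_MISSING,
    STATUS_OBSERVED,
    HourlySeries,
    MatchedDifferenceSeries,
)
from .questionnaire import QuestionnaireEntry
from .synthetic import Participant

ROSTER_COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "underlying_condition",
    "dose",
    "vaccination_time",
    "true_severity",
]
WEARABLE_COLUMNS = ["participant_id", "channel", "timestamp", "value"]
QUESTIONNAIRE_COLUMNS = ["participant_id", "timestamp", "symptoms", "temperature_c"]
HOURLY_COLUMNS = ["participant_id", "channel", "hour_offset", "value", "status", "variant"]
DIFFS_COLUMNS = ["participant_id", "channel", "hour_offset", "diff"]
TIERS_COLUMNS = ["participant_id", "dose", "tier"]

_STATUS_LABEL = {
    STATUS_MISSING: "missing",
    STATUS_OBSERVED: "observed",
    STATUS_INTERPOLATED: "interpolated",
}
_STATUS_CODE = {v: k for k, v in _STATUS_LABEL.items()}


def _require_columns(df: pd.DataFrame, columns: Sequence[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} CSV is missing columns {missing}")


def read_roster(path: str | Path) -> dict[str, Participant]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, ROSTER_COLUMNS, "roster")
    participants = {}
    for i, row in enumerate(df.itertuples(index=False)):
        severity = row.true_severity
        if pd.isna(severity) or severity == "":
            severity = None
        participants[row.participant_id] = Participant(
            participant_id=row.participant_id,
            index=i,
            age=int(row.age),
            sex=str(row.sex),
            underlying_condition=bool(row.underlying_condition),
            dose=int(row.dose),
            vaccination_time=pd.Timestamp(row.vaccination_time),
            true_severity=severity,
        )
    return participants


def read_wearable(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "channel": str})
    _require_columns(df, WEARABLE_COLUMNS, "wearable")
    unknown = set(df["channel"].unique()) - set(CHANNELS)
    if unknown:
        raise SchemaError(f"unknown channel tokens in wearable CSV: {sorted(unknown)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def read_questionnaires(path: str | Path) -> dict[str, list[QuestionnaireEntry]]:
    df = pd.read_csv(path, dtype={"participant_id": str, "symptoms": str})
    _require_columns(df, QUESTIONNAIRE_COLUMNS, "questionnaire")
    entries: dict[str, list[QuestionnaireEntry]] = {}
    for row in df.itertuples(index=False):
        raw = row.symptoms if isinstance(row.symptoms, str) else ""
        symptoms = frozenset(s.strip() for s in raw.split(";") if s.strip())
        temp = None if pd.isna(row.temperature_c) else float(row.temperature_c)
        entries.setdefault(row.participant_id, []).append(
            QuestionnaireEntry(
                participant_id=row.participant_id,
                submitted_at=pd.Timestamp(row.timestamp),
                symptoms=symptoms,
                temperature_c=temp,
            )
        )
    return entries


def hourly_frame(series: Iterable[tuple[HourlySeries, str]]) -> pd.DataFrame:
    """Long-format frame from (series, variant) pairs; variant flags smoothing."""
    parts = []
    for s, variant in series:
        parts.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "channel": s.channel,
                    "hour_offset": s.hours,
                    "value": s.values,
                    "status": [_STATUS_LABEL[int(c)] for c in s.status],
                    "variant": variant,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def read_hourly(
    path: str | Path,
    participants: Mapping[str, Participant],
    variant: str = "interpolated",
) -> dict[str, dict[str, HourlySeries]]:
    """Reconstruct hourly series keyed by participant then channel."""
    df = pd.read_csv(path, dtype={"participant_id": str, "channel": str, "status": str})
    _require_columns(df, HOURLY_COLUMNS, "hourly")
    df = df[df["variant"] == variant]
    out: dict[str, dict[str, HourlySeries]] = {}
    for (pid, channel), group in df.groupby(["participant_id", "channel"], sort=True):
        if pid not in participants:
            raise SchemaError(f"hourly CSV references unknown participant {pid!r}")
        group = group.sort_values("hour_offset")
        offsets = group["hour_offset"].to_numpy(dtype=int)
        start, stop = int(offsets[0]), int(offsets[-1]) + 1
        values = np.full(stop - start, np.nan)
        status = np.zeros(stop - start, dtype=np.int8)
        values[offsets - start] = group["value"].to_numpy(dtype=float)
        status[offsets - start] = [_STATUS_CODE[s] for s in group["status"]]
        out.setdefault(pid, {})[channel] = HourlySeries(
            pid, channel, participants[pid].vaccination_time, start, values, status
        )
    return out


def diffs_frame(diffs: Iterable[MatchedDifferenceSeries]) -> pd.DataFrame:
    parts = []
    for d in diffs:
        hours = d.hours
        parts.append(
            pd.DataFrame(
                {
                    "participant_id": d.participant_id,
                    "channel": d.channel,
                    "hour_offset": hours,
                    "diff": d.diffs[hours],
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=DIFFS_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def read_diffs(path: str | Path) -> dict[str, dict[str, MatchedDifferenceSeries]]:
    """Matched difference series keyed by channel then participant."""
    from .preprocessing import POST_H

    df = pd.read_csv(path, dtype={"participant_id": str, "channel": str})
    _require_columns(df, DIFFS_COLUMNS, "diffs")
    out: dict[str, dict[str, MatchedDifferenceSeries]] = {}
    for (channel, pid), group in df.groupby(["channel", "participant_id"], sort=True):
        diffs = np.full(POST_H, np.nan)
        offsets = group["hour_offset"].to_numpy(dtype=int)
        diffs[offsets] = group["diff"].to_numpy(dtype=float)
        out.setdefault(channel, {})[pid] = MatchedDifferenceSeries(pid, channel, diffs)
    return out


def read_tiers(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype={"participant_id": str, "tier": str})
    _require_columns(df, TIERS_COLUMNS, "tiers")
    return dict(zip(df["participant_id"], df["tier"]))


def validate_inputs(
    roster_path: str | Path,
    wearable_path: str | Path,
    questionnaire_path: str | Path,
) -> list[str]:
    """Schema checks before any computation; returns an itemized violation list."""
    violations: list[str] = []

    try:
        roster = pd.read_csv(roster_path, dtype={"participant_id": str})
        _require_columns(roster, ROSTER_COLUMNS, "roster")
    except (OSError, SchemaError, pd.errors.ParserError) as exc:
        violations.append(f"roster: {exc}")
        roster = None
    if roster is not None:
        bad_sex = roster.loc[~roster["sex"].isin(["female", "male"])]
        for idx in bad_sex.index:
            violations.append(f"roster row {idx}: unknown sex {roster.loc[idx, 'sex']!r}")
        bad_age = roster.loc[pd.to_numeric(roster["age"], errors="coerce").fillna(-1) < 18]
        for idx in bad_age.index:
            violations.append(f"roster row {idx}: age {roster.loc[idx, 'age']!r} below 18")
        parsed = pd.to_datetime(roster["vaccination_time"], errors="coerce")
        for idx in roster.index[parsed.isna()]:
            violations.append(
                f"roster row {idx}: unparseable vaccination_time "
                f"{roster.loc[idx, 'vaccination_time']!r}"
            )

    try:
        wearable = pd.read_csv(wearable_path, dtype={"participant_id": str, "channel": str})
        _require_columns(wearable, WEARABLE_COLUMNS, "wearable")
    except (OSError, SchemaError, pd.errors.ParserError) as exc:
        violations.append(f"wearable: {exc}")
        wearable = None
    if wearable is not None:
        bad = wearable.loc[~wearable["channel"].isin(CHANNELS)]
        for idx, token in bad["channel"].items():
            violations.append(f"wearable row {idx}: unknown channel token {token!r}")
        parsed = pd.to_datetime(wearable["timestamp"], errors="coerce")
        for idx in wearable.index[parsed.isna()]:
            violations.append(
                f"wearable row {idx}: unparseable timestamp {wearable.loc[idx, 'timestamp']!r}"
            )

    try:
        q = pd.read_csv(questionnaire_path, dtype={"participant_id": str, "symptoms": str})
        _require_columns(q, QUESTIONNAIRE_COLUMNS, "questionnaire")
    except (OSError, SchemaError, pd.errors.ParserError) as exc:
        violations.append(f"questionnaire: {exc}")
        q = None
    if q is not None:
        temps = pd.to_numeric(q["temperature_c"], errors="coerce")
        bad_temp = temps.notna() & ((temps < 34.0) | (temps > 43.0))
        for idx in q.index[bad_temp]:
            violations.append(
                f"questionnaire row {idx}: temperature {q.loc[idx, 'temperature_c']!r} "
                "outside [34, 43]"
            )
        parsed = pd.to_datetime(q["timestamp"], errors="coerce")
        for idx in q.index[parsed.isna()]:
            violations.append(
                f"questionnaire row {idx}: unparseable timestamp {q.loc[idx, 'timestamp']!r}"
            )
    return violations
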