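"""Cohort-level statistics on baseline-matched difference series.

Aggregates per-participant matched differences into hourly mean curves with
95% confidence intervals, 72 h window summaries stratified by severity
tier, Welch's t-tests between strata, and peak / return-to-baseline
detection on the hourly curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import POST_H, MatchedDifferenceSeries

logger = logging.getLogger(__name__)

STRATA = ("all", "none", "mild", "severe")


@dataclass(frozen=True)
class CohortCurve:
    """Hourly mean difference across participants for one stratum/channel.

    ``table`` has columns hour, mean, ci_low, ci_high, n; CI bounds are NaN
    where fewer than two participants contribute.
    """

    channel: str
    stratum: str
    table: pd.DataFrame


@dataclass(frozen=True)
class WindowSummary:
    """Per-participant window means and their group-level statistics."""

    channel: str
    stratum: str
    participant_values: pd.Series  # indexed by participant_id
    mean: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class TestResult:
    group_a: str
    group_b: str
    t: float
    df: float
    p: float


def _stack(diffs: Mapping[str, MatchedDifferenceSeries]) -> tuple[list[str], np.ndarray]:
    pids = sorted(diffs)
    if not pids:
        return [], np.empty((0, POST_H))
    return pids, np.vstack([diffs[p].diffs for p in pids])


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float, int]:
    """(mean, ci_low, ci_high, n) of a 1-d sample using the t distribution."""
    values = values[~np.isnan(values)]
    n = len(values)
    if n == 0:
        return np.nan, np.nan, np.nan, 0
    mean = float(values.mean())
    if n < 2:
        return mean, np.nan, np.nan, n
    half = float(stats.t.ppf(0.5 + level / 2.0, n - 1) * values.std(ddof=1) / np.sqrt(n))
    return mean, mean - half, mean + half, n


def cohort_curve(
    diffs: Mapping[str, MatchedDifferenceSeries],
    strata: Mapping[str, str],
    channel: str,
    level: float = 0.95,
) -> dict[str, CohortCurve]:
    """Hourly mean-difference curves per severity stratum (plus 'all').

    ``strata`` maps participant id to tier label; participants absent from
    it are skipped.  Per hour, the mean is over participants with a
    difference at that hour; the CI uses the t distribution across
    participants.
    """
    out: dict[str, CohortCurve] = {}
    for stratum in STRATA:
        if stratum == "all":
            members = {p: d for p, d in diffs.items() if p in strata}
        else:
            members = {p: d for p, d in diffs.items() if strata.get(p) == stratum}
        _, matrix = _stack(members)
        if matrix.shape[0] == 0:
            logger.info("empty stratum %r for channel %s", stratum, channel)
            out[stratum] = CohortCurve(
                channel,
                stratum,
                pd.DataFrame(columns=["hour", "mean", "ci_low", "ci_high", "n"]),
            )
            continue
        n = (~np.isnan(matrix)).sum(axis=0)
        import warnings as _warnings

        with np.errstate(invalid="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(np.where(np.isnan(matrix), np.nan, matrix), axis=0)
            sd = np.nanstd(matrix, axis=0, ddof=1)
        half = np.full(POST_H, np.nan)
        ok = n >= 2
        half[ok] = stats.t.ppf(0.5 + level / 2.0, n[ok] - 1) * sd[ok] / np.sqrt(n[ok])
        table = pd.DataFrame(
            {
                "hour": np.arange(POST_H),
                "mean": mean,
                "ci_low": mean - half,
                "ci_high": mean + half,
                "n": n,
            }
        )
        out[stratum] = CohortCurve(channel, stratum, table)
    return out


def window_mean(
    diffs: Mapping[str, MatchedDifferenceSeries],
    strata: Mapping[str, str],
    channel: str,
    window: tuple[int, int] = (0, 72),
    level: float = 0.95,
) -> dict[str, WindowSummary]:
    """Per-participant mean difference over the window, summarized per stratum."""
    lo, hi = window
    per_participant = {}
    for pid, series in diffs.items():
        chunk = series.diffs[lo:hi]
        if np.any(~np.isnan(chunk)):
            per_participant[pid] = float(np.nanmean(chunk))
    if not per_participant:
        raise ValueError("no participants with matched differences in the window")
    values = pd.Series(per_participant).sort_index()
    out = {}
    for stratum in STRATA:
        if stratum == "all":
            sel = values[[p for p in values.index if p in strata]]
        else:
            sel = values[[p for p in values.index if strata.get(p) == stratum]]
        mean, lo_ci, hi_ci, n = _t_ci(sel.to_numpy(), level)
        out[stratum] = WindowSummary(channel, stratum, sel, mean, lo_ci, hi_ci, n)
    return out


def welch_test(values_a: Sequence[float], values_b: Sequence[float]) -> TestResult:
    """Two-sided Welch's t-test (unequal variances, Welch-Satterthwaite df)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return TestResult("a", "b", 0.0, float(na + nb - 2), 1.0)
        raise ValueError("both groups are degenerate (zero variance, unequal means)")
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult("a", "b", float(t), float(df), p)


def pairwise_welch(
    summaries: Mapping[str, WindowSummary],
    pairs: Sequence[tuple[str, str]] = (("severe", "mild"), ("severe", "none"), ("mild", "none")),
) -> list[TestResult]:
    """Welch tests between stratified window means for the usual tier pairs."""
    results = []
    for a, b in pairs:
        sa = summaries.get(a)
        sb = summaries.get(b)
        if sa is None or sb is None or sa.n < 2 or sb.n < 2:
            continue
        res = welch_test(sa.participant_values.to_numpy(), sb.participant_values.to_numpy())
        results.append(TestResult(a, b, res.t, res.df, res.p))
    return results


def peak_and_return(
    curve: CohortCurve,
    peak_window: tuple[int, int] = (0, 72),
    sustain_hours: int = 24,
) -> tuple[int, float, Optional[int]]:
    """Locate the peak mean difference and the return-to-baseline hour.

    The peak is the argmax of the mean over ``peak_window``; the return hour
    is the first hour at or after the peak from which the CI contains zero
    for ``sustain_hours`` consecutive hours (hours without a CI do not
    qualify).  Returns (peak_hour, peak_value, return_hour or None).
    """
    table = curve.table
    if table.empty or table["mean"].isna().all():
        raise ValueError("curve has no data")
    mean = table["mean"].to_numpy()
    lo, hi = peak_window
    window = mean[lo:hi]
    if np.all(np.isnan(window)):
        raise ValueError("curve has no data in the peak window")
    peak_hour = lo + int(np.nanargmax(window))
    peak_value = float(mean[peak_hour])

    contains0 = (
        (table["ci_low"].to_numpy() <= 0.0)
        & (table["ci_high"].to_numpy() >= 0.0)
        & ~np.isnan(table["ci_low"].to_numpy())
    )
    # forward run length of CI-contains-zero starting at each hour
    run = 0
    best: Optional[int] = None
    for h in range(len(contains0) - 1, peak_hour - 1, -1):
        run = run + 1 if contains0[h] else 0
        if run >= sustain_hours:
            best = h
    return peak_hour, peak_value, best
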