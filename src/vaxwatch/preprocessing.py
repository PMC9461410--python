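"""Wearable preprocessing: hourly averaging, gap filling, smoothing, baseline matching.

The raw streams (heart rate every 15 s, stress every 3 min) are reduced to
wall-clock hourly means indexed by integer hour offset from the hour
containing the vaccination timestamp.  Missing runs shorter than
``GAP_LIMIT_H`` hours bounded by observed cells are linearly interpolated;
longer runs stay masked.  A centered 5 h moving average smooths the series,
and the post-vaccination fortnight is differenced against the baseline week
at identical day-of-week and hour-of-day.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, SchemaError

CHANNELS = ("heart_rate", "stress")

STATUS_MISSING = 0
STATUS_OBSERVED = 1
STATUS_INTERPOLATED = 2

#: Missing runs of this many hours or more are never interpolated
#: ("fewer than 5 h" is read strictly).
GAP_LIMIT_H = 5

#: Hours in the baseline week and the post-vaccination fortnight.
BASELINE_H = 168
POST_H = 336


@dataclass
class HourlySeries:
    """Hourly means for one participant/channel on a contiguous offset grid.

    ``values[i]`` holds the mean for hour offset ``start + i`` relative to
    the wall-clock hour containing ``origin`` (the vaccination timestamp);
    NaN where the cell carries no value.  ``status`` flags each cell as
    observed, interpolated or missing.
    """

    participant_id: str
    channel: str
    origin: pd.Timestamp
    start: int
    values: np.ndarray
    status: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.status = np.asarray(self.status, dtype=np.int8)
        if self.values.shape != self.status.shape:
            raise ValueError("values and status must have the same shape")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def stop(self) -> int:
        return self.start + len(self.values)

    @property
    def hours(self) -> np.ndarray:
        return np.arange(self.start, self.stop)

    def slice(self, lo: int, hi: int) -> "HourlySeries":
        """Restrict to hour offsets [lo, hi); offsets outside the grid are missing."""
        n = hi - lo
        values = np.full(n, np.nan)
        status = np.zeros(n, dtype=np.int8)
        a = max(lo, self.start)
        b = min(hi, self.stop)
        if b > a:
            values[a - lo : b - lo] = self.values[a - self.start : b - self.start]
            status[a - lo : b - lo] = self.status[a - self.start : b - self.start]
        return replace(self, start=lo, values=values, status=status)

    def cell_timestamp(self, offset: int) -> pd.Timestamp:
        return self.origin.floor("h") + pd.Timedelta(hours=int(offset))


@dataclass
class MatchedDifferenceSeries:
    """Post-minus-baseline hourly differences matched by calendar position.

    ``diffs[h]`` is the difference at post-vaccination hour offset h in
    [0, 336); NaN where either matched cell is missing.
    """

    participant_id: str
    channel: str
    diffs: np.ndarray

    def __post_init__(self):
        self.diffs = np.asarray(self.diffs, dtype=float)
        if self.diffs.shape != (POST_H,):
            raise ValueError(f"diffs must cover [0, {POST_H}) hours")

    @property
    def hours(self) -> np.ndarray:
        return np.flatnonzero(~np.isnan(self.diffs))

    def __len__(self) -> int:
        return int((~np.isnan(self.diffs)).sum())


def hourly_average(
    samples: pd.DataFrame,
    origin: pd.Timestamp,
    start: int = -BASELINE_H,
    stop: int = POST_H,
) -> HourlySeries:
    """Average raw samples into wall-clock hourly cells.

    ``samples`` needs columns participant_id, channel, timestamp, value and
    must hold a single participant/channel.  Hours with at least one sample
    become observed cells; hours without samples are missing.
    """
    channels = samples["channel"].unique() if len(samples) else np.array([])
    if len(channels) > 1:
        raise SchemaError(f"mixed channels in input: {sorted(channels)}")
    pids = samples["participant_id"].unique() if len(samples) else np.array([])
    if len(pids) > 1:
        raise SchemaError(f"mixed participants in input: {sorted(pids)}")
    origin = pd.Timestamp(origin)
    origin_hour = origin.floor("h").to_datetime64()

    n = stop - start
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)
    if len(samples):
        ts = samples["timestamp"].to_numpy(dtype="datetime64[ns]")
        offsets = (ts - origin_hour) // np.timedelta64(1, "h")
        mask = (offsets >= start) & (offsets < stop)
        idx = (offsets[mask] - start).astype(np.int64)
        vals = samples["value"].to_numpy(dtype=float)[mask]
        np.add.at(sums, idx, vals)
        np.add.at(counts, idx, 1)

    values = np.full(n, np.nan)
    status = np.zeros(n, dtype=np.int8)
    has = counts > 0
    values[has] = sums[has] / counts[has]
    status[has] = STATUS_OBSERVED
    pid = str(pids[0]) if len(pids) else ""
    chan = str(channels[0]) if len(channels) else ""
    return HourlySeries(pid, chan, origin, start, values, status)


def _missing_runs(status: np.ndarray) -> Iterable[tuple[int, int]]:
    """Yield (start, stop) index pairs of contiguous missing runs."""
    missing = status == STATUS_MISSING
    i = 0
    n = len(status)
    while i < n:
        if missing[i]:
            j = i
            while j < n and missing[j]:
                j += 1
            yield i, j
            i = j
        else:
            i += 1


def interpolate_gaps(series: HourlySeries, max_gap: int = GAP_LIMIT_H) -> HourlySeries:
    """Linearly fill missing runs shorter than ``max_gap`` hours.

    Only runs bounded on both sides by non-missing cells are filled; runs of
    length >= ``max_gap`` and runs touching either end of the grid stay
    missing.  Non-missing cells are never altered.
    """
    values = series.values.copy()
    status = series.status.copy()
    n = len(series)
    for i, j in _missing_runs(series.status):
        length = j - i
        if length >= max_gap or i == 0 or j == n:
            continue
        left, right = values[i - 1], values[j]
        frac = np.arange(1, length + 1) / (length + 1)
        values[i:j] = left + frac * (right - left)
        status[i:j] = STATUS_INTERPOLATED
    return replace(series, values=values, status=status)


def moving_average(series: HourlySeries, window: int = 5) -> HourlySeries:
    """Centered moving average over non-missing cells.

    Each non-missing cell becomes the mean of the non-missing cells in its
    centered window (available-subset mean at edges and next to masked runs).
    Missing cells stay missing.
    """
    if window % 2 == 0:
        raise ConfigurationError(f"moving-average window must be odd, got {window}")
    smoothed = (
        pd.Series(series.values)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    values = np.where(series.status != STATUS_MISSING, smoothed, np.nan)
    return replace(series, values=values)


def match_baseline(post: HourlySeries, baseline: HourlySeries) -> MatchedDifferenceSeries:
    """Difference post hours against the baseline week at the same calendar slot.

    Post hour h is matched to baseline hour (h mod 168) - 168, i.e. the same
    day-of-week and hour-of-day one or two weeks earlier.  A difference
    exists only where both cells are non-missing.
    """
    if (post.participant_id, post.channel) != (baseline.participant_id, baseline.channel):
        raise SchemaError("post and baseline series must share participant and channel")
    if post.origin != baseline.origin:
        raise SchemaError("post and baseline series must share the vaccination origin")
    if baseline.start != -BASELINE_H or len(baseline) != BASELINE_H:
        raise SchemaError(
            f"baseline window must be exactly [-{BASELINE_H}, 0) hours, "
            f"got [{baseline.start}, {baseline.stop})"
        )
    if post.start != 0 or len(post) != POST_H:
        raise SchemaError(
            f"post window must be exactly [0, {POST_H}) hours, got [{post.start}, {post.stop})"
        )
    base_values = np.where(baseline.status != STATUS_MISSING, baseline.values, np.nan)
    tiled = np.tile(base_values, POST_H // BASELINE_H)
    post_values = np.where(post.status != STATUS_MISSING, post.values, np.nan)
    diffs = post_values - tiled
    return MatchedDifferenceSeries(post.participant_id, post.channel, diffs)


def preprocess_stream(
    samples: pd.DataFrame,
    origin: pd.Timestamp,
    *,
    max_gap: int = GAP_LIMIT_H,
    smooth_window: int = 5,
) -> tuple[HourlySeries, HourlySeries, MatchedDifferenceSeries]:
    """Full preprocessing for one participant/channel stream.

    Returns ``(interpolated, smoothed, matched)``: the hourly series after
    gap filling (the panel-regression input), the smoothed series, and the
    baseline-matched difference series built from the smoothed values.
    """
    hourly = hourly_average(samples, origin)
    interpolated = interpolate_gaps(hourly, max_gap=max_gap)
    smoothed = moving_average(interpolated, window=smooth_window)
    matched = match_baseline(
        smoothed.slice(0, POST_H), smoothed.slice(-BASELINE_H, 0)
    )
    return interpolated, smoothed, matched
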