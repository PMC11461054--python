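"""Dive detection and dive metrics from a drift-corrected depth series.

A dive starts when the (median-filtered) depth exceeds a rolling threshold
and ends when it returns above it. The threshold is recomputed every 18 h
as the median of filtered depths in the top 10 m; a dive must span at least
10 m below its threshold to count. Before thresholding, the depth series is
smoothed with a 75 s (15-sample at 5 s) centered median filter to remove
high-frequency sensor noise; the same filtered series is used for
segmentation so momentary chatter across the threshold does not fragment
dives. Per-sample depth statistics (daily maximum, mesopelagic fraction)
use the unfiltered corrected depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from datetime import datetime

import numpy as np
import pandas as pd

from .archival import ArchivalSeries
from .solar import is_day

__all__ = [
    "DiveEvent",
    "median_prefilter",
    "compute_thresholds",
    "segment_dives",
    "day_night_mask",
    "daily_metrics",
    "dives_to_frame",
]

MESOPELAGIC_M = 200.0


@dataclass(frozen=True)
class DiveEvent:
    """One detected dive."""

    tag_id: str
    start: datetime
    end: datetime
    duration_h: float
    max_depth_m: float
    threshold_at_start_m: float
    max_descent_rate_ms: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("dive end must follow start")
        if self.max_descent_rate_ms < 0:
            raise ValueError("descent rate cannot be negative")


def median_prefilter(series: ArchivalSeries, window_samples: int = 15) -> np.ndarray:
    """Centered running median over ``window_samples`` (75 s at 5 s sampling).

    At the edges the window truncates to the available samples. Requires
    uniform sampling (guaranteed by :class:`ArchivalSeries`).
    """
    depth = pd.Series(series.depth)
    return (
        depth.rolling(window_samples, center=True, min_periods=1).median().to_numpy()
    )


def compute_thresholds(
    series: ArchivalSeries,
    filtered: np.ndarray,
    *,
    window_h: float = 18.0,
    top_m: float = 10.0,
    default_m: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rolling dive-start thresholds: per 18 h window, the median of filtered
    depths in the top 10 m.

    Windows are consecutive and anchored at the first sample. A window with
    no surface-layer samples inherits the previous window's threshold (the
    first window falls back to ``default_m``). Returns
    ``(per_window_thresholds, per_sample_threshold)``.
    """
    elapsed = (series.time.asi8 - series.time.asi8[0]) / 1e9
    win = np.floor(elapsed / (window_h * 3600.0)).astype(int)
    n_win = int(win[-1]) + 1
    thresholds = np.empty(n_win)
    prev = default_m
    for w in range(n_win):
        sel = (win == w) & (filtered <= top_m)
        if sel.any():
            prev = float(np.median(filtered[sel]))
        thresholds[w] = prev
    return thresholds, thresholds[win]


def segment_dives(
    series: ArchivalSeries,
    filtered: np.ndarray,
    sample_threshold: np.ndarray,
    *,
    min_span_m: float = 10.0,
) -> list[DiveEvent]:
    """Extract dives: maximal runs of filtered depth below the active
    threshold, kept only if the excursion spans at least ``min_span_m``
    below the threshold at the dive start.

    Duration is the run length in hours; the maximum descent rate is the
    largest positive sample-to-sample deepening rate of the filtered depth
    within the run (floored at 0 for pure-ascent degenerate runs).
    """
    dt = series.sample_interval
    deep = filtered > sample_threshold
    if not deep.any():
        return []
    edges = np.diff(deep.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0]  # last deep sample of each run
    if deep[0]:
        starts = np.insert(starts, 0, 0)
    if deep[-1]:
        ends = np.append(ends, len(deep) - 1)
    events = []
    for i0, i1 in zip(starts, ends):
        thr = float(sample_threshold[i0])
        seg = filtered[i0 : i1 + 1]
        maxd = float(seg.max())
        if maxd - thr < min_span_m:
            continue
        rate = 0.0
        if len(seg) > 1:
            rate = max(0.0, float(np.max(np.diff(seg)) / dt))
        if i1 + 1 < len(deep):
            end_time = series.time[i1 + 1]
        else:  # run reaches the end of the record
            end_time = series.time[i1] + pd.Timedelta(seconds=dt)
        events.append(
            DiveEvent(
                tag_id=series.tag_id,
                start=series.time[i0].to_pydatetime(),
                end=end_time.to_pydatetime(),
                duration_h=(i1 - i0 + 1) * dt / 3600.0,
                max_depth_m=maxd,
                threshold_at_start_m=thr,
                max_descent_rate_ms=rate,
            )
        )
    return events


def day_night_mask(
    times: pd.DatetimeIndex, lons: np.ndarray, lats: np.ndarray
) -> np.ndarray:
    """Boolean per sample: True in daylight (solar elevation > 0 at the
    sample's interpolated position)."""
    return is_day(times, lons, lats)


def daily_metrics(
    series: ArchivalSeries,
    dives: list[DiveEvent],
    day_mask: np.ndarray,
    *,
    capture_date: Date | None = None,
    mesopelagic_m: float = MESOPELAGIC_M,
) -> pd.DataFrame:
    """Per-day dive metrics.

    One row per UTC day: dive count (dives *starting* that day), daily
    maximum depth, median depth during day and night, and percent of samples
    at mesopelagic depth (>= 200 m). Days on or after a recorded capture
    date (fish taken into a farm) are excluded.
    """
    depth = series.depth
    dates = pd.Series(series.time.date)
    dive_dates = pd.Series([d.start.date() for d in dives], dtype=object)
    rows = []
    for d, idx in dates.groupby(dates).groups.items():
        if capture_date is not None and d >= capture_date:
            continue
        sel = np.asarray(idx)
        z = depth[sel]
        m = day_mask[sel]
        rows.append(
            {
                "tag_id": series.tag_id,
                "date": d,
                "dive_count": int((dive_dates == d).sum()),
                "daily_max_depth_m": float(z.max()),
                "median_day_depth_m": float(np.median(z[m])) if m.any() else np.nan,
                "median_night_depth_m": float(np.median(z[~m])) if (~m).any() else np.nan,
                "pct_mesopelagic": float(100.0 * np.mean(z >= mesopelagic_m)),
            }
        )
    return pd.DataFrame(rows)


def dives_to_frame(dives: list[DiveEvent]) -> pd.DataFrame:
    """Dive events as a tidy table (one row per dive)."""
    return pd.DataFrame(
        [
            {
                "tag_id": d.tag_id,
                "start": d.start,
                "end": d.end,
                "duration_h": d.duration_h,
                "max_depth_m": d.max_depth_m,
                "threshold_at_start_m": d.threshold_at_start_m,
                "max_descent_rate_ms": d.max_descent_rate_ms,
            }
            for d in dives
        ]
    )
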