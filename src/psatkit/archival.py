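"""Archival depth/temperature processing for recovered PSAT records.

A recovered pop-up satellite archival tag yields a depth (pressure) and
temperature time series at a fixed sampling interval (5 s for the tags this
package targets). This module handles the standard processing chain applied
to such records before any behavioural analysis:

1. pressure-sensor drift correction — a cubic polynomial fitted to the daily
   minimum depth and subtracted from the raw series;
2. daily temperature-depth profiles on a regular 1 m grid, median-smoothed;
3. mixed layer depth (MLD) by the 0.2 degC threshold relative to the 10 m
   reference temperature, plus the temperature at the MLD;
4. sea surface temperature (SST) as the median temperature in the top 5 m;
5. profile quality control;
6. depth x temperature habitat envelopes (2 m x 0.5 degC occupancy
   histograms) per (hotspot, season) group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as Date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArchivalSeries",
    "DriftModel",
    "DepthTempProfile",
    "HabitatEnvelope",
    "fit_pressure_drift",
    "correct_depth",
    "build_daily_profile",
    "estimate_mld",
    "estimate_sst",
    "qc_profile",
    "daily_profiles",
    "build_envelopes",
]

TEMP_RANGE = (-3.0, 40.0)


@dataclass
class ArchivalSeries:
    """One tag's archival record: uniform timestamps, depth (m, positive
    down) and ambient temperature (degC).

    ``depth_corrected`` is populated by :func:`correct_depth`; until then it
    is ``None`` and :attr:`depth` falls back to the raw series.
    """

    tag_id: str
    time: pd.DatetimeIndex
    depth_raw: np.ndarray
    temp: np.ndarray
    depth_corrected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = pd.DatetimeIndex(self.time)
        self.depth_raw = np.asarray(self.depth_raw, dtype=float)
        self.temp = np.asarray(self.temp, dtype=float)
        n = len(self.time)
        if len(self.depth_raw) != n or len(self.temp) != n:
            raise ValueError("time, depth and temperature must be equal length")
        if n >= 2:
            steps = np.diff(self.time.asi8)
            if (steps <= 0).any() or len(set(steps)) != 1:
                raise ValueError("timestamps must be strictly increasing and uniform")
        lo, hi = TEMP_RANGE
        finite = self.temp[np.isfinite(self.temp)]
        if finite.size and (finite.min() < lo or finite.max() > hi):
            raise ValueError(f"temperatures outside plausible range {TEMP_RANGE}")

    @property
    def sample_interval(self) -> float:
        """Sampling interval in seconds."""
        if len(self.time) < 2:
            raise ValueError("need >=2 samples to infer the sampling interval")
        return float((self.time[1] - self.time[0]).total_seconds())

    @property
    def depth(self) -> np.ndarray:
        """Corrected depth if available, raw otherwise."""
        return self.depth_raw if self.depth_corrected is None else self.depth_corrected

    @property
    def days_since_start(self) -> np.ndarray:
        return (self.time.asi8 - self.time.asi8[0]) / 86400e9

    def dates(self) -> np.ndarray:
        """Distinct UTC calendar dates covered by the record."""
        return np.unique(self.time.date)

    def day_mask(self, date: Date) -> np.ndarray:
        return self.time.date == date

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"timestamp": self.time, "depth_m": self.depth_raw, "temp_c": self.temp}
        )
        if self.depth_corrected is not None:
            df["depth_corrected_m"] = self.depth_corrected
        return df

    @classmethod
    def from_frame(cls, tag_id: str, df: pd.DataFrame) -> "ArchivalSeries":
        return cls(
            tag_id=tag_id,
            time=pd.DatetimeIndex(pd.to_datetime(df["timestamp"])),
            depth_raw=df["depth_m"].to_numpy(float),
            temp=df["temp_c"].to_numpy(float),
            depth_corrected=(
                df["depth_corrected_m"].to_numpy(float)
                if "depth_corrected_m" in df
                else None
            ),
        )


@dataclass(frozen=True)
class DriftModel:
    """Cubic pressure-drift model: drift(t) in metres, t in days since the
    first sample. ``coeffs`` are in ascending order (c0 + c1 t + c2 t^2 + c3 t^3)."""

    coeffs: tuple[float, float, float, float]
    residual_rms: float

    def __call__(self, t_days: np.ndarray) -> np.ndarray:
        c0, c1, c2, c3 = self.coeffs
        t = np.asarray(t_days, dtype=float)
        return c0 + t * (c1 + t * (c2 + t * c3))

    def to_dict(self) -> dict:
        return {"coeffs": list(self.coeffs), "residual_rms": self.residual_rms}


def fit_pressure_drift(series: ArchivalSeries) -> DriftModel:
    """Fit a third-order polynomial to the daily minimum depth.

    The daily minimum of a surfacing fish tracks the sensor's zero offset;
    its slow evolution is the pressure drift. The abscissa is the (fractional)
    time in days of each day's minimum sample, so unevenly timed surfacings
    do not bias the fit.
    """
    df = pd.DataFrame(
        {"date": series.time.date, "depth": series.depth_raw, "t": series.days_since_start}
    )
    idx = df.groupby("date")["depth"].idxmin()
    if len(idx) < 4:
        raise ValueError(
            f"drift fit needs >=4 distinct days, got {len(idx)}: cubic underdetermined"
        )
    t = df.loc[idx, "t"].to_numpy()
    dmin = df.loc[idx, "depth"].to_numpy()
    coeffs = np.polynomial.polynomial.polyfit(t, dmin, 3)
    resid = dmin - np.polynomial.polynomial.polyval(t, coeffs)
    return DriftModel(tuple(np.round(coeffs, 12)), float(np.sqrt(np.mean(resid**2))))


def correct_depth(series: ArchivalSeries, model: DriftModel) -> ArchivalSeries:
    """Subtract the fitted drift polynomial from the raw depth series.

    No clipping is applied: slightly negative corrected depths are kept, so
    the correction is exactly invertible.
    """
    corrected = series.depth_raw - model(series.days_since_start)
    return replace(series, depth_corrected=corrected)


@dataclass
class DepthTempProfile:
    """One day's temperature-depth profile on a regular 1 m grid.

    ``depth_grid`` holds integer-metre nodes spanning the day's depth range;
    ``temp_grid`` the bin-averaged, gap-interpolated and median-smoothed
    temperatures. ``day_min_depth``/``day_max_depth`` are the day's raw
    extremes (used by QC). ``mld``/``temp_at_mld``/``sst`` are filled in by
    the estimators; ``mld_reason`` records why an MLD is undefined.
    """

    tag_id: str
    date: Date
    depth_grid: np.ndarray
    temp_grid: np.ndarray
    day_min_depth: float
    day_max_depth: float
    qc_pass: bool | None = None
    mld: float | None = None
    temp_at_mld: float | None = None
    mld_reason: str | None = None
    sst: float | None = None

    def temp_at(self, depth_m: float) -> float | None:
        hit = np.nonzero(self.depth_grid == depth_m)[0]
        return float(self.temp_grid[hit[0]]) if hit.size else None


def _truncated_median_filter(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median; at the edges the window is truncated to the
    available nodes rather than padded."""
    half = window // 2
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        out[i] = np.median(x[max(0, i - half) : min(n, i + half + 1)])
    return out


def build_daily_profile(
    series: ArchivalSeries,
    date: Date,
    *,
    grid_res_m: float = 1.0,
    medfilt_window_m: float = 20.0,
) -> DepthTempProfile:
    """Build the day's 1 m-gridded temperature profile.

    The 24 h window starts at midnight UTC. Temperatures are averaged within
    1 m depth bins centred on integer metres, empty bins between the daily
    minimum and maximum depth are filled by linear interpolation (no
    extrapolation beyond the observed range), and a centered median filter
    spanning ``medfilt_window_m`` (21 nodes at the default 1 m grid) smooths
    the profile.
    """
    if series.depth_corrected is None:
        raise ValueError("drift-correct the series before building profiles")
    mask = series.day_mask(date)
    if not mask.any():
        raise ValueError(f"no samples on {date}")
    depth = series.depth_corrected[mask]
    temp = series.temp[mask]
    dmin, dmax = float(depth.min()), float(depth.max())

    z0 = int(np.floor(dmin / grid_res_m))
    z1 = int(np.ceil(dmax / grid_res_m))
    grid = np.arange(z0, z1 + 1) * grid_res_m
    node = np.clip(np.rint(depth / grid_res_m).astype(int) - z0, 0, len(grid) - 1)
    sums = np.bincount(node, weights=temp, minlength=len(grid))
    counts = np.bincount(node, minlength=len(grid))
    filled = counts > 0
    mean_t = np.full(len(grid), np.nan)
    mean_t[filled] = sums[filled] / counts[filled]
    # interior gaps only: the grid already stops at the daily extremes
    mean_t = np.interp(grid, grid[filled], mean_t[filled])

    nodes = max(1, int(round(medfilt_window_m / grid_res_m)) + 1)
    smoothed = _truncated_median_filter(mean_t, nodes)
    return DepthTempProfile(
        tag_id=series.tag_id,
        date=date,
        depth_grid=grid,
        temp_grid=smoothed,
        day_min_depth=dmin,
        day_max_depth=dmax,
    )


def qc_profile(
    profile: DepthTempProfile,
    *,
    max_min_depth_m: float = 10.0,
    min_span_m: float = 25.0,
) -> bool:
    """Profile quality control.

    A day's profile is usable for MLD work only if the fish visited the 10 m
    reference depth (daily minimum depth <= 10 m) and sampled a water-column
    span of at least 25 m. The flag is stored on the profile and returned.
    """
    span = profile.day_max_depth - profile.day_min_depth
    ok = (profile.day_min_depth <= max_min_depth_m) and (span >= min_span_m)
    profile.qc_pass = ok
    return ok


def estimate_mld(
    profile: DepthTempProfile,
    *,
    delta_t: float = 0.2,
    ref_depth_m: float = 10.0,
) -> tuple[float | None, float | None]:
    """Mixed layer depth by the temperature-threshold definition.

    The MLD is the shallowest grid depth at or below the 10 m reference where
    the temperature has dropped at least ``delta_t`` (0.2 degC) below the
    reference temperature; the temperature at that node is returned with it.
    Returns ``(None, None)`` (with a reason recorded on the profile) for
    isothermal days or profiles lacking the reference node.
    """
    t_ref = profile.temp_at(ref_depth_m)
    if t_ref is None:
        profile.mld_reason = "no_reference_node"
        profile.mld = profile.temp_at_mld = None
        return None, None
    deeper = profile.depth_grid >= ref_depth_m
    crossing = deeper & (profile.temp_grid <= t_ref - delta_t)
    if not crossing.any():
        profile.mld_reason = "no_threshold_crossing"
        profile.mld = profile.temp_at_mld = None
        return None, None
    i = int(np.nonzero(crossing)[0][0])
    profile.mld = float(profile.depth_grid[i])
    profile.temp_at_mld = float(profile.temp_grid[i])
    profile.mld_reason = None
    return profile.mld, profile.temp_at_mld


def estimate_sst(
    series: ArchivalSeries, date: Date, *, top_m: float = 5.0
) -> float | None:
    """SST for one day: median temperature over samples in the top 5 m.

    Computed from the corrected depth series and independent of profile QC —
    days whose profile is rejected still contribute an SST when the fish
    visited the surface layer. Returns ``None`` if it never did.
    """
    mask = series.day_mask(date) & (series.depth <= top_m)
    if not mask.any():
        return None
    return float(np.median(series.temp[mask]))


def daily_profiles(series: ArchivalSeries, **kwargs) -> pd.DataFrame:
    """Run the full per-day chain (profile, QC, MLD, SST) over a record.

    Returns one row per day: date, qc_pass, mld, temp_at_mld, sst, and the
    day's depth extremes. MLD fields are NaN on QC-failed days; SST is
    computed regardless.
    """
    rows = []
    for d in series.dates():
        prof = build_daily_profile(series, d, **kwargs)
        ok = qc_profile(prof)
        if ok:
            estimate_mld(prof)
        sst = estimate_sst(series, d)
        rows.append(
            {
                "tag_id": series.tag_id,
                "date": d,
                "qc_pass": ok,
                "mld_m": prof.mld if ok else np.nan,
                "temp_at_mld_c": prof.temp_at_mld if ok else np.nan,
                "sst_c": np.nan if sst is None else sst,
                "day_min_depth_m": prof.day_min_depth,
                "day_max_depth_m": prof.day_max_depth,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class HabitatEnvelope:
    """2-D occupancy histogram of (depth, temperature) samples for one
    (hotspot, season) group. Bin edges sit at multiples of the bin widths;
    ``table`` is long-format (depth_bin, temp_bin, count) listing occupied
    bins only, labelled by their lower edges."""

    hotspot: str
    season: str
    table: pd.DataFrame
    n_samples: int


def build_envelopes(
    samples: pd.DataFrame,
    *,
    depth_bin_m: float = 2.0,
    temp_bin_c: float = 0.5,
) -> list[HabitatEnvelope]:
    """Bin (depth, temperature) samples into habitat envelopes per group.

    ``samples`` needs columns depth_m, temp_c, hotspot, season — one row per
    archival sample, labels interpolated from the daily track. Counts are
    conserved: each envelope's histogram sums to its group's sample count.
    """
    df = samples.copy()
    df["depth_bin"] = np.floor(df["depth_m"] / depth_bin_m) * depth_bin_m
    df["temp_bin"] = np.floor(df["temp_c"] / temp_bin_c) * temp_bin_c
    envelopes = []
    for (hotspot, season), grp in df.groupby(["hotspot", "season"], sort=True):
        table = (
            grp.groupby(["depth_bin", "temp_bin"], sort=True)
            .size()
            .rename("count")
            .reset_index()
        )
        envelopes.append(
            HabitatEnvelope(
                hotspot=str(hotspot),
                season=str(season),
                table=table,
                n_samples=len(grp),
            )
        )
    return envelopes
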