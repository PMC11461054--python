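"""Daily-geolocation track analytics.

Tracks are daily position estimates (one lon/lat per calendar day, the
output of an external geolocation model). This module computes horizontal
speeds, season and hotspot labels, 1 deg x 1 deg occupancy grids with
tag-proportion standardization, data-driven hotspot candidates, per-region
residency with entry/exit dates, and cohort summaries of deployment
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from importlib import resources

import numpy as np
import pandas as pd

from .regions import HotspotRegion, MIGRATORY, assign_hotspots

__all__ = [
    "GeoTrack",
    "haversine_m",
    "horizontal_speed",
    "assign_season",
    "label_track",
    "interpolate_positions",
    "occupancy_grid",
    "identify_hotspots",
    "residency_summary",
    "cohort_residency",
    "load_deployment_table",
    "summarize_deployments",
]

EARTH_RADIUS_M = 6_371_000.0

SEASONS = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}


@dataclass
class GeoTrack:
    """One tag's daily positions. ``df`` columns: date, lon, lat (plus any
    labels added later); at most one record per calendar day."""

    tag_id: str
    df: pd.DataFrame
    capture_date: Date | None = None

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True).copy()
        df["date"] = pd.to_datetime(df["date"]).dt.date
        if df["date"].duplicated().any():
            raise ValueError("duplicate dates in track")
        if (df["lon"].abs() > 180).any() or (df["lat"].abs() > 90).any():
            raise ValueError("coordinates outside valid lon/lat ranges")
        self.df = df.sort_values("date").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance (m) on a sphere of radius 6371 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_M * 2 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def horizontal_speed(track: GeoTrack) -> pd.DataFrame:
    """Speed (m/s) between consecutive daily positions.

    Returns one row per step, dated by the later position. Duplicate dates
    are rejected at track construction.
    """
    df = track.df
    if len(df) < 2:
        raise ValueError("need >= 2 positions to compute speeds")
    lon, lat = df["lon"].to_numpy(), df["lat"].to_numpy()
    dist = haversine_m(lon[:-1], lat[:-1], lon[1:], lat[1:])
    secs = np.array(
        [(b - a).days * 86400.0 for a, b in zip(df["date"][:-1], df["date"][1:])]
    )
    return pd.DataFrame(
        {
            "tag_id": track.tag_id,
            "date": df["date"].iloc[1:].to_numpy(),
            "speed_ms": dist / secs,
        }
    )


def assign_season(date: Date) -> str:
    """Meteorological season: Sep-Nov autumn, Dec-Feb winter, Mar-May
    spring, Jun-Aug summer."""
    return SEASONS[date.month]


def label_track(track: GeoTrack, regions: list[HotspotRegion]) -> GeoTrack:
    """Add ``hotspot`` and ``season`` columns to the track (in place)."""
    df = track.df
    df["hotspot"] = assign_hotspots(df["lon"].to_numpy(), df["lat"].to_numpy(), regions)
    df["season"] = [assign_season(d) for d in df["date"]]
    return track


def interpolate_positions(
    track: GeoTrack, times: pd.DatetimeIndex
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate daily positions to arbitrary sample times.

    Daily positions are taken as midnight UTC anchors; times outside the
    track span clamp to the endpoints. Linear interpolation in lon/lat is
    adequate at daily steps within the study's longitude envelope (no
    antimeridian handling).
    """
    df = track.df
    anchor = pd.to_datetime(df["date"]).astype("int64").to_numpy() / 1e9
    t = times.asi8 / 1e9
    lon = np.interp(t, anchor, df["lon"].to_numpy())
    lat = np.interp(t, anchor, df["lat"].to_numpy())
    return lon, lat


def occupancy_grid(tracks: list[GeoTrack], *, bin_deg: float = 1.0) -> pd.DataFrame:
    """1 deg x 1 deg occupancy grid over all daily geolocations.

    Per bin: ``raw`` = number of daily geolocations, ``tags`` = number of
    distinct tags seen in the bin, and ``standardized`` = raw x
    (tags / total tags) — the raw density down-weighted in bins visited by
    few individuals, so shared habitat stands out over single-fish dwelling.
    """
    if not tracks:
        raise ValueError("need >= 1 track")
    frames = []
    for tr in tracks:
        d = tr.df[["lon", "lat"]].copy()
        d["tag_id"] = tr.tag_id
        frames.append(d)
    allpos = pd.concat(frames, ignore_index=True)
    allpos["lon_bin"] = np.floor(allpos["lon"] / bin_deg) * bin_deg
    allpos["lat_bin"] = np.floor(allpos["lat"] / bin_deg) * bin_deg
    total_tags = allpos["tag_id"].nunique()
    grid = (
        allpos.groupby(["lon_bin", "lat_bin"])
        .agg(raw=("tag_id", "size"), tags=("tag_id", "nunique"))
        .reset_index()
    )
    grid["standardized"] = grid["raw"] * grid["tags"] / total_tags
    return grid


def identify_hotspots(
    grid: pd.DataFrame,
    *,
    percentile: float = 95.0,
    min_span_deg: float = 4.0,
    bin_deg: float = 1.0,
) -> list[dict]:
    """Candidate hotspot regions from an occupancy grid.

    Bins strictly above the ``percentile``-th percentile of standardized
    occupancy (over occupied bins) are grouped into rook-connected
    components; a component is a candidate only if its bounding box spans
    more than ``min_span_deg`` in both longitude and latitude. Returns a
    list of dicts with the component's bins and bounding box.
    """
    occupied = grid[grid["raw"] > 0]
    if occupied.empty:
        return []
    thr = np.percentile(occupied["standardized"], percentile)
    hot = occupied[occupied["standardized"] > thr]
    cells = {(lo, la) for lo, la in zip(hot["lon_bin"], hot["lat_bin"])}
    seen: set[tuple[float, float]] = set()
    out = []
    for cell in sorted(cells):
        if cell in seen:
            continue
        comp = []
        stack = [cell]
        seen.add(cell)
        while stack:
            c = stack.pop()
            comp.append(c)
            lo, la = c
            for nb in ((lo + bin_deg, la), (lo - bin_deg, la), (lo, la + bin_deg), (lo, la - bin_deg)):
                if nb in cells and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        lons = [c[0] for c in comp]
        lats = [c[1] for c in comp]
        span_lon = max(lons) - min(lons) + bin_deg
        span_lat = max(lats) - min(lats) + bin_deg
        if span_lon > min_span_deg and span_lat > min_span_deg:
            out.append(
                {
                    "bins": sorted(comp),
                    "bbox": (min(lons), min(lats), max(lons) + bin_deg, max(lats) + bin_deg),
                    "n_bins": len(comp),
                }
            )
    return out


def residency_summary(track: GeoTrack) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-region residency for one labelled track.

    Returns ``(totals, visits)``: totals has one row per region with day
    counts and percent of track length; visits lists each maximal run inside
    a region with its entry and exit dates (so the first Med visit's entry
    date is the Mediterranean entry).
    """
    df = track.df
    if "hotspot" not in df:
        raise ValueError("label the track with hotspot assignments first")
    totals = (
        df.groupby("hotspot").size().rename("days").reset_index()
    )
    totals["pct_time"] = 100.0 * totals["days"] / len(df)
    totals.insert(0, "tag_id", track.tag_id)

    runs = []
    run_id = (df["hotspot"] != df["hotspot"].shift()).cumsum()
    for _, grp in df.groupby(run_id):
        runs.append(
            {
                "tag_id": track.tag_id,
                "hotspot": grp["hotspot"].iloc[0],
                "entry": grp["date"].iloc[0],
                "exit": grp["date"].iloc[-1],
                "days": len(grp),
            }
        )
    return totals, pd.DataFrame(runs)


def cohort_residency(
    tracks: list[GeoTrack],
    *,
    min_track_days: int = 365,
    exclude_farm_captures: bool = True,
) -> pd.DataFrame:
    """Cohort residency means over qualifying tracks.

    Tracks shorter than ``min_track_days`` days, and fish captured in
    Mediterranean tuna farms (tracks carrying a capture date), are omitted
    before averaging — the short-track/farm-capture exclusion applied to
    reported residency statistics.
    """
    kept = [
        tr
        for tr in tracks
        if len(tr) >= min_track_days
        and not (exclude_farm_captures and tr.capture_date is not None)
    ]
    if not kept:
        return pd.DataFrame(columns=["hotspot", "mean_days", "sd_days", "n_tracks"])
    per = pd.concat([residency_summary(tr)[0] for tr in kept], ignore_index=True)
    wide = per.pivot_table(
        index="tag_id", columns="hotspot", values="days", fill_value=0
    )
    out = pd.DataFrame(
        {
            "hotspot": wide.columns,
            "mean_days": wide.mean(axis=0).to_numpy(),
            "sd_days": wide.std(axis=0, ddof=1).to_numpy() if len(wide) > 1 else np.nan,
            "n_tracks": len(wide),
        }
    )
    return out.reset_index(drop=True)


SIGNIFICANT_EXCLUDE_STATUS = {"never transmitted", "few transmissions", "mortality"}


def load_deployment_table(path: str | None = None) -> pd.DataFrame:
    """Deployment metadata table; the packaged Norway cohort by default."""
    if path is None:
        with resources.files("psatkit").joinpath(
            "data/deployments_norway.csv"
        ).open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    for col in ("tagging_date", "popup_date"):
        df[col] = pd.to_datetime(df[col], format="ISO8601", errors="raise")
    return df


def summarize_deployments(table: pd.DataFrame, *, full_year_days: int = 365) -> dict:
    """Cohort summary of a deployment-metadata table.

    Reports size and status composition, pop-up fraction, curved fork length
    mean/sd over all fish, and deployment-duration statistics over the
    "significant" subset: tags that popped up and either transmitted a
    substantial dataset or were recovered, excluding never-transmitted,
    few-transmission and early-mortality deployments. Also recomputes the
    inclusive duration (pop-up minus tagging plus one day) and lists rows
    whose printed duration disagrees.
    """
    out: dict = {"n_deployments": int(len(table))}
    if table.empty:
        out.update(
            status_counts={}, n_popped_up=0, popup_fraction_pct=np.nan,
            cfl_mean_cm=np.nan, cfl_sd_cm=np.nan, n_significant=0,
            duration_mean_days=np.nan, duration_sd_days=np.nan,
            n_full_year=0, duration_mismatches=[],
        )
        return out
    out["status_counts"] = table["status"].value_counts().to_dict()
    popped = table["popup_date"].notna()
    out["n_popped_up"] = int(popped.sum())
    out["popup_fraction_pct"] = float(100.0 * popped.mean())
    out["cfl_mean_cm"] = float(table["cfl_cm"].mean())
    out["cfl_sd_cm"] = float(table["cfl_cm"].std(ddof=1))

    sig = table[
        ~table["status"].isin(SIGNIFICANT_EXCLUDE_STATUS)
        & ~table["popup_reason"].fillna("").eq("mortality")
    ]
    dur = sig["duration_days"].dropna()
    out["n_significant"] = int(len(sig))
    out["duration_mean_days"] = float(dur.mean())
    out["duration_sd_days"] = float(dur.std(ddof=1))
    out["duration_min_days"] = float(dur.min())
    out["duration_max_days"] = float(dur.max())
    out["n_full_year"] = int((dur >= full_year_days).sum())

    both = table.dropna(subset=["tagging_date", "popup_date", "duration_days"])
    recomputed = (both["popup_date"] - both["tagging_date"]).dt.days + 1
    mism = both[recomputed != both["duration_days"]]
    out["duration_mismatches"] = [
        {
            "tag_id": str(r.tag_id),
            "printed": int(r.duration_days),
            "recomputed": int(rec),
        }
        for (_, r), rec in zip(mism.iterrows(), recomputed[mism.index])
    ]
    return out
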