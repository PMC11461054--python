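"""End-to-end pipeline: simulate -> correct -> profile -> dive -> track ->
stats -> summarize -> report.

Each stage reads its inputs from, and writes its artifacts to, a single
output directory, so stages can be re-run individually (e.g. re-segment
dives from an already-corrected series) and a finished directory is a
self-describing record of the run: ``manifest.json`` stores the full
configuration and its hash, and every table is plain CSV.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import median_abs_deviation

from . import __version__
from .archival import (
    ArchivalSeries,
    build_envelopes,
    correct_depth,
    daily_profiles,
    fit_pressure_drift,
)
from .dives import (
    compute_thresholds,
    daily_metrics,
    day_night_mask,
    dives_to_frame,
    median_prefilter,
    segment_dives,
)
from .regions import MIGRATORY, load_regions
from .stats import (
    binned_median_map,
    kruskal_wallis,
    posthoc_tukey_ranks,
    spearman,
)
from .synthetic import demo_scenario, generate_archival_series, generate_track
from .tracks import (
    GeoTrack,
    cohort_residency,
    horizontal_speed,
    identify_hotspots,
    label_track,
    load_deployment_table,
    occupancy_grid,
    residency_summary,
    summarize_deployments,
)

__all__ = ["PipelineConfig", "run_pipeline", "make_report", "STAGES"]

STAGES = (
    "simulate",
    "correct",
    "profile",
    "dive",
    "track",
    "stats",
    "summarize",
    "report",
)


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline tunables, frozen at their standard values.

    The defaults are the processing parameters of the PSAT analysis this
    package implements: 5 s sampling, 75 s depth prefilter, 18 h threshold
    windows over the top 10 m, 10 m minimum dive span, profile QC at 10 m
    minimum depth / 25 m span, 1 m profile grid with a 20 m median-filter
    window, 0.2 degC MLD threshold, 5 m SST layer, 2 m x 0.5 degC envelope
    bins, 200 m mesopelagic cutoff, 1 deg grids, 95th-percentile hotspot
    threshold over >4 deg x 4 deg regions, and omission of groups with
    n <= 5.
    """

    seed: int = 0
    n_tags: int = 2
    days_per_leg: int = 6
    regions_path: str | None = None
    deployment_table: str | None = None

    sample_interval_s: float = 5.0
    prefilter_window_samples: int = 15
    threshold_window_h: float = 18.0
    threshold_top_m: float = 10.0
    dive_min_span_m: float = 10.0
    qc_max_min_depth_m: float = 10.0
    qc_min_span_m: float = 25.0
    profile_grid_m: float = 1.0
    profile_medfilt_m: float = 20.0
    mld_delta_t_c: float = 0.2
    sst_top_m: float = 5.0
    envelope_depth_bin_m: float = 2.0
    envelope_temp_bin_c: float = 0.5
    mesopelagic_m: float = 200.0
    grid_bin_deg: float = 1.0
    hotspot_percentile: float = 95.0
    hotspot_min_span_deg: float = 4.0
    min_group_n: int = 5
    iccat_meridian_deg: float = -45.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _tag_ids(cfg: PipelineConfig) -> list[str]:
    return [f"SYN{cfg.seed % 1000:03d}{i:02d}" for i in range(cfg.n_tags)]


def _stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    for i, tag in enumerate(_tag_ids(cfg)):
        scen = replace(
            demo_scenario(cfg.seed + i, days_per_leg=cfg.days_per_leg, tag_id=tag),
            sample_interval=cfg.sample_interval_s,
        )
        series, truth = generate_archival_series(scen)
        series.to_frame().to_csv(out / f"series_{tag}.csv", index=False)
        generate_track(scen).to_csv(out / f"track_{tag}.csv", index=False)
        with open(out / f"truth_{tag}.json", "w") as fh:
            json.dump(
                {
                    "drift_coeffs": list(truth.drift_coeffs),
                    "n_true_dives": truth.dive_count(),
                    "true_dives": [
                        [a.isoformat(), b.isoformat(), d]
                        for a, b, d in truth.true_dives
                    ],
                    "true_mld_by_day": {
                        str(k): v for k, v in truth.true_mld_by_day.items()
                    },
                },
                fh,
            )


def _load_series(out: Path, tag: str) -> ArchivalSeries:
    return ArchivalSeries.from_frame(tag, pd.read_csv(out / f"series_{tag}.csv"))


def _load_track(out: Path, tag: str) -> GeoTrack:
    return GeoTrack(tag, pd.read_csv(out / f"track_{tag}.csv"))


def _stage_correct(cfg: PipelineConfig, out: Path) -> None:
    for tag in _tag_ids(cfg):
        series = _load_series(out, tag)
        model = fit_pressure_drift(series)
        series = correct_depth(series, model)
        series.to_frame().to_csv(out / f"series_{tag}.csv", index=False)
        with open(out / f"drift_{tag}.json", "w") as fh:
            json.dump(model.to_dict(), fh)


def _stage_profile(cfg: PipelineConfig, out: Path) -> None:
    frames = [
        daily_profiles(
            _load_series(out, tag),
            grid_res_m=cfg.profile_grid_m,
            medfilt_window_m=cfg.profile_medfilt_m,
        )
        for tag in _tag_ids(cfg)
    ]
    pd.concat(frames, ignore_index=True).to_csv(out / "profiles.csv", index=False)


def _stage_dive(cfg: PipelineConfig, out: Path) -> None:
    dive_frames, metric_frames = [], []
    for tag in _tag_ids(cfg):
        series = _load_series(out, tag)
        track = _load_track(out, tag)
        filtered = median_prefilter(series, cfg.prefilter_window_samples)
        _, sample_thr = compute_thresholds(
            series,
            filtered,
            window_h=cfg.threshold_window_h,
            top_m=cfg.threshold_top_m,
        )
        dives = segment_dives(
            series, filtered, sample_thr, min_span_m=cfg.dive_min_span_m
        )
        lons, lats = _interp_positions(track, series.time)
        mask = day_night_mask(series.time, lons, lats)
        dive_frames.append(dives_to_frame(dives))
        metric_frames.append(
            daily_metrics(series, dives, mask, mesopelagic_m=cfg.mesopelagic_m)
        )
    pd.concat(dive_frames, ignore_index=True).to_csv(out / "dives.csv", index=False)
    pd.concat(metric_frames, ignore_index=True).to_csv(
        out / "daily_metrics.csv", index=False
    )


def _interp_positions(track: GeoTrack, times: pd.DatetimeIndex):
    from .tracks import interpolate_positions

    return interpolate_positions(track, times)


def _stage_track(cfg: PipelineConfig, out: Path) -> None:
    regions = load_regions(cfg.regions_path)
    tracks, speed_frames, totals, visits = [], [], [], []
    env_samples = []
    for tag in _tag_ids(cfg):
        track = label_track(_load_track(out, tag), regions)
        tracks.append(track)
        speed_frames.append(horizontal_speed(track))
        tot, vis = residency_summary(track)
        totals.append(tot)
        visits.append(vis)
        series = _load_series(out, tag)
        lons, lats = _interp_positions(track, series.time)
        from .regions import assign_hotspots
        from .tracks import assign_season

        env_samples.append(
            pd.DataFrame(
                {
                    "depth_m": series.depth,
                    "temp_c": series.temp,
                    "lon": lons,
                    "lat": lats,
                    "hotspot": assign_hotspots(lons, lats, regions),
                    "season": [assign_season(d) for d in series.time.date],
                }
            )
        )
    pd.concat(speed_frames, ignore_index=True).to_csv(out / "speeds.csv", index=False)
    pd.concat(totals, ignore_index=True).to_csv(out / "residency.csv", index=False)
    pd.concat(visits, ignore_index=True).to_csv(out / "visits.csv", index=False)
    cohort_residency(tracks, min_track_days=0).to_csv(
        out / "cohort_residency.csv", index=False
    )
    grid = occupancy_grid(tracks, bin_deg=cfg.grid_bin_deg)
    grid.to_csv(out / "occupancy.csv", index=False)
    with open(out / "hotspot_candidates.json", "w") as fh:
        json.dump(
            identify_hotspots(
                grid,
                percentile=cfg.hotspot_percentile,
                min_span_deg=cfg.hotspot_min_span_deg,
                bin_deg=cfg.grid_bin_deg,
            ),
            fh,
        )
    env = pd.concat(env_samples, ignore_index=True)
    envelopes = build_envelopes(
        env,
        depth_bin_m=cfg.envelope_depth_bin_m,
        temp_bin_c=cfg.envelope_temp_bin_c,
    )
    long = []
    for e in envelopes:
        t = e.table.copy()
        t.insert(0, "season", e.season)
        t.insert(0, "hotspot", e.hotspot)
        long.append(t)
    pd.concat(long, ignore_index=True).to_csv(out / "envelopes.csv", index=False)
    env[["depth_m", "temp_c", "lon", "lat", "hotspot", "season"]].iloc[::60].to_csv(
        out / "envelope_samples_5min.csv", index=False
    )


def _stage_stats(cfg: PipelineConfig, out: Path) -> None:
    profiles = pd.read_csv(out / "profiles.csv", parse_dates=["date"])
    metrics = pd.read_csv(out / "daily_metrics.csv", parse_dates=["date"])
    tracks = {
        tag: _load_track(out, tag).df.assign(
            date=lambda d: pd.to_datetime(d["date"]).dt.date
        )
        for tag in _tag_ids(cfg)
    }
    regions = load_regions(cfg.regions_path)
    from .regions import assign_hotspots

    rows, posthoc_rows = [], []
    merged = []
    for tag, tdf in tracks.items():
        t = tdf.copy()
        t["hotspot"] = assign_hotspots(t["lon"].to_numpy(), t["lat"].to_numpy(), regions)
        p = profiles[profiles["tag_id"] == tag].copy()
        p["date"] = pd.to_datetime(p["date"]).dt.date
        m = metrics[metrics["tag_id"] == tag].copy()
        m["date"] = pd.to_datetime(m["date"]).dt.date
        j = p.merge(m, on=["tag_id", "date"], how="outer").merge(
            t, on="date", how="left"
        )
        merged.append(j)
    data = pd.concat(merged, ignore_index=True)

    for metric in ("mld_m", "dive_count", "daily_max_depth_m"):
        groups = {
            str(k): g[metric].dropna().to_numpy()
            for k, g in data.groupby("hotspot")
        }
        try:
            res = kruskal_wallis(groups, min_n=cfg.min_group_n)
        except ValueError as exc:
            rows.append(
                {"test": "kruskal-wallis", "metric": metric, "statistic": np.nan,
                 "pvalue": np.nan, "note": str(exc)}
            )
            continue
        rows.append(
            {"test": "kruskal-wallis", "metric": metric,
             "statistic": res.statistic, "pvalue": res.pvalue, "note": res.note}
        )
        try:
            ph = posthoc_tukey_ranks(groups, min_n=cfg.min_group_n)
            ph.insert(0, "metric", metric)
            posthoc_rows.append(ph)
        except ValueError:
            pass

    # bin-level medians: MLD vs daily dive frequency
    bins_mld = binned_median_map(data, "mld_m", bin_deg=cfg.grid_bin_deg)
    bins_rate = binned_median_map(data, "dive_count", bin_deg=cfg.grid_bin_deg)
    both = bins_mld.merge(
        bins_rate, on=["lon_bin", "lat_bin"], suffixes=("_mld", "_rate")
    )
    if len(both) >= 4:
        res = spearman(both["median_mld"].to_numpy(), both["median_rate"].to_numpy())
        rows.append(
            {"test": "spearman", "metric": "mld_vs_dive_count",
             "statistic": res.statistic, "pvalue": res.pvalue, "note": res.note}
        )
    pd.DataFrame(rows).to_csv(out / "stats.csv", index=False)
    if posthoc_rows:
        pd.concat(posthoc_rows, ignore_index=True).to_csv(
            out / "posthoc.csv", index=False
        )


def _stage_summarize(cfg: PipelineConfig, out: Path) -> None:
    table = load_deployment_table(cfg.deployment_table)
    summary = summarize_deployments(table)
    with open(out / "deployment_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    flat = {
        k: v
        for k, v in summary.items()
        if np.isscalar(v) and not isinstance(v, str)
    }
    pd.DataFrame([flat]).to_csv(out / "deployment_summary.csv", index=False)


def _stage_report(cfg: PipelineConfig, out: Path) -> None:
    make_report(out, regions_path=cfg.regions_path)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "correct": _stage_correct,
    "profile": _stage_profile,
    "dive": _stage_dive,
    "track": _stage_track,
    "stats": _stage_stats,
    "summarize": _stage_summarize,
    "report": _stage_report,
}


def run_pipeline(
    cfg: PipelineConfig,
    outdir: str | Path,
    stages: list[str] | None = None,
) -> Path:
    """Run the pipeline (or a subset of stages) into ``outdir``.

    Artifacts are deterministic for a fixed config; ``manifest.json``
    records the configuration, its hash, and the package/library versions.
    Stage subsets assume their input artifacts are already present in
    ``outdir`` from an earlier run.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    todo = list(STAGES) if stages is None else list(stages)
    unknown = set(todo) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for stage in STAGES:  # canonical order regardless of request order
        if stage in todo:
            _STAGE_FUNCS[stage](cfg, out)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "stages": [s for s in STAGES if s in todo],
        "versions": {
            "psatkit": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def make_report(artifact_dir: str | Path, *, regions_path: str | None = None) -> dict:
    """Assemble summary tables from a finished artifact directory.

    Writes (and returns as DataFrames):

    - ``report_regions.csv`` — every configured region label plus
      ``Migratory``, with observed geolocation days (0 where unvisited);
    - ``report_envelopes.csv`` — per (hotspot, season): sample count and
      median +/- MAD of depth and temperature (empty groups omitted);
    - ``report_dive_maps.csv`` — 1-deg binned medians of each daily dive
      metric.
    """
    out = Path(artifact_dir)
    if not (out / "residency.csv").exists():
        raise FileNotFoundError("run the track stage before reporting")
    regions = load_regions(regions_path)
    labels = [r.name for r in regions] + [MIGRATORY]
    residency = pd.read_csv(out / "residency.csv")
    days = residency.groupby("hotspot")["days"].sum()
    region_table = pd.DataFrame(
        {"region": labels, "days": [int(days.get(lbl, 0)) for lbl in labels]}
    )
    region_table.to_csv(out / "report_regions.csv", index=False)

    env = pd.read_csv(out / "envelope_samples_5min.csv")
    rows = []
    for (hot, sea), grp in env.groupby(["hotspot", "season"]):
        if grp.empty:
            continue
        rows.append(
            {
                "hotspot": hot,
                "season": sea,
                "n_samples": len(grp),
                "depth_median_m": grp["depth_m"].median(),
                "depth_mad_m": median_abs_deviation(grp["depth_m"]),
                "temp_median_c": grp["temp_c"].median(),
                "temp_mad_c": median_abs_deviation(grp["temp_c"]),
            }
        )
    env_table = pd.DataFrame(rows)
    env_table.to_csv(out / "report_envelopes.csv", index=False)

    metrics = pd.read_csv(out / "daily_metrics.csv", parse_dates=["date"])
    maps = []
    tag_tracks = {
        t: pd.read_csv(p)
        for t, p in (
            (f.stem.removeprefix("track_"), f) for f in out.glob("track_*.csv")
        )
    }
    merged = []
    for tag, tdf in tag_tracks.items():
        tdf = tdf.copy()
        tdf["date"] = pd.to_datetime(tdf["date"]).dt.date
        m = metrics[metrics["tag_id"] == tag].copy()
        m["date"] = pd.to_datetime(m["date"]).dt.date
        merged.append(m.merge(tdf[["date", "lon", "lat"]], on="date", how="left"))
    dm = pd.concat(merged, ignore_index=True) if merged else pd.DataFrame()
    for col in ("dive_count", "daily_max_depth_m", "pct_mesopelagic"):
        if col in dm:
            b = binned_median_map(dm, col)
            b.insert(0, "metric", col)
            maps.append(b)
    map_table = (
        pd.concat(maps, ignore_index=True) if maps else pd.DataFrame()
    )
    map_table.to_csv(out / "report_dive_maps.csv", index=False)
    return {
        "regions": region_table,
        "envelopes": env_table,
        "dive_maps": map_table,
    }
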