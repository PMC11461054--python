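# psatkit

Processing and analysis of **pop-up satellite archival tag (PSAT)** records
from large pelagic fish — built around the kind of year-long deployments
used to study Atlantic bluefin tuna (*Thunnus thynnus*) migrating between
Nordic feeding grounds and the Mediterranean.

A recovered PSAT yields a depth/temperature archive at 5 s resolution; an
external geolocation model yields one position per day. `psatkit` covers
everything downstream of those two inputs:

- **Sensor drift correction** — a third-order polynomial fitted to the daily
  minimum depth (the surfacing signal) and subtracted from the raw record.
- **Daily temperature–depth profiles** — bin-averaged and interpolated onto
  a 1 m grid between the daily depth extremes, smoothed with a 20 m median
  filter, quality-controlled (minimum depth ≤ 10 m, span ≥ 25 m).
- **Mixed layer depth (MLD)** — the threshold definition: the shallowest
  depth ≥ 10 m where T ≤ T(10 m) − 0.2 °C, plus the temperature at the MLD;
  **SST** as the median temperature in the top 5 m.
- **Dive detection** — after a 75 s median prefilter, a dive starts when the
  fish exceeds a rolling threshold (recomputed every 18 h as the median
  depth in the top 10 m) and ends on return; a dive must span ≥ 10 m.
  Per dive: duration (h), maximum depth, maximum descent rate (m s⁻¹); per
  day: dive count, daily maximum depth, median day/night depth (solar
  elevation at the interpolated position), % time at mesopelagic depths
  (≥ 200 m).
- **Track analytics** — great-circle speeds, season labels, hotspot
  assignment against packaged region polygons (Norwegian EEZ, Newfoundland
  Basin, West European Basin, Canaries, Mediterranean; elsewhere
  "Migratory"), 1°×1° occupancy grids standardized by the proportion of
  tags per bin, data-driven hotspot candidates (> 95th percentile,
  > 4°×4°), residency and entry/exit summaries, deployment-cohort
  statistics.
- **Statistics** — Lilliefors normality screening (Monte-Carlo null),
  Kruskal–Wallis tests with the n ≤ 5 group-omission rule, Tukey–Kramer HSD
  post hocs on rank-transformed data, Spearman correlations on 1° bin
  medians.
- **Synthetic deployments** — a generator that renders 5 s archival series
  (mean-reverting surface behaviour, Poisson dives with V/U shapes, a
  two-layer thermal column, cubic pressure drift, sensor noise) and daily
  basin-scale tracks with full ground truth, so every stage is testable
  without any external archive.

## Worked example

```python
import pandas as pd
from psatkit import (REGIMES, TagScenario, generate_archival_series,
                     fit_pressure_drift, correct_depth, daily_profiles,
                     median_prefilter, compute_thresholds, segment_dives)

scen = TagScenario(duration_days=10, regimes=(REGIMES["NOR"],), seed=42,
                   drift_coeffs=(0.02, -1e-4, 0.0))
series, truth = generate_archival_series(scen)
series = correct_depth(series, fit_pressure_drift(series))
daily_min = (pd.Series(series.depth_corrected, index=series.time.date)
             .groupby(level=0).min())
profiles = daily_profiles(series)
filtered = median_prefilter(series)
_, thresholds = compute_thresholds(series, filtered)
dives = segment_dives(series, filtered, thresholds)

print(f"corrected daily minima within {daily_min.abs().max():.3f} m of the true 0 m")
print(f"median MLD: {profiles['mld_m'].median():.1f} m   median SST: {profiles['sst_c'].median():.1f} C")
print(f"dives detected: {len(dives)} ({len(dives)/10:.1f}/day; injected {truth.dive_count()})")
```

prints

```
corrected daily minima within 0.094 m of the true 0 m
median MLD: 29.0 m   median SST: 13.6 C
dives detected: 162 (16.2/day; injected 162)
```

i.e. the injected cubic pressure drift is removed to within sensor noise,
the Nordic-waters regime's 26 m mixed layer and 13.6 °C surface layer are
recovered from the gridded profiles (the 0.2 °C threshold sits a couple of
metres below the layer base by construction), and every injected dive is
found.

The same chain is available as a CLI over a staged artifact directory:

```sh
psatkit run --seed 1 --out artifacts/
psatkit dive --seed 1 --out artifacts/   # re-run one stage in place
```

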