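# Methods

This note documents the models and procedures implemented in `psatkit`,
the parameter choices behind them, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer should know
about.

## The processing chain

The package assumes two inputs per fish: a uniform depth/temperature
archive from a recovered PSAT (5 s sampling by default) and a daily track
of model-estimated positions. The geolocation model itself (light-level
longitudes, SST latitudes, state-space smoothing) is deliberately out of
scope: tracks enter as data.

### Pressure-sensor drift

PSAT pressure sensors drift over months. Because tuna surface at least
daily, the daily minimum of the recorded depth tracks the sensor's zero
offset. We fit a cubic polynomial (least squares, intercept included) to
the daily minima against time in days — using the fractional time of each
day's minimum sample, not the day index, so unevenly timed surfacings do
not bias the fit — and subtract it from the raw series. No clipping is
applied afterwards; slightly negative corrected depths are retained so the
correction is invertible and unbiased. The fit requires at least four
distinct days (a cubic has four coefficients).

### Daily profiles, MLD, SST

For each UTC day (days start at midnight UTC throughout; the tags record
UTC and the analysis never localizes), temperatures are averaged in 1 m
depth bins centred on integer metres between the day's minimum and maximum
depth, interior gaps are filled by linear interpolation (never
extrapolation beyond the observed range), and a centred median filter with
a 20 m window (21 nodes at the 1 m grid, truncated at the profile edges)
removes single-bin artefacts.

The mixed layer depth uses the temperature-threshold definition: the
shallowest grid depth at or below the 10 m reference where
T ≤ T(10 m) − 0.2 °C. The temperature at that node is reported with it;
both are read from the *filtered* profile. Isothermal days return an
undefined MLD with a reason code rather than a sentinel value.

Profile QC rejects days whose minimum depth exceeds 10 m (the reference
node would not exist) or whose depth span is under 25 m (too little of the
water column sampled). SST — the median temperature over samples in the
top 5 m — is computed for every day regardless of profile QC, since it
needs no gridded profile.

One consequence of the threshold definition worth stating: in a column
whose thermocline relaxes exponentially with e-folding scale *h* from the
mixed-layer temperature T_ml to the deep temperature T_d, the 0.2 °C
crossing sits Δz = h·ln(1/(1 − 0.2/(T_ml − T_d))) below the true layer
base. For a sharp thermocline (h ≈ 20 m, ΔT ≈ 8 °C) that is ~0.5 m; for a
diffuse one (h ≈ 100 m) it is several metres. Recovery of a generator's
injected layer base is therefore validated on sharp-thermocline scenarios,
where the definition and the injected truth coincide to within the grid
resolution; in diffuse-thermocline regimes the estimator is still correct
*by definition* but is not comparable metre-for-metre with the injected
base.

### Dive detection

The depth series is first smoothed with a centred 75 s running median
(15 samples at 5 s; edges truncated), which removes single-sample pressure
spikes without rounding genuine dive profiles. Dive-start thresholds are
recomputed every 18 h (windows anchored at the first sample,
non-overlapping) as the median of filtered depths in the top 10 m; a
window in which the fish never visited the top 10 m inherits the previous
threshold, and the first window defaults to 5 m. A dive is a maximal run
of filtered depth below the active threshold, retained only if it spans at
least 10 m below the threshold at its start. Durations are run lengths in
hours; the maximum descent rate is the largest positive sample-to-sample
deepening of the filtered depth (floored at zero).

Segmentation runs on the filtered series — the same smoothing used for the
thresholds — because raw 5 s noise would otherwise fragment dives at the
threshold crossing. Per-sample depth statistics (daily maximum depth, %
time ≥ 200 m) use the unfiltered corrected depth, so extreme depths are
not attenuated. A dive is attributed to the UTC day of its start. Days on
or after a recorded capture date (fish transferred to a farm pen) are
excluded from daily metrics.

Day/night classification uses the standard low-precision solar position
algorithm (NOAA form) at each sample's position, linearly interpolated
from the daily track; "day" is solar elevation above the geometric horizon
(0°), not civil twilight. The algorithm is accurate to a few hundredths of
a degree, far below the effect of daily-scale position uncertainty.

### Track analytics

Speeds are haversine distances (sphere, R = 6371 km) over elapsed time
between consecutive daily positions. Seasons are meteorological
(Sep–Nov autumn, Dec–Feb winter, Mar–May spring, Jun–Aug summer). Hotspot
assignment is point-in-polygon against a GeoJSON region file with a fixed
precedence (Med > NOR > NB > WEB > Canaries) so every position receives
exactly one label; everything outside the named regions is "Migratory".
The packaged polygons are approximations — the Canaries box follows its
published 24–35°N / 21–9°W extent, the Mediterranean is a basin box from
the Strait of Gibraltar east to 36°E, the Norwegian region a simplified
EEZ outline, and the two Atlantic basins rectangular stand-ins — and are
user-replaceable with any GeoJSON of the same schema.

Occupancy grids count daily geolocations in 1°×1° bins. The standardized
value multiplies each bin's raw count by the fraction of all tags seen in
that bin, down-weighting bins occupied by a single individual; the
alternative reading (dividing by the proportion) would do the opposite and
is not what a shared-hotspot map wants. Hotspot candidates are
rook-connected components of bins strictly above the 95th percentile
(linear-interpolation quantile over occupied bins), kept when their
bounding box spans more than 4° in both axes.

Residency summaries count days and maximal runs (entry/exit dates) per
region. Cohort statistics omit tracks shorter than 365 days and fish
captured in farms, matching the exclusion used for published residency
summaries. The deployment-table summary treats a deployment as a
"significant dataset" when it popped up and is neither a never/low
transmitter nor an early mortality — the mortality flag is honoured in
either the status or the pop-up-reason column — and recomputes the
inclusive duration (pop-up − tagging + 1 day), reporting rows whose
printed duration disagrees rather than silently overwriting them.

### Statistics

All comparisons are rank-based. The Lilliefors statistic (KS distance with
estimated mean/sd) gets its p-value from a seeded Monte-Carlo null
(default 10⁴ replicates) rather than table lookup, for bit-reproducibility
across platforms; the add-one estimator keeps p strictly positive. Groups
with five or fewer observations are dropped before any multi-group test.
The omnibus test is Kruskal–Wallis (tie-corrected H, χ² p-value, via
scipy). Post hocs follow the common KW-then-HSD convention: observations
are replaced by their pooled ranks and the unequal-n Tukey–Kramer
procedure (mean ranks, pooled within-group rank variance, studentized
range distribution) gives family-corrected pairwise p-values; the
implementation agrees with statsmodels' `pairwise_tukeyhsd` on ranks to
machine precision (verified in the test suite) and its family-wise error
under a simulated global null is close to the nominal 5%. Spearman
correlations (scipy, tie-handling, t approximation) operate on 1°-bin
medians of the paired quantities, not raw samples, to blunt spatial
pseudo-replication.

## The synthetic generator

The generator exists so that every stage can be validated against known
truth. One scenario fixes a route (waypoints with arrival dates,
great-circle interpolation, one position per day, implied speeds capped at
2.5 m s⁻¹), one behaviour regime per route segment, cubic drift
coefficients, and noise levels; a single integer seed makes all outputs
byte-reproducible.

Vertically, a fish performs a mean-reverting (AR(1), ~20 min reversion)
walk inside a shallow surface layer, touches the surface for ~5 min at a
random time each day (the anchor the drift correction relies on), and
dives as a Poisson process. Each dive descends and ascends at constant
rates drawn from 0.3–2.0 m s⁻¹ — bracketing observed bluefin descent
maxima — with a bottom phase absorbing whatever duration remains (V-shape
when none does), followed by a ≥ 5 min recovery interval ridden just under
the surface, as tuna do after deep excursions; the recovery interval also
guarantees consecutive dives remain separable events after the 75 s
prefilter. Water temperature is a two-layer column: uniform at T_ml above
the injected layer base, exponential relaxation to T_d below. The recorded
depth is truth + cubic drift (days) + Gaussian noise; drift applies to
pressure only, never temperature.

The default regimes (one per hotspot) are calibrated to the reported
behaviour in each region — e.g. ~17 short shallow dives/day over a 26 m
mixed layer in Nordic autumn waters, ~12 long dives/day over a ~97 m
winter mixed layer in the Newfoundland Basin, ~30 dives/day over a warm
11.8 m layer in the Mediterranean summer (22.8 °C surface). These are
plausibility calibrations, not published generative models: no published
per-hotspot dive-rate process exists, so passing tests demonstrate that
the chain recovers what was injected under realistic magnitudes, not that
it reproduces any real fish's archive.

The generator deliberately omits: ocean-current advection, light-level
records and geolocation error beyond bounded jitter, internal waves and
thermocline displacement within a day, tag-shedding physics, and
behavioural autocorrelation beyond the Poisson/AR(1) structure. Results on
real archives will differ most where those features matter — e.g. MLD
variability within a day, or dive chatter near a sharp threshold.

## Problem sizes and runtime choices

The shipped test suite and the acceptance script run desk-scale problems:
20-day single-regime deployments at 5 s (≈ 346 k samples) for drift and
dive-detection round-trips, a 30-day sharp-thermocline scenario for MLD
recovery, 8 days for the Mediterranean SST check, 500 replicates for null
calibrations, and 100 seeded random instances per brute-force oracle
comparison. The demo pipeline compresses the annual route to the minimum
leg durations the speed cap allows (~57 days). These sizes make the whole
suite run in well under a minute while leaving every estimator's sampling
regime (days × samples/day) identical to a full-year deployment's.

## Known limitations

- The packaged basin polygons are rectangles/simplified outlines; regional
  day counts near boundaries depend on them. Replace with surveyed
  boundaries for real analyses.
- Antimeridian crossings are not handled (the study envelope spans
  −54°E to 36°E).
- The MLD threshold definition reports the 0.2 °C crossing, which lags the
  physical layer base in diffuse thermoclines (see above).
- Descent rates are sample-to-sample differences of the filtered depth; a
  longer-baseline definition would give systematically smaller maxima.
- The occupancy standardization multiplies by tag proportion; the factor
  is configurable but the package takes a position on the ambiguity.
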