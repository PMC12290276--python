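# Methods

## Problem setting

Daily surface PM2.5 from a chemical-transport model is biased — typically
inflated during heavy wildfire smoke — while ground monitors are accurate
but sparse. The package produces a daily wildfire-smoke PM2.5 surface by
blending the two, then summarizes long-term exposure per census tract and
relates it to social vulnerability. All stages operate on a regular
lon-lat grid (default 0.625° × 0.5°, the native resolution of the nested
model configuration the pipeline is designed around) with half-open,
0-based cell indexing.

## Sensor QC and calibration

Hourly streams are reduced to daily means per sensor. A day is dropped when
fewer than 75% of the 24 hourly records are present; exactly 18 of 24
(75%) is retained, reading the exclusion rule literally as "fewer than".
Retained daily means ≤ 0 µg m⁻³ are dropped as implausible. Low-cost
sensors report a raw cf1 channel and relative humidity; the affine US
calibration PM2.5 = 0.524·cf1 − 0.0862·RH + 5.75 is applied per hourly
pair by default. Because the form is affine, applying it to daily means of
cf1 and RH gives identical results on the same present hours; the
`calibration="daily"` flag exists so a nonlinear calibration could be
substituted without touching the QC path. RH is validated to [0, 100]%;
cf1 is accepted as recorded, including slightly negative raw values a
clean-air inversion of the affine form can produce — implausible results
are caught at the daily level, not at the raw channel. Daily means are
averaged (unweighted) over sensors sharing a grid cell.

## Blending

The calibration chain runs in a fixed order each day: quantile map →
substitute observations → successive correction. The quantile map is
fitted once, pooled over all (model, observed) sensor-cell day pairs —
pooling statewide is the only well-posed option for networks this sparse;
a per-cell map would need ≥ 100 pairs per cell. Empirical quantiles of
both margins are taken at 101 evenly spaced probabilities (linear
interpolation between order statistics), the transform interpolates
linearly between matched knots, and queries above the model maximum return
the observed 100th quantile (the cap). The cap bounds every mapped value;
a consequence worth knowing is that a value whose quantile-matched image
would exceed the largest observation is censored to it, so exact identity
of the chain under model ≡ obs holds only within the training range.

Substitution installs observed values at sensor cells and records each
cell's bias (quantile-mapped minus observed). The successive correction
method (SCM) spreads those biases to surrounding cells over passes with
shrinking radii (default 3 then 2 cell units) using Cressman weights
w(d) = (R² − d²)/(R² + d²), d Euclidean in cell indices. The accumulated
correction at a cell relaxes toward the local weighted bias mean T with
gain min(Σw, 1):

    A ← A + min(Σw, 1) · (T − A),  A = 0 initially.

This form was chosen over re-subtracting the full weighted bias each pass,
which stacks corrections across passes and overshoots the observed level,
re-introducing the very steps the SCM is meant to remove; with the
relaxation form a single pass applies exactly w·bias for one sensor, two
passes apply 1 − (1−w₁)(1−w₂) of it, and the correction decays
continuously to zero at the influence radius. Sensor cells are never
re-adjusted (they are already exact) and the corrected field is floored at
zero. After quantile mapping most systematic bias is gone, so SCM is a
small, local touch-up: on noisy scenes its effect on ring-cell curvature
is neutral, while on systematic substitution steps it strictly reduces
them.

The coarse non-smoke field is interpolated bilinearly from cell centers to
the fine grid, clamping to the nearest coarse center (with a warning)
where fine centers fall outside the coarse center lattice. The smoke
fraction 1 − nonsmoke/total uses the uncalibrated model total in the
denominator by default: the fraction is a model-internal quantity from the
paired with/without-fire simulations, and dividing by the calibrated total
would mix observation information into a ratio the observations know
nothing about. A flag (`use_calibrated_denominator`) switches this. The
fraction is clamped to [0, 1] (0 where the denominator is 0), so smoke
never exceeds the calibrated total.

Cross-validation refits the whole chain per fold without the held-out
observations: leave-one-cell-out (each sensor cell held out with all its
days) or k-fold over sensor-day records. RMSE and R² = 1 − SSres/SStot are
reported per fold and pooled.

## Exposure metrics

Tract means are area-fraction-weighted zonal statistics: weight =
area(tract ∩ cell)/area over intersecting cells, with areas computed in a
Lambert cylindrical equal-area projection (x = R·λ, y = R·sin φ), which
is exactly equal-area on the sphere — geographic-degree areas would
overweight east–west extent at high latitudes. Daily tract means are
rounded to one decimal before AQI categorization (good < 9.1, moderate
9.1–35.4, dense ≥ 35.5 µg m⁻³) so the breakpoints form an exhaustive
partition; a flag disables rounding. Person-days multiply tract population
by days in category and are additive over tracts and days; weekly
person-days use 7-day bins anchored at May 1 (the final bin of the 153-day
season holds 6 days), so weekly values sum exactly to seasonal totals.
Seasonal means average the 153 season days (May 1 – Sep 30); annual means
divide the season sum by 365/366 with smoke set to zero outside the
season; top-10 means average the ten largest daily values. A smoke wave is
a maximal run of ≥ 2 consecutive moderate-or-dense days, counted within a
season (waves do not span years). Metric correlations are pairwise
Pearson, pairwise-complete, with zero-variance metrics reported missing.

## Vulnerability index

Tracts are ranked ascending per indicator (lowest proportion → rank 1, so
high rank = vulnerable), indicator ranks are summed within the health-
sensitivity (7 indicators) and adaptive-capacity (8 indicators) themes and
re-ranked, and the theme-rank sum is re-ranked into the WSSVI; percentile
= rank/n. Ties take average ranks at every stage, preserving the rank-sum
total n(n+1)/2. The index is invariant to strictly monotone transforms of
any single indicator. Quadrant classification marks a tract "high" on an
axis when its percentile strictly exceeds the threshold (default 0.5, the
median split). Group comparisons use Welch's unequal-variance t-test per
indicator at α = 0.05 with no multiplicity correction by default (a
Benjamini–Hochberg option exists), matching per-indicator reporting
conventions.

## Synthetic scenes

The generator emulates the four real inputs with known ground truth. All
randomness descends from one master seed through named substreams
(`fields`, `model`, `sensors`, `tracts`, `indicators`), so components
regenerate independently and scenes are bit-identical across runs.

- **Truth fields**: non-smoke background is LogNormal(ln 2, 0.3) per
  cell-day — low summer background with a median of 2 µg m⁻³. Each fire
  adds a drifting isotropic Gaussian plume peak·exp(−d²/2L²); smoke is the
  plume sum, total = nonsmoke + smoke exactly. The plume model is a
  spatial kernel, not transport physics: it exists to produce spatially
  coherent, heavy-tailed smoke, with the fire count setting quiet versus
  extreme seasons. Dates default to May 1 – Sep 30.
- **Model distortion**: the fine total is multiplied by a smoothstep ramp
  from 1 at 0 µg m⁻³ to `high_bias` (default 1.8) above 35 µg m⁻³ —
  inflation concentrated in heavy smoke — times LogNormal(0, 0.2) noise.
  The non-smoke field is block-averaged to a 2.5° × 2° coarse grid with
  LogNormal(0, 0.1) noise, emulating a coarser companion simulation.
- **Sensors**: 3 regulatory + 6 low-cost sensors by default, clustered in
  2–3 "population" cells to mimic siting near towns (real siting is not
  documented beyond city names; the clustering is a modeling choice,
  configurable). Regulatory hourly values are truth × LogNormal(0, 0.05);
  low-cost cf1 is the algebraic inversion of the calibration at hourly
  RH ~ Uniform(20, 80), so calibrating a noise-free stream recovers truth
  exactly. Hourly missingness is configurable.
- **Tracts**: ~60% small "urban" rectangles inside single cells (more
  populous), the rest multi-cell "rural" rectangles — mimicking the real
  mixture in which most tracts overlap only 1–2 model cells.
- **Vulnerability indicators**: 15 Beta-distributed proportions with
  realistic base means and sd 0.05; a planted subset of tracts (default
  20%) has every mean shifted up by `effect` (default +0.10), giving a
  known high-vulnerability set the index should recover.

What the scenes do not emulate: atmospheric transport and chemistry,
meteorology-driven plume shapes, emission inventories, sensor drift,
irregular tract shapes, or spatially correlated model error. Passing tests
therefore demonstrate the correctness of the statistical machinery under
known truth, not the accuracy of any particular real-world deployment.

## Problem sizes and numerical choices

Tests and reference computations run on a 16 × 10-cell grid with one
season (40–153 days), 9 sensors and 40 tracts — sizes chosen so the full
suite completes in well under a minute while every code path (multi-cell
tracts, clustered sensors, overlapping plumes) is exercised. Replicated
properties (blending accuracy gain over 20 seeds, index recovery and test
power over 200 replicates) use consecutive seeds from 0. Quantile knots:
101; SCM radii: (3, 2); all fields floored at 0; NetCDF output is
NetCDF3-classic with dims (time, lat, lon) and a "ug m-3" units attribute;
GeoJSON tracts carry a `population` property.

## Known limitations

- The quantile-map cap censors genuinely extreme model values to the
  observed maximum; in regions far more smoky than any monitored cell this
  underestimates peaks (the price of outlier robustness).
- Pooled quantile mapping assumes one statewide model-error distribution;
  per-cell maps are supported only where pairs are plentiful.
- SCM radii are in cell units, so the physical influence distance varies
  with latitude through the lon-lat cell geometry.
- Equal-area weights treat tract polygons as planar in the projected
  space; polygons spanning many degrees of longitude accumulate the usual
  cylindrical distortion of shape (not of area).
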