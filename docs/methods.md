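# Methods

## Model

First flight is modeled as the first day-of-year on which cumulative
degree-days, accumulated from January 1 above a base temperature T₀, reach a
species-specific requirement DD_C. The model has exactly two parameters:

| parameter | units  | meaning | default handling |
|-----------|--------|---------|------------------|
| DD_C      | °C·day | heat requirement for adult flight | calibrated by grid search, 1-DD step |
| T₀        | °C     | base temperature below which no development accrues | scanned 0–10 °C in 0.5 °C steps |

Daily contributions use the four-branch weighted rule on (T_max, T_min)
documented in `phenodd.degree_days`. The rule is continuous across branch
boundaries and non-negative whenever T_max ≥ T_min; both properties are
property-tested. Accumulation restarts every January 1 (no carry-over);
Feb 29 is included in leap years, so series have 365 or 366 entries.

Key modeling conventions:

* **First crossing, no interpolation.** The modeled FF day is the first day
  with cumulative DD ≥ DD_C; day resolution is one day, ties at exact
  equality take the first qualifying day.
* **Regional series are averages of degree-days,** computed per cell and
  then averaged day-wise across a region's cells — not degree-days of an
  averaged temperature. The two differ because the daily rule is nonlinear.
* **Primary search range.** Candidate DD_C values are anchored on the
  min/mean/max (across years) of the regional cumulative-DD series evaluated
  at the observed FF dates, extended ±20%. The regional-series reading is
  used (each observation scored against the *regional* curve of its year);
  the alternative — scoring each observation against its own cell's curve —
  is a defensible variant but would mix the calibration target with the
  point test, so it is deliberately not used here.
* **Calibration.** RMSE (days) between modeled and observed regional-average
  FF over all years with data, minimised over an integer-stepped DD_C grid
  per T₀, then over T₀. Ties break to smaller DD_C, then smaller T₀. An
  arg-min on a search boundary extends the range once by 20% and logs a
  warning. A DD_C candidate that is never reached in more than half the
  observed years is invalid for that region/T₀.
* **Not-reached is a value.** Years in which the series never reaches DD_C
  are excluded from means and RMSE with logged counts; an all-excluded
  period or calibration is an error, never a silent zero.

## Observation assumptions

Raw sightings are first reduced to the earliest entry per exact (lon, lat)
location and year. The spatial join to grid cells uses 0-based indices and
half-open cell intervals [min, max) on both axes, so boundary points belong
to the cell on their north/east side and points on the grid's outer maximum
edge are outside. Then:

* **SVA** keeps every deduplicated observation (scatter = real microclimate
  variability);
* **OBA** keeps the earliest observation per (cell, year) (scatter =
  reporting delay); exact ties keep one representative, since tied earliest
  sightings are indistinguishable to the model.

Summary statistics (spatiotemporal / spatial / temporal means and SDs)
follow the three ways of collapsing point data: all observations pooled;
per-cell means across years; per-year regional means. SDs are sample SDs
(n−1); a single value reports SD 0.

## Two-period change assessment

For two inclusive year ranges (canonically 1951–1980 vs 1981–2010) the
package reports: period means of modeled regional FF and their difference
(advancement, positive = earlier under warming); the change in regional
mean daily temperature (mean of (T_max+T_min)/2 over all days, cells and
years, incomplete cell-years excluded and logged); and the change in
regional degree-days accumulated over fixed windows (through July 31, and
the whole year) per T₀. Missing data never gap-fill: an incomplete
cell-year is dropped from the statistic it would have entered, with a count
in the log.

## Synthetic data generator

The generator emulates the structure of a gridded daily temperature product
and a citizen-science sighting stream:

* daily mean temperature = annual mean + latitudinal gradient + cosine
  seasonal cycle (period 365.25 days for cross-year phase stability, peak at
  `phase_day`, default 200) + year anomaly + step warming + iid daily noise;
  T_max/T_min sit ± half the diurnal range (default 8 °C) around it.
* **Year anomalies** (`year_anomaly_sd`, default 1 °C) are shared by all
  cells and days of a year. They represent warm and cold springs, and they
  are what makes degree-day calibration identifiable from few years: without
  inter-annual variability every DD_C inside one day's accumulation bracket
  fits equally well.
* **Warming** is a step: the later half of the simulated years is uniformly
  warmer by `warming_per_period`. With years 1951–2010 the step falls at
  1981, aligning with the canonical period pair.
* **SVA worlds** give each virtual observer location a persistent
  temperature offset δ ~ N(0, σ), σ default 0.5 °C — a microclimate, not
  daily weather — and its sighting is the first crossing on the offset
  series. **OBA worlds** delay the cell's true FF by an independent
  geometric delay on {0, 1, 2, …} (mean 3 days by default); the zero-mass
  makes the earliest-per-cell estimator consistent as observer density
  grows. Both mechanisms report each observer-year with probability
  `reporting_probability` (default 1).
* The packaged three-region demonstration uses annual means 8.2 / 6.9 /
  3.6 °C (south → north), matching the steep climate gradient of the
  Swedish study regions, with a −0.65 °C/degree latitude gradient.

What the generator does **not** emulate: spatially correlated noise fields,
autocorrelated weather (no AR structure), seasonally varying diurnal range,
observation effort varying over the season, and species misidentification.
Passing recovery tests therefore show the estimator is correct under the
stated mechanisms, not that real citizen-science data satisfy them.

### The warm/cold contrast scenario

`warm_cold_contrast_scenarios()` encodes the qualitative finding that
first-flight advancement across regions can order *opposite* to the mean
temperature rise: a warm region with a flat, maritime seasonal cycle
(8.2 °C mean, 3 °C half-amplitude, +0.8 °C warming) spends much of the year
near the base temperature, so a small warming converts many days from below
to above T₀ and advances FF strongly; a cold continental region (3.6 °C
mean, 15 °C half-amplitude, +1.2 °C warming) wastes most of its larger
warming on days far below T₀. The half-amplitudes are deliberately extreme
(idealized maritime vs continental) to isolate the threshold-conversion
mechanism; both climates are noise-free so the four asserted orderings
(ΔT, advancement, ΔDD to July 31, annual ΔDD) are structural rather than
sampled. With equal seasonal amplitudes the effect does not appear — the
two regions are then mere time-shifts of each other and advancement simply
scales with ΔT — which is itself informative about when mean warming is a
misleading proxy for phenological change.

## Problem sizes and numerical choices

* Recovery experiments use 9 cells × 8 years (noise-free) and 30 cells ×
  8 years × 5 observers over 10 seeds (noisy, σ = 0.5 °C); regional-vs-point
  RMSE uses 20 replicates of 9 cells × 5 years. These sizes give stable
  averages while keeping each experiment in seconds.
* The noise-free recovery world has zero cross-cell scatter (no gradient,
  no daily noise) so the observed regional mean FF is an integer day and
  RMSE can reach exactly 0; inter-annual anomalies (σ = 1.5 °C) provide the
  year-to-year variation that pins DD_C to within the 1-DD search step.
* Recovery calibrations run at the generating base temperature. With few
  noise-free years, neighbouring T₀ values can tie at RMSE 0 with a
  different DD_C — a real degeneracy of threshold models that the
  cross-regional consistency criterion, not raw RMSE, is designed to break.
* Floating comparisons in branch selection are exact (no epsilon): the rule
  is continuous, so ties are harmless. Oracle-equivalence tests use 1e-9
  absolute tolerance.
* Missing-value policy everywhere is exclusion with logged counts, chosen
  over gap-filling for reproducibility and conservatism.

## Limitations

* No uncertainty quantification on DD_C (bootstrap CIs would be a natural
  extension); no photoperiod, chilling or host-plant covariates.
* Only the four-branch daily rule is implemented; the modeling approach is
  agnostic to the degree-day quantification, but alternatives (sine-wave,
  hourly) are out of scope.
* The SVA/OBA pair brackets, rather than models, the true observation
  process; no mixed or probabilistic bias model is provided.
* NetCDF output is NetCDF3 classic (scipy backend): portable, but without
  compression or groups.
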