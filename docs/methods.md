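# Methods

## Data model

A sensor table is a timestamp × sensor grid of volumetric water content
(VWC, m³/m³) with missing cells; timestamps are minute-resolution, strictly
increasing, and carry a fixed local offset with no DST handling — the
loggers step at fixed intervals, and applying civil-time transitions would
fabricate gaps and duplicates. The time grid is built by cumulative
stepping: a first cadence (default 120 min) from the record start up to the
cadence-change timestamp (default 2017-02-01 00:00, configurable), then a
second cadence (default 150 min) through the end. 150 min does not divide
the day, so the second segment drifts across midnight by design; grids are
defined by stepping, never by per-day resets.

Observed timestamps are taken at face value: no resampling, no clock-drift
correction. Files may carry per-logger timestamp sets; readers form the
sorted union and treat absent cells as missing. Missing cells serialize as
empty CSV fields and SQL NULL so round trips are bit-exact. Wide-format
columns are named `<microsite>_<replicate>`, making a wide CSV
self-describing without a side table.

## QC

The anomaly rule is a range test with inclusive bounds, default [0, 1]:
negative readings (calibration-equation imbalance near dry soil) and
physically impossible values become missing; a reading of exactly 0 is
kept. Small negatives near zero may well be noise around a true zero, but
they are nulled regardless — the imputation stage can reconstruct them from
donors, whereas keeping them would poison pair correlations. The rule is
idempotent and only ever adds missingness.

The judgment call of whether a probe "still measures correctly" after an
anomaly is not automated. `peer_consistency` computes windowed correlations
against the microsite peer mean and flags windows below a threshold
(default monthly windows, r < 0.5, ≥20 common cases); a human decides what
to do with flagged sensors.

## Donor selection and imputation

The selection score for candidate donor *x* serving target *y* is
`S = %vc + 100·R² + 100·[same microsite]`, each term in [0, 100].

Decisions where the design was genuinely open:

- **%vc denominator.** Defined as 100 · n_common / n_timestamps (full grid
  length), not relative to the union of either-observed timestamps: a donor
  with longer shared coverage should outrank one with a brief, tight
  overlap, which is the point of the term.
- **Quality value.** The quality column stores the donor model's Pearson r
  (not R²): it is "the correlation coefficient of the model", signed, and
  distinguishable from the 1 assigned to observed cells.
- **Single pass by default.** Only originally observed values donate;
  imputed values never feed later fills, preventing error cascades. Cells
  with no observed eligible donor at their timestamp stay missing — with
  realistic outage patterns this leaves a residual missing fraction, which
  is the honest outcome. `iterative=True` re-runs passes (donor pool = the
  previous pass's output, models still fitted on originally observed
  overlaps) until nothing more fills.
- **One model per pair.** Fitted by OLS on all common valid cases and
  reused for every gap served by that pair; no windowed/local refits.
- **Ties.** Fully ordered: score, then %vc, then lexicographic donor id —
  imputation has no randomness anywhere.
- **Clipping.** Predictions are clipped into [0, 1] (configurable); an
  unclipped negative prediction would immediately re-trigger QC.
- **min_overlap.** Default 100 common cases before a pair may serve gaps;
  OLS slopes on shorter overlaps of sub-daily, highly autocorrelated series
  are too unstable. Tests use smaller values on small grids.

Degenerate inputs: a pair with fewer than two common cases or a constant
series on the overlap has undefined correlation; it reports r = R² = 0 and
is ineligible. `min_overlap < 2` is a configuration error.

## Validation

Reference measurements (e.g. TDR) are paired with the sensor reading
closest in time within the same calendar day and microsite, averaging
whichever replicates are observed at that timestamp — pairing is by day and
microsite, not by individual probe. The sensor value is regressed on the
reference (the reference is the trusted instrument, so it is the
predictor); the axes could defensibly be swapped, and a slope below 1 is
consistent with either direction. Reported: slope β, intercept, R²,
adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2), and a two-sided 95% CI from
Student t with n − 2 df. Requires n ≥ 3 and a non-constant reference.

## Simulator

The generator supplies what the pipeline needs — realistic cross-sensor
correlation structure, heavy block missingness, near-zero anomalies — not a
physically calibrated soil model (no Richards equation, runoff routing or
radiation-driven evaporation).

- **Weather.** Daily rain occurrence is a two-state Markov chain; the
  dry→wet probability is modulated by a seasonal cosine peaking in late
  autumn (amplitude 0.6), wet→wet persistence 0.45, and wet-day depth is
  gamma(0.7, 7.8 mm). These defaults put the long-run mean annual rainfall
  at ≈349 mm and ~65 wet days/yr, a Mediterranean-semiarid climate; mean
  temperature is 15 °C with a 9.5 °C seasonal amplitude peaking in late
  July. Humidity and solar radiation are matching sinusoids plus noise.
- **Soil.** Per microsite, a daily bucket:
  θ_{d+1} = θ_d + a·P_d·(1 − θ_d/θ_sat) − k·(θ_d − θ_res), clipped to
  [θ_res, θ_sat], then time-interpolated onto the sub-daily grid.
  Infiltration gain a (m³/m³ per mm) is ordered Retama > Stipa > BSCh >
  BSCm > BSCl (0.0085 → 0.0045) and drydown k (per day) the reverse
  (0.10 → 0.18), encoding the vegetated-vs-open contrast: plant patches
  gain more water per mm of rain and dry out more slowly. The exact values
  are package defaults chosen to give plausible dryland trajectories, not
  measured constants.
- **Replicates.** Replicate probes share the microsite curve with a
  per-replicate factor f drawn once from [0.95, 1.0] applied to the
  anomaly: θ_rep = θ_res + f·(θ − θ_res). This keeps replicates exactly
  affine in one another (so with zero noise a same-microsite donor model is
  exact, and the same-microsite score bonus is consequential in tests) and
  keeps every truth cell inside [θ_res, θ_sat]; a two-sided factor would
  breach θ_sat.
- **Observation.** I.i.d. Gaussian noise, default sd 0.01 m³/m³ — the
  repeatability level consistent with a ±3% VWC accuracy class. Outages
  arrive per sensor as a Poisson process (12/yr) with lognormal durations
  (log-mean 2.87, log-sd 0.8, i.e. mean ≈24 days), including a 120-day
  pre-record burn-in so the record starts in the stationary regime; the
  stationary busy fraction exp(−λE[D]) ≈ 0.55 matches the ~55% missingness
  of a long-running unattended network. Negative anomalies: readings whose
  truth is within 0.015 of θ_res are, with probability 0.01, replaced by a
  value in (−0.008, 0) and recorded in the mask.
- **Randomness.** One seed spawns independent child streams per mechanism
  (weather / truth / noise / outage / anomaly / validation), so changing
  one mechanism's parameters leaves the other draws bit-identical.

## What passing tests show — and what they do not

The simulator's gaps are missing-completely-at-random at the block level
and its cross-sensor relationships are exactly affine plus noise, so
imputation recovery there (MAE ≈ 0.004–0.005 m³/m³ at noise sd 0.005) is an
upper bound on real-data performance. Real networks have nonlinear
cross-microsite relationships, weather-correlated outages, sensor drift and
recalibration steps, none of which are emulated. What the tests do
establish: the score and donor walk are exactly the advertised algorithm
(verified against brute-force enumeration), observed data are never
touched, provenance is complete, the slope CI is calibrated (coverage
95% ± 3 points over 1,000 replicates), and the whole pipeline is
deterministic under a fixed seed with lossless CSV/SQLite round trips.

## Problem sizes

Tests and the acceptance script exercise the full 15-sensor network over
two simulated years (~8,000 timestamps; ~120,000 cells), 50 random small
networks (≤8 sensors × ≤200 timestamps) for oracle comparisons, 1,000
replicates of n = 169 regressions for CI calibration, and 50–100 simulated
years for climate calibration — sizes at which every check runs in seconds
while still covering the cadence change and multi-seasonal dynamics.
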