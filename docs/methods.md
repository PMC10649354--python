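# Methods note

This note records the modeling choices behind `grazetrack`: what each stage
computes, why the defaults are what they are, what the synthetic herd
generator does and does not emulate, and the numerical decisions worth
knowing before trusting an output.

## Coordinates and geometry

Collar logs may arrive as geographic (lat/lon) or planar (x/y, meters)
coordinates. Geographic fixes are projected with a transverse Mercator
(UTM) implementation built on the standard 6th-order series for the WGS84
ellipsoid (central scale 0.9996, false easting 500 km). The inverse goes
through the conformal latitude and a fixed-point iteration; round-trip error
is below 1e-6 degrees everywhere UTM is defined (|lat| ≤ 84°), and planar
distances agree with independently computed geodesic distances to 0.1% at
paddock scales. `zone_spec="local"` passes already-planar coordinates
through untouched.

Containment uses the closed convention — a fix on the boundary is inside —
because geofencing should not drop an animal standing on the fence line.
Buffering (shade canopies, water troughs are digitized as small footprints
and buffered ~10 m to a use area) uses circular-arc approximation with 64
segments per circle, accurate to well under 1% in area.

## Trajectory metrics

Two conventions drive everything downstream:

- **Collapse stationary runs.** Consecutive identical coordinates are
  collapsed to their first fix, so a step's `dt` is the *time to change
  position*. Rate of travel (distance / time-to-change-position) is
  therefore higher than distance / 24 h: an animal that walks briskly but
  rarely has a high rate and a short moving time.
- **Gaps vs stillness.** A step is invalid only if the *recording* stream
  has a gap longer than `max_gap_s` (default 300 s) inside it. A long step
  produced by a fully recorded stationary run is valid — immobility is
  behavior, not missingness. Invalid steps are excluded from distances and
  budgets; budget percentages are of classified time, so a dropout-afflicted
  day is not biased toward any state.

Days are split on local civil time (`timezone` parameter); a day with less
than `min_coverage` (default 0.8) of its expected fixes is flagged
`excluded`. Resampling to coarser intervals picks the nearest recorded fix
to each tick and refuses intervals at or below the native rate.

## Activity classification

Fixed speed thresholds in m/min: resting < 2.34, grazing 2.34–25
(inclusive on both ends), traveling > 25. The thresholds are the
collar-validation values for grazing steers at 1 Hz; both boundary values
fall to grazing so the grazing class is a closed band. Negative speeds are
an error, not a class.

## Site use

Occupancy is the fix-count share per zone (a time share at constant fix
rate; a weighted variant serves resampled data). LPI divides the time share
by the zone's area share; over an exhaustive partition of the paddock the
area-weighted mean LPI is exactly 1, a property the tests exploit.

Density surfaces bin fixes to a grid (default 1 m cells) and convolve with
a discretized kernel (quartic default; Epanechnikov and Gaussian
available) via FFT. The discrete kernel is renormalized so the surface
integrates to the number of fixes regardless of cell size; the grid is
padded by one bandwidth (five for the Gaussian) so no mass leaks off the
edge. Cells at or above twice the bandwidth trigger an undersampling
warning. Export is ESRI ASCII grid, a text raster any GIS reads.

## THI

`THI = 1.8·Tdb + 32 − (0.55 − 0.0055·RH)·(1.8·Tdb − 26.8)`. Written this
way the two structural facts are explicit: at RH = 100% the correction term
vanishes (THI is the Fahrenheit temperature), and at Tdb = 26.8/1.8 °C the
index is independent of humidity. Both are regression tests.

## Study statistics

Animal-day metrics are averaged across the (two) tester animals to
paddock-days; days with a missing tester are flagged rather than silently
averaged. Paddock-days aggregate to paddock × period cells, one observation
per treatment × block × period, and the fixed-effects model

`Y_ijk = μ + τ_i + β_j + t_k + (τ×t)_ik + ε_ijk`

is fit by the classical balanced sums-of-squares decomposition (verified in
tests against an independent indicator-variable regression). All F ratios
use the residual mean square; with 3 treatments, 4 blocks, and 5 periods the
residual has 42 df. Treatment SEM is √(MSe/(b·p)); letter groups come from
pairwise t tests at α = 0.05 with a greedy compact-letter assignment. The
design must be complete — missing cells raise rather than impute.

Calibration (type-I error, power) uses a response-level simulator that
draws cell values directly as treatment mean + block effect + residual
noise. Residual SD defaults to 1000 m/day (~20% CV of typical daily
distances) and block SD to 200 m/day, chosen a priori as realistic
dispersions; simulating full GPS tracks per calibration replicate would add
nothing because the ANOVA consumes only cell values. A vectorized
implementation of the same decomposition (`treatment_F_pvalues`) makes 2000
null replicates a sub-second computation; the tests verify it matches the
scalar ANOVA exactly.

## Synthetic herd generator

The generator is the package's ground-truth instrument: every estimator is
validated by simulating under known conditions and recovering them.

**Bout process.** Behavior alternates among resting/grazing/traveling with
exponential bout durations (means 1200/300/90 s). When a `target_budget` is
given — the default, since the treatment conditions are budgets — each
day's per-state time is fixed at the target share, split into
exponential-length bouts, and shuffled. This quota scheduling makes the
ground-truth budget equal the design budget by construction, so parameter-
recovery tests measure classifier error, not bout-process sampling noise.

**Movement.** Moving bouts draw per-step speeds from a truncated lognormal
(grazing mean 8 m/min within the grazing band; traveling mean calibrated so
the designed budget yields the designed daily distance — 55 m/min at the
defaults). Headings follow a correlated random walk with wrapped-Cauchy
turning angles (ρ = 0.7). The rectangular paddock boundary reflects
(triangle-wave folding), preserving step lengths.

**Site attraction.** Before a rest, the animal may walk goal-directed to
shade (probability 0.35) or water (0.18); the goal persists across moving
bouts until reached, the animal then mills inside the zone until the rest
completes, and afterwards walks back into the open paddock. The two
probabilities were sized so a run of days loafs roughly a fifth of the day
in shade and a tenth at water — the pattern reported for confined grazing
cattle — while leaving the budget quotas untouched.

**GPS error.** Collar error is modeled as a slowly drifting correlated
(Ornstein–Uhlenbeck) offset with 5 m marginal SD and one-hour correlation
time, updated on a 60 s hold grid and quantized to 0.1 m. Independent
per-fix noise at 1 Hz would be physically wrong: it would put every
stationary fix above the traveling threshold, and no speed classification
could work on such data — real 1 Hz solutions drift smoothly. Under the
default error model the classified budgets stay within a few points of
truth with a grazing-ward bias, and daily distance is inflated by roughly a
quarter — both effects field collar data show. `gps_noise_sd_m=0` is an
exact pass-through.

**Study layout.** `simulate_study` randomizes treatment order within each
block, applies per-period budget jitter and lognormal day/block speed
multipliers, and emits the file tree the pipeline ingests: collar CSVs,
per-paddock zone GeoJSON (boundary feature first), design table
(CSV + YAML), and per-day ground truth.

**Climate.** Daily Tdb and RH follow AR(1) processes (φ = 0.5) around
means of 26.5 °C and 80% — Gulf-coast summer daily means (26.5 °C is a
daily mean, not a daily max) — giving period-mean THI in the light-stress
74–79 band.

## Problem sizes

The shipped analysis drivers run a reduced-scale study — 12 paddocks ×
2 testers × 2 periods × 2 full 1 Hz days (~8.3 M fixes) — which this
package chooses as a size that exercises every stage in about two minutes
on one core. The estimators themselves are vectorized (step metrics and
classification are O(n) array passes; KDE is one FFT per paddock) and
handle full 5-period, 21-day seasons; only total runtime scales.

## Limitations

- The generator does not model forage selectivity: strips are geometry
  only, so strip-type preference in simulated data reflects where shade and
  water sit, not diet choice. Strip LPIs from field tables are therefore
  desk-checked directly rather than re-simulated.
- No diurnal structure (grazing bouts are as likely at 03:00 as at 18:00),
  no herd interaction, no put-and-take stocking adjustments.
- Dropout is Bernoulli per fix; real collars lose fixes in bursts.
- The ANOVA is fixed-effects per season; multi-year analyses with random
  year effects are out of scope.
- The THI band check uses simulated climate as its summer-typical input;
  observed weather-station records can be supplied through
  `read_climate_csv` instead.
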