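# Methods

## Problem setting

A trainee surgeon's instrument handling changes with accumulated cases.
Given frame-by-frame tip coordinates for each instrument in each recorded
operation, the package quantifies that change as (i) six per-case kinematic
parameters, (ii) a nonparametric trend analysis of each parameter across
the case series, and (iii) a single change-point locating the largest
distributional shift. The data model assumes one trainee (one ordered case
series), 2-D pixel coordinates in the video frame (no depth), and a known,
constant frame rate.

## Trajectory model

A trajectory is a list of *segments*: runs of consecutive frames over which
the tip was reliably tracked. Tracking pauses (instrument out of view, tip
occluded) appear only as frame-index gaps — there are no sentinel rows, and
no kinematic quantity is computed across a gap, because the motion there is
unobserved. Coordinates are 0-based pixel centers, origin top-left,
y downward (the convention of point-annotation tools); defaults are
1920×1080 px at 15 frames/s.

## Kinematic parameters

All derivatives are vector finite differences at the frame timestep,
converted to seconds by the fps factor; reported velocity/acceleration are
means of magnitudes, jerk is root-mean-square of magnitudes. Magnitude
aggregation keeps every parameter nonnegative and makes the trend direction
interpretable ("less" = calmer motion). The alternatives (per-axis RMS,
time-weighted means) are isolated behind one function each and can be
swapped without touching the pipeline.

- Path length: sum of step lengths over all segments. Defined for any
  track; 0 if no displacement exists.
- Average velocity: mean step length × fps. Undefined (NaN) without at
  least one step.
- Average acceleration: mean ‖Δv‖ × fps within segments; needs ≥3
  consecutive tracked frames.
- RMS jerk: √mean‖Δa × fps‖²; needs ≥5 consecutive frames. RMS (rather
  than mean) follows the standard smoothness-metric convention and
  penalizes bursts.
- Angular change: unsigned turn angle at each interior vertex, computed
  with atan2(|cross|, dot) for stability near 0° and 180°. Vertices with a
  zero-length incoming or outgoing step are skipped and excluded from the
  average's denominator (a stationary tip has no direction, so treating
  the vertex as 0° or 180° would bias the mean).
- Workspace coverage: area of the convex hull of all tracked points.
  "Area traversed" has no unique definition; the hull is deterministic and
  parameter-free. A grid-occupancy variant (configurable cell size) is
  provided for sensitivity analysis but is not the default.

Undefined metrics are NaN, never 0 — a zero would be read as "perfectly
smooth/stationary" downstream. The analysis layer drops NaNs listwise per
series and logs the count.

No smoothing is applied before differentiation by default; a centered
moving-average pre-filter is available (`smooth_track`) for studying the
sensitivity of jerk to annotation noise.

## Trend inference

The per-case series of each (instrument, parameter) pair is analyzed
against **case number** (not video index): case number is the actual
experience axis, and recorded videos are unevenly spaced along it. Percent
changes are reported per `10 × mean inter-video case spacing` cases
("per 10 videos", ≈ 76 cases for the default 100-video, 6–760 design), with
a `per_case` switch for the unit alternative.

- **Mann–Kendall**: S = Σ_{i<j} sgn(y_j − y_i); Var(S) with the standard
  tie-group correction; z = (S∓1)/√Var(S) (continuity correction; z = 0
  when S = 0); two-sided normal p. The normal approximation is used at all
  n — at the target n ≈ 100 its error is negligible, and the exact
  permutation distribution is retained only as a test oracle (verified to
  agree within 0.05 for all tie-free n ≤ 7).
- **Theil–Sen**: median of all pairwise slopes, ties in the abscissa
  excluded. The 95% CI uses Sen's rank method: C = z₀.₉₇₅·√Var(S); the
  bounds are the order statistics of the sorted slope list at 1-based ranks
  (N−C)/2 and (N+C)/2 + 1, linearly interpolated at fractional ranks and
  clamped into [1, N]. Measured coverage under the metric-level generator
  is ~95–96% at n = 100 (the interpolation convention is mildly
  conservative).
- **Percent change**: 100 × slope × scale ÷ median(y), CI bounds
  transformed identically. Median normalization matches the robust slope
  and keeps the quantity well-defined for skewed metrics.
- **Spearman**: product-moment correlation of average ranks; p from the
  t-approximation with n−2 df, floored at the smallest positive float so a
  perfect correlation still reports p ∈ (0,1].
- **Bonferroni**: p_adj = min(1, m·p). The family m defaults to
  (#instruments × #parameters) present in the table — 66 for the full
  11-instrument design — and is overridable when an analysis is
  pre-registered with a different family.

## Change-point detection

Pettitt's test: U_t = Σ_{i≤t} Σ_{j>t} sgn(y_j − y_i), K = max|U_t|,
p ≈ min(1, 2·exp(−6K²/(n³+n²))). Ties in the maximum resolve to the
earliest index (deterministic; favors early detection). The reported
`tau_case` is the case number of the **last pre-change observation**; the
split lies between it and the next case, and output headers state the
convention. By default the scan runs only on path length and average
angular change — the two parameters with the most direct skill
interpretation — with the subset configurable. The approximate p is known
to be conservative under the null (measured ~3–4% rejection at α = 0.05,
n = 100); only a single change-point is modeled (multiple-change-point
segmentation is out of scope).

## LOESS trendlines

Scatterplot smoothing for the report plots: for each evaluation point, the
⌈span·n⌉ nearest neighbors receive tricube weights (1−(d/d_max)³)³ and a
weighted straight line is solved locally (falling back to the weighted mean
when the local design is degenerate). Default span 0.75, no robustness
iterations; the span is recorded in the run manifest. LOESS is
presentation-only — all inference comes from the rank statistics.

## Synthetic data generator

Two layers, because the trajectory → metric map is nonlinear:

1. **Metric level** — y_c = base·(1 + trend·(c−c_min))·(1 + shift·1[c>τ])·ε_c
   with lognormal ε. Exact ground truth for testing the statistics in
   isolation. The generator refuses configurations whose noiseless mean
   goes nonpositive inside the schedule (a linear −0.15%/case trend, for
   example, is only valid over windows shorter than ~650 cases).
2. **Trajectory level** — a correlated random walk per case: step lengths
   gamma(2, s(c)/2) with s(c) = s₀·exp(β·(c−c_min)) (and an optional
   multiplicative shift past a change-point case), headings accumulated
   from von Mises turning angles with concentration κ(c) =
   κ₀·exp(β_κ·(c−c_min)), reflection at the frame borders, and random
   pauses (geometric gap lengths) splitting the track into segments.

Exponential (not linear) trends cannot go negative over a 754-case span
and keep "percent per case" interpretable. Multiplicative lognormal noise
keeps metrics positive. Defaults — s₀ = 6 px/frame, β = −0.0011/case,
β_κ = +0.0011/case, pause probability 0.002/frame, case-level noise
σ = 0.15, 100 videos drawn without replacement from cases 6–760 at 15 fps
in a 1920×1080 frame — put the per-10-video percent changes in the −2% to
−12% band that is plausible for a first-year trainee. They are a
plausibility envelope for testing the analysis, not measurements of any
surgeon; in particular the generator emulates monotone decay plus a single
abrupt shift and case-level lognormal dispersion, but not case-complexity
covariates, supervisor effects, instrument-specific usage phases, tracker
noise autocorrelation, or heavy-tailed outlier cases. Passing tests
demonstrate that the estimators recover known structure of this form — not
that clinical data has this form.

All randomness flows through `numpy.random.Generator` (PCG64) seeded from
the configuration, so a fixed seed reproduces every trajectory, schedule
and table bit-for-bit.

## Validation problem sizes

The test suite and `scripts/acceptance.py` size their simulations to run
comfortably on one CPU: 1,000 random series (n ≤ 100) for oracle
equivalence, all 5,910 tie-free orderings with n ≤ 7 for small-sample
exactness, 10,000 replicates for type-I calibration, 500 replicates each
for CI coverage and change-point recovery, 200 random tracks for the
kinematic invariances, and a 3-instrument × 100-case × 400-frame battery
for the end-to-end sign-recovery run.

## Known limitations

- 2-D pixel kinematics: no depth, forces, bimanual coordination or
  foot-pedal state; zoom or camera motion would alias into the metrics.
- The hull-based workspace is insensitive to how densely the interior is
  visited; the grid variant trades that for a cell-size parameter.
- The Pettitt approximation assumes exchangeability under the null;
  autocorrelated series inflate K. Autocorrelation-robust variants are out
  of scope.
- Percent change is undefined for series with zero median, and Spearman
  for constant series; both are reported as NaN rather than imputed.
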