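# surgmotion

Kinematic learning-curve analytics for frame-by-frame surgical
instrument-tip trajectories.

Surgical skill is usually graded by subjective preceptor ratings. An
objective alternative is to track the tip of each instrument across every
frame of an operative video and quantify how its motion changes as a
trainee accumulates cases. `surgmotion` implements that analysis for
phacoemulsification cataract surgery (11 instrument classes, from sideport
knife to IOL inserter), but nothing in the statistics layer is specific to
ophthalmology: any per-case trajectory series works.

## What it computes

**Kinematics.** From per-frame tip coordinates (x, y in pixels; tracking
pauses encoded as frame gaps), six aggregate motion parameters per
(instrument, case):

- total path length `L = Σ‖Δr_k‖` (px)
- average velocity `mean(‖v_k‖)`, `v_k = Δr_k · fps` (px/s)
- average acceleration `mean(‖a_k‖)`, `a_k = Δv_k · fps` (px/s²)
- RMS jerk `√(mean ‖j_k‖²)`, `j_k = Δa_k · fps` (px/s³) — smoothness
- average angular change: mean unsigned angle ∈ [0°, 180°] between
  consecutive displacement vectors
- workspace coverage: convex hull area of all tracked points (px²)

No displacement, angle or derivative is ever taken across a tracking gap.

**Trend inference.** Per (instrument, parameter) series ordered by case
number: the Mann–Kendall test (`S = Σ_{i<j} sgn(y_j − y_i)`, tie-corrected
variance, continuity-corrected normal p), the Theil–Sen slope (median of
all pairwise slopes) with Sen's rank-based 95% CI, the percent change per
10 recorded videos (slope × scale ÷ series median × 100), Spearman rank
correlation, and Bonferroni correction across the full
(instrument × parameter) family.

**Change-point detection.** The Pettitt test
(`U_t = Σ_{i≤t} Σ_{j>t} sgn(y_j − y_i)`, `K = max|U_t|`,
`p ≈ 2·exp(−6K²/(n³+n²))`) locates a single proficiency transition, by
default on path length and angular change.

**Synthetic data.** A two-level generator — correlated random walks per
case (gamma step lengths with exponentially decaying scale, von Mises
turning angles with rising concentration, random pauses, optional abrupt
shift) and direct metric-level series with exact known truth — so every
stage of the pipeline is testable without clinical video.

## Worked example

```python
import numpy as np
from surgmotion import generate_metric_series, mann_kendall, theil_sen, percent_change

schedule = np.arange(6, 761, 8)            # ~95 recorded cases across training
cases, y = generate_metric_series(trend=-0.001, base=5000.0,
                                  schedule=schedule, sigma=0.12, rng=3)
S, varS, z, p = mann_kendall(y)
slope, lo, hi = theil_sen(cases.astype(float), y)
pct, pct_ci = percent_change(slope, y, scale_factor=80.0, ci=(lo, hi))
print(f"S={S}, z={z:.2f}, p={p:.2e}")
print(f"Sen slope {slope:+.2f} px/case, pct change {pct:+.2f}% per 10 videos")
```

prints

```
S=-3573, z=-11.48, p=1.58e-30
Sen slope -4.93 px/case, pct change -12.73% per 10 videos
```

The generating truth was −5.0 px/case: the Mann–Kendall test detects the
monotone decline decisively, the Sen slope recovers the magnitude within
2%, and the normalized form reads as "path length falls ~13% for every 10
videos recorded". The `examples/` directory has one narrative script per
capability (simulation, kinematics, trend inference, change-points, full
report); `surgmotion --help` exposes the same stages as a CLI
(`simulate`, `metrics`, `trends`, `changepoints`, `report`).

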