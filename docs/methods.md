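# Methods

## Coordinate frame

All computation happens in a local tangent plane (metres east/north of an
origin, usually the array centroid). Geographic input is projected with a
local equirectangular projection, `x = R cos(lat₀) Δlon`, `y = R Δlat`
(`R = 6 371 000 m`): it is exactly invertible, and over the ≤1 km extent
of a receiver array its distance error relative to the great-circle
distance is far below the positioning noise (<0.1%, verified against a
haversine oracle in the tests). Full geodesy (UTM, datum transforms,
depth) is deliberately out of scope: the positioning problem is treated
as 2-D, which is the standard operating assumption for shallow-water
arrays where vertical offsets are small relative to horizontal ranges.

## TDOA solver

For three receivers the system `|p − r_i| = c (a_i − t0)` is reduced
algebraically: subtracting the squared equation for receiver 1 from the
other two cancels `|p|²`, leaving two equations *linear in p* whose
right-hand sides are *linear in t0*. Solving that 2×2 system expresses
`p(t0) = p0 + p1·t0`; substituting into receiver 1's range equation
yields a quadratic `(|p1|² − c²) t0² + 2(q·p1 + c² a₁) t0 + (|q|² − c² a₁²) = 0`
with `q = p0 − r₁`. Real roots with `t0` not after the earliest arrival
are physical candidates; a root after the first arrival would imply sound
received before emission. The solver is exact (≤10⁻⁶ m) on noise-free
forward-simulated input, which the tests check on 1000 random interior
sources.

Numerical choices: receivers whose triangle area is ≤10⁻⁶ m² are rejected
as collinear (the 2×2 system is singular; TDOA from a line of receivers
cannot resolve the side ambiguity); a near-zero quadratic leading
coefficient falls back to the linear root; a slightly negative
discriminant within rounding of zero is treated as a double root; roots
are accepted up to 1 ns past the earliest arrival to absorb rounding.

### Error sensitivity and subset combination

The field system this emulates combines all three-receiver subsets with
a weighting that "favours the lowest error sensitivity", without a
published formula. We define a subset's sensitivity as the Frobenius norm
of the 2×3 Jacobian of position with respect to the three arrival times —
dimensionally a m/s quantity mapping timing error to position error, the
TDOA analogue of geometric dilution of precision. By the implicit
function theorem it has the closed form `c · inv(M)` (first two rows),
where row `i` of `M` is the unit vector from receiver `i` to the solution
followed by `c`; the tests verify it against a central finite-difference
oracle (step 10⁻⁷ s, agreement 10⁻³ relative). Subsets are combined by a
weighted mean with weights `1/s²` — inverse-variance weighting under the
approximation that a subset's position error scales linearly with `s` —
applied to position and emission time alike; the fix reports the minimum
subset sensitivity and the number of distinct receivers. Weighting only
the single best subset would discard information; equal weighting would
let ill-conditioned subsets dominate the error budget.

Two-root ambiguity is resolved per transmission: candidates farther than
three array diameters from the array centroid are discarded as
implausible; subsets left with one candidate anchor an unweighted mean
position, and each still-ambiguous subset keeps the candidate closest to
that anchor (cross-subset consistency being the only information
available); if every subset is ambiguous, each keeps its lower-sensitivity
candidate. With ≥4 receivers the true root is shared across subsets and
the ghost roots scatter, so the anchor almost always identifies it.

### Grouping

Detections are clustered into transmissions per tag by splitting the
sorted arrival sequence wherever the gap exceeds (array diameter)/c +
guard — no two receivers can hear one ping further apart in time than the
array's acoustic traversal. The guard default (0.05 s) covers the <10 ms
ping duration plus clock slack. Within a group only the earliest
detection per receiver is kept (a later duplicate is multipath or noise),
and groups with fewer than three distinct receivers are discarded since
they cannot be positioned. No quality filtering is applied to the
resulting fixes: downstream statistics see every estimate.

## Trial statistics

*Accuracy* is the planar distance from each fix to an independent
reference: a surveyed point for stationary deployments, or the reference
track linearly interpolated to the fix time for moving trials (reference
assumed sampled at ~1 Hz; fixes more than 2 s outside the reference span
are dropped and counted rather than extrapolated). *Precision* is the
distance from each fix to the coordinate-wise median fix of the trial —
deterministic, robust, and blind to constant frame bias, so a biased but
repeatable system scores precise and inaccurate, which is exactly the
diagnostic contrast the two statistics are meant to provide. Summaries
are the median, 5th/95th percentiles (linear interpolation between
closest ranks) and range.

## Thinning and movement metrics

`thin_track` keeps the first fix and then each fix whose gap from the
last-kept fix is ≥ the minimum period. This greedy scan is equivalent to
the iterative procedure of repeatedly deleting the first fix whose gap
from its predecessor is below the threshold — both remove exactly the
fixes following the current anchor too closely — and the tests prove the
equivalence exhaustively on every subset of integer times 0..12 and on
random tracks. Consequences asserted as properties: the output is a
subset of the input, the first fix survives, all retained gaps meet the
threshold, the operation is idempotent, and the retained count is
non-increasing in the threshold. Retained *sets* do not nest across
thresholds (greedy anchors drift), so total path length is guaranteed
≤ the native length (triangle inequality) but may wobble slightly
between adjacent thresholds; only the declining trend is asserted.

Movement metrics per track: total distance (sum of step lengths), speed
(step length / step duration), and unsigned turning angle in degrees
(0 = straight) at each interior vertex; vertices adjacent to a
zero-length step have no defined angle and are skipped and counted.
Position-period summaries report the median and range of inter-fix
intervals; multi-animal tables take the median (range) across the
per-animal medians rather than pooling intervals, so no animal dominates.
The metric-versus-period regression is ordinary least squares
(statsmodels) of the — optionally log₁₀-transformed — metric on
transmission period, pooled across animals, reporting slope, intercept,
r², F(1, n−2) and p. Whether mean or median per-step speed/angle enters
the regression is a caller choice; the sensitivity table reports both.

## Synthetic-data generator

The generator emulates the field configuration the toolkit targets, and
its defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| array | centre + regular hexagon, 7 receivers | matches the reported mean nearest spacing exactly; only spacing statistics, not coordinates, are reported for the field array |
| spacing | 77.1 m | reported mean nearest-neighbour spacing |
| sound speed `c` | 1447 m/s | fresh water at the reported ~10 °C |
| transmission period | uniform on [1, 2] s (test tags) / [3, 5] s (fish tags) | reported mean and range; uniform is the minimal assumption matching both |
| timing noise `sigma_t` | 10⁻⁴ s | ≈0.145 m per arrival at `c`; yields the decimetre-to-metre position scatter typical of such systems |
| clock offsets `sigma_clock` | 0 | receivers are sync-tag synchronised |
| detection model | logistic in range, `d50` = 150 m, `k` = 0.05 m⁻¹ | within-array detection ≈ certain, loss grows smoothly with range; the field range test's exact numbers are not available |
| fix omission (thinning study) | 8% | calibrated once so the native observed position period of a 4 s tag is ≈4.2 s, the reported field value |

Trajectories are stationary points, waypoint tows at constant speed, or
correlated random walks (Gaussian heading increments, optional speed
jitter). What the generator does **not** emulate — multipath, Doppler,
thermal stratification of sound speed, signal collisions, directional
receiver sensitivity, macrophyte shadowing — bounds what passing tests
show: they validate the algorithms (solver exactness, error scaling,
statistic definitions, thinning behaviour), not field detection
performance. In particular the simulated stationary accuracy has no
systematic frame bias, whereas real deployments can show metre-scale
offsets between the acoustic frame and a handheld GPS; the accuracy /
precision decoupling that bias causes is exercised in the tests by
construction instead.

## Problem sizes

The standard thinning study uses 200 replicates × 5 fish × 900 s
sequences (~1000 sequences, ~200 000 fixes), enough to pin the Monte-
Carlo means to ≲0.05 s while running in seconds. Solver exactness uses
1000 random sources; noise-scaling uses ~250 transmissions per noise
level; regression recovery uses 500 replicates of 35-point datasets.

## Known limitations

- 2-D only; vertically migrating animals in deep arrays would need a
  third coordinate and receiver depths.
- The error-sensitivity definition and `1/s²` weighting are one
  defensible reading of an unpublished proprietary scheme; absolute
  position scatter therefore need not match any particular commercial
  system, though qualitative behaviour (interior better than edge, error
  ∝ timing noise) does.
- The logistic detection model is parametric and spatially homogeneous;
  habitat-specific shadowing (e.g. dense vegetation) must be emulated by
  placing tags out of range.
- `accuracy_moving` interpolates the reference linearly between 1 Hz
  samples; fast manoeuvres between samples alias into apparent error.
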