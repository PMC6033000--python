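# tdoatrack

Toolkit for simulating and evaluating fine-scale acoustic-telemetry
positioning of aquatic animals, and for quantifying how trajectory
metrics degrade as positioning becomes less frequent.

High-residence (HR) acoustic tags emit a <10 ms coded ping every second
or two, so an array of time-synchronised underwater receivers can
position a tagged fish almost continuously — far more often than legacy
pulse-position-modulation (PPM) tags, whose multi-second pulse trains
limit the positioning period to burst length + transmission delay (e.g.
3 s + 5 s = 8 s at best, in practice a minute or more). `tdoatrack` is
aimed at movement ecologists and biotelemetry methodologists who want to

- simulate such a system end to end (receiver array, tag schedules,
  sound propagation, range-dependent detection loss, stationary / towed /
  correlated-random-walk trajectories);
- turn detection tables into position estimates with a
  time-difference-of-arrival (TDOA) solver;
- score accuracy and precision against GPS-style references, and
- measure how thinning a high-rate track to emulate a slower tag biases
  total distance travelled, speed, and turning angle.

## The positioning model

A transmission at unknown position `p = (x, y)` and unknown emission
time `t0` reaching receiver `i` at position `r_i` satisfies

    |p − r_i| / c + t0 = a_i,    i = 1 … n,

with `c` the sound speed and `a_i` the measured arrival times. For each
subset of three receivers the system is solved exactly: differencing
pairs of squared range equations leaves two equations linear in `p`
with right-hand sides linear in `t0`; substituting `p(t0)` back into one
range equation gives a quadratic in `t0` (0, 1 or 2 physical candidates).
When a transmission is detected by more than three receivers, every
three-receiver subset is solved and a single fix is formed as a weighted
mean over subsets with weights `1 / s²`, where the *error sensitivity*
`s = ‖∂(x, y)/∂(a₁, a₂, a₃)‖_F` (a GDOP analogue, in m/s) measures how
strongly arrival-time error displaces that subset's solution.

Thinning emulates a slower tag: keep the first fix, then keep each later
fix iff its gap from the last kept fix is at least the minimum period —
provably the same result as iteratively deleting the first fix whose gap
from its predecessor is too short. Movement metrics and an OLS regression
of metric on transmission period then quantify the sampling-rate bias.

## Worked example

Simulate a 10-minute stationary deployment of a test tag (mean period
1.5 s) at (10, 5) m inside the default 7-receiver array, position every
transmission, and score it:

```python
import numpy as np, tdoatrack as tt

rng = np.random.default_rng(42)
array = tt.default_array()                      # centre + 77.1 m hexagon
traj = tt.TagTrajectory.stationary((10.0, 5.0), 600.0)
times = tt.gen_transmission_times(600.0, tt.test_tag_spec("S1"), rng)
det = tt.simulate_detections(array, traj, times, tt.PropagationModel(), rng, "S1")

track = tt.position_run(det, array)["S1"]
acc = tt.accuracy_stationary(track, tt.PlanePoint(10.0, 5.0))
prec = tt.precision_stationary(track)
print(f"transmissions {len(times)}, fixes {len(track)}")
print(f"accuracy  median {acc.median:.2f} m [{acc.p5:.2f}-{acc.p95:.2f}]")
print(f"precision median {prec.median:.2f} m [{prec.p5:.2f}-{prec.p95:.2f}]")
```

prints

```
transmissions 400, fixes 400
accuracy  median 0.11 m [0.03-0.21]
precision median 0.11 m [0.03-0.21]
```

All 400 transmissions are detected and positioned (the tag sits well
inside the detection range of all seven receivers), and the default
10⁻⁴ s arrival-time noise produces decimetre-scale scatter. Accuracy
(distance to the true position) and precision (distance to the median
estimated position) coincide here because the simulation has no
systematic offset between the positioning frame and the reference; a
constant reference bias would raise accuracy while leaving precision
untouched.

The thinning study summarising how a ~4 s fish tag's observed position
period, position count and retained fraction respond to thinning:

```python
print(tt.thinning_study(seed=1, n_replicates=200).round(2).to_string(index=False))
```

```
 threshold_s  median_period_s  mean_positions  pct_reduction
         NaN             4.08          206.81           0.00
         7.0             8.37          101.92          50.72
        15.0            16.77           52.79          74.47
        30.0            32.19           28.13          86.40
        45.0            47.18           19.35          90.64
        60.0            62.16           15.00          92.75
```

Each retained gap overshoots the threshold by roughly half a native
period, so a 60 s minimum period yields ~62 s observed periods, 15
positions per 15-minute track, and a ~93% loss of positions.

A `tdoatrack` console script exposes the same pipeline as subcommands
(`simulate`, `position`, `trials`, `thin`, `metrics`, `sensitivity`);
see `tdoatrack --help`.

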