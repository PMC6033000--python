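"""Track thinning, movement metrics, and the sampling-rate sensitivity analysis.

Thinning emulates a lower-rate tag by removing fixes until every
consecutive interval meets a minimum period. The greedy rule — keep the
first fix, then keep each later fix iff its gap from the last-kept fix is
at least the threshold — is equivalent to the iterative procedure of
repeatedly deleting the first (chronological) fix whose gap from its
predecessor is below the threshold: both always delete/skip exactly the
fixes that follow the current anchor too closely, scanning left to right.

Movement metrics (total distance travelled, per-step speed, unsigned
turning angle) are computed on each thinned dataset, and ordinary least
squares quantifies how each metric degrades with transmission period —
coarser sampling straightens the measured path, so distance, speed and
turning angle all shrink.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simulate import TagSpec, gen_transmission_times, random_omission
from .tracks import Track

#: thinning thresholds of the standard sensitivity analysis, seconds
DEFAULT_THIN_PERIODS = (7.0, 10.0, 15.0, 30.0, 45.0, 60.0)


def min_positioning_period(burst: float, delay: float) -> float:
    """Shortest achievable positioning period of a pulse-train (PPM) tag, s.

    A receiver must hear the whole pulse train, so consecutive positions
    are at best one burst length plus one transmission delay apart (e.g.
    a 3 s burst with a 5 s delay cannot position more often than every
    8 s).
    """
    if burst < 0 or delay < 0:
        raise ValueError("burst and delay must be non-negative")
    return burst + delay


def thin_times(times, min_period: float) -> np.ndarray:
    """Boolean retention mask of the greedy minimum-period thinning."""
    if min_period <= 0:
        raise ValueError("min_period must be positive")
    times = np.asarray(times, dtype=float)
    keep = np.zeros(len(times), dtype=bool)
    last = -np.inf
    for i, t in enumerate(times):
        if not np.isfinite(last) or t - last >= min_period:
            keep[i] = True
            last = t
    return keep


def thin_track(track: Track, min_period: float) -> Track:
    """Thin a track so all consecutive retained gaps are >= ``min_period``.

    The first fix is always retained; the result is a subset of the
    input and the operation is idempotent. An empty track passes through.
    """
    if len(track) == 0:
        return track
    return track.select(thin_times(track.times, min_period))


@dataclass
class MovementMetrics:
    """Step-wise movement summaries of one track.

    ``turning_angles`` are unsigned, in degrees, 0 = straight ahead;
    vertices with a zero-length adjacent step have no defined angle and
    are skipped (counted in ``n_degenerate_steps``). Summaries are NaN
    when the underlying sample is empty.
    """

    total_distance: float
    n_steps: int
    speeds: np.ndarray
    speed_mean: float
    speed_median: float
    speed_p5: float
    speed_p95: float
    turning_angles: np.ndarray
    angle_mean: float
    angle_median: float
    angle_p5: float
    angle_p95: float
    n_degenerate_steps: int = 0


def _summary(v: np.ndarray) -> tuple:
    if v.size == 0:
        return (np.nan,) * 4
    p5, med, p95 = np.percentile(v, [5, 50, 95])
    return float(v.mean()), float(med), float(p5), float(p95)


def movement_metrics(track: Track) -> MovementMetrics:
    """Total distance, per-step speeds and unsigned turning angles of a track."""
    n = len(track)
    if n < 2:
        empty = np.array([])
        return MovementMetrics(0.0, 0, empty, *(np.nan,) * 4, empty, *(np.nan,) * 4)
    steps = np.diff(track.xy, axis=0)
    lengths = np.hypot(steps[:, 0], steps[:, 1])
    dt = np.diff(track.times)
    speeds = lengths / dt
    # angle at each interior vertex between successive displacement vectors
    angles = []
    n_degenerate = 0
    for i in range(len(steps) - 1):
        if lengths[i] < 1e-12 or lengths[i + 1] < 1e-12:
            n_degenerate += 1
            continue
        cosang = np.dot(steps[i], steps[i + 1]) / (lengths[i] * lengths[i + 1])
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    angles = np.asarray(angles, dtype=float)
    return MovementMetrics(
        float(lengths.sum()),
        len(steps),
        speeds,
        *_summary(speeds),
        angles,
        *_summary(angles),
        n_degenerate_steps=n_degenerate,
    )


@dataclass(frozen=True)
class PeriodSummary:
    """Median and range of the intervals between consecutive fixes, s."""

    median: float
    min: float
    max: float
    n_intervals: int


def position_period_summary(track_or_times) -> PeriodSummary:
    """Median (range) of consecutive inter-fix intervals of one track."""
    times = (
        track_or_times.times
        if isinstance(track_or_times, Track)
        else np.asarray(track_or_times, dtype=float)
    )
    if len(times) < 2:
        raise ValueError("need at least 2 fixes to form an interval")
    gaps = np.diff(times)
    return PeriodSummary(
        float(np.median(gaps)), float(gaps.min()), float(gaps.max()), len(gaps)
    )


def percent_reduction(n_native: int, n_thinned: int) -> float:
    """Percent of positions removed by thinning: 100 (1 - thinned/native)."""
    if n_native <= 0:
        raise ValueError("n_native must be positive")
    if n_thinned > n_native:
        raise ValueError("thinned count exceeds native count")
    return 100.0 * (1.0 - n_thinned / n_native)


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of a (possibly log10-transformed) movement metric on period."""

    slope: float
    intercept: float
    r2: float
    F: float
    df1: int
    df2: int
    p: float
    slope_se: float = np.nan
    transform: str = "none"

    def predict(self, period) -> np.ndarray:
        """Fitted metric on the transformed scale."""
        return self.intercept + self.slope * np.asarray(period, dtype=float)


def metric_period_regression(points, transform: str = "none") -> RegressionFit:
    """Ordinary least squares of a movement metric on transmission period.

    ``points`` is a sequence of (period_s, metric) pairs, pooled over
    tracks. ``transform`` is "none" or "log10" (metric must then be
    strictly positive). The F statistic tests the slope with
    (1, n - 2) degrees of freedom.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) <= 0:
        raise ValueError("period has zero variance")
    if transform == "log10":
        if np.any(y <= 0):
            raise ValueError("log10 transform requires positive metric values")
        y = np.log10(y)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        F=float(res.fvalue),
        df1=int(res.df_model),
        df2=int(res.df_resid),
        p=float(res.f_pvalue),
        slope_se=float(res.bse[1]),
        transform=transform,
    )


def sensitivity_analysis(
    track: Track,
    periods: Sequence[float] = DEFAULT_THIN_PERIODS,
    native_period: float = np.nan,
) -> pd.DataFrame:
    """Movement metrics of the native track and each thinned variant.

    Returns one row per dataset — the native track first, then one per
    requested minimum period, in the order given. ``native_period`` only
    labels the native row's transmission_period_s column (e.g. the tag's
    nominal mean period), for use as the regression abscissa.
    """
    rows = []
    for label, thinned in [(native_period, track)] + [
        (p, thin_track(track, p)) for p in periods
    ]:
        m = movement_metrics(thinned)
        if len(thinned) >= 2:
            ps = position_period_summary(thinned)
            pmed, pmin, pmax = ps.median, ps.min, ps.max
        else:
            pmed = pmin = pmax = np.nan
        rows.append(
            {
                "transmission_period_s": label,
                "position_period_median": pmed,
                "position_period_min": pmin,
                "position_period_max": pmax,
                "n_positions": len(thinned),
                "distance_m": m.total_distance,
                "speed_median": m.speed_median,
                "speed_p5": m.speed_p5,
                "speed_p95": m.speed_p95,
                "angle_median": m.angle_median,
                "angle_p5": m.angle_p5,
                "angle_p95": m.angle_p95,
                "speed_mean": m.speed_mean,
                "angle_mean": m.angle_mean,
            }
        )
    return pd.DataFrame(rows)


def thinning_study(
    seed=None,
    n_replicates: int = 200,
    n_fish: int = 5,
    duration: float = 900.0,
    period_min: float = 3.0,
    period_max: float = 5.0,
    omission: float = 0.08,
    thresholds: Sequence[float] = (7.0, 15.0, 30.0, 45.0, 60.0),
) -> pd.DataFrame:
    """Monte-Carlo study of observed position period under thinning.

    Emulates the fish-tracking subset used for the sampling-rate
    analysis: ``n_fish`` 15-minute fix sequences per replicate, native
    gaps i.i.d. uniform on [period_min, period_max] seconds with a
    fraction ``omission`` of fixes lost at random (so the native observed
    position period slightly exceeds the transmission period). Each
    sequence is thinned at every threshold.

    Returns one row for the native data (threshold_s = NaN) and one per
    threshold, with columns:

    - ``median_period_s`` — mean over replicates of the across-fish
      median of each fish's median retained gap;
    - ``mean_positions`` — mean retained positions per fish;
    - ``pct_reduction`` — mean percent reduction from the native count,
      pooled over the fish of a replicate.

    ``seed`` may be an int or a Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = TagSpec("fish", period_min, period_max)
    thresholds = [float(t) for t in thresholds]
    med_acc = {t: [] for t in thresholds}
    cnt_acc = {t: [] for t in thresholds}
    red_acc = {t: [] for t in thresholds}
    native_med, native_cnt = [], []
    for _ in range(n_replicates):
        fish_times = []
        for _ in range(n_fish):
            t = gen_transmission_times(duration, spec, rng)
            fish_times.append(random_omission(t, omission, rng))
        native_med.append(np.median([np.median(np.diff(t)) for t in fish_times]))
        n_native = sum(len(t) for t in fish_times)
        native_cnt.append(n_native / n_fish)
        for thr in thresholds:
            kept = [t[thin_times(t, thr)] for t in fish_times]
            med_acc[thr].append(np.median([np.median(np.diff(k)) for k in kept]))
            n_kept = sum(len(k) for k in kept)
            cnt_acc[thr].append(n_kept / n_fish)
            red_acc[thr].append(percent_reduction(n_native, n_kept))
    rows = [
        {
            "threshold_s": np.nan,
            "median_period_s": float(np.mean(native_med)),
            "mean_positions": float(np.mean(native_cnt)),
            "pct_reduction": 0.0,
        }
    ]
    for thr in thresholds:
        rows.append(
            {
                "threshold_s": thr,
                "median_period_s": float(np.mean(med_acc[thr])),
                "mean_positions": float(np.mean(cnt_acc[thr])),
                "pct_reduction": float(np.mean(red_acc[thr])),
            }
        )
    return pd.DataFrame(rows)
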