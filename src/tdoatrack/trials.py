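"""Stationary- and moving-trial evaluation: accuracy and precision summaries.

Accuracy is the planar (Pythagorean) distance between each estimated
position and an independent reference — a surveyed point for a stationary
deployment, or the time-matched point of a 1 Hz reference (GPS) track for
a moving trial. Precision is the distance of each estimate from the
coordinate-wise median of all estimates in the trial: it measures
repeatability and is blind to any constant bias between the positioning
frame and the reference frame, so a trial can be precise yet inaccurate.

Summaries report the median, the 5th and 95th percentiles (linear
interpolation between order statistics) and the range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry_io import PlanePoint
from .tracks import Track


@dataclass
class TrialStats:
    """Percentile summary of per-fix distances for one trial."""

    distances: np.ndarray
    median: float
    p5: float
    p95: float
    min: float
    max: float
    n: int
    duration: float
    n_dropped: int = 0

    def as_row(self, trial_id: str = "", prefix: str = "") -> dict:
        """One flat table row (Table-1/2 style) for reporting."""
        row = {
            "trial": trial_id,
            "duration_min": self.duration / 60.0,
            "n_positions": self.n,
        }
        for k in ("median", "p5", "p95", "min", "max"):
            row[f"{prefix}{k}"] = getattr(self, k)
        return row


def summarize(values, duration: float = np.nan, n_dropped: int = 0) -> TrialStats:
    """Median / 5th–95th percentile / range summary of a distance sample."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    p5, med, p95 = np.percentile(v, [5, 50, 95])
    return TrialStats(
        v, float(med), float(p5), float(p95), float(v.min()), float(v.max()),
        int(v.size), float(duration), int(n_dropped),
    )


def _track_duration(track: Track) -> float:
    return float(track.times[-1] - track.times[0]) if len(track) > 1 else 0.0


def accuracy_stationary(track: Track, ref: PlanePoint) -> TrialStats:
    """Distances from each fix to the surveyed reference position."""
    if len(track) == 0:
        raise ValueError("empty track")
    d = np.hypot(track.xy[:, 0] - ref.x, track.xy[:, 1] - ref.y)
    return summarize(d, _track_duration(track))


def precision_stationary(track: Track) -> TrialStats:
    """Distances from each fix to the coordinate-wise median fix."""
    if len(track) == 0:
        raise ValueError("empty track")
    med = np.median(track.xy, axis=0)
    d = np.hypot(track.xy[:, 0] - med[0], track.xy[:, 1] - med[1])
    return summarize(d, _track_duration(track))


def accuracy_moving(
    track: Track, gps: Track, max_extrapolation: float = 2.0
) -> TrialStats:
    """Distances from each fix to the time-matched reference-track position.

    The reference track (sampled at ~1 Hz) is linearly interpolated to
    each fix's time. Fixes more than ``max_extrapolation`` seconds outside
    the reference's time span are dropped and counted in ``n_dropped``;
    fixes within that margin use the nearest endpoint position.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    if len(gps) < 2:
        raise ValueError("reference track needs at least 2 points")
    t0, t1 = gps.times[0], gps.times[-1]
    keep = (track.times >= t0 - max_extrapolation) & (
        track.times <= t1 + max_extrapolation
    )
    if not np.any(keep):
        raise ValueError("no temporal overlap between track and reference")
    t = track.times[keep]
    gx = np.interp(t, gps.times, gps.xy[:, 0])
    gy = np.interp(t, gps.times, gps.xy[:, 1])
    d = np.hypot(track.xy[keep, 0] - gx, track.xy[keep, 1] - gy)
    return summarize(d, _track_duration(track), n_dropped=int((~keep).sum()))


def stationary_trial_table(trials: dict, refs: dict) -> pd.DataFrame:
    """Per-trial accuracy and precision rows (Table-1 layout).

    ``trials`` maps trial id to Track, ``refs`` maps trial id to the
    surveyed :class:`PlanePoint`.
    """
    rows = []
    for trial_id, track in trials.items():
        acc = accuracy_stationary(track, refs[trial_id]).as_row(
            trial_id, prefix="accuracy_"
        )
        prec = precision_stationary(track).as_row(trial_id, prefix="precision_")
        acc.update({k: v for k, v in prec.items() if k.startswith("precision_")})
        rows.append(acc)
    return pd.DataFrame(rows)


def moving_trial_table(trials: dict, gps_tracks: dict) -> pd.DataFrame:
    """Per-trial moving accuracy rows (Table-2 layout)."""
    rows = [
        accuracy_moving(track, gps_tracks[trial_id]).as_row(trial_id, "accuracy_")
        for trial_id, track in trials.items()
    ]
    return pd.DataFrame(rows)
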