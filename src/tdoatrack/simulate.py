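"""Synthetic-data generation emulating a high-residence acoustic positioning study.

The generator mirrors the field configuration the toolkit is built to
analyse: a seven-receiver array with ~77 m nearest spacing in a small
freshwater lake, tags transmitting short coded pings at uniformly jittered
periods (test tags: mean 1.5 s, range 1-2 s; fish tags: mean 4 s, range
3-5 s), straight-line sound propagation with additive arrival-time noise,
range-dependent detection loss (logistic in range), and stationary, towed
or correlated-random-walk tag trajectories.

All randomness flows through an explicit :class:`numpy.random.Generator`,
so seeded runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry_io import GeoPoint, PlanePoint, latlon_to_local
from .tracks import Track

#: default sound speed, m/s — fresh water at ~10 °C
DEFAULT_SOUND_SPEED = 1447.0

#: mean nearest-neighbour receiver spacing of the emulated array, metres
DEFAULT_SPACING = 77.1


@dataclass(frozen=True)
class DetectionRecord:
    """One receiver's detection of one tag transmission."""

    receiver_id: str
    tag_id: str
    arrival_time: float


@dataclass
class ReceiverArray:
    """Receiver ids with planar positions; the geometric frame for positioning."""

    ids: tuple
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.ids = tuple(str(i) for i in self.ids)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if len(self.ids) != len(self.xy):
            raise ValueError("ids and xy must have matching lengths")
        if len(self.ids) < 3:
            raise ValueError("an array needs at least 3 receivers")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("receiver ids must be unique")
        d = self.pairwise_distances()
        if np.min(d[np.triu_indices(len(self.ids), k=1)]) <= 1e-9:
            raise ValueError("receivers must not be coincident")

    def __len__(self) -> int:
        return len(self.ids)

    def position_of(self, receiver_id: str) -> np.ndarray:
        return self.xy[self.ids.index(str(receiver_id))]

    def pairwise_distances(self) -> np.ndarray:
        diff = self.xy[:, None, :] - self.xy[None, :, :]
        return np.hypot(diff[..., 0], diff[..., 1])

    @property
    def centroid(self) -> np.ndarray:
        return self.xy.mean(axis=0)

    @property
    def diameter(self) -> float:
        """Maximum pairwise receiver distance, metres."""
        return float(self.pairwise_distances().max())

    def mean_nearest_spacing(self) -> float:
        """Mean over receivers of the distance to the nearest other receiver."""
        d = self.pairwise_distances().copy()
        np.fill_diagonal(d, np.inf)
        return float(d.min(axis=1).mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"receiver_id": self.ids, "x_m": self.xy[:, 0], "y_m": self.xy[:, 1]}
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, origin: GeoPoint | None = None
    ) -> "ReceiverArray":
        """Build an array from a receiver table.

        Accepts either plane columns (x_m, y_m) or geographic ones
        (lat, lon); the latter are projected about ``origin`` (default:
        the mean lat/lon of the receivers).
        """
        if {"x_m", "y_m"}.issubset(df.columns):
            xy = df[["x_m", "y_m"]].to_numpy(dtype=float)
        elif {"lat", "lon"}.issubset(df.columns):
            if origin is None:
                origin = GeoPoint(float(df["lat"].mean()), float(df["lon"].mean()))
            pts = [
                latlon_to_local(GeoPoint(la, lo), origin)
                for la, lo in zip(df["lat"], df["lon"])
            ]
            xy = np.array([[p.x, p.y] for p in pts])
        else:
            raise ValueError("receiver table needs x_m/y_m or lat/lon columns")
        return cls(tuple(df["receiver_id"].astype(str)), xy)


@dataclass(frozen=True)
class TagSpec:
    """A tag's transmission schedule: uniformly jittered period in [min, max] s."""

    tag_id: str
    period_min: float
    period_max: float

    def __post_init__(self) -> None:
        if not 0 < self.period_min <= self.period_max:
            raise ValueError("need 0 < period_min <= period_max")

    @property
    def period_mean(self) -> float:
        return 0.5 * (self.period_min + self.period_max)


def test_tag_spec(tag_id: str = "test") -> TagSpec:
    """Range/stationary/tow test tag: mean period 1.5 s, range 1-2 s."""
    return TagSpec(tag_id, 1.0, 2.0)


def fish_tag_spec(tag_id: str = "fish") -> TagSpec:
    """Implanted fish tag: mean period 4 s, range 3-5 s."""
    return TagSpec(tag_id, 3.0, 5.0)


@dataclass(frozen=True)
class PropagationModel:
    """Sound propagation, timing noise and range-dependent detection loss.

    Detection is independent per receiver with probability
    ``1 / (1 + exp(k (d - d50)))`` at range ``d``; a detected arrival is
    ``t0 + d/c + clock_offset + Normal(0, sigma_t)``. Defaults put the
    detection midpoint well outside a ~77 m array (within-array detection
    near certain) and give metre-scale position scatter.
    """

    c: float = DEFAULT_SOUND_SPEED
    sigma_t: float = 1e-4
    sigma_clock: float = 0.0
    d50: float = 150.0
    k: float = 0.05

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("sound speed must be positive")
        if self.sigma_t < 0 or self.sigma_clock < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.d50 <= 0:
            raise ValueError("d50 must be positive")

    def detection_probability(self, distance) -> np.ndarray:
        d = np.asarray(distance, dtype=float)
        z = np.clip(self.k * (d - self.d50), -700.0, 700.0)
        return 1.0 / (1.0 + np.exp(z))


class TagTrajectory:
    """A tag's true path: piecewise-linear in time between knot positions."""

    def __init__(self, times: Sequence[float], xy: Sequence) -> None:
        self.times = np.asarray(times, dtype=float)
        self.xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        if self.times.ndim != 1 or len(self.times) != len(self.xy):
            raise ValueError("times and xy must have matching lengths")
        if len(self.times) < 2 or not np.all(np.diff(self.times) > 0):
            raise ValueError("trajectory needs >= 2 strictly increasing times")

    @property
    def t_start(self) -> float:
        return float(self.times[0])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def at(self, t) -> np.ndarray:
        """Position(s) at time(s) ``t``; raises outside the covered span."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0] - 1e-9) or np.any(t > self.times[-1] + 1e-9):
            raise ValueError("time outside trajectory span")
        x = np.interp(t, self.times, self.xy[:, 0])
        y = np.interp(t, self.times, self.xy[:, 1])
        return np.stack([x, y], axis=-1)

    def to_track(self, tag_id: str = "truth") -> Track:
        return Track(tag_id, self.times, self.xy)

    @classmethod
    def stationary(
        cls, point: PlanePoint | Sequence[float], duration: float, t_start: float = 0.0
    ) -> "TagTrajectory":
        """A fixed tag covering ``[t_start, t_start + duration]``."""
        if duration <= 0:
            raise ValueError("duration must be positive")
        p = (point.x, point.y) if isinstance(point, PlanePoint) else tuple(point)
        return cls([t_start, t_start + duration], [p, p])


# ---------------------------------------------------------------------------
# generators


def default_array(
    spacing: float = DEFAULT_SPACING,
    seed=None,
    jitter_sd: float = 0.0,
) -> ReceiverArray:
    """The emulated seven-receiver layout: centre plus regular hexagon.

    One receiver sits at the origin and six at the vertices of a regular
    hexagon of radius ``spacing``, so every outer receiver's nearest
    neighbours (the centre and its two ring neighbours) are exactly
    ``spacing`` away. ``jitter_sd`` optionally perturbs each coordinate
    with seeded Gaussian noise to emulate deployment scatter.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    ang = np.deg2rad(60.0 * np.arange(6))
    xy = np.vstack([[0.0, 0.0], spacing * np.column_stack([np.cos(ang), np.sin(ang)])])
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        xy = xy + rng.normal(0.0, jitter_sd, xy.shape)
    ids = tuple(f"R{i}" for i in range(7))
    return ReceiverArray(ids, xy)


def gen_transmission_times(
    duration: float, spec: TagSpec, rng: np.random.Generator
) -> np.ndarray:
    """Emission times over ``[0, duration)`` with i.i.d. uniform gaps.

    The first emission is uniform on ``[0, period_max]`` (a random phase);
    successive gaps are i.i.d. uniform on ``[period_min, period_max]``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_max = int(duration / spec.period_min) + 2
    gaps = rng.uniform(spec.period_min, spec.period_max, n_max)
    t = rng.uniform(0.0, spec.period_max) + np.concatenate(([0.0], np.cumsum(gaps)))
    return t[t < duration]


def random_omission(
    times: np.ndarray, prob: float, rng: np.random.Generator
) -> np.ndarray:
    """Drop each event independently with probability ``prob``.

    Emulates transmissions that fail to yield a position (too few
    detections), so that the observed position period exceeds the
    transmission period.
    """
    if not 0 <= prob < 1:
        raise ValueError("omission probability must be in [0, 1)")
    times = np.asarray(times, dtype=float)
    return times[rng.random(len(times)) >= prob]


def simulate_detections(
    array: ReceiverArray,
    traj: TagTrajectory,
    times: Sequence[float],
    model: PropagationModel,
    rng: np.random.Generator,
    tag_id: str = "tag",
) -> list:
    """Simulate per-receiver detections of each emission, sorted by arrival.

    For an emission at time t0 from position p, each receiver at range d
    detects independently with the model's logistic probability; a detected
    arrival is t0 + d/c + clock_offset + Normal(0, sigma_t). Per-receiver
    clock offsets are drawn once per call (zero when sigma_clock = 0).
    """
    times = np.asarray(times, dtype=float)
    pos = traj.at(times)  # raises if an emission is outside the trajectory
    diff = pos[:, None, :] - array.xy[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    detect = rng.random(dist.shape) < model.detection_probability(dist)
    clock = (
        rng.normal(0.0, model.sigma_clock, len(array))
        if model.sigma_clock > 0
        else np.zeros(len(array))
    )
    noise = (
        rng.normal(0.0, model.sigma_t, dist.shape)
        if model.sigma_t > 0
        else np.zeros(dist.shape)
    )
    arrivals = times[:, None] + dist / model.c + clock[None, :] + noise
    records = [
        DetectionRecord(array.ids[r], tag_id, float(arrivals[i, r]))
        for i, r in zip(*np.nonzero(detect))
    ]
    records.sort(key=lambda rec: rec.arrival_time)
    return records


def detections_to_frame(records: Sequence[DetectionRecord]) -> pd.DataFrame:
    """Detection records as the canonical table (receiver_id, tag_id, time_s)."""
    return pd.DataFrame(
        {
            "receiver_id": [r.receiver_id for r in records],
            "tag_id": [r.tag_id for r in records],
            "time_s": [r.arrival_time for r in records],
        }
    )


def simulate_moving_track(
    waypoints: Sequence, speed: float, dt: float
) -> TagTrajectory:
    """A tow-test style trajectory: waypoints traversed at constant speed.

    Returns a piecewise-linear trajectory with knots every ``dt`` seconds
    (plus the exact endpoint).
    """
    if speed <= 0 or dt <= 0:
        raise ValueError("speed and dt must be positive")
    pts = np.array(
        [(p.x, p.y) if isinstance(p, PlanePoint) else tuple(p) for p in waypoints],
        dtype=float,
    )
    if len(pts) < 2:
        raise ValueError("need at least 2 waypoints")
    seg = np.hypot(*np.diff(pts, axis=0).T)
    if seg.sum() <= 0:
        raise ValueError("waypoints have zero total length")
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    total_time = cum[-1] / speed
    ts = np.arange(0.0, total_time, dt)
    if total_time - ts[-1] > 1e-9:
        ts = np.append(ts, total_time)
    s = speed * ts
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    return TagTrajectory(ts, np.column_stack([x, y]))


def simulate_crw(
    n_steps: int,
    speed_mean: float,
    turn_sd_deg: float,
    dt: float,
    seed=None,
    start=(0.0, 0.0),
    heading_deg: float = 0.0,
    speed_sd: float = 0.0,
) -> TagTrajectory:
    """A correlated random walk: persistent heading with Gaussian turns.

    Heading increments are Normal(0, turn_sd_deg); per-step speed is
    ``speed_mean`` (optionally jittered by a truncated Gaussian with SD
    ``speed_sd``). ``seed`` may be an int or a Generator.
    """
    if n_steps < 1 or speed_mean <= 0 or dt <= 0:
        raise ValueError("need n_steps >= 1, positive speed and dt")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    headings = np.deg2rad(heading_deg) + np.cumsum(
        rng.normal(0.0, np.deg2rad(turn_sd_deg), n_steps)
    )
    speeds = np.full(n_steps, speed_mean)
    if speed_sd > 0:
        speeds = np.clip(rng.normal(speed_mean, speed_sd, n_steps), 0.0, None)
    steps = (speeds * dt)[:, None] * np.column_stack(
        [np.cos(headings), np.sin(headings)]
    )
    xy = np.vstack([np.asarray(start, dtype=float), steps]).cumsum(axis=0)
    times = dt * np.arange(n_steps + 1)
    return TagTrajectory(times, xy)
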