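"""2-D TDOA positioning: exact three-receiver solutions combined by
error-sensitivity weighting.

A transmission detected by three or more time-synchronised receivers
constrains the source: each receiver pair's arrival-time difference puts
the source on a hyperbola. With exactly three receivers the system

    |p - r_i| / c + t0 = a_i        (i = 1, 2, 3)

is solved exactly for the plane position p and emission time t0 by
algebraic reduction — differencing pairs gives two equations linear in p
for a given t0, and back-substitution yields a quadratic in t0 (zero, one
or two physical candidates). For groups of more than three receivers,
every three-receiver subset is solved and a single position is formed as
a weighted mean across subsets that favours the lowest error sensitivity,
where a subset's sensitivity is the Frobenius norm of the Jacobian of its
position with respect to the three arrival times (a GDOP analogue, m/s):
weights are 1 / sensitivity^2.

No quality filtering is applied to the output fixes by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry_io import PlanePoint
from .simulate import DEFAULT_SOUND_SPEED, DetectionRecord, ReceiverArray
from .tracks import Track

#: grouping guard added to the maximum acoustic traversal of the array, s
DEFAULT_GUARD = 0.05

#: triangle area below which a three-receiver geometry is treated as collinear, m^2
COLLINEAR_AREA = 1e-6


class DegenerateGeometryError(ValueError):
    """The receiver geometry cannot support a position solution."""


@dataclass(frozen=True)
class SubsetSolution:
    """An exact candidate solution from one three-receiver subset."""

    position: PlanePoint
    emission_time: float
    sensitivity: float
    receiver_ids: tuple

    @property
    def x(self) -> float:
        return self.position.x

    @property
    def y(self) -> float:
        return self.position.y


@dataclass(frozen=True)
class PositionFix:
    """One estimated position: the sensitivity-weighted combination of subsets."""

    tag_id: str
    time: float
    x: float
    y: float
    sensitivity: float
    n_receivers: int

    @property
    def position(self) -> PlanePoint:
        return PlanePoint(self.x, self.y)


def _as_detection_frame(detections) -> pd.DataFrame:
    if isinstance(detections, pd.DataFrame):
        return detections
    return pd.DataFrame(
        {
            "receiver_id": [d.receiver_id for d in detections],
            "tag_id": [d.tag_id for d in detections],
            "time_s": [d.arrival_time for d in detections],
        }
    )


def group_by_transmission(
    detections,
    array: ReceiverArray,
    c: float = DEFAULT_SOUND_SPEED,
    guard: float = DEFAULT_GUARD,
) -> list:
    """Cluster detections into per-transmission groups.

    Single-linkage clustering in arrival time per tag (equivalently:
    split the sorted arrivals wherever the gap exceeds the link
    threshold), with threshold = max pairwise receiver distance / c +
    guard — no two detections of one transmission can be further apart in
    time. Within a group, only the earliest detection per receiver is
    kept; groups with fewer than three distinct receivers are discarded.

    Returns a list of groups, each a list of :class:`DetectionRecord`
    sorted by arrival time.
    """
    df = _as_detection_frame(detections)
    threshold = array.diameter / c + guard
    groups: list = []
    for tag_id, sub in df.groupby("tag_id", sort=True):
        sub = sub.sort_values("time_s", kind="stable")
        t = sub["time_s"].to_numpy(dtype=float)
        if len(t) == 0:
            continue
        breaks = np.flatnonzero(np.diff(t) > threshold) + 1
        for chunk in np.split(np.arange(len(t)), breaks):
            block = sub.iloc[chunk].drop_duplicates("receiver_id", keep="first")
            if block["receiver_id"].nunique() < 3:
                continue
            groups.append(
                [
                    DetectionRecord(str(r.receiver_id), str(tag_id), float(r.time_s))
                    for r in block.itertuples()
                ]
            )
    groups.sort(key=lambda g: g[0].arrival_time)
    return groups


def solve_tdoa_triple(
    positions, arrivals, c: float = DEFAULT_SOUND_SPEED, receiver_ids=None
) -> list:
    """Solve the three-receiver TDOA system exactly.

    ``positions`` is a (3, 2) array of receiver coordinates, ``arrivals``
    their three arrival times. Differencing the squared range equations
    gives two equations linear in (x, y) with right-hand sides linear in
    t0; solving them expresses the position as p(t0) = p0 + p1 t0, and
    substituting into one range equation yields a quadratic in t0. All
    real roots with t0 not after the earliest arrival are returned as
    :class:`SubsetSolution` candidates (0, 1 or 2), each with its error
    sensitivity attached. Collinear receivers raise
    :class:`DegenerateGeometryError`.
    """
    r = np.asarray(positions, dtype=float).reshape(3, 2)
    a = np.asarray(arrivals, dtype=float).reshape(3)
    if receiver_ids is None:
        receiver_ids = ("r0", "r1", "r2")
    u, v = r[1] - r[0], r[2] - r[0]
    area = 0.5 * abs(u[0] * v[1] - u[1] * v[0])
    if area <= COLLINEAR_AREA:
        raise DegenerateGeometryError(f"collinear receivers (area {area:.3g} m^2)")

    # A p = b0 + b1 t0, rows from differencing receiver i against receiver 0
    A = 2.0 * (r[1:] - r[0])
    rsq = np.sum(r**2, axis=1)
    b0 = c**2 * (a[0] ** 2 - a[1:] ** 2) - rsq[0] + rsq[1:]
    b1 = -2.0 * c**2 * (a[0] - a[1:])
    p0 = np.linalg.solve(A, b0)
    p1 = np.linalg.solve(A, b1)

    # |p0 + p1 t0 - r0|^2 = c^2 (a0 - t0)^2  ->  quadratic in t0
    q = p0 - r[0]
    qa = p1 @ p1 - c**2
    qb = 2.0 * (q @ p1 + c**2 * a[0])
    qc = q @ q - c**2 * a[0] ** 2

    scale = max(abs(qa), abs(qb), abs(qc), 1.0)
    if abs(qa) <= 1e-12 * scale:
        roots = [] if abs(qb) <= 1e-12 * scale else [-qc / qb]
    else:
        disc = qb**2 - 4.0 * qa * qc
        if disc < 0:
            roots = [-qb / (2.0 * qa)] if disc > -1e-9 * qb**2 - 1e-12 else []
        else:
            sq = np.sqrt(disc)
            roots = [(-qb - sq) / (2.0 * qa), (-qb + sq) / (2.0 * qa)]

    amin = float(a.min())
    out = []
    for t0 in roots:
        if t0 > amin + 1e-9:
            continue
        if any(abs(t0 - s.emission_time) < 1e-12 for s in out):
            continue
        p = p0 + p1 * t0
        sol = SubsetSolution(
            PlanePoint(float(p[0]), float(p[1])),
            float(t0),
            np.nan,
            tuple(receiver_ids),
        )
        try:
            sens = error_sensitivity(sol, r, c)
        except DegenerateGeometryError:
            continue
        out.append(
            SubsetSolution(sol.position, sol.emission_time, sens, tuple(receiver_ids))
        )
    return out


def error_sensitivity(sol: SubsetSolution, positions, c: float = DEFAULT_SOUND_SPEED) -> float:
    """Arrival-time-to-position error sensitivity of a subset solution, m/s.

    The Frobenius norm of the 2x3 Jacobian d(x, y)/d(a1, a2, a3) at the
    solution, obtained in closed form by the implicit function theorem:
    with F_i = |p - r_i| - c (a_i - t0) = 0, the full Jacobian of
    (x, y, t0) with respect to the arrivals is c M^{-1}, where M has rows
    (unit vector from receiver i to p, c). A large value means small
    arrival-time errors displace the solved position far — the quantity
    the subset-combination weights penalise.
    """
    r = np.asarray(positions, dtype=float).reshape(3, 2)
    p = np.array([sol.position.x, sol.position.y])
    d = np.hypot(*(p - r).T)
    if np.any(d < 1e-9):
        raise DegenerateGeometryError("solution coincides with a receiver")
    M = np.column_stack([(p - r) / d[:, None], np.full(3, c)])
    try:
        J = c * np.linalg.inv(M)[:2, :]
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError("singular sensitivity geometry") from exc
    sens = float(np.sqrt(np.sum(J**2)))
    if not np.isfinite(sens) or sens <= 0:
        raise DegenerateGeometryError("non-finite error sensitivity")
    return sens


def resolve_candidates(
    candidate_lists: Sequence[Sequence[SubsetSolution]],
    array: ReceiverArray,
    max_centroid_distance: float | None = None,
) -> list:
    """Pick one solution per subset from the two-root TDOA ambiguity.

    Candidates farther than ``max_centroid_distance`` (default: three
    array diameters) from the array centroid are implausible and dropped.
    Subsets left with one candidate are unambiguous. A subset with two
    surviving candidates keeps the one closest to the unweighted mean of
    all unambiguous candidates; if no subset is unambiguous, it keeps its
    lower-sensitivity candidate. Subsets with no plausible candidate are
    dropped.
    """
    if max_centroid_distance is None:
        max_centroid_distance = 3.0 * array.diameter
    cx, cy = array.centroid
    plausible = [
        [
            s
            for s in cands
            if np.hypot(s.position.x - cx, s.position.y - cy) <= max_centroid_distance
        ]
        for cands in candidate_lists
    ]
    unambiguous = [cands[0] for cands in plausible if len(cands) == 1]
    chosen = list(unambiguous)
    anchor = (
        np.mean([[s.position.x, s.position.y] for s in unambiguous], axis=0)
        if unambiguous
        else None
    )
    for cands in plausible:
        if len(cands) < 2:
            continue
        if anchor is not None:
            best = min(
                cands,
                key=lambda s: np.hypot(s.position.x - anchor[0], s.position.y - anchor[1]),
            )
        else:
            best = min(cands, key=lambda s: s.sensitivity)
        chosen.append(best)
    return chosen


def combine_position(
    solutions: Sequence[SubsetSolution],
    tag_id: str = "",
    n_receivers: int | None = None,
) -> PositionFix:
    """Weighted mean of subset solutions with weights 1 / sensitivity^2.

    Position and emission time are combined with the same weights; the
    fix's reported sensitivity is the minimum over the used subsets.
    """
    if not solutions:
        raise ValueError("no subset solutions to combine")
    s = np.array([sol.sensitivity for sol in solutions])
    w = 1.0 / s**2
    w = w / w.sum()
    x = float(np.sum(w * [sol.position.x for sol in solutions]))
    y = float(np.sum(w * [sol.position.y for sol in solutions]))
    t = float(np.sum(w * [sol.emission_time for sol in solutions]))
    if n_receivers is None:
        used = set()
        for sol in solutions:
            used.update(sol.receiver_ids)
        n_receivers = len(used)
    return PositionFix(tag_id, t, x, y, float(s.min()), int(n_receivers))


def position_group(
    group: Sequence[DetectionRecord],
    array: ReceiverArray,
    c: float = DEFAULT_SOUND_SPEED,
) -> PositionFix | None:
    """Position one transmission group, or None if no subset yields a solution."""
    ids = [d.receiver_id for d in group]
    arrivals = np.array([d.arrival_time for d in group])
    xy = np.array([array.position_of(i) for i in ids])
    candidate_lists = []
    for subset in combinations(range(len(group)), 3):
        idx = list(subset)
        try:
            cands = solve_tdoa_triple(
                xy[idx], arrivals[idx], c, receiver_ids=tuple(ids[i] for i in idx)
            )
        except DegenerateGeometryError:
            continue  # e.g. a collinear triple through the array centre
        if cands:
            candidate_lists.append(cands)
    chosen = resolve_candidates(candidate_lists, array)
    if not chosen:
        return None
    return combine_position(chosen, group[0].tag_id, len(set(ids)))


def position_run(
    detections,
    array: ReceiverArray,
    c: float = DEFAULT_SOUND_SPEED,
    guard: float = DEFAULT_GUARD,
) -> dict:
    """Full pipeline: group detections, position each group, return tracks.

    Returns a dict mapping tag_id to a time-ordered :class:`Track` (tags
    whose detections never reach three receivers map to empty tracks only
    if they appear in the input with a positioned-free group; tags with no
    positionable group are simply absent).
    """
    df = _as_detection_frame(detections)
    fixes: dict = {}
    for group in group_by_transmission(df, array, c, guard):
        fix = position_group(group, array, c)
        if fix is not None:
            fixes.setdefault(fix.tag_id, []).append(fix)
    out = {}
    for tag_id, fx in fixes.items():
        fx.sort(key=lambda f: f.time)
        # identical emission-time duplicates cannot occur from distinct groups
        out[tag_id] = Track(
            tag_id,
            np.array([f.time for f in fx]),
            np.array([[f.x, f.y] for f in fx]),
            np.array([f.sensitivity for f in fx]),
            np.array([f.n_receivers for f in fx]),
        )
    return out


def fixes_to_frame(tracks: dict) -> pd.DataFrame:
    """Fix tables for all tags of a :func:`position_run` result."""
    frames = [t.to_frame() for t in tracks.values()]
    if not frames:
        return pd.DataFrame(
            columns=["tag_id", "time_s", "x_m", "y_m", "sensitivity", "n_receivers"]
        )
    return pd.concat(frames, ignore_index=True)
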