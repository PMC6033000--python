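"""Planar geometry and delimited-table plumbing shared by the pipeline.

All positioning runs in a local tangent plane. Geographic input
(WGS84 lat/lon) is projected with a local equirectangular projection about
a chosen origin — exactly invertible and accurate to well under a
millimetre at the sub-kilometre scales of a receiver array — and every
distance thereafter is planar Euclidean.

Tables are plain comma-separated text with a header row. Timestamps may be
given as epoch seconds or ISO-8601 strings; they are normalised to float
epoch seconds on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

EARTH_RADIUS_M = 6_371_000.0

#: canonical column sets for the tables exchanged between pipeline stages
DETECTION_COLUMNS = ("receiver_id", "tag_id", "time_s")
FIX_COLUMNS = ("tag_id", "time_s", "x_m", "y_m")
RECEIVER_COLUMNS = ("receiver_id",)
TRACK_COLUMNS = ("time_s", "x_m", "y_m")


class TableFormatError(ValueError):
    """A delimited table is missing required structure (header, column, value)."""


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 geographic coordinate in decimal degrees."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lat) and math.isfinite(self.lon)):
            raise ValueError("GeoPoint coordinates must be finite")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


@dataclass(frozen=True)
class PlanePoint:
    """A point in the local tangent plane: metres east (x) / north (y) of the origin."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("PlanePoint coordinates must be finite")


def latlon_to_local(p: GeoPoint, origin: GeoPoint) -> PlanePoint:
    """Project a geographic point onto the local plane about ``origin``.

    Equirectangular: x = R cos(lat0) dlon, y = R dlat, with R the mean Earth
    radius. Intended for points within a few tens of km of the origin.
    """
    dlat = math.radians(p.lat - origin.lat)
    dlon = math.radians(p.lon - origin.lon)
    x = EARTH_RADIUS_M * math.cos(math.radians(origin.lat)) * dlon
    y = EARTH_RADIUS_M * dlat
    return PlanePoint(x, y)


def local_to_latlon(p: PlanePoint, origin: GeoPoint) -> GeoPoint:
    """Exact inverse of :func:`latlon_to_local` about the same origin."""
    lat = origin.lat + math.degrees(p.y / EARTH_RADIUS_M)
    lon = origin.lon + math.degrees(
        p.x / (EARTH_RADIUS_M * math.cos(math.radians(origin.lat)))
    )
    return GeoPoint(lat, lon)


def plane_distance(a: PlanePoint, b: PlanePoint) -> float:
    """Euclidean (Pythagorean) distance between two plane points, metres."""
    return math.hypot(a.x - b.x, a.y - b.y)


# ---------------------------------------------------------------------------
# time normalisation


def to_epoch_seconds(values: Sequence, column: str = "time_s") -> np.ndarray:
    """Normalise a column of timestamps to float epoch seconds.

    Each element may be a number (already epoch seconds) or an ISO-8601
    string; formats may be mixed within a column. Unparseable entries raise
    :class:`TableFormatError` naming the row and column.
    """
    s = pd.Series(values)
    numeric = pd.to_numeric(s, errors="coerce")
    out = numeric.to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(out))
    for i in bad:
        v = s.iloc[i]
        try:
            ts = pd.Timestamp(str(v))
            if ts.tzinfo is None:
                ts = ts.tz_localize("UTC")
            out[i] = ts.timestamp()
        except (ValueError, TypeError) as exc:
            raise TableFormatError(
                f"row {i}, column {column!r}: cannot parse time {v!r}"
            ) from exc
    return out


# ---------------------------------------------------------------------------
# table I/O


def read_table(
    path: str | Path,
    required: Sequence[str],
    time_column: str | None = "time_s",
) -> pd.DataFrame:
    """Read a comma-separated table, validating header and normalising times.

    Raises :class:`TableFormatError` for an empty file, a missing required
    column (which also catches header-less files, whose first data row will
    not match the required names), or an unparseable timestamp.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError(f"{path}: empty file") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    if time_column is not None and time_column in df.columns:
        df[time_column] = to_epoch_seconds(df[time_column], column=time_column)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as comma-separated text with a header row."""
    pd.DataFrame(df).to_csv(path, index=False)


def read_detections(path: str | Path) -> pd.DataFrame:
    """Read a detection table (receiver_id, tag_id, time_s), sorted by time."""
    df = read_table(path, DETECTION_COLUMNS)
    return df.sort_values(["tag_id", "time_s"], kind="stable").reset_index(drop=True)


def read_fixes(path: str | Path) -> pd.DataFrame:
    """Read an estimated-position table (tag_id, time_s, x_m, y_m, ...)."""
    df = read_table(path, FIX_COLUMNS)
    return df.sort_values(["tag_id", "time_s"], kind="stable").reset_index(drop=True)


def read_plane_track(path: str | Path) -> pd.DataFrame:
    """Read a reference (e.g. GPS) track already in plane coordinates."""
    df = read_table(path, TRACK_COLUMNS)
    return df.sort_values("time_s", kind="stable").reset_index(drop=True)


def load_config(path: str | Path) -> Mapping:
    """Load a YAML key-value configuration file (thresholds, noise, seed)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def records_to_frame(records: Iterable, columns: Sequence[str]) -> pd.DataFrame:
    """Materialise an iterable of dataclass-like records into a DataFrame."""
    rows = [[getattr(r, f) for f in columns] for r in records]
    return pd.DataFrame(rows, columns=list(columns))
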