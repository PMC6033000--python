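"""Time-ordered position sequences (tracks) shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class Track:
    """A time-ordered sequence of 2-D position fixes for one tag.

    ``times`` are epoch seconds (strictly increasing), ``xy`` is an (n, 2)
    array of plane coordinates in metres. ``sensitivity`` (m/s) and
    ``n_receivers`` are optional per-fix quality metadata carried through
    from positioning.
    """

    tag_id: str
    times: np.ndarray
    xy: np.ndarray
    sensitivity: np.ndarray | None = None
    n_receivers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if self.times.ndim != 1 or len(self.times) != len(self.xy):
            raise ValueError("times and xy must have matching lengths")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("track times must be strictly increasing")
        for name in ("sensitivity", "n_receivers"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if len(v) != len(self.times):
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, v)

    def __len__(self) -> int:
        return len(self.times)

    def select(self, mask: Sequence[bool]) -> "Track":
        """A new track containing the fixes where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return Track(
            self.tag_id,
            self.times[mask],
            self.xy[mask],
            None if self.sensitivity is None else self.sensitivity[mask],
            None if self.n_receivers is None else self.n_receivers[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "tag_id": self.tag_id,
                "time_s": self.times,
                "x_m": self.xy[:, 0],
                "y_m": self.xy[:, 1],
            }
        )
        if self.sensitivity is not None:
            df["sensitivity"] = self.sensitivity
        if self.n_receivers is not None:
            df["n_receivers"] = self.n_receivers
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, tag_id: str | None = None) -> "Track":
        """Build a track from a fix table (tag_id, time_s, x_m, y_m, ...).

        With ``tag_id=None`` the frame must contain a single tag (or no
        tag_id column at all, in which case the id defaults to "track").
        """
        if tag_id is not None and "tag_id" in df.columns:
            df = df[df["tag_id"] == tag_id]
        elif tag_id is None:
            if "tag_id" in df.columns:
                tags = df["tag_id"].unique()
                if len(tags) > 1:
                    raise ValueError(f"frame contains multiple tags {list(tags)}")
                tag_id = str(tags[0]) if len(tags) else "track"
            else:
                tag_id = "track"
        df = df.sort_values("time_s", kind="stable")
        return cls(
            str(tag_id),
            df["time_s"].to_numpy(dtype=float),
            df[["x_m", "y_m"]].to_numpy(dtype=float),
            df["sensitivity"].to_numpy() if "sensitivity" in df.columns else None,
            df["n_receivers"].to_numpy() if "n_receivers" in df.columns else None,
        )


def tracks_to_frame(tracks: Sequence[Track]) -> pd.DataFrame:
    """Concatenate several tracks into one fix table."""
    if not tracks:
        return pd.DataFrame(columns=["tag_id", "time_s", "x_m", "y_m"])
    return pd.concat([t.to_frame() for t in tracks], ignore_index=True)
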