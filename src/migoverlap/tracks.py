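"""GPS track container and delimited-text I/O.

Coordinates are planar meters in an arbitrary local projection; the study
systems span a few tens of kilometres, so no geodesy is used anywhere.
Timestamps are UTC-naive. The monitoring year is anchored at 13 February
(the earliest capture date in the emulated study design), so "study day"
means days elapsed since the most recent 13 February.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

HOUR = np.timedelta64(3600, "s")
DAY = np.timedelta64(86400, "s")

#: (month, day) at which the monitoring year starts.
MONITOR_YEAR_START = (2, 13)

TRACK_COLUMNS = ["id", "species", "sex", "pack", "timestamp", "x_m", "y_m"]


@dataclass
class Track:
    """One animal's time-ordered relocations with identity covariates."""

    id: str
    species: str  # deer | moose | wolf
    sex: str  # F | M
    pack: str | None
    t: np.ndarray  # datetime64[s], strictly increasing
    xy: np.ndarray  # (n, 2) float64 meters

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype="datetime64[s]")
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must have shape (n, 2)")
        if self.t.shape[0] != self.xy.shape[0]:
            raise ValueError("t and xy lengths differ")
        if self.t.size > 1 and not np.all(np.diff(self.t) > np.timedelta64(0, "s")):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.t.size)

    def hours(self, origin: np.datetime64 | None = None) -> np.ndarray:
        """Times as float hours since `origin` (default: first fix)."""
        if self.n == 0:
            return np.empty(0)
        if origin is None:
            origin = self.t[0]
        return (self.t - np.datetime64(origin, "s")) / HOUR

    def subset(self, index) -> "Track":
        """A new track keeping the given boolean mask or integer index."""
        return replace(self, t=self.t[index], xy=self.xy[index])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.id,
                "species": self.species,
                "sex": self.sex,
                "pack": self.pack if self.pack is not None else "",
                "timestamp": pd.DatetimeIndex(self.t).strftime("%Y-%m-%dT%H:%M:%S"),
                "x_m": self.xy[:, 0],
                "y_m": self.xy[:, 1],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Track":
        ids = df["id"].unique()
        if len(ids) != 1:
            raise ValueError("frame must contain exactly one animal id")
        df = df.sort_values("timestamp")
        pack = str(df["pack"].iloc[0])
        return cls(
            id=str(df["id"].iloc[0]),
            species=str(df["species"].iloc[0]),
            sex=str(df["sex"].iloc[0]),
            pack=pack if pack not in ("", "nan", "None") else None,
            t=pd.to_datetime(df["timestamp"]).to_numpy(),
            xy=df[["x_m", "y_m"]].to_numpy(float),
        )


def study_day(times) -> np.ndarray:
    """Days elapsed since the most recent 13 February, as floats.

    13 February itself maps to 0.0; the value grows continuously through the
    following 12 February.
    """
    idx = pd.DatetimeIndex(np.asarray(times, dtype="datetime64[s]"))
    anchor_year = idx.year.to_numpy().copy()
    m, d = MONITOR_YEAR_START
    before = (idx.month.to_numpy() < m) | (
        (idx.month.to_numpy() == m) & (idx.day.to_numpy() < d)
    )
    anchor_year[before] -= 1
    anchors = pd.to_datetime(
        {"year": anchor_year, "month": m, "day": d}
    ).to_numpy()
    return (idx.to_numpy() - anchors) / DAY


def study_year(times) -> np.ndarray:
    """Calendar year in which each timestamp's monitoring year started."""
    idx = pd.DatetimeIndex(np.asarray(times, dtype="datetime64[s]"))
    year = idx.year.to_numpy().copy()
    m, d = MONITOR_YEAR_START
    before = (idx.month.to_numpy() < m) | (
        (idx.month.to_numpy() == m) & (idx.day.to_numpy() < d)
    )
    year[before] -= 1
    return year


def write_tracks(tracks: list[Track], path) -> None:
    """Write tracks as one delimited text file (CSV) with standard columns."""
    frames = [tr.to_frame() for tr in tracks]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TRACK_COLUMNS)
    )
    out.to_csv(path, index=False)


def read_tracks(path) -> list[Track]:
    df = pd.read_csv(path, dtype={"id": str, "pack": str}, keep_default_na=False)
    return [Track.from_frame(g) for _, g in df.groupby("id", sort=True)]
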