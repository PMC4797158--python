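"""Bearing triangulation and trajectory construction.

Two observers with known GPS positions take simultaneous compass bearings on
a radio-tagged bird every 10 minutes.  Each bearing pair is converted to a
position estimate ("fix") at the intersection of the two forward rays;
fixes further than 1000 m from either observer are discarded as unreliable,
and the remaining fixes of one bird form a trajectory with derived step
lengths, headings and turning angles.

Conventions
-----------
* Coordinates are planar metres in a projected CRS.
* Azimuths are degrees clockwise from grid north, in [0, 360).
* Turning angles are wrapped to (-180, 180], positive = clockwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BearingObservation",
    "Fix",
    "Trajectory",
    "TriangulationError",
    "triangulate",
    "triangulate_bearing_table",
    "filter_fixes",
    "build_trajectory",
]

#: Fixes further than this from either observer are dropped (metres).
DEFAULT_MAX_OBSERVER_DISTANCE = 1000.0

#: |sin(azimuth difference)| below which bearings are treated as parallel.
PARALLEL_TOLERANCE = 1e-6


class TriangulationError(ValueError):
    """Bearing pair admits no valid forward-ray intersection."""


@dataclass(frozen=True)
class BearingObservation:
    """One compass bearing from a known observer position."""

    observer_id: str
    x: float
    y: float
    azimuth: float  # degrees clockwise from grid north, [0, 360)
    timestamp: object = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("observer coordinates must be finite")
        if not 0.0 <= self.azimuth < 360.0:
            raise ValueError(f"azimuth {self.azimuth!r} outside [0, 360)")


@dataclass
class Fix:
    """One triangulated bird position."""

    bird_id: str
    timestamp: object
    x: float
    y: float
    dist_a: float
    dist_b: float
    valid: bool = True


def _direction(azimuth_deg: float) -> tuple[float, float]:
    a = math.radians(azimuth_deg)
    return math.sin(a), math.cos(a)


def triangulate(a: BearingObservation, b: BearingObservation) -> tuple[float, float]:
    """Intersect the forward rays of two simultaneous bearings.

    Returns the (x, y) intersection point.  Raises
    :class:`TriangulationError` when the bearings are (near-)parallel or the
    intersection lies behind either observer (a back-bearing).
    """
    if (a.x, a.y) == (b.x, b.y):
        raise TriangulationError("observers are co-located")
    dax, day = _direction(a.azimuth)
    dbx, dby = _direction(b.azimuth)
    denom = dax * dby - day * dbx  # sin(azA - azB)
    if abs(denom) < PARALLEL_TOLERANCE:
        raise TriangulationError(
            f"bearings nearly parallel (Δazimuth sine {denom:.2e})"
        )
    rx, ry = b.x - a.x, b.y - a.y
    t = (rx * dby - ry * dbx) / denom
    u = (rx * day - ry * dax) / denom
    if t < 0 or u < 0:
        raise TriangulationError("intersection behind an observer (back-bearing)")
    return a.x + t * dax, a.y + t * day


def triangulate_bearing_table(table: pd.DataFrame, bird_id: str | None = None) -> list[Fix]:
    """Triangulate a paired-bearings table into fixes.

    Expects the bearings CSV schema: ``bird_id, timestamp, obs_a_x, obs_a_y,
    obs_a_az, obs_b_x, obs_b_y, obs_b_az`` (one simultaneous pair per row).
    Rows whose rays fail to intersect are marked invalid rather than raised,
    mirroring field practice where bad pairs are logged and skipped.
    """
    fixes: list[Fix] = []
    for row in table.itertuples(index=False):
        bid = bird_id or str(getattr(row, "bird_id", "bird"))
        a = BearingObservation("A", row.obs_a_x, row.obs_a_y, row.obs_a_az % 360.0, row.timestamp)
        b = BearingObservation("B", row.obs_b_x, row.obs_b_y, row.obs_b_az % 360.0, row.timestamp)
        try:
            x, y = triangulate(a, b)
        except TriangulationError:
            fixes.append(Fix(bid, row.timestamp, np.nan, np.nan, np.inf, np.inf, valid=False))
            continue
        da = math.hypot(x - a.x, y - a.y)
        db = math.hypot(x - b.x, y - b.y)
        fixes.append(Fix(bid, row.timestamp, x, y, da, db, valid=True))
    return fixes


def filter_fixes(
    fixes: Sequence[Fix], max_dist: float = DEFAULT_MAX_OBSERVER_DISTANCE
) -> tuple[list[Fix], int]:
    """Drop fixes further than ``max_dist`` from either observer.

    The rule is strict: a fix at exactly ``max_dist`` is kept, one beyond it
    is removed.  Invalid fixes are removed too.  Returns the retained fixes
    (order preserved) and the number removed.
    """
    kept = [
        f
        for f in fixes
        if f.valid and f.dist_a <= max_dist and f.dist_b <= max_dist
    ]
    return kept, len(fixes) - len(kept)


def _wrap_turn(deg: np.ndarray) -> np.ndarray:
    """Wrap angle differences to (-180, 180]."""
    w = (np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(w == -180.0, 180.0, w)


@dataclass
class Trajectory:
    """Time-ordered fixes of one bird with derived step statistics.

    ``headings`` are step azimuths (degrees clockwise from north, one per
    step); ``turn_angles`` are successive heading changes (n_steps - 1
    values, defined from the second step onward).
    """

    bird_id: str
    times: np.ndarray  # datetime64[ns] or float minutes
    xy: np.ndarray  # (n, 2) metres
    step_lengths: np.ndarray
    dt_min: np.ndarray
    headings: np.ndarray
    turn_angles: np.ndarray

    @property
    def n_fixes(self) -> int:
        return len(self.xy)

    @property
    def n_steps(self) -> int:
        return len(self.step_lengths)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bird_id": self.bird_id, "timestamp": self.times,
             "x": self.xy[:, 0], "y": self.xy[:, 1]}
        )


def _times_to_minutes(times: np.ndarray) -> np.ndarray:
    if np.issubdtype(times.dtype, np.datetime64):
        return (times - times[0]) / np.timedelta64(60, "s")
    return times.astype(float)


def build_trajectory(fixes: Sequence[Fix] | pd.DataFrame, bird_id: str | None = None) -> Trajectory:
    """Assemble ordered fixes into a :class:`Trajectory`.

    Accepts a fix list or a DataFrame with ``timestamp, x, y`` columns.
    Raises on fewer than two fixes or duplicate timestamps.
    """
    if isinstance(fixes, pd.DataFrame):
        df = fixes
        bid = bird_id or (str(df["bird_id"].iloc[0]) if "bird_id" in df else "bird")
        times = df["timestamp"].to_numpy()
        xy = df[["x", "y"]].to_numpy(dtype=float)
    else:
        if not fixes:
            raise ValueError("no fixes")
        bid = bird_id or fixes[0].bird_id
        times = np.asarray([f.timestamp for f in fixes])
        xy = np.asarray([(f.x, f.y) for f in fixes], dtype=float)
    if len(xy) < 2:
        raise ValueError("a trajectory needs at least two fixes")
    if np.issubdtype(np.asarray(times).dtype, np.object_):
        times = pd.to_datetime(times).to_numpy()
    order = np.argsort(times, kind="stable")
    times, xy = times[order], xy[order]
    minutes = _times_to_minutes(np.asarray(times))
    dt = np.diff(minutes)
    if np.any(dt <= 0):
        raise ValueError("duplicate or non-increasing timestamps")
    d = np.diff(xy, axis=0)
    lengths = np.hypot(d[:, 0], d[:, 1])
    headings = np.degrees(np.arctan2(d[:, 0], d[:, 1])) % 360.0
    turns = _wrap_turn(np.diff(headings))
    return Trajectory(bid, times, xy, lengths, dt, headings, turns)
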