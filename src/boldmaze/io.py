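"""Reading, validation and conditioning of tracking exports.

The package consumes time-stamped 2-D centroid tracks exported by video
tracking software, one subject per file, plus optional pre-extracted L/R
turn-sequence files. Everything is converted to SI (meters, seconds) on
ingestion; the documented CSV schemas are

* tracking:       ``fish_id,t_s,x_m,y_m`` (column names remappable)
* turn sequence:  ``fish_id,token,t_s`` with token in {L, R}

Frames whose coordinates fall outside the declared arena are dropped and
treated as tracking gaps (clamping would manufacture wall-hugging).
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .arena import ArenaGeometry
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_COLUMNS = {"subject": "fish_id", "time": "t_s", "x": "x_m", "y": "y_m"}

__all__ = [
    "Trajectory",
    "TurnEvent",
    "GapRecord",
    "read_tracking_csv",
    "write_tracking_csv",
    "interpolate_gaps",
    "read_turn_sequence",
    "write_turn_sequence",
]


@dataclass(frozen=True)
class GapRecord:
    """One tracking dropout: the time span with no usable frames and whether
    it was filled by interpolation or left as a segment break."""

    t_start: float
    t_end: float
    filled: bool


@dataclass
class Trajectory:
    """One subject's validated centroid path in a named arena.

    ``break_indices`` lists sample indices that *start* a new unbroken
    segment (a break sits between index ``i-1`` and ``i``); downstream step
    and turn computations never bridge a break.
    """

    subject_id: str
    arena_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate_hint: Optional[float] = None
    break_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    gap_log: list[GapRecord] = field(default_factory=list, compare=False)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.break_indices = np.asarray(self.break_indices, dtype=int)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValidationError(
                f"{self.subject_id}: t, x, y must have equal length")
        if len(self.t) < 2:
            raise ValidationError(
                f"{self.subject_id}: trajectory needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError(
                f"{self.subject_id}: timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def segments(self) -> Iterator[slice]:
        """Yield slices delimiting unbroken tracking segments."""
        bounds = [0, *self.break_indices.tolist(), len(self.t)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a >= 1:
                yield slice(a, b)


@dataclass(frozen=True)
class TurnEvent:
    """A completed left/right arm turn in the Y-maze."""

    token: str
    t_completed: float
    from_arm: Optional[int] = None
    to_arm: Optional[int] = None

    def __post_init__(self):
        if self.token not in ("L", "R"):
            raise FormatError(f"turn token must be L or R, got {self.token!r}")
        if (self.from_arm is not None and self.to_arm is not None
                and self.from_arm == self.to_arm):
            raise ValidationError("a turn must connect two distinct arms")


def read_tracking_csv(
    path,
    arena: ArenaGeometry,
    columns: Optional[dict] = None,
    scale_xy: float = 1.0,
    scale_t: float = 1.0,
    max_missing_frac: float = 0.2,
    frame_rate_hint: Optional[float] = None,
) -> Trajectory:
    """Read one subject's tracking export into a validated :class:`Trajectory`.

    Parameters
    ----------
    columns:
        Mapping with keys ``subject``, ``time``, ``x``, ``y`` naming the CSV
        columns; defaults to ``fish_id,t_s,x_m,y_m``.
    scale_xy, scale_t:
        Multiplicative conversion to meters / seconds (e.g. ``scale_xy=0.01``
        for a file in centimeters).
    max_missing_frac:
        Reject the subject if more than this fraction of frames is dropped
        for lying outside the arena.
    """
    colmap = {**DEFAULT_COLUMNS, **(columns or {})}
    df = pd.read_csv(path)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}; found {list(df.columns)}")

    subjects = df[colmap["subject"]].astype(str).unique()
    if len(subjects) != 1:
        raise FormatError(f"{path}: expected a single subject, found {list(subjects)}")
    subject_id = subjects[0]

    t = df[colmap["time"]].to_numpy(dtype=float) * scale_t
    x = df[colmap["x"]].to_numpy(dtype=float) * scale_xy
    y = df[colmap["y"]].to_numpy(dtype=float) * scale_xy
    if np.any(~np.isfinite(t)) or np.any(np.diff(t) <= 0):
        raise ValidationError(f"{subject_id}: non-monotonic or invalid time column")

    ok = np.isfinite(x) & np.isfinite(y) & arena.contains(x, y)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("%s: dropped %d/%d out-of-bounds frames", subject_id, dropped, len(t))
    if len(t) == 0 or dropped / len(t) > max_missing_frac:
        raise ValidationError(
            f"{subject_id}: {dropped}/{len(t)} frames out of bounds "
            f"exceeds max_missing_frac={max_missing_frac}")
    return Trajectory(
        subject_id=subject_id,
        arena_id=arena.kind,
        t=t[ok],
        x=x[ok],
        y=y[ok],
        frame_rate_hint=frame_rate_hint,
    )


def write_tracking_csv(traj: Trajectory, path, columns: Optional[dict] = None) -> None:
    """Serialize a trajectory back to the canonical tracking schema."""
    colmap = {**DEFAULT_COLUMNS, **(columns or {})}
    pd.DataFrame({
        colmap["subject"]: traj.subject_id,
        colmap["time"]: traj.t,
        colmap["x"]: traj.x,
        colmap["y"]: traj.y,
    }).to_csv(path, index=False)


def _modal_interval(t: np.ndarray) -> float:
    diffs = np.round(np.diff(t), 6)
    return float(Counter(diffs.tolist()).most_common(1)[0][0])


def interpolate_gaps(traj: Trajectory, max_gap_s: float = 0.5) -> Trajectory:
    """Fill short tracking dropouts by linear interpolation.

    Gaps no longer than ``max_gap_s`` are filled at the modal frame interval;
    longer gaps are recorded as segment breaks so that downstream speed and
    turn computations do not bridge them. The returned trajectory carries a
    ``gap_log`` listing every gap and whether it was filled.
    """
    if max_gap_s <= 0:
        raise ValueError("max_gap_s must be positive")
    dt_mode = _modal_interval(traj.t)
    gap_threshold = 1.5 * dt_mode  # anything beyond one nominal frame step

    ts, xs, ys = [traj.t[0]], [traj.x[0]], [traj.y[0]]
    breaks: list[int] = []
    gaps: list[GapRecord] = []
    existing_breaks = set(traj.break_indices.tolist())

    for i in range(1, len(traj.t)):
        dt = traj.t[i] - traj.t[i - 1]
        if i in existing_breaks:
            breaks.append(len(ts))
        elif dt > gap_threshold:
            if dt <= max_gap_s:
                n_insert = int(round(dt / dt_mode)) - 1
                frac = (np.arange(1, n_insert + 1) * dt_mode) / dt
                frac = frac[frac < 1 - 1e-9]
                ts.extend(traj.t[i - 1] + frac * dt)
                xs.extend(traj.x[i - 1] + frac * (traj.x[i] - traj.x[i - 1]))
                ys.extend(traj.y[i - 1] + frac * (traj.y[i] - traj.y[i - 1]))
                gaps.append(GapRecord(traj.t[i - 1], traj.t[i], filled=True))
            else:
                breaks.append(len(ts))
                gaps.append(GapRecord(traj.t[i - 1], traj.t[i], filled=False))
        ts.append(traj.t[i])
        xs.append(traj.x[i])
        ys.append(traj.y[i])

    for g in gaps:
        logger.info("%s: gap %.3f-%.3f s %s", traj.subject_id, g.t_start, g.t_end,
                    "interpolated" if g.filled else "segment break")
    return replace(
        traj,
        t=np.array(ts), x=np.array(xs), y=np.array(ys),
        break_indices=np.array(breaks, dtype=int),
        gap_log=list(traj.gap_log) + gaps,
    )


def read_turn_sequence(path) -> list[TurnEvent]:
    """Read a pre-extracted L/R turn stream (``fish_id,token,t_s``).

    Optional ``from_arm``/``to_arm`` columns are preserved when present.
    """
    df = pd.read_csv(path)
    for col in ("token", "t_s"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    bad = set(df["token"].astype(str)) - {"L", "R"}
    if bad:
        raise FormatError(f"{path}: unknown turn tokens {sorted(bad)}")
    has_arms = "from_arm" in df.columns and "to_arm" in df.columns
    events = []
    for row in df.itertuples(index=False):
        events.append(TurnEvent(
            token=str(row.token),
            t_completed=float(row.t_s),
            from_arm=int(row.from_arm) if has_arms else None,
            to_arm=int(row.to_arm) if has_arms else None,
        ))
    if any(events[i].t_completed > events[i + 1].t_completed
           for i in range(len(events) - 1)):
        raise ValidationError(f"{path}: turn timestamps must be non-decreasing")
    return events


def write_turn_sequence(events: Sequence[TurnEvent], path, fish_id: str = "") -> None:
    """Serialize turn events to the canonical turn-sequence schema."""
    df = pd.DataFrame({
        "fish_id": fish_id,
        "token": [e.token for e in events],
        "t_s": [e.t_completed for e in events],
    })
    if events and events[0].from_arm is not None:
        df["from_arm"] = [e.from_arm for e in events]
        df["to_arm"] = [e.to_arm for e in events]
    df.to_csv(path, index=False)
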