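"""FMP Y-maze turn extraction and tetragram sequence analysis.

A fish exploring a three-arm Y-maze produces a stream of left/right arm
choices. Working memory and repetitive behavior are read out from the
composition of overlapping *tetragrams* — sliding windows of four consecutive
turns, of which there are 2^4 = 16 possible patterns. Two patterns classes
summarize the main search strategies:

* alternations (LRLR + RLRL) — the cognitively demanding, working-memory
  linked strategy;
* repetitions (LLLL + RRRR) — the stress-sensitive, perseverative strategy.

Profiles are computed globally over the whole session and within consecutive
10-minute bins of the 1-hour test ("immediate" strategy); tetragram windows
never span a bin boundary, so per-bin percentages are self-contained.

Turn chirality follows the counterclockwise-equals-left convention: with arms
labelled 0, 1, 2 counterclockwise from above, a transition to the next arm
counterclockwise is an L, to the next clockwise an R. All alternation and
repetition summaries are invariant to this choice by L/R symmetry.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .arena import ArenaGeometry
from .errors import ValidationError
from .io import Trajectory, TurnEvent

__all__ = [
    "PATTERNS",
    "ALTERNATION_PATTERNS",
    "REPETITION_PATTERNS",
    "ArmVisit",
    "TetragramProfile",
    "BinnedProfile",
    "detect_arm_entries",
    "turns_from_entries",
    "tetragram_counts",
    "bin_profiles",
    "global_summary",
    "profile_to_row",
]

#: The 16 possible four-turn patterns, lexicographic.
PATTERNS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("LR", repeat=4))
ALTERNATION_PATTERNS = ("LRLR", "RLRL")
REPETITION_PATTERNS = ("LLLL", "RRRR")


@dataclass(frozen=True)
class ArmVisit:
    """One registered entry into a maze arm."""

    arm: int
    t_entry: float


@dataclass
class TetragramProfile:
    """Tetragram composition of one turn sequence (or one time bin).

    ``pct`` maps each pattern to its percentage of ``total_tetragrams``;
    percentages are ``None`` when the window holds fewer than four turns.
    """

    subject_id: str
    window: tuple[float, float]
    counts: dict[str, int]
    total_turns: int
    total_tetragrams: int
    pct: Optional[dict[str, float]] = None
    alternations_pct: Optional[float] = None
    repetitions_pct: Optional[float] = None


@dataclass
class BinnedProfile:
    """Per-bin tetragram profiles tiling one session without overlap."""

    subject_id: str
    bins: list[TetragramProfile] = field(default_factory=list)


def detect_arm_entries(
    traj: Trajectory,
    maze: ArenaGeometry,
    min_dwell_s: float = 0.2,
) -> list[ArmVisit]:
    """Extract the ordered sequence of arm visits from a top-view trajectory.

    An entry is registered when the centroid penetrates an arm beyond the
    maze's ``center_exclusion_radius`` and remains in that arm for at least
    ``min_dwell_s`` (debouncing against boundary jitter). Consecutive visits
    to the same arm collapse to one. A trajectory that never leaves the
    center yields an empty list.
    """
    arm, depth = maze.arm_membership(traj.x, traj.y)
    # frame-level zone: the arm id where penetration passes the threshold, else -1
    zone = np.where((arm >= 0) & (depth >= maze.center_exclusion_radius), arm, -1)

    visits: list[ArmVisit] = []
    i = 0
    n = len(zone)
    while i < n:
        z = zone[i]
        j = i
        while j + 1 < n and zone[j + 1] == z:
            j += 1
        if z >= 0 and (traj.t[j] - traj.t[i] >= min_dwell_s or (i == 0 and j == n - 1)):
            if not visits or visits[-1].arm != z:
                visits.append(ArmVisit(int(z), float(traj.t[i])))
        i = j + 1
    return visits


def turns_from_entries(visits: Sequence[ArmVisit]) -> list[TurnEvent]:
    """Convert an arm-visit sequence into L/R turn events.

    With arms 0, 1, 2 labelled counterclockwise, moving to the next arm
    counterclockwise (``(from + 1) mod 3``) is a left turn and to the next
    clockwise (``(from + 2) mod 3``) a right turn. Same-arm re-entries carry
    no left/right identity and emit no event.
    """
    events: list[TurnEvent] = []
    for prev, cur in zip(visits[:-1], visits[1:]):
        if cur.arm == prev.arm:
            continue
        token = "L" if (cur.arm - prev.arm) % 3 == 1 else "R"
        events.append(TurnEvent(token=token, t_completed=cur.t_entry,
                                from_arm=prev.arm, to_arm=cur.arm))
    return events


def tetragram_counts(
    tokens: Sequence[str],
    subject_id: str = "",
    window: tuple[float, float] = (0.0, 0.0),
) -> TetragramProfile:
    """Count the 16 overlapping tetragrams in an L/R token sequence.

    A sliding window of length 4 and stride 1 gives ``max(0, n - 3)``
    tetragrams for ``n`` turns. Percentages are taken over the tetragram
    total and are undefined (``None``) for sequences shorter than 4.
    """
    tokens = list(tokens)
    bad = set(tokens) - {"L", "R"}
    if bad:
        raise ValidationError(f"turn tokens must be L or R, got {sorted(bad)}")
    counts = {p: 0 for p in PATTERNS}
    for i in range(len(tokens) - 3):
        counts["".join(tokens[i:i + 4])] += 1
    total = max(0, len(tokens) - 3)
    profile = TetragramProfile(
        subject_id=subject_id,
        window=window,
        counts=counts,
        total_turns=len(tokens),
        total_tetragrams=total,
    )
    if total > 0:
        profile.pct = {p: 100.0 * c / total for p, c in counts.items()}
        profile.alternations_pct = sum(profile.pct[p] for p in ALTERNATION_PATTERNS)
        profile.repetitions_pct = sum(profile.pct[p] for p in REPETITION_PATTERNS)
    return profile


def bin_profiles(
    events: Sequence[TurnEvent],
    session_length_s: float = 3600.0,
    bin_length_s: float = 600.0,
    subject_id: str = "",
) -> BinnedProfile:
    """Tetragram profiles over consecutive time bins of one session.

    Turns are assigned to bins by completion time and tetragrams are
    recomputed independently within each bin, so windows never span a bin
    boundary; bins holding fewer than four turns report zero tetragrams.
    A 60-minute session with 10-minute bins yields exactly six profiles.
    """
    n_bins = session_length_s / bin_length_s
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_length_s must divide session_length_s")
    n_bins = int(round(n_bins))
    times = np.array([e.t_completed for e in events])
    if len(times) and (times.min() < 0 or times.max() > session_length_s):
        raise ValidationError(
            f"{subject_id}: turn events outside [0, {session_length_s}] s")

    binned = BinnedProfile(subject_id=subject_id)
    for b in range(n_bins):
        lo, hi = b * bin_length_s, (b + 1) * bin_length_s
        # half-open bins; the final bin includes the session end
        in_bin = [e.token for e in events
                  if lo <= e.t_completed < hi or (b == n_bins - 1 and e.t_completed == hi)]
        binned.bins.append(
            tetragram_counts(in_bin, subject_id=subject_id, window=(lo, hi)))
    return binned


def global_summary(
    events: Sequence[TurnEvent], subject_id: str = ""
) -> tuple[int, Optional[float], Optional[float]]:
    """Session-wide ``(total_turns, alternations_pct, repetitions_pct)``.

    Computed from the unbroken whole-session tetragram profile; percentages
    are over total tetragrams (turns − 3), the only denominator under which
    the 16 pattern percentages sum to 100.
    """
    profile = tetragram_counts([e.token for e in events], subject_id=subject_id)
    return profile.total_turns, profile.alternations_pct, profile.repetitions_pct


def profile_to_row(profile: TetragramProfile) -> dict:
    """Flatten a profile into one tidy table row (16 pct columns included)."""
    row = {
        "subject_id": profile.subject_id,
        "total_turns": profile.total_turns,
        "total_tetragrams": profile.total_tetragrams,
        "alternations_pct": profile.alternations_pct,
        "repetitions_pct": profile.repetitions_pct,
    }
    for p in PATTERNS:
        row[f"pct_{p}"] = profile.pct[p] if profile.pct else None
    return row
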