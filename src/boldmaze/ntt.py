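"""Novel tank test (NTT) endpoints and boldness phenotyping.

The NTT records a single fish in a narrow tank viewed from the side for six
minutes. Four endpoints are extracted from the centroid track: total distance
traveled (m), maximum speed (m/s), cumulative absolute turn angle (deg), and
time-averaged distance from the tank bottom (m). Boldness is scored as a
weighted combination of the two most diagnostic endpoints after cohort-wise
min-max normalization,

    boldness_index = 0.67 * norm(distance from bottom)
                   + 0.33 * norm(distance traveled)

top exploration carrying double the weight of locomotion, and the cohort is
median-split into bold and shy phenotypes.

Distance and turn angle use a minimum-displacement (noise floor) filter:
displacement is accumulated from an anchor point and registered only once it
exceeds the floor, which suppresses centroid jitter that would otherwise
inflate both endpoints at 30 fps.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InsufficientDataError, ValidationError
from .io import Trajectory

__all__ = [
    "NttEndpoints",
    "BoldnessConfig",
    "BoldnessRecord",
    "compute_ntt_endpoints",
    "normalize_cohort",
    "boldness_index",
    "classify_phenotypes",
    "score_cohort",
]


@dataclass(frozen=True)
class NttEndpoints:
    """The four scalar NTT readouts for one fish (SI units, degrees)."""

    subject_id: str
    distance_traveled: float
    max_speed: float
    absolute_turn_angle: float
    distance_from_bottom: float


@dataclass(frozen=True)
class BoldnessConfig:
    """Weights and rules for the boldness index.

    ``w_bottom``/``w_distance`` must sum to 1; the defaults give distance
    from bottom double the weight of distance traveled. Normalization is
    min-max over the analyzed cohort and the phenotype split is a balanced
    median split.
    """

    w_bottom: float = 0.67
    w_distance: float = 0.33
    normalization: str = "minmax_cohort"
    split_rule: str = "median"
    noise_floor_m: float = 0.002

    def __post_init__(self):
        if not (0 < self.w_bottom < 1 and 0 < self.w_distance < 1):
            raise ValueError("weights must lie in (0, 1)")
        if abs(self.w_bottom + self.w_distance - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass
class BoldnessRecord:
    """Normalized components, weighted index and phenotype label for one fish."""

    subject_id: str
    norm_distance_from_bottom: float
    norm_distance_traveled: float
    boldness_index: Optional[float] = None
    phenotype: Optional[str] = None


def compute_ntt_endpoints(traj: Trajectory, noise_floor: float = 0.002) -> NttEndpoints:
    """Extract the four NTT endpoints from a validated side-view trajectory.

    Within each unbroken tracking segment, displacement is accumulated from an
    anchor point; once it exceeds ``noise_floor`` (m) the displacement vector
    is registered: its length adds to distance traveled and the absolute
    heading change relative to the previous registered vector adds to the turn
    angle. Maximum speed is taken over raw frame-to-frame steps; distance from
    bottom is the duration-weighted mean of the vertical coordinate.
    """
    if noise_floor < 0:
        raise ValueError("noise_floor must be non-negative")
    if len(traj) < 2:
        raise InsufficientDataError(f"{traj.subject_id}: fewer than 2 usable points")

    distance = 0.0
    turn_deg = 0.0
    max_speed = 0.0
    w_sum = 0.0
    wy_sum = 0.0

    for seg in traj.segments():
        t, x, y = traj.t[seg], traj.x[seg], traj.y[seg]
        if len(t) >= 2:
            dt = np.diff(t)
            step = np.hypot(np.diff(x), np.diff(y))
            max_speed = max(max_speed, float(np.max(step / dt)))
            # trapezoid duration weights for the vertical average
            w = np.zeros(len(t))
            w[:-1] += dt / 2
            w[1:] += dt / 2
            w_sum += float(w.sum())
            wy_sum += float((w * y).sum())
        # noise-floor displacement filter
        ax, ay = x[0], y[0]
        prev_heading = None
        for i in range(1, len(t)):
            dx, dy = x[i] - ax, y[i] - ay
            d = np.hypot(dx, dy)
            if d > noise_floor:
                distance += float(d)
                heading = np.arctan2(dy, dx)
                if prev_heading is not None:
                    dh = np.angle(np.exp(1j * (heading - prev_heading)))
                    turn_deg += abs(float(np.degrees(dh)))
                prev_heading = heading
                ax, ay = x[i], y[i]

    dist_bottom = wy_sum / w_sum if w_sum > 0 else float(np.mean(traj.y))
    return NttEndpoints(
        subject_id=traj.subject_id,
        distance_traveled=distance,
        max_speed=max_speed,
        absolute_turn_angle=turn_deg,
        distance_from_bottom=dist_bottom,
    )


def _minmax(values: np.ndarray, name: str) -> np.ndarray:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi - lo <= 0:
        raise DegenerateDataError(
            f"component {name!r} is constant across the cohort; cannot rank")
    return (values - lo) / (hi - lo)


def normalize_cohort(
    endpoints: Sequence[NttEndpoints], cfg: BoldnessConfig = BoldnessConfig()
) -> list[BoldnessRecord]:
    """Min-max normalize the two index components across the cohort.

    Cohort extremes map to exactly 0 and 1 per component.
    """
    if len(endpoints) < 2:
        raise InsufficientDataError("cohort normalization needs at least 2 fish")
    bottom = _minmax(np.array([e.distance_from_bottom for e in endpoints]),
                     "distance_from_bottom")
    dist = _minmax(np.array([e.distance_traveled for e in endpoints]),
                   "distance_traveled")
    return [
        BoldnessRecord(e.subject_id, float(b), float(d))
        for e, b, d in zip(endpoints, bottom, dist)
    ]


def boldness_index(rec: BoldnessRecord, cfg: BoldnessConfig = BoldnessConfig()) -> float:
    """Weighted boldness index of one fish from its normalized components."""
    b, d = rec.norm_distance_from_bottom, rec.norm_distance_traveled
    if not (0 <= b <= 1 and 0 <= d <= 1):
        raise ValidationError(
            f"{rec.subject_id}: normalized components must lie in [0, 1]")
    return cfg.w_bottom * b + cfg.w_distance * d


def classify_phenotypes(
    records: Sequence[BoldnessRecord], cfg: BoldnessConfig = BoldnessConfig()
) -> list[BoldnessRecord]:
    """Median-split the cohort on the boldness index into bold and shy.

    Fish strictly above the cohort median are bold, strictly below shy. Ties
    at the median are broken by higher normalized distance from bottom, then
    by subject id, which makes the split deterministic and balanced: with
    distinct indices an even cohort splits exactly in half and an odd
    cohort's median fish goes to the shy side.
    """
    if len(records) < 2:
        raise InsufficientDataError("classification needs at least 2 fish")
    scored = [
        replace(r, boldness_index=boldness_index(r, cfg)) for r in records
    ]
    order = sorted(
        range(len(scored)),
        key=lambda i: (-scored[i].boldness_index,
                       -scored[i].norm_distance_from_bottom,
                       scored[i].subject_id),
    )
    n_bold = len(scored) // 2
    for rank, i in enumerate(order):
        scored[i].phenotype = "bold" if rank < n_bold else "shy"
    return scored


def score_cohort(
    endpoints: Sequence[NttEndpoints], cfg: BoldnessConfig = BoldnessConfig()
) -> pd.DataFrame:
    """Normalize, score and classify a cohort; returns the tidy per-fish table.

    Columns: ``subject_id, distance_traveled_m, max_speed_mps,
    abs_turn_angle_deg, dist_from_bottom_m, norm_bottom, norm_distance,
    boldness_index, phenotype``.
    """
    records = classify_phenotypes(normalize_cohort(endpoints, cfg), cfg)
    by_id = {r.subject_id: r for r in records}
    rows = []
    for e in endpoints:
        r = by_id[e.subject_id]
        rows.append({
            "subject_id": e.subject_id,
            "distance_traveled_m": e.distance_traveled,
            "max_speed_mps": e.max_speed,
            "abs_turn_angle_deg": e.absolute_turn_angle,
            "dist_from_bottom_m": e.distance_from_bottom,
            "norm_bottom": r.norm_distance_from_bottom,
            "norm_distance": r.norm_distance_traveled,
            "boldness_index": r.boldness_index,
            "phenotype": r.phenotype,
        })
    return pd.DataFrame(rows)
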