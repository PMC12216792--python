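"""Arena geometries for the two behavioral assays.

Two arenas are modelled, both in SI units (meters):

* the novel tank test (NTT) tank seen from the side — a 0.25 m long column of
  water 0.10 m deep, with ``y = 0`` at the tank bottom;
* the free-movement-pattern (FMP) Y-maze seen from above — three identical
  rectangular arms (0.05 m long, 0.02 m wide) radiating at 120 deg from an
  equilateral center triangle whose side equals the arm width.

The Y-maze is described analytically rather than with a polygon library: each
arm ``i`` has a unit axis ``u_i``; a point belongs to arm ``i`` when its
projection on ``u_i`` lies between the center-triangle apothem and the apothem
plus the arm length, and its lateral offset is at most half the arm width.
The center triangle is the intersection of the three half-planes
``p . u_i <= apothem``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NTT_LENGTH_M = 0.25
NTT_DEPTH_M = 0.10
YMAZE_ARM_LENGTH_M = 0.05
YMAZE_ARM_WIDTH_M = 0.02

#: Arm axis angles, radians; arms are labelled 0, 1, 2 counterclockwise
#: when the maze is viewed from above.
_ARM_ANGLES = np.deg2rad([90.0, 210.0, 330.0])


@dataclass(frozen=True)
class ArenaGeometry:
    """Geometry of one recording arena.

    Parameters
    ----------
    kind:
        ``"ntt_side_view"`` or ``"ymaze_top_view"``.
    center_exclusion_radius:
        Y-maze only: how far (m) past the center-triangle edge the centroid
        must travel along an arm before an arm entry is registered.
    """

    kind: str
    ntt_length: float = NTT_LENGTH_M
    ntt_depth: float = NTT_DEPTH_M
    arm_length: float = YMAZE_ARM_LENGTH_M
    arm_width: float = YMAZE_ARM_WIDTH_M
    center_exclusion_radius: float = 0.01
    _axes: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.kind not in ("ntt_side_view", "ymaze_top_view"):
            raise ValueError(f"unknown arena kind: {self.kind!r}")
        axes = np.stack([np.cos(_ARM_ANGLES), np.sin(_ARM_ANGLES)], axis=1)
        object.__setattr__(self, "_axes", axes)

    # -- derived quantities -------------------------------------------------
    @property
    def apothem(self) -> float:
        """Distance from maze center to the midpoint of a triangle edge."""
        return self.arm_width / (2.0 * np.sqrt(3.0))

    # -- membership tests ---------------------------------------------------
    def contains(self, x, y) -> np.ndarray:
        """Vectorized point-in-arena test."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.kind == "ntt_side_view":
            return (x >= 0) & (x <= self.ntt_length) & (y >= 0) & (y <= self.ntt_depth)
        proj = self._projections(x, y)          # (n, 3) along-axis
        lat = self._laterals(x, y)              # (n, 3) |across-axis|
        in_center = np.all(proj <= self.apothem + 1e-12, axis=-1)
        in_arm = np.any(
            (proj >= self.apothem - 1e-12)
            & (proj <= self.apothem + self.arm_length + 1e-12)
            & (lat <= self.arm_width / 2 + 1e-12),
            axis=-1,
        )
        return in_center | in_arm

    def arm_membership(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Classify points into arms.

        Returns ``(arm, depth)`` where ``arm`` is 0/1/2 for points inside an
        arm rectangle and -1 elsewhere (center or outside), and ``depth`` is
        the distance travelled into the arm past the center-triangle edge
        (0 for non-arm points).
        """
        if self.kind != "ymaze_top_view":
            raise ValueError("arm_membership is defined for the Y-maze only")
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        proj = self._projections(x, y)
        lat = self._laterals(x, y)
        inside = (
            (proj >= self.apothem - 1e-12)
            & (proj <= self.apothem + self.arm_length + 1e-12)
            & (lat <= self.arm_width / 2 + 1e-12)
        )
        # arms are pairwise disjoint so at most one column is True per row
        arm = np.where(inside.any(axis=-1), inside.argmax(axis=-1), -1)
        depth = np.where(
            arm >= 0,
            np.take_along_axis(proj, np.maximum(arm, 0)[..., None], axis=-1)[..., 0]
            - self.apothem,
            0.0,
        )
        return arm, np.maximum(depth, 0.0)

    def arm_point(self, arm: int, depth: float, lateral: float = 0.0) -> tuple[float, float]:
        """Coordinates of a point ``depth`` m into ``arm`` (test helper)."""
        u = self._axes[arm]
        n = np.array([-u[1], u[0]])
        p = (self.apothem + depth) * u + lateral * n
        return float(p[0]), float(p[1])

    def _projections(self, x, y):
        pts = np.stack([x, y], axis=-1)
        return pts @ self._axes.T

    def _laterals(self, x, y):
        pts = np.stack([x, y], axis=-1)
        normals = np.stack([-self._axes[:, 1], self._axes[:, 0]], axis=1)
        return np.abs(pts @ normals.T)


def ntt_arena() -> ArenaGeometry:
    """The 25 x 5 cm novel-tank side view with 10 cm water depth."""
    return ArenaGeometry(kind="ntt_side_view")


def ymaze_arena(center_exclusion_radius: float = 0.01) -> ArenaGeometry:
    """The three-arm FMP Y-maze top view (5 x 2 cm arms at 120 deg)."""
    return ArenaGeometry(kind="ymaze_top_view",
                         center_exclusion_radius=center_exclusion_radius)
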