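"""Pure rigid-body geometry for the hinge-and-axis construction.

Centroids, chamber axes (unit vectors from the atrioventricular-canal
centroid to a chamber centroid), minimal rotations aligning one axis onto
another, and signed rotation angles measured about an axis in the plane
perpendicular to it.

Conventions: all positions in microns, all angles in degrees, right-handed
coordinate system. A positive angle about an axis is counterclockwise when
viewed from the tip of the axis vector looking toward the origin. All
computation is double precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "AxisFrame",
    "RigidRotation",
    "DegenerateAxisError",
    "UndefinedAngleError",
    "EPS_PROJ_UM",
    "centroid",
    "chamber_axis",
    "minimal_rotation",
    "signed_angle_about_axis",
]

#: Minimum perpendicular distance (µm) from the rotation axis for a cell's
#: rotation angle to be defined. Sub-voxel offsets (voxels are ≥0.889 µm)
#: are noise-dominated, so such cell/frame pairs are skipped.
EPS_PROJ_UM = 0.5

_UNIT_TOL = 1e-9


class DegenerateAxisError(ValueError):
    """Chamber centroid coincides with the AV-canal centroid."""


class UndefinedAngleError(ValueError):
    """A point lies (numerically) on the rotation axis; no angle defined."""


@dataclass(frozen=True)
class AxisFrame:
    """Per-timepoint hinge frame: AV centroid plus the two chamber axes.

    ``ventricle_axis`` and ``atrium_axis`` are unit vectors pointing from
    the AV-canal centroid toward the respective chamber centroid.
    """

    t_index: int
    av_centroid: np.ndarray
    ventricle_axis: np.ndarray
    atrium_axis: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ventricle_axis", "atrium_axis"):
            v = np.asarray(getattr(self, name), dtype=float)
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} is not unit-norm")
            object.__setattr__(self, name, v)
        object.__setattr__(
            self, "av_centroid", np.asarray(self.av_centroid, dtype=float)
        )


@dataclass(frozen=True)
class RigidRotation:
    """A proper rotation stored as (unit axis, angle in degrees [0, 180])."""

    axis: np.ndarray
    angle_deg: float

    def __post_init__(self) -> None:
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("rotation axis must be unit-norm")
        if not 0.0 <= self.angle_deg <= 180.0:
            raise ValueError("rotation angle must be in [0, 180] degrees")
        object.__setattr__(self, "axis", a)

    @property
    def matrix(self) -> np.ndarray:
        """The equivalent 3×3 orthonormal matrix (determinant +1)."""
        return Rotation.from_rotvec(
            np.deg2rad(self.angle_deg) * self.axis
        ).as_matrix()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Rotate one point or an (n, 3) array of points."""
        return np.asarray(points, dtype=float) @ self.matrix.T


def centroid(points) -> np.ndarray:
    """Component-wise arithmetic mean of a non-empty collection of 3-vectors."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("centroid of an empty point collection is undefined")
    return pts.mean(axis=0)


def chamber_axis(av_centroid, chamber_points) -> np.ndarray:
    """Unit vector from the AV-canal centroid to the chamber centroid.

    Raises :class:`DegenerateAxisError` if the two centroids coincide
    (within 1e-6 µm).
    """
    av = np.asarray(av_centroid, dtype=float)
    d = centroid(chamber_points) - av
    n = np.linalg.norm(d)
    if n <= 1e-6:
        raise DegenerateAxisError(
            "chamber centroid coincides with the AV-canal centroid"
        )
    return d / n


def minimal_rotation(u, v) -> RigidRotation:
    """The smallest-angle rotation mapping unit vector ``u`` onto ``v``.

    The rotation axis is proportional to ``u × v``; the angle equals
    ``arccos(u·v)``. Antiparallel inputs (``u ≈ −v``) need a 180° rotation
    whose axis is not determined by the cross product; the documented
    tie-break uses the component of global +z perpendicular to ``u``, or
    global +x when ``u`` is parallel to z.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c = np.cross(u, v)
    s = np.linalg.norm(c)
    d = float(np.clip(np.dot(u, v), -1.0, 1.0))
    if s < _UNIT_TOL:
        if d > 0:  # already aligned
            return RigidRotation(axis=np.array([0.0, 0.0, 1.0]), angle_deg=0.0)
        # antiparallel: 180° about the documented fallback axis
        z = np.array([0.0, 0.0, 1.0])
        perp = z - np.dot(z, u) * u
        n = np.linalg.norm(perp)
        axis = perp / n if n >= _UNIT_TOL else np.array([1.0, 0.0, 0.0])
        return RigidRotation(axis=axis, angle_deg=180.0)
    angle = np.degrees(np.arctan2(s, d))
    return RigidRotation(axis=c / s, angle_deg=float(angle))


def signed_angle_about_axis(p_prev, p_next, axis, eps_proj: float = EPS_PROJ_UM) -> float:
    """Signed rotation angle (degrees) from ``p_prev`` to ``p_next`` about ``axis``.

    Both points are projected onto the plane through the origin
    perpendicular to ``axis`` (the axis passes through the origin — i.e.
    positions must be expressed in the hinge-rooted frame); the returned
    angle is ``atan2((q̂_prev × q̂_next)·axis, q̂_prev·q̂_next)`` in
    (−180, 180], positive counterclockwise seen from the axis tip.

    Raises :class:`UndefinedAngleError` when either projection is shorter
    than ``eps_proj`` (the point lies essentially on the axis); callers
    skip and log that cell/frame pair.
    """
    a = np.asarray(axis, dtype=float)
    p0 = np.asarray(p_prev, dtype=float)
    p1 = np.asarray(p_next, dtype=float)
    q0 = p0 - np.dot(p0, a) * a
    q1 = p1 - np.dot(p1, a) * a
    n0, n1 = np.linalg.norm(q0), np.linalg.norm(q1)
    if n0 <= eps_proj or n1 <= eps_proj:
        raise UndefinedAngleError(
            f"perpendicular offset below {eps_proj} um; angle undefined"
        )
    q0, q1 = q0 / n0, q1 / n1
    ang = np.degrees(np.arctan2(np.dot(np.cross(q0, q1), a), np.dot(q0, q1)))
    # map -180 exactly to +180 so the range is (-180, 180]
    return float(ang if ang != -180.0 else 180.0)


def signed_angles_about_axis(
    prev: np.ndarray, next_: np.ndarray, axis, eps_proj: float = EPS_PROJ_UM
) -> np.ndarray:
    """Vectorized :func:`signed_angle_about_axis` over (n, 3) point arrays.

    Returns an array of angles with NaN where the angle is undefined
    (either projection below ``eps_proj``) instead of raising.
    """
    a = np.asarray(axis, dtype=float)
    p0 = np.atleast_2d(np.asarray(prev, dtype=float))
    p1 = np.atleast_2d(np.asarray(next_, dtype=float))
    q0 = p0 - np.outer(p0 @ a, a)
    q1 = p1 - np.outer(p1 @ a, a)
    n0 = np.linalg.norm(q0, axis=1)
    n1 = np.linalg.norm(q1, axis=1)
    ok = (n0 > eps_proj) & (n1 > eps_proj)
    out = np.full(len(p0), np.nan)
    if ok.any():
        u0 = q0[ok] / n0[ok, None]
        u1 = q1[ok] / n1[ok, None]
        cross = np.cross(u0, u1) @ a
        dot = np.einsum("ij,ij->i", u0, u1)
        ang = np.degrees(np.arctan2(cross, dot))
        ang[ang == -180.0] = 180.0
        out[ok] = ang
    return out
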