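"""Shape descriptors: cell roundness, boundary straightness, AV-canal angle.

Secondary measurements accompanying the track analysis:

* **roundness** of a 2D cell outline — the Fiji-style descriptor
  ``4·area / (π·major_axis²)``, where the major axis is that of the
  polygon's best-fit (second-moment) ellipse. A circle scores 1, an
  ellipse with semi-axes a ≥ b scores b/a. The classic isoperimetric
  *circularity* ``4π·area / perimeter²`` is available behind a switch.
* **straightness index** of a 3D boundary polyline — chord length from
  start to end divided by the arc length measured along the path; 1 for a
  straight border, → 0 for a closed loop.
* **AV-canal angle** — the angle between the two chamber axes after
  projection into a viewing plane (ventral view), in [0, 180]°; 180° is an
  unlooped straight tube.

Polygons are carried as shapely geometry for validity/area/perimeter; the
second-moment ellipse fit is computed from exact shoelace-type area
integrals of the polygon interior.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "Polygon2D",
    "Polyline3D",
    "roundness",
    "circularity",
    "straightness_index",
    "av_canal_angle",
]


class Polygon2D:
    """A closed, simple polygon in the plane (vertices in µm, ≥3, area > 0)."""

    def __init__(self, vertices) -> None:
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise ValueError("polygon needs >= 3 two-dimensional vertices")
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 3:
            raise ValueError("polygon needs >= 3 distinct vertices")
        shp = _ShapelyPolygon(v)
        if not shp.is_valid:
            raise ValueError("polygon is self-intersecting or otherwise invalid")
        if shp.area <= 0:
            raise ValueError("polygon has zero area")
        self.vertices = v
        self._shapely = shp

    @property
    def area(self) -> float:
        return float(self._shapely.area)

    @property
    def perimeter(self) -> float:
        return float(self._shapely.length)

    def second_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Centroid and 2×2 central second-moment (covariance) matrix of the
        uniformly-filled polygon interior, from exact boundary integrals."""
        v = self.vertices
        x, y = v[:, 0], v[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = 0.5 * cross.sum()                       # signed area
        cx = ((x + xn) * cross).sum() / (6.0 * a)
        cy = ((y + yn) * cross).sum() / (6.0 * a)
        # raw second moments about the origin, normalized by area
        ixx = ((y * y + y * yn + yn * yn) * cross).sum() / (12.0 * a)
        iyy = ((x * x + x * xn + xn * xn) * cross).sum() / (12.0 * a)
        ixy = ((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross).sum() / (24.0 * a)
        cov = np.array(
            [[iyy - cx * cx, ixy - cx * cy], [ixy - cx * cy, ixx - cy * cy]]
        )
        return np.array([cx, cy]), cov


class Polyline3D:
    """An open polyline in 3D (vertices in µm, ≥2, consecutive distinct)."""

    def __init__(self, vertices) -> None:
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or len(v) < 2:
            raise ValueError("polyline needs >= 2 three-dimensional vertices")
        seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
        if (seg == 0).any():
            raise ValueError("consecutive polyline vertices must be distinct")
        self.vertices = v
        self._segment_lengths = seg

    @property
    def arc_length(self) -> float:
        return float(self._segment_lengths.sum())

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(self.vertices[-1] - self.vertices[0]))


def roundness(polygon: Polygon2D) -> float:
    """Fiji-style roundness: 4·area / (π·major_axis²) in (0, 1].

    The major axis is the full major-axis length of the ellipse with the
    same area-normalized second moments as the polygon interior: for
    covariance eigenvalues λ₁ ≥ λ₂ the semi-major axis is 2√λ₁. For an
    exact ellipse with semi-axes a ≥ b this reduces to b/a.
    """
    _, cov = polygon.second_moments()
    lam = np.linalg.eigvalsh(cov)
    major = 2.0 * (2.0 * np.sqrt(lam[-1]))   # full major-axis length
    if major <= 0:
        raise ValueError("degenerate polygon: zero major axis")
    return float(4.0 * polygon.area / (np.pi * major * major))


def circularity(polygon: Polygon2D) -> float:
    """Isoperimetric circularity 4π·area / perimeter² in (0, 1]."""
    return float(4.0 * np.pi * polygon.area / polygon.perimeter**2)


def straightness_index(border: Polyline3D) -> float:
    """Chord-to-arc ratio of a boundary polyline, in [0, 1].

    1 means the border is a straight line; values below 1 indicate a
    tortuous (e.g. anisotropically grown) boundary.
    """
    arc = border.arc_length
    if arc <= 0:
        raise ValueError("zero-length border")
    return min(border.chord_length / arc, 1.0)


def av_canal_angle(ventricle_axis, atrium_axis, view_normal=(0.0, 0.0, 1.0)) -> float:
    """Angle (degrees, [0, 180]) between the chamber axes in a viewing plane.

    Both axes are projected onto the plane perpendicular to ``view_normal``
    (default: ventral view down the z axis) and the unsigned angle between
    the projections is returned. 180° corresponds to an unlooped straight
    tube, smaller angles to progressively tighter looping.
    """
    n = np.asarray(view_normal, dtype=float)
    n = n / np.linalg.norm(n)
    out = []
    for axis in (ventricle_axis, atrium_axis):
        a = np.asarray(axis, dtype=float)
        q = a - np.dot(a, n) * n
        qn = np.linalg.norm(q)
        if qn <= 1e-6:
            raise ValueError("axis is (numerically) parallel to the view normal")
        out.append(q / qn)
    cosang = float(np.clip(np.dot(out[0], out[1]), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))
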