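"""Planar contour geometry, registration and section-plane arithmetic.

All lengths are micrometres; rostrocaudal (Bregma) positions are millimetres
and converted to micrometres only where serial sections are counted.

The registration convention is image-like (y grows downward on screen), so
the "superior left" anchor of a contour is the (min x, min y) corner of its
bounding box.  Rendering code labels the y axis accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import NamedTuple, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon


class GeometryError(ValueError):
    """Degenerate or self-intersecting polygon input."""


def as_points(points: Sequence | np.ndarray) -> np.ndarray:
    """Coerce input to a finite (n, 2) float array of x, y coordinates."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 2)
    if pts.ndim == 1:
        pts = pts.reshape(1, -1)
    if pts.ndim != 2 or pts.shape[1] < 2:
        raise ValueError("points must be an (n, 2) array-like of x, y")
    pts = np.array(pts[:, :2], dtype=float)
    if not np.isfinite(pts).all():
        raise ValueError("non-finite coordinates in point set")
    return pts


@dataclass(frozen=True)
class Contour:
    """Closed simple polygon tracing one anatomical region on one plane.

    Parameters
    ----------
    vertices
        Ordered (x, y) pairs in micrometres.  A repeated closing vertex is
        accepted and stripped; the ring is implicitly closed.
    label
        Region name, e.g. ``"LAd"``, ``"PL"``, ``"IL"``.
    bregma_mm
        Signed rostrocaudal plane coordinate in millimetres.
    """

    vertices: np.ndarray
    label: str = ""
    bregma_mm: float | None = None

    def __post_init__(self) -> None:
        pts = as_points(self.vertices)
        if len(pts) >= 4 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise GeometryError("contour needs at least 3 distinct vertices")
        dup = np.all(pts == np.roll(pts, -1, axis=0), axis=1)
        if dup.any():
            raise GeometryError("consecutive duplicate vertices in contour")
        poly = Polygon(pts)
        if not poly.is_valid or not poly.is_simple:
            raise GeometryError("contour polygon is self-intersecting")
        if poly.area <= 0.0:
            raise GeometryError("contour encloses zero area (collinear vertices?)")
        object.__setattr__(self, "vertices", pts)

    @cached_property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(min x, min y, max x, max y) of the vertex set, in micrometres."""
        xs, ys = self.vertices[:, 0], self.vertices[:, 1]
        return float(xs.min()), float(ys.min()), float(xs.max()), float(ys.max())

    @property
    def anchor(self) -> tuple[float, float]:
        """Superior-left (min x, min y) corner of the bounding box."""
        xmin, ymin, _, _ = self.bounds
        return xmin, ymin

    def translated(self, dx: float, dy: float) -> "Contour":
        return Contour(self.vertices + np.array([dx, dy]),
                       label=self.label, bregma_mm=self.bregma_mm)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Contour):
            return NotImplemented
        return (np.array_equal(self.vertices, other.vertices)
                and self.label == other.label
                and self.bregma_mm == other.bregma_mm)


@dataclass(frozen=True)
class AnchorPoint:
    """A named reference point in the shared micrometre frame."""

    x: float
    y: float
    description: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("anchor coordinates must be finite")


def polygon_area(contour: Contour) -> float:
    """Absolute shoelace area of the contour in square micrometres.

    Independent of vertex orientation and of the starting vertex.
    """
    pts = contour.vertices
    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area <= 0.0:
        raise GeometryError("degenerate polygon: zero area")
    return float(area)


def max_feret(contour: Contour) -> float:
    """Maximum Feret (caliper) diameter of the contour in micrometres.

    Equal to the maximum pairwise distance over convex-hull vertices; the
    hull is small for traced contours so the O(V^2) scan is exact and cheap.
    """
    hull = contour.polygon.convex_hull
    coords = np.asarray(hull.exterior.coords)[:-1]
    if len(coords) < 2:
        raise GeometryError("max Feret undefined for fewer than 2 distinct vertices")
    diff = coords[:, None, :] - coords[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=-1)).max())


def register_to_anchor(
    points: Sequence | np.ndarray, contour: Contour
) -> tuple[np.ndarray, Contour]:
    """Translate contour and points so the superior-left bbox corner is (0, 0).

    The identical rigid translation is applied to both, preserving all
    relative geometry.  An empty point list registers the contour alone.
    Idempotent: an already registered contour maps to itself.
    """
    pts = as_points(points)
    ax, ay = contour.anchor
    shifted = pts - np.array([ax, ay]) if len(pts) else pts
    return shifted, contour.translated(-ax, -ay)


def rotate_points(
    points: Sequence | np.ndarray,
    angle_degrees: float,
    pivot: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Rotate points counter-clockwise by ``angle_degrees`` about ``pivot``."""
    if not np.isfinite(angle_degrees):
        raise ValueError("rotation angle must be finite")
    px, py = float(pivot[0]), float(pivot[1])
    if not (np.isfinite(px) and np.isfinite(py)):
        raise ValueError("pivot must be finite")
    pts = as_points(points)
    theta = np.deg2rad(angle_degrees)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    return (pts - (px, py)) @ rot.T + (px, py)


class SectionSpan(NamedTuple):
    """Number of serial sections spanning a Bregma interval."""

    n_sections: int
    exact: bool  # False when the interval is not an exact multiple of thickness


def sections_between(
    bregma_a_mm: float, bregma_b_mm: float, thickness_um: float
) -> SectionSpan:
    """Count sections of ``thickness_um`` between two Bregma planes (mm).

    Rounds to the nearest integer and flags (rather than rejects) intervals
    that are not exact multiples of the cutting thickness, since real
    cutting thickness varies slightly.
    """
    if not np.isfinite([bregma_a_mm, bregma_b_mm, thickness_um]).all():
        raise ValueError("non-finite input")
    if thickness_um <= 0:
        raise ValueError("section thickness must be positive")
    distance_um = abs(bregma_a_mm - bregma_b_mm) * 1000.0
    ratio = distance_um / thickness_um
    n = int(round(ratio))
    exact = abs(ratio - n) < 1e-6
    return SectionSpan(n, exact)


def points_in_contour(points: Sequence | np.ndarray, contour: Contour) -> np.ndarray:
    """Boolean containment per point; boundary points count as inside.

    Counting the boundary as inside prevents silent marker loss for markers
    placed exactly on a traced edge.
    """
    pts = as_points(points)
    if len(pts) == 0:
        return np.zeros(0, dtype=bool)
    geoms = shapely.points(pts[:, 0], pts[:, 1])
    return shapely.covers(contour.polygon, geoms)


def point_in_contour(point: Sequence, contour: Contour) -> bool:
    """Scalar convenience wrapper around :func:`points_in_contour`."""
    return bool(points_in_contour(np.asarray(point, dtype=float).reshape(1, 2),
                                  contour)[0])
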