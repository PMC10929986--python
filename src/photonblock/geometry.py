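"""Projective polygon geometry for divergent-beam block design.

Everything in the block pipeline reduces to four primitives on planar
polygons expressed in a point-source beam coordinate system (beam axis +Z
from source toward patient, X/Y the collimator axes, origin on the central
axis): the shoelace area, central projection between planes by similar
triangles, the frustum volume of a divergence-lofted solid, and polygon
offsetting for wall generation.

Units: polygon vertices are millimetres in-plane; plane distances from the
source are centimetres (the field's convention: shapes are designed at the
100 cm reference plane and projected to the tray plane).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon as _ShPolygon

#: Coordinates are snapped to a 1 um grid before validity tests; treatment
#: planning system exports carry float noise well below this scale.
SNAP_GRID_MM = 1e-3


class DegeneratePolygonError(ValueError):
    """Polygon has fewer than three distinct vertices or zero area."""


class SelfIntersectionError(ValueError):
    """Polygon boundary crosses itself."""


def _snap(vertices: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(vertices, dtype=float) / SNAP_GRID_MM) * SNAP_GRID_MM


@dataclass(frozen=True)
class Polygon2D:
    """A simple planar polygon at a stated distance from the beam source.

    Parameters
    ----------
    vertices
        Ordered ``(n, 2)`` array of in-plane points, millimetres.  Closure
        is implicit: vertex ``n-1`` connects back to vertex ``0``.
    plane_z_cm
        Distance from the point source to the plane containing the polygon,
        centimetres; must be positive.
    """

    vertices: np.ndarray
    plane_z_cm: float = 100.0

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2:
            raise DegeneratePolygonError(
                f"vertices must be (n, 2), got shape {verts.shape}"
            )
        # drop sub-um consecutive duplicates, but store unmodified coordinates
        snapped = _snap(verts)
        keep = np.any(snapped != np.roll(snapped, 1, axis=0), axis=1)
        verts = verts[keep]
        if len(verts) < 3:
            raise DegeneratePolygonError(
                f"polygon needs >= 3 distinct vertices, got {len(verts)}"
            )
        if self.plane_z_cm <= 0:
            raise ValueError(f"plane_z_cm must be > 0, got {self.plane_z_cm}")
        # validity is judged on the um-snapped copy: float noise from TPS
        # exports must not flag a clean outline, and sub-um slivers are
        # treated as genuine self-intersections
        sh = _ShPolygon(_snap(verts))
        if not sh.is_valid or sh.area == 0.0:
            raise SelfIntersectionError(
                "polygon is self-intersecting or degenerate: "
                + shapely.is_valid_reason(sh)
            )
        object.__setattr__(self, "vertices", verts)

    @property
    def n(self) -> int:
        return len(self.vertices)

    @property
    def signed_area_mm2(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def is_clockwise(self) -> bool:
        # In a right-handed XY frame a clockwise loop has negative signed area.
        return self.signed_area_mm2 < 0

    def reversed(self) -> "Polygon2D":
        return Polygon2D(self.vertices[::-1].copy(), self.plane_z_cm)

    def to_shapely(self) -> _ShPolygon:
        return _ShPolygon(self.vertices)

    def perimeter_mm(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


def shoelace_area(poly: Polygon2D) -> float:
    """Unsigned polygon area by the shoelace formula, mm^2.

    ``|1/2 * sum_i (x_i * y_{i+1} - x_{i+1} * y_i)|`` with cyclic indexing;
    winding-invariant by the absolute value.
    """
    return abs(poly.signed_area_mm2)


def project_polygon(poly: Polygon2D, target_z_cm: float) -> Polygon2D:
    """Project a polygon to another plane through the point source.

    Each vertex scales by ``target_z_cm / plane_z_cm`` about the central
    axis (similar triangles), so areas scale by the square of that ratio.
    """
    if target_z_cm <= 0:
        raise ValueError(f"target_z_cm must be > 0, got {target_z_cm}")
    s = target_z_cm / poly.plane_z_cm
    return Polygon2D(poly.vertices * s, target_z_cm)


@dataclass(frozen=True)
class FrustumSpec:
    """Two parallel cross-section areas (mm^2) a height ``h`` (mm) apart."""

    area_top_mm2: float
    area_bottom_mm2: float
    height_mm: float

    def __post_init__(self) -> None:
        if self.area_top_mm2 < 0 or self.area_bottom_mm2 < 0:
            raise ValueError("frustum areas must be >= 0")
        if self.height_mm <= 0:
            raise ValueError(f"frustum height must be > 0, got {self.height_mm}")


def frustum_volume(spec: FrustumSpec) -> float:
    """Frustum volume ``(h/3) * (Atop + sqrt(Atop*Abottom) + Abottom)``, mm^3.

    Exact for any solid whose cross-sections are similar figures scaled
    linearly between the two faces — which is precisely the shape a
    point-source divergence loft produces.  Symmetric in top/bottom;
    degenerates to a prism (``Atop == Abottom``) and a pyramid
    (``Atop == 0``).
    """
    a, b, h = spec.area_top_mm2, spec.area_bottom_mm2, spec.height_mm
    return (h / 3.0) * (a + math.sqrt(a * b) + b)


def offset_polygon(
    poly: Polygon2D,
    delta_mm: float,
    *,
    mitre_limit: float = 5.0,
) -> Polygon2D | None:
    """Offset a polygon boundary outward (+) or inward (-) by ``delta_mm``.

    Joins are mitred, falling back to a bevel where the mitre would exceed
    ``mitre_limit`` times the offset (printable walls need bounded spike
    length at sharp vertices).  An inward offset that annihilates the
    polygon returns ``None``; an offset that splits the polygon into
    several pieces raises, since a wall boundary must stay one loop.
    """
    if delta_mm == 0.0:
        return poly
    sh = poly.to_shapely()
    out = sh.buffer(
        delta_mm,
        join_style="mitre",
        mitre_limit=mitre_limit,
        quad_segs=1,
    )
    if out.is_empty:
        return None
    if out.geom_type == "MultiPolygon":
        raise SelfIntersectionError(
            f"offset by {delta_mm} mm splits the polygon into "
            f"{len(out.geoms)} pieces near {[g.centroid.coords[0] for g in out.geoms]}"
        )
    verts = np.asarray(out.exterior.coords[:-1], dtype=float)
    result = Polygon2D(verts, poly.plane_z_cm)
    if result.is_clockwise != poly.is_clockwise:
        result = result.reversed()
    return result
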