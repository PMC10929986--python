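"""Printable block-shell construction: divergent BB cavities, baseplate,
holes — assembled into a watertight triangle mesh and written as binary STL.

The assembly has two kinds of bodies, both built analytically (no CSG):

* one *tub* per island block — the 1.2 mm wall shell around a divergence-
  lofted cavity.  Its surface is: outer frustum side walls, an outer top
  cap (source side), inner cavity side walls, an inner cavity ceiling, and
  a flat bottom annulus where the tub meets the baseplate.  A single
  closed genus-0 surface whose volume is exactly (outer frustum) − (cavity
  frustum);
* the baseplate — a prismatic extrusion of the jaw rectangle projected to
  the tray plane plus a 1 cm margin (also projected), with bolt holes,
  one fill hole per cavity, and an optional checkerboard hole lattice.

The bodies abut but never overlap, so the concatenated mesh is watertight
and its volume is the exact sum of component volumes.  Coordinates are mm;
+Z runs from source toward patient, so "up" (toward the source) is −Z and
the cavity's small face is its top.
"""

from __future__ import annotations

import struct
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh
from pydantic import BaseModel, ConfigDict, model_validator
from shapely.geometry import Point

from ._triangulate import triangulate_polygon
from .ciao import ciao_polygon
from .geometry import (
    Polygon2D,
    frustum_volume,
    FrustumSpec,
    offset_polygon,
    project_polygon,
    shoelace_area,
)
from .plan import BeamGeometry, BlockOutline, FieldDefinition


class ShellBuildError(ValueError):
    """Geometry cannot be realized as a printable shell."""


class ClearanceWarning(UserWarning):
    """Shell stack is taller than the available collimator clearance."""


class PlugSpec(BaseModel):
    """Cylindrical plug sealing a fill hole (printed separately)."""

    model_config = ConfigDict(frozen=True)

    diameter_mm: float = 11.6
    height_mm: float = 10.0


class Checkerboard(BaseModel):
    model_config = ConfigDict(frozen=True)

    enabled: bool = False
    pitch_mm: float = 20.0
    hole_mm: float = 6.0


class ShellDesignSpec(BaseModel):
    """Parametric description of the printable shell assembly.

    Defaults are the validated print design: 1.2 mm walls, 8 cm BB
    interior, 1 cm baseplate margin beyond the jaws (at the reference
    plane), 1.6 mm PLA baseplate, 7.75 mm bolt holes matching the vendor
    tray.  ``tray_plane_z_cm`` overrides the field's beam-geometry tray
    distance when set.
    """

    model_config = ConfigDict(frozen=True)

    wall_thickness_mm: float = 1.2
    interior_height_cm: float = 8.0
    baseplate_margin_cm: float = 1.0
    baseplate_thickness_mm: float = 1.6
    fill_hole_diameter_mm: float = 12.0
    plug: PlugSpec = PlugSpec()
    bolt_hole_diameter_mm: float = 7.75
    bolt_positions_mm: Optional[tuple[tuple[float, float], ...]] = None
    bolt_inset_mm: float = 9.0
    checkerboard: Checkerboard = Checkerboard()
    tray_plane_z_cm: Optional[float] = None
    circle_segments: int = 24

    @model_validator(mode="after")
    def _check(self) -> "ShellDesignSpec":
        if self.wall_thickness_mm <= 0:
            raise ValueError("wall thickness must be > 0")
        if self.interior_height_cm <= 0:
            raise ValueError("interior height must be > 0")
        return self

    def tray_z_cm(self, geom: BeamGeometry) -> float:
        return self.tray_plane_z_cm or geom.source_to_tray_cm


def _circle(cx: float, cy: float, r: float, n: int) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.c_[cx + r * np.cos(t), cy + r * np.sin(t)]


def _ccw(verts: np.ndarray) -> np.ndarray:
    x, y = verts[:, 0], verts[:, 1]
    if 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) < 0:
        return verts[::-1]
    return verts


def _ring3(verts2: np.ndarray, z_mm: float) -> np.ndarray:
    return np.c_[verts2, np.full(len(verts2), z_mm)]


def _loft_faces(offset_a: int, offset_b: int, n: int) -> list[tuple[int, int, int]]:
    """Quad band between two rings of n corresponding vertices, as triangles."""
    faces = []
    for i in range(n):
        j = (i + 1) % n
        faces.append((offset_a + i, offset_a + j, offset_b + j))
        faces.append((offset_a + i, offset_b + j, offset_b + i))
    return faces


def _finalize(vertices: np.ndarray, faces: list) -> trimesh.Trimesh:
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces, dtype=np.int64),
                           process=True)
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _solid_between_rings(
    ring_pairs: list[tuple[np.ndarray, float, np.ndarray, float]],
    caps: list[tuple[np.ndarray, list[np.ndarray], float]],
) -> trimesh.Trimesh:
    """Assemble a closed solid from loft bands and planar (holed) caps.

    ``ring_pairs``: (verts2_a, z_a, verts2_b, z_b) wall bands with vertex
    correspondence.  ``caps``: (outer2, holes2, z) planar caps.  Face
    orientation is normalized afterwards by :func:`_finalize`; duplicate
    vertices between bands and caps are merged by trimesh processing.
    """
    all_v: list[np.ndarray] = []
    all_f: list[tuple[int, int, int]] = []
    for a2, za, b2, zb in ring_pairs:
        n = len(a2)
        base = len(all_v)
        all_v.extend(_ring3(a2, za))
        all_v.extend(_ring3(b2, zb))
        all_f.extend(_loft_faces(base, base + n, n))
    for outer2, holes2, z in caps:
        cv, cf = triangulate_polygon(outer2, list(holes2))
        base = len(all_v)
        all_v.extend(_ring3(cv, z))
        all_f.extend((base + a, base + b, base + c) for a, b, c in cf)
    return _finalize(np.asarray(all_v), all_f)


# ---------------------------------------------------------------------------
# Cavity frusta


def _projected_outline(block: BlockOutline, ref_z_cm: float, target_z_cm: float) -> Polygon2D:
    poly = block.polygon(ref_z_cm)
    return project_polygon(poly, target_z_cm)


def build_cavity(
    block: BlockOutline, geom: BeamGeometry, spec: ShellDesignSpec
) -> tuple[trimesh.Trimesh, trimesh.Trimesh]:
    """Closed inner (BB cavity) and outer (cavity + walls) frustum solids.

    The inner solid lofts the block outline, projected through the source,
    between the tray plane and the plane one interior-height closer to the
    source.  The outer solid lofts the outward wall offset of the tray-
    plane outline between planes extended by one wall thickness on both
    ends.  The inner solid is strictly inside the outer one.
    """
    if block.polygon().n < 3:
        raise ShellBuildError("block outline is degenerate")
    tray = spec.tray_z_cm(geom)
    z_bot = tray
    z_top = tray - spec.interior_height_cm
    if z_top <= 0:
        raise ShellBuildError("interior height exceeds source-tray distance")
    ref = geom.source_to_reference_cm

    inner_bot = _projected_outline(block, ref, z_bot)
    inner = _frustum_solid(inner_bot, z_top, z_bot)

    wall_cm = spec.wall_thickness_mm / 10.0
    outer_bot = offset_polygon(inner_bot, spec.wall_thickness_mm)
    if outer_bot is None:
        raise ShellBuildError(
            f"block {block.label!r} too small for a "
            f"{spec.wall_thickness_mm} mm wall offset"
        )
    outer = _frustum_solid(outer_bot, z_top - wall_cm, z_bot + wall_cm)
    return inner, outer


def _frustum_solid(outline_at_own_plane: Polygon2D, z_near_cm: float,
                   z_far_cm: float) -> trimesh.Trimesh:
    """Closed divergence-lofted solid between two planes."""
    near = project_polygon(outline_at_own_plane, z_near_cm)
    far = project_polygon(outline_at_own_plane, z_far_cm)
    a2 = _ccw(near.vertices)
    b2 = project_polygon(Polygon2D(a2, z_near_cm), z_far_cm).vertices
    return _solid_between_rings(
        ring_pairs=[(a2, z_near_cm * 10.0, b2, z_far_cm * 10.0)],
        caps=[(a2, [], z_near_cm * 10.0), (b2, [], z_far_cm * 10.0)],
    )


def _tub_solid(block: BlockOutline, geom: BeamGeometry,
               spec: ShellDesignSpec) -> trimesh.Trimesh:
    """The printable wall shell around one cavity: closed, cavity open
    toward the baseplate (sealed by it in the assembly)."""
    tray = spec.tray_z_cm(geom)
    ref = geom.source_to_reference_cm
    z_bot = tray
    z_top = tray - spec.interior_height_cm
    wall_cm = spec.wall_thickness_mm / 10.0
    z_top_out = z_top - wall_cm

    inner_bot = _ccw(_projected_outline(block, ref, z_bot).vertices)
    outer_poly = offset_polygon(Polygon2D(inner_bot, z_bot), spec.wall_thickness_mm)
    if outer_poly is None:
        raise ShellBuildError(
            f"block {block.label!r} too small for a "
            f"{spec.wall_thickness_mm} mm wall offset"
        )
    outer_bot = _ccw(outer_poly.vertices)

    scale_in = z_top / z_bot
    scale_out = z_top_out / z_bot
    inner_top = inner_bot * scale_in
    outer_top = outer_bot * scale_out

    return _solid_between_rings(
        ring_pairs=[
            (outer_top, z_top_out * 10.0, outer_bot, z_bot * 10.0),  # outer walls
            (inner_top, z_top * 10.0, inner_bot, z_bot * 10.0),      # cavity walls
        ],
        caps=[
            (outer_top, [], z_top_out * 10.0),          # top (source side)
            (inner_top, [], z_top * 10.0),              # cavity ceiling
            (outer_bot, [inner_bot], z_bot * 10.0),     # bottom annulus
        ],
    )


def tub_volume_mm3(block: BlockOutline, geom: BeamGeometry,
                   spec: ShellDesignSpec) -> float:
    """Closed-form wall-material volume of one tub (outer − cavity)."""
    tray = spec.tray_z_cm(geom)
    ref = geom.source_to_reference_cm
    z_bot, z_top = tray, tray - spec.interior_height_cm
    wall_cm = spec.wall_thickness_mm / 10.0
    inner_bot = _projected_outline(block, ref, z_bot)
    outer_bot = offset_polygon(inner_bot, spec.wall_thickness_mm)
    a_in_bot = shoelace_area(inner_bot)
    a_in_top = a_in_bot * (z_top / z_bot) ** 2
    a_out_bot = shoelace_area(outer_bot)
    a_out_top = a_out_bot * ((z_top - wall_cm) / z_bot) ** 2
    v_out = frustum_volume(FrustumSpec(a_out_top, a_out_bot,
                                       (spec.interior_height_cm + wall_cm) * 10.0))
    v_in = frustum_volume(FrustumSpec(a_in_top, a_in_bot,
                                      spec.interior_height_cm * 10.0))
    return v_out - v_in


# ---------------------------------------------------------------------------
# Baseplate


def default_bolt_positions(field: FieldDefinition,
                           spec: ShellDesignSpec) -> tuple[tuple[float, float], ...]:
    """Four bolts at the projected jaw-rectangle corners, inset inward.

    Corners of a shaped field are shielded by the conformal MLC, so the
    inset corners sit outside the CIAO for typical blocked fields; the
    positions are validated (and overridable) regardless.
    """
    tray = spec.tray_z_cm(field.beam_geometry)
    s = tray / field.beam_geometry.source_to_reference_cm
    j = field.jaws
    d = spec.bolt_inset_mm
    return (
        (j.x1_mm * s + d, j.y1_mm * s + d),
        (j.x2_mm * s - d, j.y1_mm * s + d),
        (j.x2_mm * s - d, j.y2_mm * s - d),
        (j.x1_mm * s + d, j.y2_mm * s - d),
    )


def _plate_holes(field: FieldDefinition, spec: ShellDesignSpec) -> tuple[
        list[np.ndarray], list[tuple[float, float]]]:
    """All baseplate through-hole loops (tray-plane mm) and bolt centers."""
    geom = field.beam_geometry
    tray = spec.tray_z_cm(geom)
    s = tray / geom.source_to_reference_cm
    bolts = spec.bolt_positions_mm or default_bolt_positions(field, spec)

    if field.mlc is not None:
        ciao = ciao_polygon(field)
        for bx, by in bolts:
            if ciao.contains(Point(bx / s, by / s)):
                raise ShellBuildError(
                    f"bolt position ({bx:.1f}, {by:.1f}) mm at the tray plane "
                    "falls inside the CIAO; bolts must sit in shielded area"
                )
    else:
        warnings.warn(
            "no MLC state: bolt positions cannot be validated against the CIAO",
            UserWarning, stacklevel=2,
        )

    holes = [
        _circle(bx, by, spec.bolt_hole_diameter_mm / 2.0, spec.circle_segments)
        for bx, by in bolts
    ]
    # one fill hole per cavity, over the cavity footprint centroid
    for blk in field.blocks:
        foot = _projected_outline(blk, geom.source_to_reference_cm, tray)
        c = foot.to_shapely().centroid
        r = spec.fill_hole_diameter_mm / 2.0
        if not foot.to_shapely().contains(c.buffer(r)):
            raise ShellBuildError(
                f"fill hole (d={spec.fill_hole_diameter_mm} mm) does not fit "
                f"inside the cavity footprint of block {blk.label!r}"
            )
        holes.append(_circle(c.x, c.y, r, spec.circle_segments))
    return holes, list(bolts)


def _plate_footprint(field: FieldDefinition, spec: ShellDesignSpec) -> tuple[
        float, float, float, float]:
    geom = field.beam_geometry
    s = spec.tray_z_cm(geom) / geom.source_to_reference_cm
    m = spec.baseplate_margin_cm * 10.0 * s
    j = field.jaws
    return (j.x1_mm * s - m, j.x2_mm * s + m, j.y1_mm * s - m, j.y2_mm * s + m)


def _checkerboard_holes(field: FieldDefinition, spec: ShellDesignSpec,
                        existing: list[np.ndarray]) -> list[np.ndarray]:
    if not spec.checkerboard.enabled:
        return []
    x0, x1, y0, y1 = _plate_footprint(field, spec)
    pitch, half = spec.checkerboard.pitch_mm, spec.checkerboard.hole_mm / 2.0
    from shapely.geometry import Polygon as ShPoly
    keep_out = [ShPoly(h).buffer(1.0) for h in existing]
    tray = spec.tray_z_cm(field.beam_geometry)
    cavities = [
        _projected_outline(b, field.beam_geometry.source_to_reference_cm, tray)
        .to_shapely().buffer(spec.wall_thickness_mm + 1.0)
        for b in field.blocks
    ]
    out = []
    xs = np.arange(x0 + pitch, x1 - pitch / 2.0, pitch)
    ys = np.arange(y0 + pitch, y1 - pitch / 2.0, pitch)
    for i, cx in enumerate(xs):
        for jj, cy in enumerate(ys):
            if (i + jj) % 2:
                continue
            sq = np.array([
                [cx - half, cy - half], [cx + half, cy - half],
                [cx + half, cy + half], [cx - half, cy + half],
            ])
            sp = ShPoly(sq)
            if any(sp.intersects(k) for k in keep_out + cavities):
                continue
            if not (x0 + 1 < cx - half and cx + half < x1 - 1
                    and y0 + 1 < cy - half and cy + half < y1 - 1):
                continue
            out.append(sq)
    return out


def build_baseplate(field: FieldDefinition, spec: ShellDesignSpec) -> trimesh.Trimesh:
    """Prismatic baseplate at the tray plane with bolt, fill and optional
    checkerboard holes; footprint is the projected jaw rectangle plus the
    projected margin."""
    x0, x1, y0, y1 = _plate_footprint(field, spec)
    rect = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
    holes, _ = _plate_holes(field, spec)
    holes = holes + _checkerboard_holes(field, spec, holes)

    tray_mm = spec.tray_z_cm(field.beam_geometry) * 10.0
    z_lo, z_hi = tray_mm, tray_mm + spec.baseplate_thickness_mm
    ring_pairs = [(rect, z_lo, rect, z_hi)]
    for h in holes:
        ring_pairs.append((h, z_lo, h, z_hi))
    return _solid_between_rings(
        ring_pairs=ring_pairs,
        caps=[(rect, holes, z_lo), (rect, holes, z_hi)],
    )


def baseplate_volume_mm3(field: FieldDefinition, spec: ShellDesignSpec) -> float:
    """Closed-form plate volume (rectangle minus polygonal hole areas)."""
    x0, x1, y0, y1 = _plate_footprint(field, spec)
    holes, _ = _plate_holes(field, spec)
    holes = holes + _checkerboard_holes(field, spec, holes)
    area = (x1 - x0) * (y1 - y0)
    for h in holes:
        area -= shoelace_area(Polygon2D(h, 1.0))
    return area * spec.baseplate_thickness_mm


# ---------------------------------------------------------------------------
# Assembly and STL


def assemble_and_mesh(field: FieldDefinition, spec: ShellDesignSpec | None = None
                      ) -> trimesh.Trimesh:
    """Full shell assembly (baseplate + one tub per block) as one watertight
    multi-body mesh whose volume is the exact sum of its components."""
    spec = spec or ShellDesignSpec()
    if not field.blocks:
        raise ShellBuildError("field has no block outlines to build")

    stack_mm = spec.interior_height_cm * 10.0 + spec.wall_thickness_mm
    clearance_mm = field.beam_geometry.collimator_clearance_cm * 10.0
    if stack_mm > clearance_mm:
        warnings.warn(
            f"shell stack {stack_mm:.1f} mm exceeds collimator clearance "
            f"{clearance_mm:.1f} mm",
            ClearanceWarning, stacklevel=2,
        )

    bodies = [build_baseplate(field, spec)]
    expected = baseplate_volume_mm3(field, spec)
    for blk in field.blocks:
        bodies.append(_tub_solid(blk, field.beam_geometry, spec))
        expected += tub_volume_mm3(blk, field.beam_geometry, spec)

    mesh = trimesh.util.concatenate(bodies)
    if not mesh.is_watertight:
        bad = mesh.edges[trimesh.grouping.group_rows(
            mesh.edges_sorted, require_count=1)]
        raise ShellBuildError(
            f"assembled mesh is not watertight; {len(bad)} boundary edges, "
            f"first few: {bad[:5].tolist()}"
        )
    if abs(mesh.volume - expected) > 1e-3 * expected:
        raise ShellBuildError(
            f"mesh volume {mesh.volume:.1f} mm^3 deviates from predicted "
            f"{expected:.1f} mm^3 by more than 0.1%"
        )
    mesh.metadata["predicted_volume_mm3"] = expected
    return mesh


def build_plug(spec: ShellDesignSpec) -> trimesh.Trimesh:
    """The reusable cylindrical fill-hole plug."""
    return trimesh.creation.cylinder(
        radius=spec.plug.diameter_mm / 2.0,
        height=spec.plug.height_mm,
        sections=spec.circle_segments,
    )


def write_stl(mesh: trimesh.Trimesh, path: str | Path, *,
              patient_id: str = "", field_id: str = "",
              force: bool = False) -> None:
    """Write binary little-endian STL (units mm) with the patient and field
    identifiers embedded in the 80-byte header."""
    if not mesh.is_watertight and not force:
        raise ShellBuildError("refusing to write non-watertight mesh (use force=True)")
    header = f"photonblock patient={patient_id} field={field_id}".encode()[:80]
    header = header.ljust(80, b"\0")
    tris = mesh.triangles.astype("<f4")
    normals = mesh.face_normals.astype("<f4")
    n = len(tris)
    rec = np.zeros(n, dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)),
                             ("attr", "<u2")])
    rec["n"] = normals
    rec["v"] = tris
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(struct.pack("<I", n))
        fh.write(rec.tobytes())


def read_stl(path: str | Path) -> trimesh.Trimesh:
    """Load an STL back as a processed trimesh (vertex-merged)."""
    return trimesh.load_mesh(str(path), file_type="stl")
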