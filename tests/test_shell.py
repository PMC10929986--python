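"""Shell construction: cavities, baseplate, watertight assembly, STL."""

import numpy as np
import pytest
import trimesh

from photonblock.geometry import FrustumSpec, frustum_volume, shoelace_area
from photonblock.massqa import shell_volumes
from photonblock.plan import BlockOutline, FieldDefinition, JawSet
from photonblock.shell import (
    ClearanceWarning,
    ShellBuildError,
    ShellDesignSpec,
    assemble_and_mesh,
    build_baseplate,
    build_cavity,
    build_plug,
    default_bolt_positions,
    read_stl,
    write_stl,
)

SPEC = ShellDesignSpec()


def _circle_block(r=30.0, n=24, cx=0.0, cy=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return BlockOutline(
        vertices_mm=tuple(map(tuple, np.c_[cx + r * np.cos(t),
                                           cy + r * np.sin(t)])))


class TestCavity:
    def test_cavity_volume_matches_frustum_closed_form(self, round_field):
        """Mesh volume of the lofted cavity equals the frustum formula on
        the projected face areas to well within 0.5%."""
        geom = round_field.beam_geometry
        blk = _circle_block()
        inner, outer = build_cavity(blk, geom, SPEC)
        tray = SPEC.tray_z_cm(geom)
        poly = blk.polygon(geom.source_to_reference_cm)
        a_ref = shoelace_area(poly)
        a_bot = a_ref * (tray / 100.0) ** 2
        a_top = a_ref * ((tray - SPEC.interior_height_cm) / 100.0) ** 2
        expected = frustum_volume(FrustumSpec(a_top, a_bot,
                                              SPEC.interior_height_cm * 10))
        assert inner.volume == pytest.approx(expected, rel=5e-3)

    def test_inner_inside_outer(self, round_field):
        inner, outer = build_cavity(_circle_block(), round_field.beam_geometry,
                                    SPEC)
        assert inner.volume < outer.volume
        assert inner.is_watertight and outer.is_watertight

    def test_degenerate_outline_rejected(self):
        with pytest.raises(Exception):
            BlockOutline(vertices_mm=((0, 0), (10, 10)))

    def test_cavity_cross_section_respects_divergence(self, round_field):
        """Slicing the cavity at an intermediate plane recovers the outline
        scaled by z/z_ref."""
        geom = round_field.beam_geometry
        blk = _circle_block(r=30.0)
        inner, _ = build_cavity(blk, geom, SPEC)
        z_cm = 51.0  # between tray-8 and tray
        sec = inner.section(plane_origin=[0, 0, z_cm * 10.0],
                            plane_normal=[0, 0, 1])
        planar, _ = sec.to_2D()
        area = sum(abs(p.area) for p in planar.polygons_full)
        a_ref = shoelace_area(blk.polygon(geom.source_to_reference_cm))
        assert area == pytest.approx(a_ref * (z_cm / 100.0) ** 2, rel=1e-3)


class TestBaseplate:
    def test_footprint_projection_arithmetic(self, round_field):
        """Jaws +-100 mm at 100 cm with a 1 cm margin, projected to the
        55.4 cm tray plane, give a 121.88 mm square footprint."""
        f = FieldDefinition(
            patient_id="p", field_id="f",
            jaws=JawSet(x1_mm=-100, x2_mm=100, y1_mm=-100, y2_mm=100),
            blocks=(_circle_block(r=25),),
        )
        with pytest.warns(UserWarning, match="CIAO"):  # jaw-only field
            plate = build_baseplate(f, SPEC)
        ext = plate.bounds[1] - plate.bounds[0]
        assert ext[0] == pytest.approx(2 * 110 * 0.554, abs=1e-6)
        assert ext[1] == pytest.approx(2 * 110 * 0.554, abs=1e-6)
        assert ext[2] == pytest.approx(SPEC.baseplate_thickness_mm, abs=1e-9)

    def test_genus_equals_hole_count(self, field):
        plate = build_baseplate(field, SPEC)
        n_holes = 4 + len(field.blocks)  # bolts + one fill hole per cavity
        assert plate.is_watertight
        assert (2 - plate.euler_number) // 2 == n_holes

    def test_bolt_inside_ciao_rejected(self, round_field):
        centroid = np.mean(
            np.asarray(round_field.blocks[0].vertices_mm), axis=0)
        s = SPEC.tray_z_cm(round_field.beam_geometry) / 100.0
        spec = ShellDesignSpec(
            bolt_positions_mm=((centroid[0] * s, centroid[1] * s),) )
        with pytest.raises(ShellBuildError, match="CIAO"):
            build_baseplate(round_field, spec)

    def test_default_bolts_outside_ciao(self, field):
        # all archetypes must accept the default corner placement
        build_baseplate(field, SPEC)
        assert len(default_bolt_positions(field, SPEC)) == 4


class TestAssembly:
    def test_watertight_and_volume_agreement(self, field):
        """Divergence-theorem mesh volume equals the closed-form component
        sum within 0.1% for every archetype assembly."""
        mesh = assemble_and_mesh(field)
        assert mesh.is_watertight
        predicted = mesh.metadata["predicted_volume_mm3"]
        assert mesh.volume == pytest.approx(predicted, rel=1e-3)

    def test_two_blocks_two_cavities_one_plate(self, round_field):
        mesh = assemble_and_mesh(round_field)
        assert mesh.body_count == 3  # plate + two tubs

    def test_clearance_warning(self, round_field):
        tall = ShellDesignSpec(interior_height_cm=9.0)
        with pytest.warns(ClearanceWarning):
            assemble_and_mesh(round_field, tall)

    def test_no_blocks_rejected(self, round_field):
        empty = FieldDefinition(
            patient_id="p", field_id="f", jaws=round_field.jaws,
            mlc=round_field.mlc, blocks=())
        with pytest.raises(ShellBuildError, match="no block"):
            assemble_and_mesh(empty)


class TestSTL:
    def test_unit_cube_stl(self, tmp_path):
        cube = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        p = tmp_path / "cube.stl"
        write_stl(cube, p)
        raw = p.read_bytes()
        assert len(raw) == 80 + 4 + 12 * 50
        assert int.from_bytes(raw[80:84], "little") == 12
        re = read_stl(p)
        assert re.volume == pytest.approx(1.0)

    def test_header_embeds_identifiers(self, tmp_path, round_field):
        mesh = assemble_and_mesh(round_field)
        p = tmp_path / "shell.stl"
        write_stl(mesh, p, patient_id=round_field.patient_id,
                  field_id=round_field.field_id)
        header = p.read_bytes()[:80]
        assert round_field.patient_id.encode() in header
        assert int.from_bytes(p.read_bytes()[80:84], "little") == len(mesh.faces)

    def test_roundtrip_preserves_geometry(self, tmp_path, round_field):
        mesh = assemble_and_mesh(round_field)
        p = tmp_path / "shell.stl"
        write_stl(mesh, p)
        re = read_stl(p)
        assert re.is_watertight
        # float32 quantization only
        assert re.volume == pytest.approx(mesh.volume, rel=1e-4)

    def test_non_watertight_refused(self, tmp_path):
        tri = trimesh.Trimesh(vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
                              faces=[[0, 1, 2]])
        with pytest.raises(ShellBuildError):
            write_stl(tri, tmp_path / "bad.stl")
        write_stl(tri, tmp_path / "forced.stl", force=True)  # escape hatch


def test_plug_is_printable_cylinder():
    plug = build_plug(SPEC)
    assert plug.is_watertight
    r = SPEC.plug.diameter_mm / 2
    expected = np.pi * r**2 * SPEC.plug.height_mm
    assert plug.volume == pytest.approx(expected, rel=0.02)
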