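"""Synthetic treatment-field and portal-image fixtures.

Three patient archetypes drive end-to-end testing without any clinical
data: a nearly circular mantle-field lung shielding case, a pelvis-field
ovary shielding case, and a long, thin mantle-field lung shielding case.
Each yields a two-block field with archetype-appropriate jaws, a conformal
single-control-point MLC, and island-block outlines whose default cavity
volumes land in the realistic 50-92 cc per-shell range.

Portal images are simulated as ideal fluence (1.0 in the open CIAO,
``blocked_transmission`` under a block, 0.0 outside the CIAO), optionally
shifted/rotated/noised to emulate delivery and mounting error, blurred to
emulate penumbra, with seeded Gaussian detector noise.  Everything is
bit-for-bit reproducible per seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import numpy as np
import shapely
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.ndimage import gaussian_filter
from shapely import affinity
from shapely.geometry import Polygon as ShPolygon
from shapely.ops import unary_union

from .ciao import ciao_polygon
from .fieldqa import PortalImage, make_grid
from .plan import (
    BeamGeometry,
    BlockOutline,
    FieldDefinition,
    JawSet,
    MLCControlPoint,
    MLCState,
    write_plan_file,
)

Archetype = Literal["round_mantle_lungs", "pelvis_ovaries", "thin_mantle_lungs"]


class Perturbation(BaseModel):
    model_config = ConfigDict(frozen=True)

    shift_mm: tuple[float, float] = (0.0, 0.0)
    rotation_deg: float = 0.0
    edge_noise_mm: float = 0.0


class ImageSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    spacing_mm: float = 0.5
    blur_sigma_mm: float = 0.0
    noise_sd: float = 0.0
    blocked_transmission: float = 0.05

    @model_validator(mode="after")
    def _check(self) -> "ImageSpec":
        if not 0.0 < self.blocked_transmission < 1.0:
            raise ValueError("blocked transmission must be in (0, 1)")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be > 0")
        return self


class FixtureSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    archetype: Archetype
    rng_seed: int = 0
    perturbation: Perturbation = Perturbation()
    image: ImageSpec = ImageSpec()


# target block shapes: (jaws, [(cx, cy, rx, ry, tilt_deg), ...])
_ARCHETYPES = {
    # two quasi-circular lung blocks in a large mantle field
    "round_mantle_lungs": (
        (-150.0, 150.0, -150.0, 150.0),
        [(-70.0, 10.0, 33.0, 33.0, 0.0), (70.0, 10.0, 33.0, 33.0, 0.0)],
    ),
    # two small round ovary blocks in a pelvis field
    "pelvis_ovaries": (
        (-100.0, 100.0, -80.0, 80.0),
        [(-45.0, 0.0, 28.5, 28.5, 0.0), (45.0, 0.0, 28.5, 28.5, 0.0)],
    ),
    # two long, thin lung blocks in a tall mantle field
    "thin_mantle_lungs": (
        (-160.0, 160.0, -170.0, 170.0),
        [(-85.0, 0.0, 24.5, 54.0, 8.0), (85.0, 0.0, 24.5, 54.0, -8.0)],
    ),
}

_MLC_LEAF_WIDTH_MM = 10.0


def _block_vertices(cx: float, cy: float, rx: float, ry: float,
                    tilt_deg: float, rng: np.random.Generator,
                    n: int = 24) -> np.ndarray:
    """A gently irregular ellipse: low-order harmonic radial wobble keeps the
    outline organic without materially changing its area."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    wobble = 1.0 + 0.04 * np.sin(2 * t + p1) + 0.025 * np.sin(3 * t + p2)
    x = rx * wobble * np.cos(t)
    y = ry * wobble * np.sin(t)
    a = np.deg2rad(tilt_deg)
    xr = x * np.cos(a) - y * np.sin(a) + cx
    yr = x * np.sin(a) + y * np.cos(a) + cy
    return np.c_[xr, yr]


def _conformal_mlc(jaws: JawSet) -> MLCState:
    """Single-control-point MLC conforming loosely to the jaw opening:
    fully open at mid-field, pulled to 75% at the field's Y extremes, so
    the rectangle corners stay shielded (where mounting bolts go)."""
    half_w = max(abs(jaws.x1_mm), abs(jaws.x2_mm))
    half_h = max(abs(jaws.y1_mm), abs(jaws.y2_mm))
    lo = np.floor(jaws.y1_mm / _MLC_LEAF_WIDTH_MM) * _MLC_LEAF_WIDTH_MM
    hi = np.ceil(jaws.y2_mm / _MLC_LEAF_WIDTH_MM) * _MLC_LEAF_WIDTH_MM
    bounds = tuple(np.arange(lo, hi + _MLC_LEAF_WIDTH_MM / 2, _MLC_LEAF_WIDTH_MM))
    centers = (np.asarray(bounds[:-1]) + np.asarray(bounds[1:])) / 2.0
    opening = half_w * (0.75 + 0.25 * np.cos(np.pi * centers / (2.0 * half_h)))
    return MLCState(
        leaf_boundaries_mm=bounds,
        control_points=(
            MLCControlPoint(
                bank_a_mm=tuple(-opening), bank_b_mm=tuple(opening)
            ),
        ),
    )


def make_field(spec: FixtureSpec) -> FieldDefinition:
    """Deterministic two-block field for the requested archetype."""
    if spec.archetype not in _ARCHETYPES:
        raise ValueError(f"unknown archetype {spec.archetype!r}")
    (x1, x2, y1, y2), shapes = _ARCHETYPES[spec.archetype]
    rng = np.random.default_rng(spec.rng_seed)
    jaws = JawSet(x1_mm=x1, x2_mm=x2, y1_mm=y1, y2_mm=y2)
    blocks = tuple(
        BlockOutline(
            vertices_mm=tuple(map(tuple, _block_vertices(*shape, rng))),
            label=f"block{i + 1}",
        )
        for i, shape in enumerate(shapes)
    )
    return FieldDefinition(
        patient_id=f"SYN-{spec.archetype}",
        field_id=f"F{spec.rng_seed}",
        orientation_tag="PA" if spec.archetype == "thin_mantle_lungs" else "AP",
        beam_geometry=BeamGeometry(),
        jaws=jaws,
        mlc=_conformal_mlc(jaws),
        blocks=blocks,
    )


def _perturbed_block_union(field: FieldDefinition, spec: FixtureSpec,
                           rng: np.random.Generator):
    polys = []
    for blk in field.blocks:
        v = np.asarray(blk.vertices_mm, dtype=float)
        if spec.perturbation.edge_noise_mm > 0:
            v = v + rng.normal(0.0, spec.perturbation.edge_noise_mm, v.shape)
        polys.append(ShPolygon(v).buffer(0))
    geom = unary_union(polys)
    if spec.perturbation.rotation_deg:
        geom = affinity.rotate(geom, spec.perturbation.rotation_deg,
                               origin=(0.0, 0.0))
    dx, dy = spec.perturbation.shift_mm
    if dx or dy:
        geom = affinity.translate(geom, dx, dy)
    return geom


def make_portal_image(field: FieldDefinition, spec: FixtureSpec) -> PortalImage:
    """Simulated MV portal image of the delivered field at the reference
    plane: CIAO fluence with perturbed blocks, penumbra blur, seeded noise."""
    rng = np.random.default_rng(spec.rng_seed + 1)
    spacing = spec.image.spacing_mm
    origin, (ny, nx) = make_grid(field, spacing)
    xs = origin[0] + np.arange(nx) * spacing
    ys = origin[1] + np.arange(ny) * spacing
    gx, gy = np.meshgrid(xs, ys)

    ciao = ciao_polygon(field)
    open_field = shapely.contains_xy(ciao, gx.ravel(), gy.ravel()).reshape(ny, nx)
    blocked_geom = _perturbed_block_union(field, spec, rng)
    under_block = shapely.contains_xy(
        blocked_geom, gx.ravel(), gy.ravel()).reshape(ny, nx)

    fluence = np.where(open_field,
                       np.where(under_block, spec.image.blocked_transmission, 1.0),
                       0.0)
    if spec.image.blur_sigma_mm > 0:
        fluence = gaussian_filter(fluence, spec.image.blur_sigma_mm / spacing)
    if spec.image.noise_sd > 0:
        fluence = fluence + rng.normal(0.0, spec.image.noise_sd, fluence.shape)
    return PortalImage(pixels=fluence, spacing_mm=spacing,
                       imager_z_cm=field.beam_geometry.source_to_reference_cm,
                       origin_mm=origin,
                       reference_z_cm=field.beam_geometry.source_to_reference_cm)


def write_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write a plan file and a 16-bit PNG portal image pair to ``outdir``."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    field = make_field(spec)
    plan_path = outdir / f"{spec.archetype}_seed{spec.rng_seed}_plan.json"
    write_plan_file(field, plan_path)
    image = make_portal_image(field, spec)
    img = np.clip(image.pixels, 0.0, None)
    img16 = np.round(img / max(img.max(), 1e-12) * 65535.0).astype(np.uint16)
    png_path = outdir / f"{spec.archetype}_seed{spec.rng_seed}_portal.png"
    iio.imwrite(png_path, img16)
    return {"plan": plan_path, "image": png_path}


def make_rtplan_dataset(field: FieldDefinition):
    """A minimal synthetic DICOM RT Plan carrying one beam with the field's
    jaws, MLC and block outlines — for exercising the RT Plan importer.

    Synthetic: the dataset contains only the tags the importer reads and
    is not a clinically meaningful plan.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.RTPlanStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = pydicom.uid.RTPlanStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.PatientID = field.patient_id
    ds.PatientName = field.patient_id

    beam = Dataset()
    beam.BeamNumber = 1
    beam.BeamName = field.field_id

    mlc_dev = Dataset()
    mlc_dev.RTBeamLimitingDeviceType = "MLCX"
    assert field.mlc is not None
    mlc_dev.LeafPositionBoundaries = [float(b) for b in field.mlc.leaf_boundaries_mm]
    mlc_dev.NumberOfLeafJawPairs = field.mlc.n_pairs
    beam.BeamLimitingDeviceSequence = [mlc_dev]

    blocks = []
    for i, blk in enumerate(field.blocks):
        b = Dataset()
        b.BlockName = blk.label or f"BLOCK{i + 1}"
        b.BlockNumber = i + 1
        b.BlockNumberOfPoints = len(blk.vertices_mm)
        b.BlockData = [float(c) for xy in blk.vertices_mm for c in xy]
        blocks.append(b)
    beam.BlockSequence = blocks
    beam.NumberOfBlocks = len(blocks)

    cps = []
    for cp_state in field.mlc.control_points:
        cp = Dataset()
        cp.IsocenterPosition = [0.0, 0.0, 0.0]
        jx = Dataset()
        jx.RTBeamLimitingDeviceType = "ASYMX"
        jx.LeafJawPositions = [field.jaws.x1_mm, field.jaws.x2_mm]
        jy = Dataset()
        jy.RTBeamLimitingDeviceType = "ASYMY"
        jy.LeafJawPositions = [field.jaws.y1_mm, field.jaws.y2_mm]
        ml = Dataset()
        ml.RTBeamLimitingDeviceType = "MLCX"
        ml.LeafJawPositions = [float(v) for v in
                               cp_state.bank_a_mm + cp_state.bank_b_mm]
        cp.BeamLimitingDevicePositionSequence = [jx, jy, ml]
        cps.append(cp)
    beam.ControlPointSequence = cps
    beam.NumberOfControlPoints = len(cps)

    ds.BeamSequence = [beam]
    return ds
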