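"""Treatment-field data model and plan-file I/O.

A *plan file* is this package's neutral, versioned JSON interchange for the
handful of treatment-planning-system quantities the block pipeline needs:
jaw positions, MLC leaf positions (the source of the CIAO — the complete
irradiated area outline), and the ordered island-block outlines, all
expressed in millimetres at the 100 cm reference plane.  A DICOM RT Plan
importer populates the same model from the portable clinical equivalent.

All stored coordinates are mm at the reference plane; any divergence
scaling happens only in :mod:`photonblock.geometry`.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .geometry import Polygon2D

SCHEMA_VERSION = 1


class PlanSchemaError(ValueError):
    """Plan file is missing a required key or is structurally malformed."""


class PlanValidationError(ValueError):
    """Plan file parsed but violates a physical invariant."""


class BlockOutsideJawsWarning(UserWarning):
    """A block outline extends beyond the jaw rectangle.

    Not an error: Cerrobend practice deliberately extends blocks out of the
    field to make room for mounting screws, and imported legacy outlines
    may do the same.
    """


class BeamGeometry(BaseModel):
    """Point-source beam geometry distances, centimetres."""

    model_config = ConfigDict(frozen=True)

    source_to_reference_cm: float = 100.0
    source_to_tray_cm: float = 55.4
    collimator_clearance_cm: float = 8.2

    @model_validator(mode="after")
    def _check(self) -> "BeamGeometry":
        if min(self.source_to_reference_cm, self.source_to_tray_cm,
               self.collimator_clearance_cm) <= 0:
            raise ValueError("all beam geometry distances must be > 0")
        if self.source_to_tray_cm >= self.source_to_reference_cm:
            raise ValueError(
                f"source_to_tray_cm ({self.source_to_tray_cm}) must be < "
                f"source_to_reference_cm ({self.source_to_reference_cm})"
            )
        return self


class JawSet(BaseModel):
    """Signed jaw edge coordinates at the reference plane, millimetres."""

    model_config = ConfigDict(frozen=True)

    x1_mm: float
    x2_mm: float
    y1_mm: float
    y2_mm: float

    @model_validator(mode="after")
    def _check(self) -> "JawSet":
        if not self.x1_mm < self.x2_mm:
            raise ValueError(f"jaws require x1 < x2, got {self.x1_mm} >= {self.x2_mm}")
        if not self.y1_mm < self.y2_mm:
            raise ValueError(f"jaws require y1 < y2, got {self.y1_mm} >= {self.y2_mm}")
        return self

    @property
    def width_mm(self) -> float:
        return self.x2_mm - self.x1_mm

    @property
    def height_mm(self) -> float:
        return self.y2_mm - self.y1_mm


class MLCControlPoint(BaseModel):
    """Per-leaf tip X positions for the two opposing banks, one control point."""

    model_config = ConfigDict(frozen=True)

    bank_a_mm: tuple[float, ...]
    bank_b_mm: tuple[float, ...]

    @model_validator(mode="after")
    def _check(self) -> "MLCControlPoint":
        if len(self.bank_a_mm) != len(self.bank_b_mm):
            raise ValueError("bank A and bank B must have the same leaf count")
        for i, (a, b) in enumerate(zip(self.bank_a_mm, self.bank_b_mm)):
            if a > b:
                raise ValueError(
                    f"leaf pair {i}: bank A tip {a} exceeds bank B tip {b}"
                )
        return self


class MLCState(BaseModel):
    """MLC leaf geometry: pair boundaries along Y plus per-control-point tips."""

    model_config = ConfigDict(frozen=True)

    leaf_boundaries_mm: tuple[float, ...]
    control_points: tuple[MLCControlPoint, ...]

    @model_validator(mode="after")
    def _check(self) -> "MLCState":
        b = np.asarray(self.leaf_boundaries_mm)
        if len(b) < 2 or np.any(np.diff(b) <= 0):
            raise ValueError("leaf boundaries must be strictly increasing, >= 2 edges")
        if not self.control_points:
            raise ValueError("MLC state needs at least one control point")
        n_pairs = len(b) - 1
        for cp in self.control_points:
            if len(cp.bank_a_mm) != n_pairs:
                raise ValueError(
                    f"control point has {len(cp.bank_a_mm)} leaf pairs, "
                    f"boundaries imply {n_pairs}"
                )
        return self

    @property
    def n_pairs(self) -> int:
        return len(self.leaf_boundaries_mm) - 1


class BlockOutline(BaseModel):
    """One ordered, simple island-block polygon at the reference plane.

    Outlines are normalized to clockwise vertex order on construction (the
    block-design convention); area computations take absolute values and
    are winding-invariant regardless.
    """

    model_config = ConfigDict(frozen=True)

    vertices_mm: tuple[tuple[float, float], ...]
    label: str = ""

    @field_validator("vertices_mm")
    @classmethod
    def _normalize(cls, v):
        poly = Polygon2D(np.asarray(v, dtype=float))  # validates simplicity, n >= 3
        if not poly.is_clockwise:
            poly = poly.reversed()
        return tuple((float(x), float(y)) for x, y in poly.vertices)

    def polygon(self, plane_z_cm: float = 100.0) -> Polygon2D:
        return Polygon2D(np.asarray(self.vertices_mm), plane_z_cm)


class FieldDefinition(BaseModel):
    """Everything the pipeline needs to know about one treatment beam."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    field_id: str
    orientation_tag: Literal["AP", "PA"] = "AP"
    beam_geometry: BeamGeometry = BeamGeometry()
    jaws: JawSet
    mlc: Optional[MLCState] = None
    blocks: tuple[BlockOutline, ...] = ()

    @model_validator(mode="after")
    def _warn_blocks_outside_jaws(self) -> "FieldDefinition":
        j = self.jaws
        for blk in self.blocks:
            v = np.asarray(blk.vertices_mm)
            if (v[:, 0].min() < j.x1_mm or v[:, 0].max() > j.x2_mm
                    or v[:, 1].min() < j.y1_mm or v[:, 1].max() > j.y2_mm):
                warnings.warn(
                    f"block {blk.label!r} extends outside the jaw rectangle "
                    "(tolerated: out-of-field extensions are masked by the CIAO)",
                    BlockOutsideJawsWarning,
                    stacklevel=2,
                )
        return self


# ---------------------------------------------------------------------------
# Canonical JSON plan files


def _field_to_schema(field: FieldDefinition) -> dict:
    doc: dict = {
        "schema_version": SCHEMA_VERSION,
        "patient_id": field.patient_id,
        "field_id": field.field_id,
        "orientation": field.orientation_tag,
        "geometry": {
            "sad_cm": field.beam_geometry.source_to_reference_cm,
            "tray_cm": field.beam_geometry.source_to_tray_cm,
            "clearance_cm": field.beam_geometry.collimator_clearance_cm,
        },
        "jaws": {
            "x1": field.jaws.x1_mm,
            "x2": field.jaws.x2_mm,
            "y1": field.jaws.y1_mm,
            "y2": field.jaws.y2_mm,
        },
        "blocks": [
            {"label": b.label, "vertices": [[x, y] for x, y in b.vertices_mm]}
            for b in field.blocks
        ],
    }
    if field.mlc is not None:
        doc["mlc"] = {
            "boundaries": list(field.mlc.leaf_boundaries_mm),
            "control_points": [
                {"bankA": list(cp.bank_a_mm), "bankB": list(cp.bank_b_mm)}
                for cp in field.mlc.control_points
            ],
        }
    return doc


def _require(mapping: dict, key: str, context: str) -> object:
    if key not in mapping:
        raise PlanSchemaError(f"plan file missing required key {key!r} in {context}")
    return mapping[key]


def _field_from_schema(doc: dict) -> FieldDefinition:
    version = _require(doc, "schema_version", "top level")
    if version != SCHEMA_VERSION:
        raise PlanSchemaError(
            f"unsupported plan schema_version {version!r}; expected {SCHEMA_VERSION}"
        )
    geo = _require(doc, "geometry", "top level")
    jaws = _require(doc, "jaws", "top level")
    mlc_doc = doc.get("mlc")
    mlc = None
    if mlc_doc is not None:
        mlc = MLCState(
            leaf_boundaries_mm=tuple(_require(mlc_doc, "boundaries", "mlc")),
            control_points=tuple(
                MLCControlPoint(
                    bank_a_mm=tuple(_require(cp, "bankA", "mlc.control_points")),
                    bank_b_mm=tuple(_require(cp, "bankB", "mlc.control_points")),
                )
                for cp in _require(mlc_doc, "control_points", "mlc")
            ),
        )
    try:
        return FieldDefinition(
            patient_id=str(_require(doc, "patient_id", "top level")),
            field_id=str(_require(doc, "field_id", "top level")),
            orientation_tag=_require(doc, "orientation", "top level"),
            beam_geometry=BeamGeometry(
                source_to_reference_cm=_require(geo, "sad_cm", "geometry"),
                source_to_tray_cm=_require(geo, "tray_cm", "geometry"),
                collimator_clearance_cm=_require(geo, "clearance_cm", "geometry"),
            ),
            jaws=JawSet(
                x1_mm=_require(jaws, "x1", "jaws"),
                x2_mm=_require(jaws, "x2", "jaws"),
                y1_mm=_require(jaws, "y1", "jaws"),
                y2_mm=_require(jaws, "y2", "jaws"),
            ),
            mlc=mlc,
            blocks=tuple(
                BlockOutline(
                    label=str(b.get("label", "")),
                    vertices_mm=tuple(
                        (float(x), float(y))
                        for x, y in _require(b, "vertices", "blocks[]")
                    ),
                )
                for b in _require(doc, "blocks", "top level")
            ),
        )
    except PlanSchemaError:
        raise
    except (ValueError, TypeError) as exc:
        raise PlanValidationError(str(exc)) from exc


def write_plan_file(field: FieldDefinition, path: str | Path) -> None:
    """Serialize a field to the canonical plan-file form (sorted keys, 2-space
    indent, trailing newline).  ``write(read(p))`` is byte-identical on
    canonical files."""
    text = json.dumps(_field_to_schema(field), sort_keys=True, indent=2,
                      ensure_ascii=False) + "\n"
    Path(path).write_text(text, encoding="utf-8")


def read_plan_file(path: str | Path) -> FieldDefinition:
    """Read and fully validate a plan file; see module docstring for units."""
    p = Path(path)
    try:
        doc = json.loads(p.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise PlanSchemaError(f"{p}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise PlanSchemaError(f"{p}: plan file must be a JSON object")
    return _field_from_schema(doc)


# ---------------------------------------------------------------------------
# DICOM RT Plan importer


def from_dicom_rtplan(path: str | Path, beam_selector: str) -> FieldDefinition:
    """Build a :class:`FieldDefinition` from a DICOM RT Plan beam.

    The portable clinical equivalent of a vendor scripting interface: jaw
    and leaf positions come from ``BeamLimitingDevicePositionSequence``
    (already mm at the isocenter plane, passed through unscaled), block
    outlines from ``BlockSequence`` ``BlockData``.

    Parameters
    ----------
    path
        RT Plan file.
    beam_selector
        ``BeamName`` (or, failing that, ``BeamNumber`` as a string) of the
        beam to import.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    beams = getattr(ds, "BeamSequence", None)
    if not beams:
        raise PlanSchemaError("RT Plan has no BeamSequence")
    beam = None
    for b in beams:
        if str(getattr(b, "BeamName", "")) == beam_selector or \
                str(getattr(b, "BeamNumber", "")) == beam_selector:
            beam = b
            break
    if beam is None:
        names = [str(getattr(b, "BeamName", "?")) for b in beams]
        raise PlanSchemaError(
            f"beam {beam_selector!r} not found in RT Plan (beams: {names})"
        )

    cps = list(getattr(beam, "ControlPointSequence", []))
    if not cps:
        raise PlanSchemaError("selected beam has no ControlPointSequence")
    isocenters = {
        tuple(float(v) for v in cp.IsocenterPosition)
        for cp in cps if getattr(cp, "IsocenterPosition", None) is not None
    }
    if len(isocenters) > 1:
        raise PlanValidationError(
            "multi-isocenter beams are unsupported "
            f"({len(isocenters)} distinct isocenters found)"
        )

    jaw_vals: dict[str, float] = {}
    leaf_cps: list[MLCControlPoint] = []
    boundaries: tuple[float, ...] | None = None
    for bld in getattr(beam, "BeamLimitingDeviceSequence", []):
        if bld.RTBeamLimitingDeviceType.startswith("MLC"):
            boundaries = tuple(float(v) for v in bld.LeafPositionBoundaries)

    for cp in cps:
        for bld in getattr(cp, "BeamLimitingDevicePositionSequence", []):
            kind = bld.RTBeamLimitingDeviceType
            pos = [float(v) for v in bld.LeafJawPositions]
            if kind in ("X", "ASYMX"):
                jaw_vals.setdefault("x1", pos[0])
                jaw_vals.setdefault("x2", pos[1])
            elif kind in ("Y", "ASYMY"):
                jaw_vals.setdefault("y1", pos[0])
                jaw_vals.setdefault("y2", pos[1])
            elif kind.startswith("MLC"):
                half = len(pos) // 2
                leaf_cps.append(MLCControlPoint(
                    bank_a_mm=tuple(pos[:half]), bank_b_mm=tuple(pos[half:]),
                ))
    for key in ("x1", "x2", "y1", "y2"):
        if key not in jaw_vals:
            raise PlanSchemaError(
                f"RT Plan beam carries no {key.upper()} jaw position"
            )

    block_seq = list(getattr(beam, "BlockSequence", []))
    if not block_seq:
        raise PlanSchemaError(
            "RT Plan beam has no BlockSequence (island-block outlines required)"
        )
    blocks = []
    for blk in block_seq:
        data = [float(v) for v in blk.BlockData]
        pts = tuple((data[i], data[i + 1]) for i in range(0, len(data), 2))
        blocks.append(BlockOutline(
            vertices_mm=pts, label=str(getattr(blk, "BlockName", "")),
        ))

    mlc = None
    if boundaries is not None and leaf_cps:
        mlc = MLCState(leaf_boundaries_mm=boundaries,
                       control_points=tuple(leaf_cps))

    return FieldDefinition(
        patient_id=str(getattr(ds, "PatientID", "")) or "UNKNOWN",
        field_id=str(getattr(beam, "BeamName", beam_selector)),
        jaws=JawSet(x1_mm=jaw_vals["x1"], x2_mm=jaw_vals["x2"],
                    y1_mm=jaw_vals["y1"], y2_mm=jaw_vals["y2"]),
        mlc=mlc,
        blocks=tuple(blocks),
    )
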