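"""Field-geometry QA: aperture rasterization, portal-image binarization and
Jaccard-distance comparison.

Delivered block apertures are compared with planned ones as pixel sets on
a common raster at the reference plane.  The planned set comes from
rasterizing the block outlines; the delivered set from thresholding a
megavoltage portal image.  Both are clipped to the CIAO — the MLC-defined
open region — so deliberate out-of-field block extensions (a Cerrobend
mounting practice) do not count as disagreement.  Dissimilarity is the
Jaccard distance

    dj(A, B) = (|A u B| - |A n B|) / |A u B|,   0 <= dj <= 1,

a metric on nonempty pixel sets: 0 for identical apertures, 1 for
disjoint ones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Optional

import numpy as np
import shapely
from shapely.geometry import Polygon as ShPolygon
from shapely.ops import unary_union

from .ciao import ciao_polygon
from .plan import FieldDefinition


class EmptyMaskError(ValueError):
    """An operation is undefined because the pixel sets involved are empty."""


@dataclass(frozen=True)
class ApertureMask:
    """Binary raster at the reference plane.

    ``pixels[i, j]`` covers the point ``origin_mm + (j, i) * spacing_mm``
    (x along columns, y along rows); membership everywhere follows the
    pixel-center-in-region rule.  ``provenance`` tags the source: ``"TPS"``
    (planned), ``"measured"``, ``"3D"`` or ``"CB"``.
    """

    pixels: np.ndarray
    spacing_mm: float
    origin_mm: tuple[float, float]
    provenance: str = "TPS"

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError(f"pixel spacing must be > 0, got {self.spacing_mm}")
        object.__setattr__(self, "pixels",
                           np.asarray(self.pixels, dtype=bool))

    @property
    def count(self) -> int:
        return int(self.pixels.sum())

    @property
    def area_mm2(self) -> float:
        return self.count * self.spacing_mm**2

    def same_grid(self, other: "ApertureMask") -> bool:
        return (
            self.pixels.shape == other.pixels.shape
            and np.isclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def intersect(self, other: "ApertureMask") -> "ApertureMask":
        if not self.same_grid(other):
            raise ValueError("masks are on different grids; resample first")
        return replace(self, pixels=self.pixels & other.pixels)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.pixels.shape
        xs = self.origin_mm[0] + np.arange(nx) * self.spacing_mm
        ys = self.origin_mm[1] + np.arange(ny) * self.spacing_mm
        return xs, ys


def make_grid(field: FieldDefinition, spacing_mm: float,
              margin_mm: float = 20.0) -> tuple[tuple[float, float],
                                                tuple[int, int]]:
    """Deterministic common raster covering the jaw rectangle plus margin.

    Returns ``(origin_mm, (ny, nx))``; every QA raster for a field is laid
    out on this grid so masks compare pixel-for-pixel.
    """
    if spacing_mm <= 0:
        raise ValueError(f"pixel spacing must be > 0, got {spacing_mm}")
    j = field.jaws
    x0, y0 = j.x1_mm - margin_mm, j.y1_mm - margin_mm
    nx = int(np.ceil((j.x2_mm + margin_mm - x0) / spacing_mm)) + 1
    ny = int(np.ceil((j.y2_mm + margin_mm - y0) / spacing_mm)) + 1
    return (x0, y0), (ny, nx)


def _rasterize_geometry(geom, origin: tuple[float, float],
                        shape: tuple[int, int], spacing: float) -> np.ndarray:
    ny, nx = shape
    xs = origin[0] + np.arange(nx) * spacing
    ys = origin[1] + np.arange(ny) * spacing
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel())
    return inside.reshape(ny, nx)


def rasterize_blocks(field: FieldDefinition, spacing_mm: float,
                     margin_mm: float = 20.0,
                     provenance: str = "TPS") -> ApertureMask:
    """Pixel-center raster of the union of block outlines at the reference
    plane."""
    if not field.blocks:
        raise EmptyMaskError("field has no block outlines to rasterize")
    union = unary_union([ShPolygon(b.vertices_mm) for b in field.blocks])
    origin, shape = make_grid(field, spacing_mm, margin_mm)
    pix = _rasterize_geometry(union, origin, shape, spacing_mm)
    return ApertureMask(pix, spacing_mm, origin, provenance)


def ciao_mask(field: FieldDefinition, spacing_mm: float,
              margin_mm: float = 20.0) -> ApertureMask:
    """Raster of the CIAO (union over control points of the open aperture,
    clipped to the jaws).  Falls back to the jaw rectangle, with a warning,
    when no MLC state is present."""
    geom = ciao_polygon(field)
    origin, shape = make_grid(field, spacing_mm, margin_mm)
    pix = _rasterize_geometry(geom, origin, shape, spacing_mm)
    return ApertureMask(pix, spacing_mm, origin, "CIAO")


# ---------------------------------------------------------------------------
# Portal images


@dataclass(frozen=True)
class PortalImage:
    """Grayscale portal image with its acquisition geometry.

    ``spacing_mm`` is the pixel pitch *at the imager plane*;
    ``imager_z_cm`` the source-imager distance.  Binarization rescales the
    grid to the reference plane by ``reference_z / imager_z``.
    """

    pixels: np.ndarray
    spacing_mm: float
    imager_z_cm: float = 100.0
    origin_mm: tuple[float, float] = (0.0, 0.0)
    reference_z_cm: float = 100.0


def load_portal_image(path, *, spacing_mm: float | None = None,
                      imager_z_cm: float | None = None,
                      reference_z_cm: float = 100.0) -> PortalImage:
    """Read a portal image from DICOM (spacing tags honored) or from a
    16-bit PNG/TIFF raster (spacing must then be supplied)."""
    p = str(path)
    if p.lower().endswith((".dcm", ".dicom")):
        import pydicom

        ds = pydicom.dcmread(p)
        arr = ds.pixel_array.astype(float)
        tag_spacing = getattr(ds, "ImagePlanePixelSpacing",
                              getattr(ds, "PixelSpacing", None))
        if spacing_mm is None:
            if tag_spacing is None:
                raise ValueError(f"{p}: no pixel spacing tag; pass spacing_mm")
            spacing_mm = float(tag_spacing[0])
        if imager_z_cm is None:
            sid = getattr(ds, "RTImageSID", None)
            imager_z_cm = float(sid) / 10.0 if sid is not None else reference_z_cm
    else:
        import imageio.v3 as iio

        arr = iio.imread(p).astype(float)
        if spacing_mm is None:
            raise ValueError(f"{p}: raster images carry no spacing; pass spacing_mm")
        if imager_z_cm is None:
            imager_z_cm = reference_z_cm
    ny, nx = arr.shape
    origin = (-(nx - 1) / 2.0 * spacing_mm, -(ny - 1) / 2.0 * spacing_mm)
    return PortalImage(arr, spacing_mm, imager_z_cm, origin, reference_z_cm)


def _midpoint_threshold(pixels: np.ndarray) -> float:
    """Midpoint of the low and high modal intensities, estimated robustly
    as the 1st/99th percentile pair (exact for two-level images)."""
    lo = float(np.percentile(pixels, 1))
    hi = float(np.percentile(pixels, 99))
    return 0.5 * (lo + hi)


def binarize_image(
    image: PortalImage,
    method: Literal["midpoint", "otsu"] | float = "midpoint",
    *,
    invert: bool = False,
    provenance: str = "measured",
) -> ApertureMask:
    """Threshold a portal image into a blocked-region mask.

    Low-signal pixels (under an attenuator) are "blocked" and set True;
    ``invert`` flips the polarity for detectors with inverted response.
    The mask grid is rescaled from the imager plane to the reference plane
    by similar triangles.
    """
    pix = np.asarray(image.pixels, dtype=float)
    if isinstance(method, str):
        if np.ptp(pix) == 0:
            raise ValueError(
                "constant image: automatic thresholding is undefined"
            )
        if method == "midpoint":
            thr = _midpoint_threshold(pix)
        elif method == "otsu":
            from skimage.filters import threshold_otsu

            thr = float(threshold_otsu(pix))
        else:
            raise ValueError(f"unknown threshold method {method!r}")
    else:
        thr = float(method)
    blocked = pix < thr
    if invert:
        blocked = ~blocked
    s = image.reference_z_cm / image.imager_z_cm
    return ApertureMask(blocked, image.spacing_mm * s,
                        (image.origin_mm[0] * s, image.origin_mm[1] * s),
                        provenance)


# ---------------------------------------------------------------------------
# Jaccard comparison


def jaccard_distance(a: ApertureMask, b: ApertureMask) -> float:
    """``(|A u B| - |A n B|) / |A u B|`` on identical grids."""
    if not a.same_grid(b):
        raise ValueError("masks are on different grids; resample first")
    union = int((a.pixels | b.pixels).sum())
    if union == 0:
        raise EmptyMaskError("Jaccard distance is undefined for two empty masks")
    inter = int((a.pixels & b.pixels).sum())
    return (union - inter) / union


@dataclass(frozen=True)
class ComparisonEntry:
    """One dj(X, TPS) value for one patient case."""

    case: str
    group: str  # "3D" or "CB" (or any provenance label)
    dj: float


def compare_apertures(measured: ApertureMask, planned: ApertureMask,
                      ciao: ApertureMask, *, case: str = "",
                      group: str | None = None) -> ComparisonEntry:
    """Jaccard distance between CIAO-clipped measured and planned apertures.

    Pixels outside the CIAO never contribute, which removes deliberate
    out-of-field block extensions from the comparison.
    """
    if ciao.count == 0:
        raise EmptyMaskError("CIAO mask is empty; nothing to compare inside")
    dj = jaccard_distance(measured.intersect(ciao), planned.intersect(ciao))
    return ComparisonEntry(case=case, group=group or measured.provenance, dj=dj)


@dataclass(frozen=True)
class JaccardReport:
    """Per-case dj values, per-group means and per-case group ratios."""

    entries: tuple[ComparisonEntry, ...]
    group_means: dict
    ratios_pct: dict

    def to_text(self) -> str:
        lines = ["case  " + "  ".join(f"dj({g},TPS)" for g in self.group_means)]
        cases = sorted({e.case for e in self.entries})
        by = {(e.case, e.group): e.dj for e in self.entries}
        for c in cases:
            vals = "  ".join(
                f"{by.get((c, g), float('nan')):10.3f}" for g in self.group_means
            )
            ratio = self.ratios_pct.get(c)
            lines.append(f"{c:4s}  {vals}  " +
                         (f"{ratio:4d}%" if ratio is not None else "  n/a"))
        lines.append("mean  " + "  ".join(
            f"{m:10.3f}" for m in self.group_means.values()))
        return "\n".join(lines)

    def to_frame(self):
        import pandas as pd

        cases = sorted({e.case for e in self.entries})
        by = {(e.case, e.group): e.dj for e in self.entries}
        rows = []
        for c in cases:
            row = {"case": c}
            for g in self.group_means:
                row[f"dj({g},TPS)"] = round(by.get((c, g), float("nan")), 3)
            row["ratio_pct"] = self.ratios_pct.get(c)
            rows.append(row)
        return pd.DataFrame(rows)


def summarize(entries: Iterable[ComparisonEntry],
              ratio_of: tuple[str, str] = ("CB", "3D")) -> JaccardReport:
    """Group means (3 d.p.) and per-case ratios (integer percent).

    ``ratio_of = (num, den)`` names the groups whose per-case dj ratio is
    reported; a zero denominator yields ``None`` (undefined).
    """
    entries = tuple(entries)
    if not entries:
        raise ValueError("no comparison entries to summarize")
    groups: dict[str, list[float]] = {}
    for e in entries:
        groups.setdefault(e.group, []).append(e.dj)
    means = {g: round(float(np.mean(v)), 3) for g, v in groups.items()}

    num_g, den_g = ratio_of
    by = {(e.case, e.group): e.dj for e in entries}
    ratios: dict[str, Optional[int]] = {}
    for case in sorted({e.case for e in entries}):
        num = by.get((case, num_g))
        den = by.get((case, den_g))
        if num is None or den is None:
            continue
        ratios[case] = None if den == 0 else int(round(100.0 * num / den))
    return JaccardReport(entries=entries, group_means=means, ratios_pct=ratios)
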