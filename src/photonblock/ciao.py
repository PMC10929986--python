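"""Complete irradiated area outline (CIAO) construction.

The CIAO is the union, over all control points of a field, of the open
MLC aperture clipped to the jaw rectangle.  It defines where beam can
reach, and therefore both where mounting bolts may not go and which pixels
count in field-geometry comparisons.  Static fields degenerate to a single
control point.
"""

from __future__ import annotations

import warnings

from shapely.geometry import box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .plan import FieldDefinition

#: A leaf pair is considered open when the gap between opposing tips
#: exceeds this (mm); parked/abutted leaves leak but do not open the field.
OPEN_GAP_MM = 1e-6


class NoMLCWarning(UserWarning):
    """Field has no MLC state; the CIAO falls back to the jaw rectangle."""


def jaw_box(field: FieldDefinition):
    j = field.jaws
    return box(j.x1_mm, j.y1_mm, j.x2_mm, j.y2_mm)


def ciao_polygon(field: FieldDefinition) -> BaseGeometry:
    """CIAO as a shapely geometry in mm at the reference plane.

    Union over control points of the open leaf-pair strips, intersected
    with the jaw rectangle.  Without MLC data the jaw rectangle itself is
    returned, with a warning — jaw-only fields are legitimately open
    everywhere inside the jaws.
    """
    jaws = jaw_box(field)
    if field.mlc is None:
        warnings.warn(
            "field has no MLC state; using the jaw rectangle as the CIAO",
            NoMLCWarning,
            stacklevel=2,
        )
        return jaws
    bounds = field.mlc.leaf_boundaries_mm
    strips = []
    for cp in field.mlc.control_points:
        for i, (a, b) in enumerate(zip(cp.bank_a_mm, cp.bank_b_mm)):
            if b - a > OPEN_GAP_MM:
                strips.append(box(a, bounds[i], b, bounds[i + 1]))
    if not strips:
        return jaws.intersection(jaws.boundary)  # empty geometry
    return unary_union(strips).intersection(jaws)
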