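"""Weight-based quality assurance of BB-filled block shells.

The fill mass of a shell is predicted from pure geometry: each cavity is a
divergence frustum, so its volume follows from the shoelace areas of the
block outline projected to the cavity's top and bottom planes,

    V = (h/3) * (Atop + sqrt(Atop * Abottom) + Abottom),

and the packed tungsten BB mass is

    M = eta * rho * sum_i V_i,

with ``eta`` the random sphere packing fraction (~0.6) and ``rho`` the BB
alloy density (~17.6 g/cc), giving an effective fill density of roughly
10.5 g/cc.  Weighing the filled shell against M catches wrong-volume and
wrong-fill errors before the block reaches a treatment machine; a site
should calibrate the product ``eta*rho`` by weighing a few fully filled
reference shells.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .geometry import FrustumSpec, frustum_volume, project_polygon, shoelace_area
from .plan import FieldDefinition
from .shell import ShellDesignSpec

#: Densest possible sphere packing (FCC); random packings must be below it.
FCC_PACKING_BOUND = np.pi / np.sqrt(18.0)


class PackingModel(BaseModel):
    """Packing fraction and BB density, or a calibrated effective density."""

    model_config = ConfigDict(frozen=True)

    eta: float = 0.6
    rho_g_per_cc: float = 17.6
    eta_rho_calibrated_g_per_cc: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "PackingModel":
        if not 0.0 < self.eta < FCC_PACKING_BOUND:
            raise ValueError(
                f"packing fraction must be in (0, {FCC_PACKING_BOUND:.4f}), "
                f"got {self.eta}"
            )
        if self.rho_g_per_cc <= 0:
            raise ValueError("BB density must be > 0")
        return self

    @property
    def effective_density_g_per_cc(self) -> float:
        if self.eta_rho_calibrated_g_per_cc is not None:
            return self.eta_rho_calibrated_g_per_cc
        return self.eta * self.rho_g_per_cc


def shell_volumes(field_def: FieldDefinition,
                  spec: ShellDesignSpec | None = None) -> list[float]:
    """Per-block BB cavity volumes in cc, from design geometry.

    Atop/Abottom are the shoelace areas of each outline projected to the
    cavity's top and bottom planes; h is the interior height along the
    beam axis.
    """
    spec = spec or ShellDesignSpec()
    geom = field_def.beam_geometry
    tray = spec.tray_z_cm(geom)
    z_top = tray - spec.interior_height_cm
    if z_top <= 0:
        raise ValueError("interior height exceeds source-tray distance")
    vols = []
    for blk in field_def.blocks:
        ref_poly = blk.polygon(geom.source_to_reference_cm)
        a_bot = shoelace_area(project_polygon(ref_poly, tray))
        a_top = shoelace_area(project_polygon(ref_poly, z_top))
        v_mm3 = frustum_volume(
            FrustumSpec(a_top, a_bot, spec.interior_height_cm * 10.0))
        vols.append(v_mm3 / 1000.0)
    return vols


def predicted_mass(volumes_cc: Sequence[float],
                   model: PackingModel | None = None) -> float:
    """Predicted BB fill mass in grams: effective density times total volume."""
    model = model or PackingModel()
    volumes = np.asarray(volumes_cc, dtype=float)
    if np.any(volumes < 0):
        raise ValueError("cavity volumes must be >= 0")
    return float(model.effective_density_g_per_cc * volumes.sum())


def percent_difference(calculated_g: float, measured_g: float) -> float:
    """Signed percent difference, ``100 * (calculated - measured) / calculated``.

    Negative means the shell took more BBs than predicted (overfill).
    """
    if calculated_g <= 0:
        raise ValueError(f"calculated mass must be > 0, got {calculated_g}")
    return 100.0 * (calculated_g - measured_g) / calculated_g


def calibrate_eta_rho(
    reference: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Calibrate the effective fill density from weighed reference shells.

    Least-squares slope through the origin of measured mass against total
    cavity volume, ``sum(m*v) / sum(v^2)``, over ``(volume_cc, mass_g)``
    pairs.  Returns ``(slope_g_per_cc, residual_rms_g)``.
    """
    if not len(reference):
        raise ValueError("calibration needs at least one reference shell")
    v = np.asarray([r[0] for r in reference], dtype=float)
    m = np.asarray([r[1] for r in reference], dtype=float)
    if np.any(v <= 0):
        raise ValueError("reference volumes must be > 0")
    slope = float((m * v).sum() / (v * v).sum())
    resid = m - slope * v
    return slope, float(np.sqrt(np.mean(resid**2)))


@dataclass(frozen=True)
class MassQAReport:
    """Table-style weight QA verdict for one shell assembly."""

    patient_id: str
    field_id: str
    volumes_cc: tuple[float, ...]
    calculated_mass_g: float
    measured_mass_g: float
    percent_difference: float
    tolerance_under_pct: float
    tolerance_over_pct: float
    verdict: str = field(init=False)

    def __post_init__(self) -> None:
        # positive pd = underfill (measured below calculated)
        ok = (-self.tolerance_over_pct
              <= self.percent_difference
              <= self.tolerance_under_pct)
        object.__setattr__(self, "verdict", "PASS" if ok else "FAIL")

    @property
    def passed(self) -> bool:
        return self.verdict == "PASS"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "patient": self.patient_id,
            "field": self.field_id,
            "calculated_mass_g": round(self.calculated_mass_g, 1),
            "measured_mass_g": round(self.measured_mass_g, 1),
            "percent_difference": round(self.percent_difference, 2),
            "verdict": self.verdict,
        }])

    def to_csv(self) -> str:
        buf = io.StringIO()
        self.to_frame().to_csv(buf, index=False)
        return buf.getvalue()

    def to_text(self) -> str:
        lines = [
            f"Mass QA — patient {self.patient_id}, field {self.field_id}",
            "  cavity volumes: "
            + ", ".join(f"{v:.1f} cc" for v in self.volumes_cc),
            f"  calculated mass: {self.calculated_mass_g:.1f} g",
            f"  measured mass:   {self.measured_mass_g:.1f} g",
            f"  difference:      {self.percent_difference:+.2f} % "
            f"(tolerance -{self.tolerance_over_pct:g}/+{self.tolerance_under_pct:g} %)",
            f"  verdict:         {self.verdict}",
        ]
        return "\n".join(lines)


def qa_report(
    field_def: FieldDefinition,
    measured_g: float,
    *,
    spec: ShellDesignSpec | None = None,
    model: PackingModel | None = None,
    tolerance_pct: float = 2.0,
    tolerance_over_pct: float | None = None,
) -> MassQAReport:
    """Predict, compare and judge the BB fill mass for one field.

    ``tolerance_pct`` bounds underfill; ``tolerance_over_pct`` (defaults to
    the same value) bounds overfill and may be set looser, since slight
    over-attenuation is clinically preferable to under-attenuation.
    """
    vols = shell_volumes(field_def, spec)
    calc = predicted_mass(vols, model)
    pd_pct = percent_difference(calc, measured_g)
    return MassQAReport(
        patient_id=field_def.patient_id,
        field_id=field_def.field_id,
        volumes_cc=tuple(vols),
        calculated_mass_g=calc,
        measured_mass_g=measured_g,
        percent_difference=pd_pct,
        tolerance_under_pct=tolerance_pct,
        tolerance_over_pct=(tolerance_over_pct if tolerance_over_pct is not None
                            else tolerance_pct),
    )
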