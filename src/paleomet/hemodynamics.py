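"""Nutrient-foramen hemodynamics.

The femoral nutrient foramen transmits the nutrient artery; its aperture
area proxies arterial size and hence the blood flow perfusing the femoral
shaft.  Treating the aperture as a geometric circle and the arterial lumen
as a fixed fraction (default 20%) of it gives the lumen radius

    r_i = sqrt(area * lumen_fraction / pi)          [mm]

and the curved polynomial flow calibration (base-10 logs)

    log10 Qdot = -0.20 (log10 r_i)^2 + 1.91 log10 r_i + 1.82   [mL s^-1]

which is strictly increasing in r_i up to r_i = 10**4.775 mm, far beyond
any biological artery, so the relation is invertible on its useful domain.
"""
from __future__ import annotations

import dataclasses
import math

__all__ = [
    "QUADRATIC_COEF",
    "LINEAR_COEF",
    "INTERCEPT",
    "ForamenMeasurement",
    "BloodFlowEstimate",
    "lumen_radius",
    "blood_flow_rate",
    "flow_from_foramen",
    "radius_from_flow",
]

QUADRATIC_COEF = -0.20
LINEAR_COEF = 1.91
INTERCEPT = 1.82

# vertex of the log-quadratic: monotone below this radius
_LOG_R_MAX = LINEAR_COEF / (-2.0 * QUADRATIC_COEF)            # 4.775
_LOG_Q_MAX = INTERCEPT + LINEAR_COEF**2 / (-4.0 * QUADRATIC_COEF)


@dataclasses.dataclass(frozen=True)
class ForamenMeasurement:
    """A specimen's foramen aperture area (mm^2) and lumen fraction."""

    specimen_id: str
    area_mm2: float
    lumen_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not self.area_mm2 > 0:
            raise ValueError("foramen aperture area must be > 0")
        if not (0.0 < self.lumen_fraction <= 1.0):
            raise ValueError("lumen fraction must lie in (0, 1]")


@dataclasses.dataclass(frozen=True)
class BloodFlowEstimate:
    """Derived lumen radius (mm) and nutrient-artery flow (mL s^-1)."""

    specimen_id: str
    radius_mm: float
    flow_ml_s: float

    def __post_init__(self) -> None:
        if not self.radius_mm > 0 or not self.flow_ml_s > 0:
            raise ValueError("radius and flow must be > 0")


def lumen_radius(measurement: ForamenMeasurement) -> float:
    """Arterial lumen radius (mm) from the circle-equivalent aperture."""
    return math.sqrt(measurement.area_mm2 * measurement.lumen_fraction / math.pi)


def blood_flow_rate(r_i: float) -> float:
    """Nutrient-artery blood flow Qdot (mL s^-1) from lumen radius (mm)."""
    if not r_i > 0:
        raise ValueError("lumen radius must be > 0")
    t = math.log10(r_i)
    return 10.0 ** (QUADRATIC_COEF * t * t + LINEAR_COEF * t + INTERCEPT)


def flow_from_foramen(measurement: ForamenMeasurement) -> BloodFlowEstimate:
    """Compose aperture -> lumen radius -> flow for one specimen."""
    r = lumen_radius(measurement)
    return BloodFlowEstimate(
        specimen_id=measurement.specimen_id,
        radius_mm=r,
        flow_ml_s=blood_flow_rate(r),
    )


def radius_from_flow(q_ml_s: float) -> float:
    """Invert the flow calibration: lumen radius (mm) giving flow ``q_ml_s``.

    Solves the log-quadratic in closed form, taking the root on the
    monotone-increasing branch (r_i < 10**4.775 mm).
    """
    if not q_ml_s > 0:
        raise ValueError("flow must be > 0")
    logq = math.log10(q_ml_s)
    if logq >= _LOG_Q_MAX:
        raise ValueError("flow exceeds the calibration's attainable range")
    disc = LINEAR_COEF**2 - 4.0 * QUADRATIC_COEF * (INTERCEPT - logq)
    t = (-LINEAR_COEF + math.sqrt(disc)) / (2.0 * QUADRATIC_COEF)
    return 10.0 ** t
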