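"""Instrument calibration: Growth-Profiler green values to OD600, OD to CDW.

The Growth Profiler reports culture density as camera-derived green values
(GV).  A fitted polynomial-type calibration maps the blank-subtracted GV to
OD600:

    OD = a·Δ^b + c·Δ^d + e·Δ^f,   Δ = GV − GV_blank

with a linear leading term (b = 1) and two power-law corrections.  The
default constants were calibrated on *S. cerevisiae* CEN.PK113-7D in Delft
minimal medium.  Cell dry weight is obtained from OD through a strain-specific
linear slope (g DW · L⁻¹ per OD unit) established gravimetrically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np


class CalibrationError(ValueError):
    """Missing or invalid calibration constants."""


@dataclass(frozen=True)
class CalibrationModel:
    """GV→OD calibration constants plus per-strain CDW-vs-OD slopes.

    Parameters
    ----------
    a, b, c, d, e, f
        Dimensionless constants of the GV→OD polynomial.
    gv_blank
        Green value of a blank (cell-free) well; must be positive.
    cdw_slopes
        Mapping strain name → CDW/OD slope in g/L per OD unit.
    od_from_gv
        Optional replacement calibration callable ``f(delta) -> OD`` applied
        to the blank-subtracted GV, for substituting an alternative fitted
        form.
    """

    a: float = 0.019
    b: float = 1.0
    c: float = 3.82e-6
    d: float = 2.66
    e: float = 3.111e-22
    f: float = 10.5
    gv_blank: float = 26.3
    cdw_slopes: Mapping[str, float] = field(default_factory=dict)
    od_from_gv: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d", "e", "f", "gv_blank"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise CalibrationError(f"calibration constant {name!r} missing or non-finite")
        if self.gv_blank <= 0:
            raise CalibrationError("gv_blank must be positive")
        for strain, slope in self.cdw_slopes.items():
            if slope <= 0:
                raise CalibrationError(f"cdw_slope for {strain!r} must be positive")

    def cdw_slope(self, strain: str) -> float:
        try:
            return float(self.cdw_slopes[strain])
        except KeyError:
            raise CalibrationError(
                f"no CDW calibration slope registered for strain {strain!r}"
            ) from None

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "CalibrationModel":
        known = {k: cfg[k] for k in ("a", "b", "c", "d", "e", "f", "gv_blank") if k in cfg}
        return cls(cdw_slopes=dict(cfg.get("cdw_slopes", {})), **known)


def gv_to_od(gv, cal: CalibrationModel):
    """Convert green values to OD600.

    Monotone nondecreasing in GV, zero at the blank; values below the blank
    clamp to OD 0 with a warning.  Accepts scalars or arrays.
    """
    gv_arr = np.asarray(gv, dtype=float)
    delta = gv_arr - cal.gv_blank
    below = delta < 0
    if np.any(below):
        warnings.warn(
            "GV readings below the blank were clamped to OD 0", stacklevel=2
        )
        delta = np.where(below, 0.0, delta)
    if cal.od_from_gv is not None:
        od = np.asarray(cal.od_from_gv(delta), dtype=float)
    else:
        od = cal.a * delta**cal.b + cal.c * delta**cal.d + cal.e * delta**cal.f
    od = np.where(delta <= 0, 0.0, od)
    return float(od) if np.isscalar(gv) else od
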