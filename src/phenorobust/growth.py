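"""Growth-curve fitting: μmax, lag phase and the no-growth QC rule.

A cubic smoothing spline is fitted to the log-transformed density signal
versus time; the maximum specific growth rate μmax is the maximum of the
spline's first derivative, located on a dense time grid.  The lag phase is
obtained geometrically as the x coordinate of the intersection between the
line of slope μmax through the inflection point and the horizontal baseline
through y0 (the spline value at the first timepoint):

    lag = t_infl − (y_infl − y0) / μmax

Wells where the spline describes the data poorly (R² below a threshold,
default 0.99 — typical of wells that never grew) are censored by the QC rule:
μmax is set to 0 and the lag phase to missing.

Growth parameters are extracted from the raw instrument signal (GV units):
the log-slope is invariant to linear rescaling of the signal, so converting
to OD first is unnecessary for rate and lag estimation.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .io import TimeSeriesWell

logger = logging.getLogger(__name__)


class GrowthFitError(ValueError):
    pass


@dataclass(frozen=True)
class GrowthFit:
    """Fitted growth parameters for one well.

    ``mu_max`` is in 1/h, ``lag`` in hours (``nan`` when the well did not
    grow), ``r_squared`` is the coefficient of determination of the spline
    against the log-signal.  ``grew`` is the QC flag: when False, ``mu_max``
    is 0 and ``lag`` is missing.
    """

    well_id: str
    mu_max: float
    lag: float
    r_squared: float
    y0: float
    inflection_time: float
    inflection_value: float
    grew: bool
    strain: str = ""
    condition_id: str = ""
    replicate: int = 0

    def summary(self) -> str:
        lag = "NA" if np.isnan(self.lag) else f"{self.lag:.2f} h"
        return (
            f"GrowthFit(well={self.well_id}, mu_max={self.mu_max:.4f} 1/h, "
            f"lag={lag}, R2={self.r_squared:.4f}, grew={self.grew})"
        )


def _no_growth_fit(ts: TimeSeriesWell, y0: float = np.nan) -> GrowthFit:
    return GrowthFit(
        well_id=ts.well_id,
        mu_max=0.0,
        lag=np.nan,
        r_squared=0.0,
        y0=y0,
        inflection_time=np.nan,
        inflection_value=np.nan,
        grew=False,
        strain=ts.strain,
        condition_id=ts.condition_id,
        replicate=ts.replicate,
    )


class GrowthCurveModel:
    """Smoothing-spline growth model for a single well's trajectory.

    Parameters
    ----------
    ts
        The well time series (GV units or OD600).
    blank
        Background signal subtracted before the log transform (the GV blank
        for Growth-Profiler data; 0 for OD signals that are already
        blank-corrected).
    smoothing
        Spline smoothing parameter ``lam``; ``None`` (default) selects it by
        generalized cross-validation.
    dense_factor
        The derivative is maximized on a grid ``dense_factor`` times finer
        than the input sampling (ties broken toward the earliest time).
    """

    def __init__(
        self,
        ts: TimeSeriesWell,
        blank: float = 0.0,
        smoothing: float | None = None,
        dense_factor: int = 20,
    ) -> None:
        if dense_factor < 10:
            raise GrowthFitError("dense_factor must be at least 10")
        self.ts = ts
        self.blank = float(blank)
        self.smoothing = smoothing
        self.dense_factor = int(dense_factor)

    def fit(self) -> GrowthFit:
        ts = self.ts
        t = ts.times
        signal = ts.values - self.blank

        if np.all(signal == signal[0]):
            # perfectly flat trace: nothing to fit, well did not grow
            return _no_growth_fit(ts)
        if (signal <= 0).any():
            if self.blank == 0.0:
                bad = np.nonzero(signal <= 0)[0]
                raise GrowthFitError(
                    f"well {ts.well_id}: nonpositive readings at indices "
                    f"{bad.tolist()}; cannot log-transform"
                )
            positive = signal[signal > 0]
            if positive.size < 4:
                # signal never rose above the blank
                return _no_growth_fit(ts)
            # readings at/below blank are floored to the smallest positive
            # blank-subtracted reading so the log transform stays defined
            signal = np.clip(signal, positive.min(), None)

        y = np.log(signal)
        if np.ptp(y) == 0:
            return _no_growth_fit(ts, y0=y[0])

        spline = make_smoothing_spline(t, y, lam=self.smoothing)
        dense = np.linspace(t[0], t[-1], t.size * self.dense_factor)
        deriv = spline.derivative()(dense)
        i_max = int(np.argmax(deriv))  # argmax returns the earliest maximum
        mu_max = float(deriv[i_max])

        y_hat = spline(t)
        ss_res = float(np.sum((y - y_hat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

        if mu_max <= 0:
            return _no_growth_fit(ts, y0=float(spline(t[0])))

        fit = GrowthFit(
            well_id=ts.well_id,
            mu_max=mu_max,
            lag=np.nan,
            r_squared=r2,
            y0=float(spline(t[0])),
            inflection_time=float(dense[i_max]),
            inflection_value=float(spline(dense[i_max])),
            grew=True,
            strain=ts.strain,
            condition_id=ts.condition_id,
            replicate=ts.replicate,
        )
        return dataclasses.replace(fit, lag=compute_lag(fit))


def fit_growth_curve(
    ts: TimeSeriesWell,
    blank: float = 0.0,
    smoothing: float | None = None,
    dense_factor: int = 20,
) -> GrowthFit:
    """Fit one well; convenience wrapper around :class:`GrowthCurveModel`."""
    return GrowthCurveModel(ts, blank=blank, smoothing=smoothing, dense_factor=dense_factor).fit()


def compute_lag(fit: GrowthFit) -> float:
    """Tangent-construction lag phase in hours.

    Intersects the μmax tangent through the inflection point with the
    horizontal line through y0; missing (``nan``) when the well did not grow.
    Negative intersections clamp to 0 (lag is physically nonnegative).
    """
    if not fit.grew or fit.mu_max <= 0 or np.isnan(fit.inflection_time):
        return np.nan
    lag = fit.inflection_time - (fit.inflection_value - fit.y0) / fit.mu_max
    if lag < 0:
        warnings.warn(
            f"well {fit.well_id}: tangent construction gave negative lag "
            f"({lag:.3f} h); clamped to 0",
            stacklevel=2,
        )
        lag = 0.0
    return float(lag)


def apply_qc(fit: GrowthFit, r2_threshold: float = 0.99) -> GrowthFit:
    """Censor poorly-fitted wells: if R² < threshold the well is treated as
    not grown (μmax 0, lag missing).  Idempotent; the comparison is strict.
    """
    if not 0 < r2_threshold <= 1:
        raise GrowthFitError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    if fit.r_squared < r2_threshold and (fit.grew or fit.mu_max != 0 or not np.isnan(fit.lag)):
        return dataclasses.replace(fit, mu_max=0.0, lag=np.nan, grew=False)
    return fit


def fit_plate(
    wells: Sequence[TimeSeriesWell],
    blank: float = 0.0,
    smoothing: float | None = None,
    r2_threshold: float = 0.99,
) -> list[GrowthFit]:
    """Fit every well of a plate and apply the QC rule."""
    fits = []
    for ts in wells:
        fit = fit_growth_curve(ts, blank=blank, smoothing=smoothing)
        fits.append(apply_qc(fit, r2_threshold=r2_threshold))
    n_censored = sum(not f.grew for f in fits)
    if n_censored:
        logger.info("QC censored %d/%d wells (no growth detected)", n_censored, len(fits))
    return fits


def fits_to_frame(fits: Sequence[GrowthFit]) -> pd.DataFrame:
    """Tidy DataFrame of fitted growth parameters, one row per well."""
    return pd.DataFrame(
        [
            {
                "well_id": f.well_id,
                "strain": f.strain,
                "condition_id": f.condition_id,
                "replicate": f.replicate,
                "mu_max": f.mu_max,
                "lag": f.lag,
                "r_squared": f.r_squared,
                "grew": f.grew,
            }
            for f in fits
        ]
    )
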