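"""Per-well cellular performance functions and the tidy function table.

Five functions are computed for every well: maximum specific growth rate
(1/h) and lag phase (h) from the growth fits, cell dry weight (g/L) from the
48-h OD600 via the strain-specific CDW slope, and biomass and ethanol yields
(g per g of total consumed sugars):

    ethanol yield = ethanol produced / Σ consumed sugars
    biomass yield = (CDW_final − CDW_initial) / Σ consumed sugars

The function set is an extensible registry so additional functions (biosensor
signal, reporter expression, ...) can be scored with the same robustness
machinery.  Replicates are kept as individual records and never pre-averaged.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationModel
from .growth import GrowthFit
from .io import FUNCTION_COLUMNS, SUGARS, EndpointTable, PlateLayout

logger = logging.getLogger(__name__)

#: default inoculation density of the plate cultures
START_OD = 0.02

#: registry of scoreable functions → units
FUNCTION_UNITS: dict[str, str] = {
    "mu_max": "1/h",
    "lag": "h",
    "cdw": "g/L",
    "biomass_yield": "g/g",
    "ethanol_yield": "g/g",
}


def register_function(name: str, units: str) -> None:
    """Register an additional cellular function (e.g. a biosensor signal)."""
    FUNCTION_UNITS[name] = units


class PerformanceError(ValueError):
    pass


def consumed_sugars(endpoint_row: Mapping) -> float:
    """Total consumed sugars (g/L): Σ max(initial − final, 0) over the five
    measured sugars.  Raises if no substrate was supplied at all."""
    initials = np.array([float(endpoint_row[f"{s}_initial"]) for s in SUGARS])
    finals = np.array([float(endpoint_row[f"{s}_final"]) for s in SUGARS])
    if not (initials > 0).any():
        raise PerformanceError("no substrate defined: all initial sugar concentrations are 0")
    diff = initials - finals
    if (diff < 0).any():
        over = [s for s, d in zip(SUGARS, diff) if d < 0]
        warnings.warn(
            f"final > initial for {over}; those sugars contribute 0 to consumption",
            stacklevel=2,
        )
        diff = np.clip(diff, 0.0, None)
    return float(diff.sum())


def ethanol_yield(ethanol_produced: float, consumed: float) -> float:
    """Ethanol yield in g per g consumed sugars; missing when nothing was
    consumed (division undefined)."""
    if consumed <= 0:
        warnings.warn("no sugars consumed; ethanol yield undefined", stacklevel=2)
        return np.nan
    return float(ethanol_produced) / float(consumed)


def biomass_yield(cdw_final: float, cdw_initial: float, consumed: float) -> float:
    """Biomass yield in g biomass per g consumed sugars, inoculum subtracted;
    negative values floor at 0."""
    if consumed <= 0:
        warnings.warn("no sugars consumed; biomass yield undefined", stacklevel=2)
        return np.nan
    y = (float(cdw_final) - float(cdw_initial)) / float(consumed)
    if y < 0:
        warnings.warn(f"negative biomass yield ({y:.4g}) floored at 0", stacklevel=2)
        y = 0.0
    return y


def cdw_from_od(od: float, strain_slope: float) -> float:
    """Cell dry weight (g/L) from OD600 via the strain calibration slope."""
    if od < 0:
        raise PerformanceError(f"OD must be nonnegative, got {od}")
    if strain_slope <= 0:
        raise PerformanceError(f"CDW slope must be positive, got {strain_slope}")
    return float(od) * float(strain_slope)


def assemble_function_table(
    fits: Sequence[GrowthFit],
    endpoints: EndpointTable | None,
    layout: PlateLayout,
    cal: CalibrationModel,
    start_od: float = START_OD,
    subtract_inoculum: bool = True,
) -> pd.DataFrame:
    """Build the tidy (strain, function, condition_id, replicate, value)
    table, five records per well.

    Wells that failed growth QC contribute μmax = 0 and a missing lag.  Wells
    with growth fits but no endpoint measurements contribute only μmax and
    lag, with a warning.  The inoculum biomass (``start_od`` × CDW slope) is
    subtracted from the biomass yield unless ``subtract_inoculum`` is False.
    """
    endpoint_wells = set(endpoints.wells) if endpoints is not None else set()
    records: list[dict] = []
    n_missing: dict[str, int] = {f: 0 for f in FUNCTION_UNITS}

    def add(fit: GrowthFit, function: str, value: float) -> None:
        records.append(
            {
                "strain": fit.strain,
                "function": function,
                "condition_id": fit.condition_id,
                "replicate": fit.replicate,
                "value": value,
            }
        )
        if np.isnan(value):
            n_missing[function] += 1

    no_endpoint: list[str] = []
    for fit in fits:
        add(fit, "mu_max", fit.mu_max)
        add(fit, "lag", fit.lag)

        if fit.well_id not in endpoint_wells:
            no_endpoint.append(fit.well_id)
            continue

        row = endpoints.row(fit.well_id)
        slope = cal.cdw_slope(fit.strain)
        cdw_final = cdw_from_od(float(row["od600_48h"]), slope)
        add(fit, "cdw", cdw_final)

        consumed = consumed_sugars(row)
        cdw_initial = cdw_from_od(start_od, slope) if subtract_inoculum else 0.0
        add(fit, "biomass_yield", biomass_yield(cdw_final, cdw_initial, consumed))
        add(fit, "ethanol_yield", ethanol_yield(float(row["ethanol"]), consumed))

    if no_endpoint:
        warnings.warn(
            f"no endpoint measurements for wells {no_endpoint}; "
            "only mu_max and lag recorded",
            stacklevel=2,
        )
    for function, n in n_missing.items():
        if n:
            logger.info("function %s: %d missing values", function, n)

    df = pd.DataFrame(records, columns=list(FUNCTION_COLUMNS))
    dup = df[["strain", "function", "condition_id", "replicate"]].duplicated()
    if dup.any():
        raise PerformanceError("duplicate (strain, function, condition, replicate) records")
    return df
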