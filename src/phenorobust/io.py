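"""Reading and writing of plate phenomics tables.

All files are plain CSV (comma-separated, UTF-8, ``.`` decimal, header row
mandatory) with time expressed in hours and missing values encoded ``NA``.
Four table kinds are handled:

* **time series** — either wide form (first column ``time_h``, one column per
  well) or long form (``time_h, well_id, value``);
* **plate layout** — ``well_id, strain, condition_id, replicate, is_control``;
* **endpoints** — per-well initial/final sugar concentrations (g/L), endpoint
  ethanol (g/L) and the 48-h OD600;
* **tidy result tables** (function tables, robustness tables, ...) written
  with a provenance header comment.

The layout is always a separate file; well identities are never inferred from
naming conventions.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

logger = logging.getLogger(__name__)

#: sugars quantified in the endpoint assays, in canonical column order
SUGARS = ("glucose", "mannose", "xylose", "galactose", "arabinose")

LAYOUT_COLUMNS = ("well_id", "strain", "condition_id", "replicate", "is_control")

ENDPOINT_COLUMNS = tuple(
    ["well_id"]
    + [f"{s}_initial" for s in SUGARS]
    + [f"{s}_final" for s in SUGARS]
    + ["ethanol", "od600_48h"]
)

FUNCTION_COLUMNS = ("strain", "function", "condition_id", "replicate", "value")


class PlateDataError(ValueError):
    """Raised for malformed plate files (duplicate keys, unknown wells, ...)."""


@dataclass(frozen=True)
class PlateLayout:
    """Mapping of wells to (strain, condition, replicate) identities.

    One plate is used per strain; each well corresponds to one growth
    condition assayed in replicate.  At most one condition may be flagged as
    the control (e.g. the 20 g/L glucose reference needed by the Kitano
    metric).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
        if missing:
            raise PlateDataError(f"layout is missing columns: {missing}")
        dup_wells = df.loc[df["well_id"].duplicated(), "well_id"].tolist()
        if dup_wells:
            raise PlateDataError(f"duplicate well ids in layout: {sorted(set(dup_wells))}")
        key = df[["strain", "condition_id", "replicate"]]
        if key.duplicated().any():
            dups = key[key.duplicated()].drop_duplicates().to_records(index=False).tolist()
            raise PlateDataError(
                f"duplicate (strain, condition_id, replicate) triples: {dups}"
            )
        if (df["replicate"] < 1).any():
            raise PlateDataError("replicate indices must be positive integers")
        n_ctrl_cond = df.loc[df["is_control"].astype(bool), "condition_id"].nunique()
        if n_ctrl_cond > 1:
            raise PlateDataError("at most one condition may be flagged is_control")

    @property
    def wells(self) -> list[str]:
        return self.table["well_id"].tolist()

    @property
    def control_condition(self) -> str | None:
        ctrl = self.table.loc[self.table["is_control"].astype(bool), "condition_id"]
        return None if ctrl.empty else str(ctrl.iloc[0])

    def identity(self, well_id: str) -> tuple[str, str, int]:
        row = self.table.loc[self.table["well_id"] == well_id]
        if row.empty:
            raise PlateDataError(f"well {well_id!r} not present in layout")
        r = row.iloc[0]
        return str(r["strain"]), str(r["condition_id"]), int(r["replicate"])


@dataclass(frozen=True)
class TimeSeriesWell:
    """Density trajectory of a single well, in GV units or OD600."""

    well_id: str
    times: np.ndarray
    values: np.ndarray
    strain: str
    condition_id: str
    replicate: int
    signal_kind: str = "GV"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if self.signal_kind not in ("GV", "OD"):
            raise PlateDataError(f"signal_kind must be 'GV' or 'OD', got {self.signal_kind!r}")
        if t.ndim != 1 or t.shape != v.shape:
            raise PlateDataError(f"well {self.well_id}: times and values must match in length")
        if t.size < 4:
            raise PlateDataError(f"well {self.well_id}: need at least 4 timepoints, got {t.size}")
        if (t < 0).any():
            raise PlateDataError(f"well {self.well_id}: negative times")
        if not (np.diff(t) > 0).all():
            bad = np.nonzero(np.diff(t) <= 0)[0]
            raise PlateDataError(
                f"well {self.well_id}: time not strictly increasing at rows {bad.tolist()}"
            )
        if (v < 0).any():
            raise PlateDataError(f"well {self.well_id}: negative density readings")


@dataclass(frozen=True)
class EndpointTable:
    """Per-well endpoint measurements: sugars in/out, ethanol, 48-h OD600."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in ENDPOINT_COLUMNS if c not in df.columns]
        if missing:
            raise PlateDataError(f"endpoint table is missing columns: {missing}")
        num = df[list(ENDPOINT_COLUMNS[1:])]
        if (num.to_numpy(dtype=float) < -1e-12).any():
            raise PlateDataError("endpoint concentrations must be nonnegative")
        for s in SUGARS:
            over = df[f"{s}_final"] > df[f"{s}_initial"] + 1e-9
            if over.any():
                warnings.warn(
                    f"{s}: final concentration exceeds initial in wells "
                    f"{df.loc[over, 'well_id'].tolist()}; consumed amount will be 0",
                    stacklevel=2,
                )

    def row(self, well_id: str) -> pd.Series:
        sub = self.table.loc[self.table["well_id"] == well_id]
        if sub.empty:
            raise KeyError(well_id)
        return sub.iloc[0]

    @property
    def wells(self) -> list[str]:
        return self.table["well_id"].tolist()


def read_layout(path: str | Path) -> PlateLayout:
    """Read a plate layout CSV (``well_id, strain, condition_id, replicate,
    is_control``)."""
    df = pd.read_csv(path, comment="#", na_values="NA")
    df["replicate"] = df["replicate"].astype(int)
    df["is_control"] = df["is_control"].astype(bool)
    return PlateLayout(df)


def read_timeseries(
    path: str | Path,
    layout: PlateLayout,
    signal_kind: str = "GV",
) -> list[TimeSeriesWell]:
    """Read a plate time-series CSV into one :class:`TimeSeriesWell` per well.

    Accepts wide form (``time_h`` plus one column per well) or long form
    (``time_h, well_id, value``); the form is detected from the header.  Rows
    are sorted by time; wells present in the file but absent from the layout
    raise an error naming them.
    """
    df = pd.read_csv(path, comment="#", na_values="NA")
    if "time_h" not in df.columns:
        raise PlateDataError("time-series file must have a 'time_h' column")
    long_form = {"well_id", "value"} <= set(df.columns)

    if long_form:
        bad = df[pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()]
        if not bad.empty:
            raise PlateDataError(f"non-numeric values at rows {bad.index.tolist()}")
        groups = {str(w): g for w, g in df.groupby("well_id", sort=False)}
    else:
        groups = {}
        for col in df.columns:
            if col == "time_h":
                continue
            vals = pd.to_numeric(df[col], errors="coerce")
            bad_rows = vals.isna() & df[col].notna()
            if bad_rows.any():
                raise PlateDataError(
                    f"non-numeric values in column {col} at rows {bad_rows[bad_rows].index.tolist()}"
                )
            groups[str(col)] = pd.DataFrame({"time_h": df["time_h"], "value": vals})

    unknown = sorted(set(groups) - set(layout.wells))
    if unknown:
        raise PlateDataError(f"wells present in time series but absent from layout: {unknown}")

    wells: list[TimeSeriesWell] = []
    for well_id, g in groups.items():
        g = g.sort_values("time_h", kind="stable")
        strain, condition_id, replicate = layout.identity(well_id)
        wells.append(
            TimeSeriesWell(
                well_id=well_id,
                times=g["time_h"].to_numpy(dtype=float),
                values=g["value"].to_numpy(dtype=float),
                strain=strain,
                condition_id=condition_id,
                replicate=replicate,
                signal_kind=signal_kind,
            )
        )
    return wells


def read_endpoints(path: str | Path) -> EndpointTable:
    """Read the per-well endpoint table; an empty file yields an empty table
    with a logged warning."""
    df = pd.read_csv(path, comment="#", na_values="NA")
    if df.empty:
        logger.warning("endpoint file %s contains no rows", path)
        df = df.reindex(columns=list(ENDPOINT_COLUMNS))
    return EndpointTable(df)


def read_function_table(path: str | Path) -> pd.DataFrame:
    """Read a tidy function table (``strain, function, condition_id,
    replicate, value``)."""
    df = pd.read_csv(path, comment="#", na_values="NA")
    missing = [c for c in FUNCTION_COLUMNS if c not in df.columns]
    if missing:
        raise PlateDataError(f"function table is missing columns: {missing}")
    df["replicate"] = df["replicate"].astype(int)
    return df


def config_hash(config: Mapping | None) -> str:
    """Short deterministic hash of a run configuration mapping."""
    payload = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(
    records: pd.DataFrame,
    path: str | Path,
    config: Mapping | None = None,
) -> Path:
    """Write a tidy result table as CSV with a provenance header comment.

    The header names the package version and a hash of the run configuration
    so result files are traceable; missing values are written as ``NA``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    buf.write(f"# phenorobust {__version__} config_hash={config_hash(config)}\n")
    records.to_csv(buf, index=False, na_rep="NA")
    path.write_text(buf.getvalue())
    return path


def write_timeseries(wells: Sequence[TimeSeriesWell], path: str | Path) -> Path:
    """Write wells in long form (``time_h, well_id, value``)."""
    frames = [
        pd.DataFrame({"time_h": w.times, "well_id": w.well_id, "value": w.values})
        for w in wells
    ]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["time_h", "well_id", "value"]
    )
    return write_table(df, path)
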