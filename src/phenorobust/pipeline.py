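"""Run configuration and the one-shot analysis pipeline.

``run_all`` takes plate inputs (time series + layout + endpoints per plate)
through growth fitting, function assembly, robustness scoring, strain
comparison and trade-off analysis, writing tidy CSV outputs:

    fits.csv, functions.csv, robustness.csv, tests.csv, tradeoffs.csv

The configuration is validated before any stage runs and persisted next to
the outputs together with its content hash, so a rerun with the same config
and inputs reproduces the outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .calibration import CalibrationModel
from .growth import fit_plate, fits_to_frame
from .io import config_hash, read_endpoints, read_layout, read_timeseries, write_table
from .performance import assemble_function_table
from .robustness import PerturbationSpace, RobustnessModel

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated configuration of a full analysis run."""

    timeseries: list[str]
    layouts: list[str]
    endpoints: list[str]
    outdir: str = "results"
    signal_kind: str = "GV"
    calibration: dict = field(default_factory=dict)
    r2_threshold: float = 0.99
    spline_smoothing: float | None = None
    metric: str = "fano"
    variance: str = "sample"  # "sample" (ddof=1) or "population" (ddof=0)
    equal_var: bool = False  # Student's instead of Welch's t test
    control: str | None = None
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.timeseries) == len(self.layouts) == len(self.endpoints)):
            raise PipelineError(
                "config: timeseries, layouts and endpoints must list one file per plate"
            )
        if not self.timeseries:
            raise PipelineError("config: no input plates listed")
        if self.signal_kind not in ("GV", "OD"):
            raise PipelineError("config: signal_kind must be GV or OD")
        if self.metric not in ("cv", "kitano", "fano"):
            raise PipelineError(f"config: unknown metric {self.metric!r}")
        if self.variance not in ("sample", "population"):
            raise PipelineError("config: variance must be 'sample' or 'population'")
        if not 0 < self.r2_threshold <= 1:
            raise PipelineError("config: r2_threshold must be in (0, 1]")
        for path in [*self.timeseries, *self.layouts, *self.endpoints]:
            if not Path(path).exists():
                raise PipelineError(f"config: input file not found: {path}")

    @property
    def ddof(self) -> int:
        return 1 if self.variance == "sample" else 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class RunBundle:
    """All tables produced by one pipeline run."""

    fits: pd.DataFrame
    functions: pd.DataFrame
    robustness: pd.DataFrame
    tests: pd.DataFrame
    tradeoffs: pd.DataFrame
    paths: dict


def run_all(config: RunConfig) -> RunBundle:
    """Execute every stage; any failure raises :class:`PipelineError` naming
    the stage and offending record."""
    cal = CalibrationModel.from_dict(config.calibration)
    blank = cal.gv_blank if config.signal_kind == "GV" else 0.0

    all_fits = []
    all_functions = []
    for ts_path, layout_path, ep_path in zip(
        config.timeseries, config.layouts, config.endpoints
    ):
        try:
            layout = read_layout(layout_path)
            wells = read_timeseries(ts_path, layout, signal_kind=config.signal_kind)
            endpoints = read_endpoints(ep_path)
        except Exception as exc:
            raise PipelineError(f"stage read ({ts_path}): {exc}") from exc
        try:
            fits = fit_plate(
                wells, blank=blank, smoothing=config.spline_smoothing,
                r2_threshold=config.r2_threshold,
            )
        except Exception as exc:
            raise PipelineError(f"stage fit-growth ({ts_path}): {exc}") from exc
        try:
            functions = assemble_function_table(fits, endpoints, layout, cal)
        except Exception as exc:
            raise PipelineError(f"stage compute-functions ({ts_path}): {exc}") from exc
        all_fits.append(fits_to_frame(fits))
        all_functions.append(functions)

    fits_df = pd.concat(all_fits, ignore_index=True)
    functions_df = pd.concat(all_functions, ignore_index=True)

    try:
        space = PerturbationSpace.from_table(functions_df, control=config.control)
        model = RobustnessModel(
            functions_df, space=space, metric=config.metric, ddof=config.ddof
        )
        results = model.fit()
    except Exception as exc:
        raise PipelineError(f"stage robustness: {exc}") from exc
    try:
        tests_df = results.pairwise_tests(alpha=config.alpha, equal_var=config.equal_var)
    except Exception as exc:
        raise PipelineError(f"stage test: {exc}") from exc
    try:
        tradeoffs_df = results.tradeoffs()
    except Exception as exc:
        raise PipelineError(f"stage tradeoffs: {exc}") from exc

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.to_dict()
    paths = {
        "fits": write_table(fits_df, outdir / "fits.csv", cfg),
        "functions": write_table(functions_df, outdir / "functions.csv", cfg),
        "robustness": write_table(results.table, outdir / "robustness.csv", cfg),
        "tests": write_table(tests_df, outdir / "tests.csv", cfg),
        "tradeoffs": write_table(tradeoffs_df, outdir / "tradeoffs.csv", cfg),
    }
    run_info = {
        "package": f"phenorobust {__version__}",
        "config": cfg,
        "config_hash": config_hash(cfg),
    }
    (outdir / "run.json").write_text(json.dumps(run_info, indent=2, default=str))
    paths["run"] = outdir / "run.json"
    logger.info("run complete: %d wells, %d function records", len(fits_df), len(functions_df))
    return RunBundle(
        fits=fits_df, functions=functions_df, robustness=results.table,
        tests=tests_df, tradeoffs=tradeoffs_df, paths=paths,
    )
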