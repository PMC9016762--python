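"""Synthetic plate phenomics experiments with known ground truth.

Generates complete experiments — per-strain plate time series in GV units,
plate layouts, endpoint tables — from strain and perturbation specifications,
so every pipeline stage (calibration, growth fitting, performance functions,
robustness scoring, strain comparison) can be validated against known
parameters.

The growth generator is a modified Gompertz curve in log-signal space
(Zwietering parametrization),

    y(t) = y0 + A · exp(−exp(μmax·e/A · (λ − t) + 1)),

whose λ coincides with the tangent-construction lag against the asymptotic
baseline y0, so rate and lag recovery are exact by design.  Because the
fitting contract estimates the baseline as the curve value at the first
timepoint — which sits above the asymptote by A·exp(−exp(μe·λ/A + 1)) when
the curve has not settled at t = 0 — the ground-truth table reports the
*effective* tangent lag

    λ_eff = λ + (y(0) − y0) / μmax

(closed form) as the recovery target, alongside the raw λ.

Noise model: multiplicative lognormal noise on the above-blank signal (plate
readers scale-noise), additive Gaussian noise on endpoint concentrations.
A single seed governs all streams through documented SeedSequence substream
derivation, making reruns byte-identical.

The default design emulates the study conditions: 3 strains (a laboratory
strain and two industrial bioethanol strains of differing robustness) × 29
single-component lignocellulosic-hydrolysate-like perturbations (including a
20 g/L glucose control) × 3 replicates, sampled every 30 min for 48 h.
Aldehyde-like perturbations degrade all five functions, pentose-like ones
leave them unchanged or improved, and organic acids mainly reduce cell dry
weight and biomass yield.  Each strain carries a *sensitivity* factor that
scales how strongly perturbation effects deviate from 1: lower sensitivity →
tighter responses across the space → higher Fano robustness, a built-in
ordering used by recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationModel
from .io import (
    ENDPOINT_COLUMNS,
    LAYOUT_COLUMNS,
    SUGARS,
    EndpointTable,
    PlateLayout,
    TimeSeriesWell,
    write_table,
    write_timeseries,
)

#: inoculation density of every simulated well
START_OD = 0.02

#: GV signal units per OD unit over the linear range (sets the signal scale)
GV_PER_OD = 40.0


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class StrainSpec:
    """Ground-truth strain parameters under the control condition.

    ``sensitivity`` scales how far perturbation multipliers deviate from 1
    for this strain (an effective multiplier of ``1 + (mult − 1)·sensitivity``
    is applied); strains with lower sensitivity respond more tightly across
    the perturbation space and are therefore more robust by construction.
    """

    name: str
    mu_max: float  # 1/h
    lag: float  # h
    ethanol_yield: float  # g/g consumed
    biomass_yield: float  # g/g consumed
    cdw_slope: float  # g/L per OD
    capacity_od: float = 5.0  # final OD under the control condition
    sensitivity: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mu_max", "lag", "ethanol_yield", "biomass_yield", "cdw_slope",
                     "capacity_od", "sensitivity"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{self.name}: {name} must be nonnegative")
        if not self.ethanol_yield < 1 or not self.biomass_yield < 1:
            raise SimulationError(f"{self.name}: yields must be < 1 g/g")


@dataclass(frozen=True)
class PerturbationSpec:
    """Multiplicative effects of one growth condition on the base parameters.

    Multipliers below 1 degrade the function (for lag, a multiplier above 1
    lengthens it, which is the degraded direction).  ``abolishes_growth``
    produces a flat noisy baseline trace.
    """

    condition_id: str
    mu_mult: float = 1.0
    lag_mult: float = 1.0
    cdw_mult: float = 1.0
    biomass_yield_mult: float = 1.0
    ethanol_yield_mult: float = 1.0
    consumption_mult: float = 1.0
    abolishes_growth: bool = False
    is_control: bool = False

    def __post_init__(self) -> None:
        for name in ("mu_mult", "lag_mult", "cdw_mult", "biomass_yield_mult",
                     "ethanol_yield_mult", "consumption_mult"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{self.condition_id}: {name} must be nonnegative")


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement noise levels (all ≥ 0; zero = noiseless)."""

    timeseries_sd: float = 0.02  # lognormal sd on the above-blank signal
    endpoint_sd: float = 0.1  # additive Gaussian sd on concentrations, g/L
    function_sd: float = 0.05  # relative lognormal sd for direct function values

    def __post_init__(self) -> None:
        for name in ("timeseries_sd", "endpoint_sd", "function_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be nonnegative")


NOISELESS = NoiseConfig(0.0, 0.0, 0.0)


def default_strains() -> list[StrainSpec]:
    """Three strains emulating the study design: a laboratory strain and two
    industrial bioethanol producers with distinct robustness/performance
    profiles."""
    return [
        # laboratory reference: middling everything
        StrainSpec("LAB-1", mu_max=0.35, lag=3.0, ethanol_yield=0.41,
                   biomass_yield=0.10, cdw_slope=0.50, capacity_od=5.0, sensitivity=1.0),
        # robust industrial producer: tight responses, lower mean yields
        StrainSpec("IND-R", mu_max=0.40, lag=2.5, ethanol_yield=0.38,
                   biomass_yield=0.09, cdw_slope=0.55, capacity_od=5.5, sensitivity=0.5),
        # high-performing but fragile industrial strain
        StrainSpec("IND-P", mu_max=0.38, lag=2.8, ethanol_yield=0.45,
                   biomass_yield=0.11, cdw_slope=0.52, capacity_od=5.2, sensitivity=1.5),
    ]


def default_perturbations() -> list[PerturbationSpec]:
    """The default 29-condition perturbation space (incl. the glucose
    control): severity-graded aldehydes, weak organic acids, pentoses and
    osmotic/solvent stresses typical of lignocellulosic hydrolysates."""
    perts: list[PerturbationSpec] = [
        PerturbationSpec("glucose_20gL", is_control=True),
    ]
    # aldehydes degrade every function; the harshest abolishes growth
    aldehydes = {"furfural": (1.0, 2.0, 3.0), "hmf": (1.0, 2.0, 3.0),
                 "vanillin": (0.5, 1.0, 1.5), "syringaldehyde": (0.5, 1.0)}
    for name, doses in aldehydes.items():
        for i, dose in enumerate(doses):
            sev = (i + 1) / len(doses)  # 1/3 .. 1 severity
            perts.append(
                PerturbationSpec(
                    f"{name}_{dose:g}gL",
                    mu_mult=1.0 - 0.45 * sev,
                    lag_mult=1.0 + 1.2 * sev,
                    cdw_mult=1.0 - 0.30 * sev,
                    biomass_yield_mult=1.0 - 0.25 * sev,
                    ethanol_yield_mult=1.0 - 0.20 * sev,
                    consumption_mult=1.0 - 0.30 * sev,
                )
            )
    perts.append(PerturbationSpec("furfural_4gL", mu_mult=0.0, abolishes_growth=True,
                                  cdw_mult=0.0, biomass_yield_mult=0.0,
                                  ethanol_yield_mult=0.0, consumption_mult=0.02))
    # weak acids mainly cost biomass
    acids = {"acetic_acid": (2.0, 4.0, 6.0), "formic_acid": (1.0, 2.0),
             "levulinic_acid": (2.0, 4.0), "lactic_acid": (2.0, 4.0)}
    for name, doses in acids.items():
        for i, dose in enumerate(doses):
            sev = (i + 1) / len(doses)
            perts.append(
                PerturbationSpec(
                    f"{name}_{dose:g}gL",
                    mu_mult=1.0 - 0.15 * sev,
                    lag_mult=1.0 + 0.5 * sev,
                    cdw_mult=1.0 - 0.35 * sev,
                    biomass_yield_mult=1.0 - 0.40 * sev,
                    ethanol_yield_mult=1.0 - 0.05 * sev,
                    consumption_mult=1.0 - 0.15 * sev,
                )
            )
    # pentoses: unchanged or mildly improved functions
    for name, dose, boost in (("xylose", 10, 0.05), ("xylose", 20, 0.08),
                              ("arabinose", 10, 0.02), ("arabinose", 20, 0.04)):
        perts.append(
            PerturbationSpec(
                f"{name}_{dose}gL",
                mu_mult=1.0 + boost,
                lag_mult=1.0,
                cdw_mult=1.0 + boost,
                biomass_yield_mult=1.0 + boost,
                ethanol_yield_mult=1.0 + boost / 2,
                consumption_mult=1.0,
            )
        )
    # osmotic / solvent stress
    perts += [
        PerturbationSpec("nacl_0.5M", mu_mult=0.70, lag_mult=1.8, cdw_mult=0.80,
                         biomass_yield_mult=0.80, ethanol_yield_mult=0.95,
                         consumption_mult=0.75),
        PerturbationSpec("ethanol_20gL", mu_mult=0.75, lag_mult=1.6, cdw_mult=0.85,
                         biomass_yield_mult=0.85, consumption_mult=0.8),
        PerturbationSpec("ethanol_40gL", mu_mult=0.45, lag_mult=2.5, cdw_mult=0.60,
                         biomass_yield_mult=0.60, ethanol_yield_mult=0.85,
                         consumption_mult=0.5),
    ]
    assert len(perts) == 29
    return perts


def _eff_mult(mult: float, sensitivity: float) -> float:
    return max(0.0, 1.0 + (mult - 1.0) * sensitivity)


@dataclass(frozen=True)
class EffectiveParams:
    """Ground-truth effective parameters of one strain × condition."""

    strain: str
    condition_id: str
    mu_max: float
    lag: float  # Gompertz λ
    lag_tangent: float  # effective tangent lag against the first-timepoint baseline
    amplitude: float  # log-signal amplitude A
    cdw_final: float
    ethanol_yield: float
    biomass_yield: float
    consumed: float
    abolished: bool


def effective_params(
    strain: StrainSpec,
    pert: PerturbationSpec,
    t0: float = 0.0,
    base_sugar: float = 20.0,
    base_consumed_fraction: float = 0.95,
) -> EffectiveParams:
    """Apply a perturbation's multipliers (scaled by the strain sensitivity)
    to the strain's base parameters."""
    s = strain.sensitivity
    if pert.abolishes_growth:
        mu = 0.0
        lag = np.nan
        lag_t = np.nan
        A = 0.0
        consumed = base_sugar * base_consumed_fraction * pert.consumption_mult
        cdw_final = START_OD * strain.cdw_slope
        y_eth = 0.0
        y_bio = 0.0
    else:
        mu = strain.mu_max * _eff_mult(pert.mu_mult, s)
        lag = strain.lag * _eff_mult(pert.lag_mult, s)
        consumed = base_sugar * base_consumed_fraction * _eff_mult(pert.consumption_mult, s)
        consumed = min(consumed, base_sugar)
        y_eth = strain.ethanol_yield * _eff_mult(pert.ethanol_yield_mult, s)
        y_bio = strain.biomass_yield * _eff_mult(pert.biomass_yield_mult, s)
        cdw_initial = START_OD * strain.cdw_slope
        cdw_final = cdw_initial + y_bio * consumed
        od_final = max(cdw_final / strain.cdw_slope, START_OD * 1.001)
        A = float(np.log(od_final / START_OD))
        if mu > 0:
            offset = A * np.exp(-np.exp(mu * np.e / A * (lag - t0) + 1.0))
            lag_t = lag + offset / mu
        else:
            lag_t = np.nan
    return EffectiveParams(
        strain=strain.name,
        condition_id=pert.condition_id,
        mu_max=mu,
        lag=lag,
        lag_tangent=lag_t,
        amplitude=A,
        cdw_final=cdw_final,
        ethanol_yield=y_eth,
        biomass_yield=y_bio,
        consumed=consumed,
        abolished=pert.abolishes_growth,
    )


def _rng(seed: int, *stream: int) -> np.random.Generator:
    """Deterministic substream: every noise source derives from the one run
    seed through a SeedSequence keyed by integer stream coordinates."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


def gompertz_log_signal(t: np.ndarray, y0: float, A: float, mu: float, lam: float) -> np.ndarray:
    """Modified Gompertz growth curve in log-signal space."""
    if A <= 0 or mu <= 0:
        return np.full_like(t, y0, dtype=float)
    return y0 + A * np.exp(-np.exp(mu * np.e / A * (lam - t) + 1.0))


def simulate_growth_curve(
    strain: StrainSpec,
    pert: PerturbationSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_grid: np.ndarray | None = None,
    cal: CalibrationModel | None = None,
    well_id: str = "A1",
    replicate: int = 1,
) -> TimeSeriesWell:
    """Simulate one well's GV trajectory (default 0–48 h every 30 min).

    The above-blank signal is ``GV_PER_OD × OD(t)`` with multiplicative
    lognormal noise of sd ``noise_sd``; growth-abolishing conditions give a
    flat noisy baseline at the inoculation density.
    """
    if noise_sd < 0:
        raise SimulationError("noise_sd must be nonnegative")
    cal = cal or CalibrationModel()
    t = np.arange(0.0, 48.0 + 1e-9, 0.5) if t_grid is None else np.asarray(t_grid, float)
    eff = effective_params(strain, pert, t0=float(t[0]))
    y0 = float(np.log(START_OD * GV_PER_OD))
    y = gompertz_log_signal(t, y0, eff.amplitude, eff.mu_max, eff.lag if eff.mu_max > 0 else 0.0)
    rng = _rng(seed, 1, replicate)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.size)
    gv = cal.gv_blank + np.exp(y)
    return TimeSeriesWell(
        well_id=well_id,
        times=t,
        values=gv,
        strain=strain.name,
        condition_id=pert.condition_id,
        replicate=replicate,
        signal_kind="GV",
    )


def simulate_endpoints(
    strain: StrainSpec,
    pert: PerturbationSpec,
    seed: int = 0,
    noise_sd: float = 0.0,
    base_sugar: float = 20.0,
    well_id: str = "A1",
    replicate: int = 1,
) -> dict:
    """Simulate one well's endpoint row (sugars in/out, ethanol, 48-h OD).

    Noiseless rows invert the yield equations exactly: the computed ethanol
    and biomass yields downstream equal the effective ground-truth yields.
    """
    eff = effective_params(strain, pert, base_sugar=base_sugar)
    rng = _rng(seed, 2, replicate)
    ethanol = eff.ethanol_yield * eff.consumed
    cdw_final = eff.cdw_final
    if noise_sd > 0:
        ethanol = max(0.0, ethanol + rng.normal(0.0, noise_sd))
        cdw_final = max(START_OD * strain.cdw_slope, cdw_final + rng.normal(0.0, noise_sd))
    row = {"well_id": well_id}
    for s in SUGARS:
        row[f"{s}_initial"] = base_sugar if s == "glucose" else 0.0
        row[f"{s}_final"] = (
            max(0.0, base_sugar - eff.consumed) if s == "glucose" else 0.0
        )
    row["ethanol"] = ethanol
    row["od600_48h"] = cdw_final / strain.cdw_slope
    return row


@dataclass(frozen=True)
class SimulatedPlate:
    strain: str
    wells: tuple[TimeSeriesWell, ...]
    layout: PlateLayout
    endpoints: EndpointTable


@dataclass(frozen=True)
class SimulatedExperiment:
    """One plate per strain, plus the ground-truth parameter table."""

    plates: tuple[SimulatedPlate, ...]
    ground_truth: pd.DataFrame
    layout: PlateLayout  # all plates combined (well ids prefixed by plate)
    seed: int

    @property
    def all_wells(self) -> list[TimeSeriesWell]:
        return [w for p in self.plates for w in p.wells]


def _well_name(index: int) -> str:
    return f"{'ABCDEFGH'[index // 12]}{index % 12 + 1}"


def simulate_experiment(
    strains: Sequence[StrainSpec] | None = None,
    perturbations: Sequence[PerturbationSpec] | None = None,
    n_replicates: int = 3,
    noise: NoiseConfig = NOISELESS,
    seed: int = 0,
    cal: CalibrationModel | None = None,
) -> SimulatedExperiment:
    """Simulate the full design: one 96-well plate per strain, each condition
    in replicate, with layouts, endpoint tables and the ground-truth table.
    """
    strains = list(strains) if strains is not None else default_strains()
    perturbations = (
        list(perturbations) if perturbations is not None else default_perturbations()
    )
    if n_replicates < 1:
        raise SimulationError("n_replicates must be at least 1")
    if len(perturbations) * n_replicates > 96:
        raise SimulationError("design does not fit a 96-well plate")
    cal = cal or CalibrationModel(
        cdw_slopes={s.name: s.cdw_slope for s in strains}
    )

    plates: list[SimulatedPlate] = []
    truth_rows: list[dict] = []
    combined_layout: list[dict] = []
    for si, strain in enumerate(strains):
        layout_rows: list[dict] = []
        wells: list[TimeSeriesWell] = []
        endpoint_rows: list[dict] = []
        idx = 0
        for pi, pert in enumerate(perturbations):
            eff = effective_params(strain, pert)
            truth_rows.append(dataclasses.asdict(eff))
            for rep in range(1, n_replicates + 1):
                well_id = _well_name(idx)
                idx += 1
                layout_rows.append(
                    {
                        "well_id": well_id,
                        "strain": strain.name,
                        "condition_id": pert.condition_id,
                        "replicate": rep,
                        "is_control": pert.is_control,
                    }
                )
                combined_layout.append(
                    {**layout_rows[-1], "well_id": f"{strain.name}:{well_id}"}
                )
                # distinct noise substream per (strain, condition, replicate)
                stream = rep + 100 * pi + 10_000 * si
                well = simulate_growth_curve(
                    strain, pert,
                    noise_sd=noise.timeseries_sd,
                    seed=seed, t_grid=None, cal=cal,
                    well_id=well_id, replicate=stream,
                )
                wells.append(dataclasses.replace(well, replicate=rep))
                ep = simulate_endpoints(
                    strain, pert, seed=seed,
                    noise_sd=noise.endpoint_sd,
                    well_id=well_id, replicate=stream,
                )
                endpoint_rows.append(ep)
        layout = PlateLayout(pd.DataFrame(layout_rows, columns=list(LAYOUT_COLUMNS)))
        endpoints = EndpointTable(
            pd.DataFrame(endpoint_rows, columns=list(ENDPOINT_COLUMNS))
        )
        plates.append(
            SimulatedPlate(strain=strain.name, wells=tuple(wells), layout=layout,
                           endpoints=endpoints)
        )
    ground_truth = pd.DataFrame(truth_rows)
    all_layout = PlateLayout(pd.DataFrame(combined_layout, columns=list(LAYOUT_COLUMNS)))
    return SimulatedExperiment(
        plates=tuple(plates), ground_truth=ground_truth, layout=all_layout, seed=seed
    )


def simulate_function_table(
    strains: Sequence[StrainSpec] | None = None,
    perturbations: Sequence[PerturbationSpec] | None = None,
    n_replicates: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Measurement-level shortcut: tidy function table of effective
    ground-truth values with relative lognormal measurement noise, bypassing
    curve simulation and refitting.  Used for metric-level recovery and
    ranking studies where the growth-fitting stage is not under test.
    """
    strains = list(strains) if strains is not None else default_strains()
    perturbations = (
        list(perturbations) if perturbations is not None else default_perturbations()
    )
    rows: list[dict] = []
    for si, strain in enumerate(strains):
        for pi, pert in enumerate(perturbations):
            eff = effective_params(strain, pert)
            truth = {
                "mu_max": eff.mu_max,
                "lag": eff.lag,
                "cdw": eff.cdw_final,
                "biomass_yield": eff.biomass_yield,
                "ethanol_yield": eff.ethanol_yield if eff.consumed > 0 else np.nan,
            }
            if eff.abolished:
                truth["lag"] = np.nan
                truth["mu_max"] = 0.0
            for rep in range(1, n_replicates + 1):
                rng = _rng(seed, 3, si, pi, rep)
                eps = rng.normal(0.0, noise_sd, size=len(truth)) if noise_sd > 0 else None
                for k, (function, value) in enumerate(truth.items()):
                    v = value
                    if eps is not None and not np.isnan(v):
                        v = v * float(np.exp(eps[k]))
                    rows.append(
                        {
                            "strain": strain.name,
                            "function": function,
                            "condition_id": pert.condition_id,
                            "replicate": rep,
                            "value": v,
                        }
                    )
    return pd.DataFrame(rows)


def write_experiment(exp: SimulatedExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated experiment as the CSV set the readers consume, one
    time-series/layout/endpoint file per plate plus ground_truth.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for plate in exp.plates:
        tag = plate.strain.replace("/", "_")
        paths[f"timeseries_{tag}"] = write_timeseries(
            plate.wells, outdir / f"timeseries_{tag}.csv"
        )
        paths[f"layout_{tag}"] = write_table(plate.layout.table, outdir / f"layout_{tag}.csv")
        paths[f"endpoints_{tag}"] = write_table(
            plate.endpoints.table, outdir / f"endpoints_{tag}.csv"
        )
    paths["ground_truth"] = write_table(exp.ground_truth, outdir / "ground_truth.csv")
    return paths
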