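import numpy as np
import pandas as pd
import pytest

from phenorobust import (
    CalibrationModel,
    NoiseConfig,
    PerturbationSpec,
    StrainSpec,
    default_strains,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def cal() -> CalibrationModel:
    return CalibrationModel(cdw_slopes={s.name: s.cdw_slope for s in default_strains()})


@pytest.fixture(scope="session")
def small_design():
    """2 strains × 4 perturbations (incl. control) × 2 replicates — a fast
    stand-in for the full plate design."""
    strains = [
        StrainSpec("S-tight", mu_max=0.35, lag=3.0, ethanol_yield=0.40,
                   biomass_yield=0.10, cdw_slope=0.50, sensitivity=0.5),
        StrainSpec("S-loose", mu_max=0.35, lag=3.0, ethanol_yield=0.40,
                   biomass_yield=0.10, cdw_slope=0.50, sensitivity=1.5),
    ]
    perts = [
        PerturbationSpec("glucose_20gL", is_control=True),
        PerturbationSpec("stress_mild", mu_mult=0.9, lag_mult=1.2, cdw_mult=0.95,
                         biomass_yield_mult=0.95, ethanol_yield_mult=0.97,
                         consumption_mult=0.95),
        PerturbationSpec("stress_harsh", mu_mult=0.6, lag_mult=1.8, cdw_mult=0.7,
                         biomass_yield_mult=0.7, ethanol_yield_mult=0.85,
                         consumption_mult=0.7),
        PerturbationSpec("boost", mu_mult=1.05, cdw_mult=1.05,
                         biomass_yield_mult=1.05, ethanol_yield_mult=1.02),
    ]
    return strains, perts


@pytest.fixture(scope="session")
def noiseless_small_experiment(small_design):
    strains, perts = small_design
    return simulate_experiment(strains, perts, n_replicates=2, seed=11)


@pytest.fixture()
def simple_function_table() -> pd.DataFrame:
    """One strain, 3 perturbations × 2 replicates with hand-pickable values."""
    rows = []
    values = {("p1", 1): 1.0, ("p2", 1): 2.0, ("p3", 1): 3.0,
              ("p1", 2): 1.5, ("p2", 2): 2.0, ("p3", 2): 2.5}
    for (cond, rep), v in values.items():
        rows.append({"strain": "A", "function": "mu_max", "condition_id": cond,
                     "replicate": rep, "value": v})
    return pd.DataFrame(rows)
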