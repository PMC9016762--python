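import numpy as np
import pandas as pd
import pytest

from phenorobust import (
    CalibrationModel,
    GrowthFit,
    assemble_function_table,
    biomass_yield,
    cdw_from_od,
    consumed_sugars,
    ethanol_yield,
)
from phenorobust.io import ENDPOINT_COLUMNS, EndpointTable, PlateLayout
from phenorobust.performance import PerformanceError


def _endpoint_row(**kw):
    row = {c: 0.0 for c in ENDPOINT_COLUMNS[1:]}
    row["well_id"] = kw.pop("well_id", "A1")
    row.update(kw)
    return row


class TestConsumedSugars:
    def test_two_sugar_arithmetic(self):
        row = _endpoint_row(glucose_initial=20, glucose_final=2,
                            xylose_initial=10, xylose_final=10)
        assert consumed_sugars(row) == pytest.approx(18.0)

    def test_overshoot_contributes_zero_with_warning(self):
        row = _endpoint_row(glucose_initial=20, glucose_final=2,
                            xylose_initial=10, xylose_final=11)
        with pytest.warns(UserWarning, match="xylose"):
            assert consumed_sugars(row) == pytest.approx(18.0)

    def test_five_sugars_sum(self):
        kw = {}
        for s in ("glucose", "mannose", "xylose", "galactose", "arabinose"):
            kw[f"{s}_initial"], kw[f"{s}_final"] = 2.0, 1.0
        assert consumed_sugars(_endpoint_row(**kw)) == pytest.approx(5.0)

    def test_no_substrate_rejected(self):
        with pytest.raises(PerformanceError, match="substrate"):
            consumed_sugars(_endpoint_row())


class TestYields:
    def test_ethanol_yield_arithmetic(self):
        assert ethanol_yield(8.0, 20.0) == pytest.approx(0.40)

    def test_zero_ethanol(self):
        assert ethanol_yield(0.0, 20.0) == 0.0

    def test_nothing_consumed_is_missing(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(ethanol_yield(1.0, 0.0))

    def test_biomass_yield_arithmetic(self):
        assert biomass_yield(1.02, 0.02, 10.0) == pytest.approx(0.10)

    def test_no_growth_yields_zero(self):
        assert biomass_yield(0.5, 0.5, 10.0) == 0.0

    def test_negative_biomass_floors_at_zero(self):
        with pytest.warns(UserWarning, match="floored"):
            assert biomass_yield(0.4, 0.5, 10.0) == 0.0


class TestCdw:
    def test_linear_map(self):
        assert cdw_from_od(2.0, 0.5) == pytest.approx(1.0)
        assert cdw_from_od(0.0, 0.5) == 0.0

    def test_per_strain_slopes_differ(self):
        assert cdw_from_od(2.0, 0.5) != cdw_from_od(2.0, 0.6)

    def test_invalid_inputs(self):
        with pytest.raises(PerformanceError):
            cdw_from_od(-1.0, 0.5)
        with pytest.raises(PerformanceError):
            cdw_from_od(1.0, 0.0)


def _fits_and_tables(n_conditions=2, n_reps=3, fail_well=None):
    cal = CalibrationModel(cdw_slopes={"S1": 0.5})
    fits, layout_rows, ep_rows = [], [], []
    idx = 0
    for c in range(n_conditions):
        for r in range(1, n_reps + 1):
            well = f"A{idx + 1}"
            idx += 1
            grew = well != fail_well
            fits.append(GrowthFit(
                well_id=well, mu_max=0.3 if grew else 0.0,
                lag=2.0 if grew else np.nan, r_squared=0.999 if grew else 0.5,
                y0=0.0, inflection_time=8.0, inflection_value=2.0, grew=grew,
                strain="S1", condition_id=f"c{c}", replicate=r,
            ))
            layout_rows.append((well, "S1", f"c{c}", r, c == 0))
            ep_rows.append(_endpoint_row(
                well_id=well, glucose_initial=20.0, glucose_final=1.0,
                ethanol=7.6, od600_48h=2.0,
            ))
    layout = PlateLayout(pd.DataFrame(
        layout_rows, columns=["well_id", "strain", "condition_id", "replicate", "is_control"]
    ))
    endpoints = EndpointTable(pd.DataFrame(ep_rows))
    return fits, endpoints, layout, cal


class TestAssembleFunctionTable:
    def test_five_records_per_well(self):
        fits, ep, layout, cal = _fits_and_tables()
        table = assemble_function_table(fits, ep, layout, cal)
        assert len(table) == 5 * 6
        assert set(table["function"]) == {
            "mu_max", "lag", "cdw", "biomass_yield", "ethanol_yield"
        }

    def test_qc_failed_well_has_missing_lag_zero_mu(self):
        fits, ep, layout, cal = _fits_and_tables(fail_well="A1")
        table = assemble_function_table(fits, ep, layout, cal)
        sub = table[(table["condition_id"] == "c0") & (table["replicate"] == 1)]
        assert sub.loc[sub["function"] == "mu_max", "value"].item() == 0.0
        assert np.isnan(sub.loc[sub["function"] == "lag", "value"].item())

    def test_empty_inputs_give_empty_table(self):
        _, ep, layout, cal = _fits_and_tables()
        assert assemble_function_table([], ep, layout, cal).empty

    def test_well_without_endpoints_gets_growth_records_only(self):
        fits, ep, layout, cal = _fits_and_tables()
        ep = EndpointTable(ep.table[ep.table["well_id"] != "A1"].reset_index(drop=True))
        with pytest.warns(UserWarning, match="A1"):
            table = assemble_function_table(fits, ep, layout, cal)
        a1 = table[(table["condition_id"] == "c0") & (table["replicate"] == 1)]
        assert set(a1["function"]) == {"mu_max", "lag"}

    def test_yields_match_endpoint_arithmetic(self):
        fits, ep, layout, cal = _fits_and_tables()
        table = assemble_function_table(fits, ep, layout, cal)
        eth = table.loc[table["function"] == "ethanol_yield", "value"]
        # 7.6 g/L ethanol over 19 g/L consumed
        assert np.allclose(eth, 0.4)
        bio = table.loc[table["function"] == "biomass_yield", "value"]
        # (2.0 OD × 0.5 − 0.02 × 0.5) / 19
        assert np.allclose(bio, (1.0 - 0.01) / 19.0)
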