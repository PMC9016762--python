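import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenorobust import (
    PerturbationSpace,
    RobustnessModel,
    cv_robustness,
    fano_robustness,
    kitano_robustness,
    normalization_mean,
    robustness_with_sem,
    simulate_function_table,
)
from phenorobust.robustness import RobustnessError

positive_values = st.lists(
    st.floats(min_value=0.1, max_value=100.0), min_size=2, max_size=12
)


class TestCv:
    def test_hand_computation(self):
        # sample σ of {2,4,6} is 2, mean 4
        assert cv_robustness([2.0, 4.0, 6.0]) == pytest.approx(0.5)

    def test_constant_values(self):
        assert cv_robustness([3.0, 3.0, 3.0]) == 0.0

    def test_exceeds_one_when_sd_beats_mean(self):
        assert cv_robustness([0.01, 0.01, 5.0]) > 1.0

    def test_zero_mean_is_undefined(self):
        assert np.isnan(cv_robustness([-1.0, 1.0]))


class TestKitano:
    def test_identity_ratio(self):
        assert kitano_robustness([2.0, 2.0, 2.0], control_value=2.0) == 1.0

    def test_symmetric_deviations_cancel(self):
        # {1, 3} against control 2: deviations cancel to exactly 1.0
        assert kitano_robustness([1.0, 3.0], control_value=2.0) == 1.0

    def test_better_than_control_scores_above_one(self):
        assert kitano_robustness([3.0, 4.0], control_value=2.0) > 1.0

    def test_missing_control_rejected(self):
        with pytest.raises(RobustnessError, match="control"):
            kitano_robustness([1.0, 2.0], control_value=np.nan)


class TestFano:
    def test_two_strain_hand_computation(self):
        # A {1,2,3}: sample σ²=1, x̄=2, Fano=1/2; m pooled over both strains = 2
        m = np.mean([1, 2, 3, 2, 2, 2])
        assert fano_robustness([1.0, 2.0, 3.0], m=m) == pytest.approx(-0.25)
        assert fano_robustness([2.0, 2.0, 2.0], m=m) == 0.0

    def test_zero_dispersion_is_maximum(self):
        assert fano_robustness([5.0, 5.0, 5.0, 5.0], m=5.0) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(values=positive_values)
    def test_upper_bound_zero(self, values):
        r = fano_robustness(values, m=float(np.mean(values)))
        assert r <= 0.0
        if np.var(values, ddof=1) == 0:
            assert r == 0.0
        else:
            assert r < 0.0

    @settings(deadline=None, derandomize=True)
    @given(values=positive_values, k=st.sampled_from([1e-3, 0.1, 10.0, 1e3]))
    def test_scale_invariance_with_m_recomputed(self, values, k):
        v = np.asarray(values)
        base = fano_robustness(v, m=float(v.mean()))
        scaled = fano_robustness(k * v, m=float(k * v.mean()))
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)

    def test_duplication_exact_with_population_variance(self):
        v = np.array([1.0, 2.0, 4.0])
        m = 2.0
        base = fano_robustness(v, m=m, ddof=0)
        doubled = fano_robustness(np.tile(v, 2), m=m, ddof=0)
        assert doubled == pytest.approx(base, rel=1e-12)
        # sample variance drifts by the documented O(1/n) ddof effect
        drift = abs(fano_robustness(np.tile(v, 2), m=m) - fano_robustness(v, m=m))
        assert 0 < drift < abs(base) * 0.3


class TestOracleEquivalence:
    @settings(deadline=None, derandomize=True)
    @given(
        values=st.lists(st.integers(min_value=1, max_value=9), min_size=2, max_size=6)
    )
    def test_metrics_match_brute_force(self, values):
        v = np.asarray(values, float)
        n, mean = v.size, v.mean()
        var = float(sum((x - mean) ** 2 for x in v) / (n - 1))
        assert cv_robustness(v) == pytest.approx(np.sqrt(var) / mean, abs=1e-12)
        assert fano_robustness(v, m=mean) == pytest.approx(-(var / mean) / mean, abs=1e-12)
        assert kitano_robustness(v, control_value=2.0) == pytest.approx(
            float(sum(x / 2.0 for x in v) / n), abs=1e-12
        )


class TestNormalizationMean:
    def test_equal_counts_pool_to_midpoint(self):
        df = pd.DataFrame({
            "strain": ["A"] * 2 + ["B"] * 2,
            "function": "f",
            "condition_id": ["p1", "p2"] * 2,
            "replicate": 1,
            "value": [0.5, 1.5, 2.5, 3.5],
        })
        assert normalization_mean(df, "f") == pytest.approx(2.0)

    def test_unbalanced_missingness_is_count_weighted(self):
        df = pd.DataFrame({
            "strain": ["A", "A", "A", "B"],
            "function": "f",
            "condition_id": ["p1", "p2", "p3", "p1"],
            "replicate": 1,
            "value": [1.0, 2.0, 3.0, np.nan],
        })
        assert normalization_mean(df, "f") == pytest.approx(2.0)

    def test_empty_rejected(self):
        df = pd.DataFrame({"strain": [], "function": [], "condition_id": [],
                           "replicate": [], "value": []})
        with pytest.raises(RobustnessError):
            normalization_mean(df, "f")


def _slice_table(slice_specs, m_center=2.0):
    """Function table where replicate r's values are {c−d_r, c+d_r}; with all
    centers equal to m_center the pooled m is m_center and each slice's Fano
    R is −d_r²/2 for m_center = 2."""
    rows = []
    for rep, d in enumerate(slice_specs, start=1):
        for cond, v in zip(("p1", "p2"), (m_center - d, m_center + d)):
            rows.append({"strain": "A", "function": "f", "condition_id": cond,
                         "replicate": rep, "value": v})
    return pd.DataFrame(rows)


class TestRobustnessWithSem:
    def test_identical_slices_have_zero_sem(self):
        df = _slice_table([0.5, 0.5, 0.5])
        space = PerturbationSpace(("p1", "p2"))
        res = robustness_with_sem(df, "A", "f", space, metric="fano")
        assert res.sem == pytest.approx(0.0)
        assert res.n_replicates == 3

    def test_sem_hand_computation(self):
        # slice Fano R values −0.2, −0.3, −0.4 → mean −0.3, SEM 0.0577
        ds = [np.sqrt(0.4), np.sqrt(0.6), np.sqrt(0.8)]
        df = _slice_table(ds)
        space = PerturbationSpace(("p1", "p2"))
        res = robustness_with_sem(df, "A", "f", space, metric="fano", m=2.0)
        assert sorted(res.slice_values) == pytest.approx([-0.4, -0.3, -0.2])
        assert res.R == pytest.approx(-0.3)
        assert res.sem == pytest.approx(0.05773, abs=1e-4)

    def test_missing_replicate_drops_to_two_slices(self):
        df = _slice_table([0.5, 0.6, 0.7])
        df.loc[df["replicate"] == 3, "value"] = np.nan
        space = PerturbationSpace(("p1", "p2"))
        res = robustness_with_sem(df, "A", "f", space, metric="fano")
        assert res.n_replicates == 2

    def test_single_slice_has_missing_sem(self):
        df = _slice_table([0.5])
        space = PerturbationSpace(("p1", "p2"))
        res = robustness_with_sem(df, "A", "f", space, metric="fano")
        assert np.isnan(res.sem) and res.n_replicates == 1


class TestPerturbationSpace:
    def test_needs_two_conditions(self):
        with pytest.raises(RobustnessError):
            PerturbationSpace(("only",))

    def test_weights_must_sum_to_one(self):
        with pytest.raises(RobustnessError, match="sum to 1"):
            PerturbationSpace(("a", "b"), weights={"a": 0.6, "b": 0.6})

    def test_control_excluded_from_perturbed(self):
        sp = PerturbationSpace(("ctrl", "a", "b"), control="ctrl")
        assert sp.perturbed == ("a", "b")


class TestRobustnessModel:
    def test_full_design_result_count(self):
        table = simulate_function_table(seed=2, noise_sd=0.05)
        results = RobustnessModel(table, metric="fano").fit()
        assert len(results.results) == 3 * 5

    def test_builtin_dispersion_ordering_detected(self):
        table = simulate_function_table(seed=2, noise_sd=0.05)
        results = RobustnessModel(table, metric="fano").fit()
        for fn in ("mu_max", "cdw"):
            r = {s: results.get(s, fn).R for s in ("IND-R", "LAB-1", "IND-P")}
            assert r["IND-R"] > r["LAB-1"] > r["IND-P"]

    def test_kitano_requires_control(self):
        table = simulate_function_table(seed=2, noise_sd=0.0)
        with pytest.raises(RobustnessError, match="control"):
            RobustnessModel(table, metric="kitano").fit()

    def test_kitano_with_control_runs(self):
        table = simulate_function_table(seed=2, noise_sd=0.0)
        space = PerturbationSpace.from_table(table, control="glucose_20gL")
        results = RobustnessModel(table, space=space, metric="kitano").fit()
        mu_r = results.get("LAB-1", "mu_max").R
        assert 0 < mu_r < 1.2

    def test_summary_lists_every_result(self):
        table = simulate_function_table(seed=2, noise_sd=0.0)
        text = RobustnessModel(table).fit().summary()
        assert "mu_max" in text and "IND-R" in text
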