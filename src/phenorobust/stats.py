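"""Strain comparison statistics and robustness–performance trade-offs.

Robustness differences between strains are tested with an unpaired,
two-sided t test on the replicate-slice R values (Welch's unequal-variance
form by default — the safer choice for n = 3 heteroscedastic slices;
Student's form available by flag).  p-values are adjusted with the
Holm–Bonferroni step-down method, with the family taken as all strain pairs
within one function.

Trade-off records pair each strain × function's mean performance over the
perturbation space with its robustness score, computed from exactly the same
records.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class StatsError(ValueError):
    pass


def pairwise_strain_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float, bool]:
    """Unpaired two-sided t test between two strains' replicate-slice R
    values.

    Returns ``(t, p, degenerate)``.  When both groups have zero variance the
    t statistic is undefined: equal means report p = 1, unequal means report
    the limiting p ≈ 0, both flagged degenerate.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise StatsError("need at least 2 replicate-slice values per strain")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, True
        return np.inf if a.mean() > b.mean() else -np.inf, 0.0, True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p), False


def holm_bonferroni(pvalues: Sequence[float]) -> np.ndarray:
    """Holm–Bonferroni step-down adjustment (monotone, capped at 1,
    adjusted ≥ raw)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def pairwise_strain_tests(
    robustness_results,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """All strain-pairwise robustness comparisons, Holm-adjusted within each
    function's family of pairs."""
    rows: list[dict] = []
    by_function: dict[str, list[int]] = {}
    for r in robustness_results.results:
        by_function.setdefault(r.function, []).append(r)

    for function, results in by_function.items():
        usable = [r for r in results if len(r.slice_values) >= 2]
        fam_rows = []
        for ra, rb in itertools.combinations(usable, 2):
            t, p, degenerate = pairwise_strain_test(
                ra.slice_values, rb.slice_values, equal_var=equal_var
            )
            fam_rows.append(
                {
                    "function": function,
                    "strain_a": ra.strain,
                    "strain_b": rb.strain,
                    "t": t,
                    "pvalue": p,
                    "degenerate": degenerate,
                }
            )
        if fam_rows:
            adj = holm_bonferroni([r["pvalue"] for r in fam_rows])
            for row, padj in zip(fam_rows, adj):
                row["pvalue_adjusted"] = float(padj)
                row["significant"] = bool(padj < alpha)
            rows.extend(fam_rows)
    return pd.DataFrame(
        rows,
        columns=[
            "function", "strain_a", "strain_b", "t",
            "pvalue", "pvalue_adjusted", "significant", "degenerate",
        ],
    )


def tradeoff_table(function_table: pd.DataFrame, robustness_results) -> pd.DataFrame:
    """One record per strain × function pairing mean performance (over
    perturbations and replicates, missing values dropped) with robustness R
    and the SEM of each."""
    space = robustness_results.model.space
    analysed = function_table[function_table["condition_id"].isin(space.perturbed)]
    rows: list[dict] = []
    for r in robustness_results.results:
        sub = analysed[
            (analysed["strain"] == r.strain) & (analysed["function"] == r.function)
        ]["value"].dropna()
        if sub.empty:
            warnings.warn(
                f"no performance values for {r.strain}/{r.function}; omitted",
                stacklevel=2,
            )
            continue
        if np.isnan(r.R):
            warnings.warn(
                f"robustness undefined for {r.strain}/{r.function}; omitted",
                stacklevel=2,
            )
            continue
        perf_sem = (
            float(sub.std(ddof=1) / np.sqrt(sub.size)) if sub.size >= 2 else np.nan
        )
        rows.append(
            {
                "strain": r.strain,
                "function": r.function,
                "performance": float(sub.mean()),
                "performance_sem": perf_sem,
                "robustness": r.R,
                "robustness_sem": r.sem,
                "metric": r.metric,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "strain", "function", "performance", "performance_sem",
            "robustness", "robustness_sem", "metric",
        ],
    )
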