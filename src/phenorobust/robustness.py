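"""Robustness scoring of cellular functions over a perturbation space.

Robustness R of a function *i* of strain *S* over a perturbation space *P*
is scored with one of three metrics:

* **CV** — coefficient of variation σ/x̄ (dimensionless; 0 = perfectly
  stable, larger = less robust);
* **Kitano** — frequency-weighted mean ratio of perturbed to control
  performance, Σ_p ψ(p)·f(p)/f(0) (1 = control-like behaviour; requires a
  control condition such as 20 g/L glucose);
* **Fano** — the negative mean-normalized Fano factor,
  R = −(σ²/x̄)/m, where m is the mean of the function pooled across all
  strains, perturbations and replicates of the analysed dataset.  R is
  bounded above by 0 (perfect stability) and is dimensionless and
  frequency-independent; it is the recommended headline metric.

Because m is recomputed per analysed dataset, Fano R values are always
relative to the investigated data case; m is therefore stored with every
result.

The headline R and its uncertainty follow a replicate-slice scheme: R is
computed separately on each replicate's values across the perturbation space
and reported as the mean of the slice values with their standard error
(n = number of replicates).  A pooled mode (all replicates together, no SEM)
is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .performance import FUNCTION_UNITS

logger = logging.getLogger(__name__)

Metric = Literal["cv", "kitano", "fano"]

#: orientation metadata: does a larger R mean a more robust function?
HIGHER_IS_MORE_ROBUST: dict[str, bool] = {"cv": False, "kitano": True, "fano": True}


class RobustnessError(ValueError):
    pass


@dataclass(frozen=True)
class PerturbationSpace:
    """The set of conditions over which robustness is evaluated.

    Frequencies ψ(p) default to equal and must sum to 1; a control condition
    is required by the Kitano metric only.  When the control is a member of
    the space it is excluded from the perturbed set and serves as the
    reference f(0).
    """

    conditions: tuple[str, ...]
    weights: Mapping[str, float] | None = None
    control: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(str(c) for c in self.conditions))
        if len(set(self.conditions)) != len(self.conditions):
            raise RobustnessError("duplicate condition ids in perturbation space")
        if len(self.conditions) < 2:
            raise RobustnessError("a perturbation space needs at least 2 conditions")
        if self.weights is not None:
            w = np.array([self.weights[c] for c in self.perturbed], dtype=float)
            if (w <= 0).any():
                raise RobustnessError("perturbation frequencies must be positive")
            if abs(w.sum() - 1.0) > 1e-9:
                raise RobustnessError(f"frequencies must sum to 1, got {w.sum()!r}")

    @property
    def perturbed(self) -> tuple[str, ...]:
        """Conditions excluding the control reference."""
        return tuple(c for c in self.conditions if c != self.control)

    def frequency(self, condition: str) -> float:
        if self.weights is None:
            return 1.0 / len(self.perturbed)
        return float(self.weights[condition])

    @classmethod
    def from_table(
        cls, function_table: pd.DataFrame, control: str | None = None
    ) -> "PerturbationSpace":
        conds = tuple(pd.unique(function_table["condition_id"]).astype(str))
        return cls(conditions=conds, control=control)


@dataclass(frozen=True)
class RobustnessResult:
    """Robustness score of one strain × function.

    ``sem`` is missing when fewer than 2 replicate slices were usable;
    ``m`` (the normalization mean) is set for the Fano metric only.
    ``n_perturbations`` counts perturbations that contributed at least one
    value; ``n_missing`` the remainder of the space.
    """

    strain: str
    function: str
    metric: str
    R: float
    sem: float
    n_perturbations: int
    n_missing: int
    n_replicates: int
    m: float = np.nan
    higher_is_more_robust: bool = True
    degenerate: bool = False
    slice_values: tuple[float, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# elementary metric formulas
# ---------------------------------------------------------------------------

def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[~np.isnan(v)]


def cv_robustness(values, ddof: int = 1) -> float:
    """Coefficient of variation σ/x̄ (sample standard deviation by default).

    Undefined (nan) when the mean is 0.
    """
    v = _clean(values)
    if v.size < 2:
        raise RobustnessError("CV needs at least 2 non-missing values")
    mean = v.mean()
    if mean == 0:
        return np.nan
    return float(np.std(v, ddof=ddof) / mean)


def kitano_robustness(values, control_value: float, weights=None) -> float:
    """Frequency-weighted mean ratio of perturbed to control performance,
    R = Σ_p ψ(p)·f(p)/f(0) with ψ summing to 1 (equal by default)."""
    v = np.asarray(values, dtype=float)
    keep = ~np.isnan(v)
    v = v[keep]
    if v.size == 0:
        raise RobustnessError("Kitano robustness needs at least 1 perturbed value")
    if control_value is None or np.isnan(control_value):
        raise RobustnessError("a control condition value is required for the Kitano metric")
    if control_value == 0:
        return np.nan
    if weights is None:
        w = np.full(v.size, 1.0 / v.size)
    else:
        w = np.asarray(weights, dtype=float)[keep]
        w = w / w.sum()  # renormalize after dropping missing values
    return float(np.sum(w * v / control_value))


def fano_robustness(values, m: float, ddof: int = 1) -> float:
    """Negative mean-normalized Fano factor, R = −(σ²/x̄)/m ≤ 0.

    Equals 0 iff the values have zero dispersion; undefined (nan) for
    nonpositive x̄ or m.
    """
    v = _clean(values)
    if v.size < 2:
        raise RobustnessError("Fano robustness needs at least 2 non-missing values")
    mean = v.mean()
    if mean <= 0 or m <= 0:
        return np.nan
    r = float(-(np.var(v, ddof=ddof) / mean) / m)
    return 0.0 if r == 0 else r  # avoid signed zero at the upper bound


def normalization_mean(function_table: pd.DataFrame, function: str) -> float:
    """Pooled mean m of a function's non-missing values over every strain,
    perturbation and replicate of the analysed dataset."""
    vals = function_table.loc[function_table["function"] == function, "value"].dropna()
    if vals.empty:
        raise RobustnessError(f"no non-missing values for function {function!r}")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# replicate-slice scoring
# ---------------------------------------------------------------------------

def robustness_with_sem(
    function_table: pd.DataFrame,
    strain: str,
    function: str,
    space: PerturbationSpace,
    metric: Metric = "fano",
    m: float | None = None,
    ddof: int = 1,
    pooled: bool = False,
) -> RobustnessResult:
    """Score one strain × function over the space.

    In the default replicate-slice mode, R is computed on each replicate's
    values across the perturbations; the reported R is the mean of the slice
    values and ``sem`` their standard error.  Perturbations missing within a
    slice are dropped from that slice.  ``pooled=True`` instead computes a
    single R on all values with no SEM.
    """
    sub = function_table[
        (function_table["strain"] == strain)
        & (function_table["function"] == function)
        & (function_table["condition_id"].isin(space.perturbed))
    ]
    if metric == "fano" and m is None:
        m = normalization_mean(
            function_table[function_table["condition_id"].isin(space.perturbed)], function
        )
    control_by_rep: dict[int, float] = {}
    if metric == "kitano":
        if space.control is None:
            raise RobustnessError(
                "a control condition (e.g. 20 g/L glucose) is needed for the Kitano metric"
            )
        ctrl = function_table[
            (function_table["strain"] == strain)
            & (function_table["function"] == function)
            & (function_table["condition_id"] == space.control)
        ]
        if ctrl.empty:
            raise RobustnessError(
                f"no measurements of control condition {space.control!r} for {strain}/{function}"
            )
        control_by_rep = dict(zip(ctrl["replicate"].astype(int), ctrl["value"].astype(float)))

    def score(values: pd.Series, replicate: int | None) -> float:
        if metric == "cv":
            return cv_robustness(values, ddof=ddof)
        if metric == "fano":
            return fano_robustness(values, m=m, ddof=ddof)
        if replicate is None:
            control = float(np.nanmean(list(control_by_rep.values())))
        else:
            control = control_by_rep.get(replicate, np.nan)
            if np.isnan(control):
                control = float(np.nanmean(list(control_by_rep.values())))
        return kitano_robustness(values, control_value=control)

    used_perturbations = set(sub.loc[sub["value"].notna(), "condition_id"])
    n_pert = len(used_perturbations)
    n_missing = len(space.perturbed) - n_pert

    if pooled:
        vals = sub["value"].astype(float)
        R = score(vals.to_numpy(), None)
        return RobustnessResult(
            strain=strain, function=function, metric=metric, R=R, sem=np.nan,
            n_perturbations=n_pert, n_missing=n_missing,
            n_replicates=int(sub["replicate"].nunique()),
            m=m if metric == "fano" else np.nan,
            higher_is_more_robust=HIGHER_IS_MORE_ROBUST[metric],
            degenerate=bool(np.isnan(R)),
        )

    slice_R: list[float] = []
    for rep, grp in sub.groupby("replicate"):
        vals = grp["value"].astype(float).dropna()
        dropped = len(space.perturbed) - vals.size
        if dropped:
            logger.debug(
                "%s/%s replicate %s: %d perturbations dropped (missing values)",
                strain, function, rep, dropped,
            )
        if vals.size < 2:
            logger.info("%s/%s replicate %s unusable (<2 values)", strain, function, rep)
            continue
        slice_R.append(score(vals.to_numpy(), int(rep)))

    slice_arr = np.array(slice_R, dtype=float)
    ok = slice_arr[~np.isnan(slice_arr)]
    if ok.size == 0:
        R, sem, degenerate = np.nan, np.nan, True
    else:
        R = float(ok.mean())
        sem = float(np.std(ok, ddof=1) / np.sqrt(ok.size)) if ok.size >= 2 else np.nan
        degenerate = ok.size < slice_arr.size
    return RobustnessResult(
        strain=strain, function=function, metric=metric, R=R, sem=sem,
        n_perturbations=n_pert, n_missing=n_missing, n_replicates=ok.size,
        m=m if metric == "fano" else np.nan,
        higher_is_more_robust=HIGHER_IS_MORE_ROBUST[metric],
        degenerate=degenerate,
        slice_values=tuple(ok.tolist()),
    )


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class RobustnessModel:
    """Robustness analysis of a tidy function table.

    Parameters
    ----------
    function_table
        Tidy records (strain, function, condition_id, replicate, value).
    space
        The perturbation space; defaults to every condition present in the
        table (flagging none as control).
    metric
        ``"fano"`` (default), ``"cv"`` or ``"kitano"``.
    ddof
        Delta degrees of freedom of the variance estimator (1 = sample
        variance, default; 0 = population variance).
    pooled
        Pool replicates into a single R instead of the replicate-slice
        scheme.

    Examples
    --------
    >>> model = RobustnessModel.from_dataframe(table, metric="fano")
    >>> results = model.fit()
    >>> print(results.summary())
    """

    def __init__(
        self,
        function_table: pd.DataFrame,
        space: PerturbationSpace | None = None,
        metric: Metric = "fano",
        ddof: int = 1,
        pooled: bool = False,
    ) -> None:
        if metric not in HIGHER_IS_MORE_ROBUST:
            raise RobustnessError(f"unknown metric {metric!r}")
        if ddof not in (0, 1):
            raise RobustnessError("ddof must be 0 (population) or 1 (sample)")
        required = {"strain", "function", "condition_id", "replicate", "value"}
        if not required <= set(function_table.columns):
            raise RobustnessError(f"function table must have columns {sorted(required)}")
        self.function_table = function_table.copy()
        self.space = space or PerturbationSpace.from_table(function_table)
        self.metric = metric
        self.ddof = ddof
        self.pooled = pooled

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "RobustnessModel":
        return cls(df, **kwargs)

    def fit(self) -> "RobustnessResults":
        table = self.function_table
        analysed = table[table["condition_id"].isin(self.space.perturbed)]
        results: list[RobustnessResult] = []
        for function in pd.unique(table["function"]):
            m = None
            if self.metric == "fano":
                m = normalization_mean(analysed, function)
            for strain in pd.unique(table["strain"]):
                results.append(
                    robustness_with_sem(
                        table, strain, function, self.space,
                        metric=self.metric, m=m, ddof=self.ddof, pooled=self.pooled,
                    )
                )
        return RobustnessResults(self, results)


class RobustnessResults:
    """Fitted robustness scores with uncertainties and downstream analyses."""

    def __init__(self, model: RobustnessModel, results: Sequence[RobustnessResult]) -> None:
        self.model = model
        self.results = list(results)

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strain": r.strain,
                    "function": r.function,
                    "metric": r.metric,
                    "R": r.R,
                    "sem": r.sem,
                    "n_perturbations": r.n_perturbations,
                    "n_missing": r.n_missing,
                    "n_replicates": r.n_replicates,
                    "m": r.m,
                    "higher_is_more_robust": r.higher_is_more_robust,
                }
                for r in self.results
            ]
        )

    def get(self, strain: str, function: str) -> RobustnessResult:
        for r in self.results:
            if r.strain == strain and r.function == function:
                return r
        raise KeyError((strain, function))

    def pairwise_tests(self, alpha: float = 0.05, equal_var: bool = False) -> pd.DataFrame:
        """Strain-pairwise significance of robustness differences
        (unpaired two-sided t test on replicate-slice R values, Holm-adjusted
        per function)."""
        from .stats import pairwise_strain_tests

        return pairwise_strain_tests(self, alpha=alpha, equal_var=equal_var)

    def tradeoffs(self) -> pd.DataFrame:
        """Mean performance versus robustness per strain × function."""
        from .stats import tradeoff_table

        return tradeoff_table(self.model.function_table, self)

    def plot_robustness(self, ax=None):
        from .plotting import plot_robustness_bars

        return plot_robustness_bars(self, ax=ax)

    def plot_tradeoffs(self, ax=None):
        from .plotting import plot_tradeoffs

        return plot_tradeoffs(self.tradeoffs(), ax=ax)

    def summary(self) -> str:
        lines = [
            f"Robustness analysis — metric: {self.model.metric} "
            f"(higher is more robust: {HIGHER_IS_MORE_ROBUST[self.model.metric]})",
            f"Perturbation space: {len(self.model.space.perturbed)} conditions"
            + (f", control: {self.model.space.control}" if self.model.space.control else ""),
            "",
            f"{'strain':<16}{'function':<16}{'R':>12}{'SEM':>10}{'n_pert':>8}{'n_rep':>7}",
        ]
        for r in self.results:
            sem = "NA" if np.isnan(r.sem) else f"{r.sem:.4f}"
            lines.append(
                f"{r.strain:<16}{r.function:<16}{r.R:>12.4f}{sem:>10}"
                f"{r.n_perturbations:>8}{r.n_replicates:>7}"
            )
        return "\n".join(lines)
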