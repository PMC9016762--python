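# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `phenorobust`.

## Signal calibration

Growth Profiler instruments report culture density as camera green values
(GV). OD600 is obtained from the blank-subtracted GV through

    OD = a·Δ^b + c·Δ^d + e·Δ^f,   Δ = GV − GV_blank,

with defaults a = 0.019, b = 1, c = 3.82·10⁻⁶, d = 2.66, e = 3.111·10⁻²²,
f = 10.5 and GV_blank = 26.3: a linear leading term plus two power-law
corrections that only matter at high densities. The functional form is a
pluggable callable on `CalibrationModel`, so a differently fitted
calibration can be substituted without touching the pipeline. Readings below
the blank clamp to OD 0 with a warning. Cell dry weight is linear in OD with
a strain-specific slope (g DW L⁻¹ per OD unit) from gravimetric calibration;
the calibration config must supply one slope per strain.

Growth parameters (μmax, lag) are extracted from the raw GV trajectory, not
from converted OD: the log-slope is invariant to linear rescaling of the
signal, and the calibration is approximately linear over the growth range.
Only the 48-h endpoint is converted to OD (for CDW).

## Growth model and fitting

The log-transformed, blank-subtracted signal is fitted with a cubic
smoothing spline whose penalty λ is selected by generalized cross-validation
(`scipy.interpolate.make_smoothing_spline`); an explicit λ can be set in the
config. μmax is the maximum of the spline's first derivative, located on a
grid 20× finer than the input sampling (ties take the earliest time). R² is
the coefficient of determination of the spline against the log data — on the
log scale, where the fit is performed. The lag phase is the x-coordinate of
the intersection of the μmax tangent through the inflection point with the
horizontal baseline through y0, the spline value at the first timepoint:

    lag = t_infl − (y_infl − y0) / μmax.

Negative intersections clamp to 0 (lag is physically nonnegative), with a
warning.

**No-growth QC.** Wells with R² < 0.99 (strict, configurable) are censored:
μmax := 0, lag := NA, `grew = False`. The rule is idempotent. GCV behaves
well here: on noiseless sigmoids it effectively interpolates (R² ≈ 1.0), on
flat noisy baselines it smooths toward the mean (R² ≈ 0.1–0.2), so
non-growing wells fail the threshold robustly. Degenerate traces are handled
before fitting: a perfectly constant signal, or one that never rises above
the blank, returns a no-growth fit directly; nonpositive readings with no
blank handling active (OD signals) raise instead, because they indicate a
data problem rather than a non-growing well. Readings at or below the blank
in an otherwise growing GV trace are floored to the smallest positive
blank-subtracted reading so the log transform stays defined.

## Performance functions

Five functions per well: μmax (1/h), lag (h), CDW (g/L), biomass yield and
ethanol yield (g per g of total consumed sugars). Consumed sugars sum
max(initial − final, 0) over glucose, mannose, xylose, galactose and
arabinose; a final concentration above its initial is zeroed with a warning
(assay noise), and an endpoint row with no substrate at all is an error.
Yields are undefined (missing, with a warning) when nothing was consumed.
The inoculum biomass (start OD 0.02 × strain slope) is subtracted in the
biomass yield by default — the yield should count *produced* biomass — and
`subtract_inoculum=False` disables this. Negative biomass yields floor at 0.
Replicates are never pre-averaged; the function table keeps one record per
well so downstream aggregation (replicate slices, SEM) stays explicit. The
function set is a registry; additional functions (biosensor output, reporter
expression) can be registered with units and scored identically.

## Robustness metrics

Given values x of one function over the perturbation space P:

* **CV**: σ/x̄ (σ = sample standard deviation). Orientation: 0 is best.
* **Control-ratio (Kitano-style)**: Σ_p ψ(p)·f(p)/f(0) with frequencies ψ
  summing to 1 (equal by default) and f(0) the control-condition value. The
  weighted ratios are averaged; with equal ψ this coincides with summing
  normalized weights. When the control is part of the space it is excluded
  from the perturbed set.
* **Fano**: R = −(σ²/x̄)/m ≤ 0, with m the pooled mean of the function over
  every strain, perturbation and replicate of the analysed dataset.
  R = 0 iff the dispersion is zero. Because of m, R values are by definition
  relative to the investigated data case; m is stored with each result.

Variance estimator: sample variance (ddof = 1) by default — perturbation
counts per replicate slice are small — switchable to population variance
(ddof = 0). With ddof = 0, duplicating every perturbation's values leaves
Fano R exactly unchanged; with ddof = 1 there is a documented O(1/n) drift.

Metrics are reported on their native scales; each result carries a
`higher_is_more_robust` flag (CV: False; control-ratio and Fano: True) so
rankings and plots orient correctly. The printed form of the CV-based score
is ambiguous in the literature (σ/x̄, its negative, or 1 − σ/x̄); the raw CV
with orientation metadata is exposed.

**Replicate-slice scheme.** The headline R per strain × function is computed
on each replicate's values across P; the mean of the slice R values is
reported with their standard error (matching n = 3 error bars in typical
plate designs). Perturbations missing within a slice (e.g. lag in
non-growing wells) are dropped from that slice, with counts recorded; a
pooled mode (all replicates together, no SEM) is available. Fewer than two
usable slices → SEM missing.

## Criteria audit

The four consistency criteria are operationalized as seeded Monte-Carlo
probes (defaults: 1000 reps):

1. **Frequency independence** — (a) skewing the testing frequency ψ across a
   fixed value set must not move R (CV and Fano take one value per
   perturbation regardless of multiplicity; the control-ratio form weights
   by ψ and moves); (b) E[R] must be stable (< 5% drift) between 10 and 50
   i.i.d.-sampled perturbations, which tolerates the small-sample bias of
   sample-variance-based estimators.
2. **Deviation penalty** — {c−d, c+d} must score strictly worse than {c, c}
   for random c and d. Symmetric deviations cancel exactly in the
   control-ratio score ({1, 3} vs control 2 → 1.0).
3. **Monotonicity** — mild (≤20%) vs harsh (≤60%) random degradations of a
   control level across 10 perturbations must rank correctly (≥95% of reps)
   on each metric's oriented scale.
4. **Dimensionless comparability** — (a) rescaling values (with control and
   m rescaled consistently) must leave R unchanged to 1e-9; (b) two
   functions at matched relative spread, one with mean in (0, 1) and one in
   (1, 10), must rank by absolute dispersion (≥90% agreement). The CV is
   blind to this (equal relative spread ⇒ equal CV; ranking is decided by
   sampling noise) and the control-ratio score carries no dispersion
   information under symmetric spread; the mean-normalized Fano ranks
   consistently.

The audit reproduces the expected verdict table — Fano passes all four, CV
fails only criterion 4, the control-ratio metric fails 1, 2 and 4 — as a
computation, not an assertion.

## Strain comparison and trade-offs

Robustness differences are tested on the replicate-slice R values with an
unpaired two-sided t test — Welch's form by default, since n = 3 slices with
unequal variances is the typical case; Student's form by flag. Zero variance
in both groups is degenerate: equal means report p = 1, unequal means the
limiting p = 0, both flagged. p-values are Holm–Bonferroni-adjusted, with
the family defined as all strain pairs within one function (per-function
families, configurable in principle via direct calls). Trade-off records
pair the mean performance (same records as the robustness computation,
missing dropped) with R and the SEM of each.

## Synthetic experiments

Growth is generated as a modified Gompertz curve in log-signal space; its λ
parameter equals the tangent-construction lag against the asymptotic
baseline. Since the fitting contract estimates the baseline at the first
timepoint, the ground-truth table also stores the closed-form *effective*
tangent lag λ + A·exp(−exp(μe·λ/A + 1))/μ, which is the correct recovery
target when the curve has not settled at t = 0 (the discrepancy reaches
several hours at μ ≈ 0.05 1/h with short λ). Recovery tests compare against
this effective lag.

Defaults emulate the study conditions: 3 strains × 29 perturbations
(including a 20 g/L glucose control and one growth-abolishing aldehyde
condition) × 3 replicates on one 96-well plate per strain, 0–48 h sampled
every 30 min. Strain bases are realistic for anaerobic yeast fermentation
(μmax 0.35–0.40 1/h, lag 2.5–3 h, ethanol yield 0.38–0.45 g/g, biomass
yield 0.09–0.11 g/g, CDW slope ≈ 0.5 g/L per OD, final OD ≈ 5 from 20 g/L
glucose at start OD 0.02). Perturbation effects are multiplicative on each
base parameter: severity-graded aldehydes degrade everything, weak acids
mainly cost CDW and biomass yield, pentoses leave functions unchanged or
mildly improved, osmotic/solvent stresses slow growth. Each strain's
`sensitivity` scales effect deviations from 1, building a known robustness
ordering (sensitivities 0.5 / 1.0 / 1.5) that ranking tests must recover.

Noise: multiplicative lognormal on the above-blank signal (default sd 0.02,
a few percent, typical of plate readers), additive Gaussian on endpoint
concentrations (default 0.1 g/L, typical of enzymatic assays), and relative
lognormal sd 0.05 for the measurement-level function-table generator. All
randomness derives from one run seed through `SeedSequence` substreams keyed
by (strain, condition, replicate), so reruns are byte-identical.

What the generator does **not** emulate: mechanistic inhibitor kinetics,
diauxie and pentose co-consumption chemistry, plate edge/position effects,
correlated (batch) noise between wells, and instrument saturation.
Passing tests therefore demonstrate correctness of the estimators and
pipeline plumbing under idealized plate data, not robustness of the fitting
to every pathology of real screens.

## Problem sizes in the validation suite

The noiseless end-to-end closure runs the full 3 × 29 × 3 design once
(261 spline fits); parameter recovery uses 100 noiseless curves over the
(μmax ∈ [0.05, 0.5] 1/h) × (lag ∈ [0, 10] h) box; the noisy ranking study
uses 100 seeds of the measurement-level generator, which produces function
values directly from ground truth — the growth-fitting stage is validated
separately by the recovery study, so repeating it 100× would add cost
without adding information. Audits run 1000 reps.

## Known limitations

* The GV→OD calibration form is a documented assumption (constants are
  instrument- and medium-specific); recalibrate and substitute the callable
  for other setups.
* R² on the log scale is a blunt growth detector for very low-amplitude
  growth; wells that barely double may pass or fail QC depending on noise.
* The Fano normalization m couples R to the analysed strain set: adding or
  removing strains rescales every R. Comparisons are only meaningful within
  one analysis.
* Lag estimates inherit the first-timepoint baseline convention; trajectories
  already growing at t = 0 yield effective lags larger than the underlying
  Gompertz λ.
* Holm families are fixed to strain pairs within a function; other family
  definitions require calling `holm_bonferroni` directly.
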