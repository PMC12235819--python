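# Methods

This note documents the models, defaults, and numerical choices behind
`ersmix`, and what the synthetic-data-based tests do and do not establish.

## The analysis model

The pipeline targets a cross-sectional design: n subjects with a panel of
P = 18 whole-blood metal concentrations, a binary depressive-symptom flag
(PHQ-9 total ≥ 10), and the adjustment set age, sex, BMI, 5-level family
income, smoking, alcohol, physical activity.

Concentrations are log10-transformed (they are right-skewed and
dose–response is closer to linear on that scale) and z-scored with the n−1
denominator. The candidate design holds all main effects, squares, and
pairwise products of the z-scores: 2P + P(P−1)/2 = 189 columns. Products are
formed **after** standardizing the mains and are deliberately not
re-standardized — a coefficient on `Sn^2` or `La:Ce` multiplies an
interpretable product of z-scores, the same quantity the risk score later
sums. This is the most consequential under-determined convention in the
pipeline: re-standardizing products would change the penalized solution and
the ERS scale. The stored training scaling is reusable, so scores are
computable for held-out subjects.

## Adaptive elastic net

Selection minimizes the penalized average negative Bernoulli log-likelihood
with an unpenalized intercept (README shows the objective). The two-stage
("adaptive") procedure is: stage 1, unit penalty weights, (α, λ) chosen by
stratified 10-fold cross-validated deviance over α ∈ {0.1, 0.3, 0.5, 0.7,
0.9} and a 100-point log-spaced λ grid from λ_max down to 10⁻³ λ_max; stage
2, penalty weights wⱼ = (|β̂ⱼ| + 1/n)^(−γ) from the stage-1 coefficients
(γ = 1 default), searched over the same grid. The 1/n offset keeps
stage-1 zeros *eligible* rather than screened out. Stage 1 always reports
its λ-of-minimum-deviance solution (its job is weight information, not
parsimony); the stage-2 reporting rule is minimum mean CV deviance by
default, with the more conservative within-1-SE rule available
(`selection_rule="1se"`).

Known operating characteristics, measured by the acceptance suite on
generator data: with the five planted terms at 3× their default magnitudes
(n = 20,000) the default rule recovers all five with a handful of false
positives; on pure-noise outcomes the minimum-deviance rule — like
`lambda.min` in any cross-validated lasso — retains a few noise terms in
roughly half of datasets, where the 1-SE rule is much closer to empty but
can drop the weakest true term (the small quadratic). This recall/parsimony
trade is intrinsic to CV-based penalized selection, not an implementation
artifact; we verified the same behaviour with an independent R elastic-net
implementation on identical data. Users who need a sparse, defensible final
model should prefer `selection_rule="1se"`; users running the hierarchical
refit + ERS (which re-estimates coefficients without penalty) lose little
from a few false positives and keep the weak nonlinear terms with the
default.

### Solver

The solver is cyclic coordinate descent on a quadratic model of the logistic
loss, organized in three loops:

- **outer** — refresh the exact gradient for all 189 columns, make one full
  pass (this is where inactive coordinates can activate), and declare
  convergence when a full pass at a fresh quadratic moves no coefficient
  (nor the intercept) by more than the tolerance;
- **middle** — exact iteratively-reweighted least squares restricted to the
  active set: the weighted Gram matrix of the active columns is rebuilt at
  each refresh (O(n·a²) for a active terms, skipped above a = 64 where the
  outer loop takes over);
- **inner** — coordinate sweeps on the cached quadratic, O(a) per
  coordinate, solved loosely while far from the fixed point.

The outer full pass uses a precomputed unweighted Gram X'X/n with a scalar
curvature bound s = min(1/4, 1.5·mean μ(1−μ)); because s below 1/4 is not a
global majorizer, an objective-decrease safeguard reverts any ascending
refresh and falls back to the guaranteed 1/4 bound. λ paths are
warm-started; λ_max = maxⱼ |⟨xⱼ, y−ȳ⟩|/(n·α·wⱼ) reproduces the exact
all-zero threshold.

Tolerances: returned (full-data) solutions converge at 1e−7 maximum absolute
coefficient change per full pass and satisfy the KKT conditions within 1e−5
(tests certify ~1e−8); cross-validation fold fits, which only feed deviance
curves, use 1e−4 — deviance is flat at that scale and the looser tolerance
keeps the 10-fold × 5-α × 100-λ × 2-stage search tractable on one core.
During CV the folds advance down each α's λ grid in lockstep and the descent
stops after 15 consecutive grid points without a new mean-deviance minimum;
the skipped tail (the deep-overfitting region) carries its last deviance
forward and is flagged `evaluated=False` in the CV table. Sweep budget:
10,000 per path point, exceeded → explicit `ConvergenceError`.

## Hierarchical refit and the ERS

The refit model contains the selected terms **plus the main effect of every
metal appearing in a selected quadratic or interaction** (hierarchy keeps the
nonlinear coefficients interpretable), plus covariates (income dummy-coded
against its lowest bracket, sex as a male indicator). The fit is ordinary
maximum likelihood (Newton, tol 1e−10); separation or non-convergence raises
a dedicated error rather than returning garbage.

ERSᵢ sums the metal terms only — no intercept, no covariates — so it is a
pure mixture-burden scalar. In-sample it equals the refit's metal-block
linear predictor, which has a structural consequence worth knowing: a
logistic fit of the outcome on the in-sample ERS with the same adjustment
set returns a per-unit log-OR of **exactly 1** (OR = e ≈ 2.718). The
per-unit OR is therefore not evidence of association strength when computed
in-sample; quintile contrasts, stratified fits, and the split-sample mode
carry the real information. We surface rather than hide this because the
workflow this package implements is routinely run in-sample.

Quintiles cut at the 20/40/60/80th percentiles with half-open intervals
(top closed); a binary outcome makes indicator-coded binary logistic
identical to the multinomial formulation. Quintiles whose 2×2 table against
Q1 has an empty cell are structurally non-estimable: they are flagged, their
subjects are held out of the fit, and the remaining contrasts are reported.
Wald intervals throughout. The stratified difference test is
z = (b₁−b₂)/√(SE₁²+SE₂²), two-sided.

## Restricted cubic splines

Basis: Harrell's restricted truncated-power construction, scaled by the
squared boundary-knot span; k knots give k−1 columns (x plus k−2 curvature
terms), linear beyond the boundary knots. Default 4 knots at the
5/35/65/95th percentiles (configurable 3–7 with the standard quantile
tables); reference value = sample median (log-OR ≡ 0 there); curve on a
200-point grid with pointwise Wald bands; nonlinearity tested by LRT of the
curvature block (Wald behind a flag). Calibration is verified by simulation:
~5% type-I error under a linear truth, >95% power against the planted
inverted U at n = 20,000.

## Quantile g-computation

Exposures are rank-transformed (average ranks, so ties and any monotone
transform are irrelevant) and bucketed into q = 4 quantile scores by
default. The non-bootstrap estimator is primary: ψ = Σ exposure
coefficients from one covariate-adjusted logistic fit; SE by the delta
method (1'Σ1 over the exposure block); weights = |coefficient| normalized
within each sign group. Optional nonparametric bootstrap (fixed seed)
reports a percentile CI; replicate fits tolerate quasi-separated nuisance
covariates (sparse resampled cells) as long as ψ is finite, and more than
10% failed replicates is an error. The model is strictly additive in the
quantized scores — planted quadratic or antagonistic-interaction structure
is invisible to it by design, which is exactly why it serves as a
sensitivity analysis next to the ERS.

## Synthetic cohort generator

The generator defines the study conditions the tests run under:

- **Metals** — Gaussian copula: latent MVN with a unit-diagonal
  positive-definite correlation matrix, mapped per metal to
  10^(median + sd·z). Copulas preserve ranks, so pairwise Spearman
  correlations follow 6/π·arcsin(ρ/2) exactly — a closed-form oracle the
  tests exploit. The default correlation is two 9-metal blocks
  (within-block 0.4–0.7 decaying with panel distance, 0.2 between), giving
  the observed 0.1–0.7 Spearman range. Per-metal log10 medians/SDs are
  plausible whole-blood placeholders (iron ~450 mg/L down to rare earths
  ~0.05 µg/L); the real panel's marginals are unpublished.
- **Covariates** — independent draws from the emulated cohort's marginals
  (age 18.39 ± 0.64 y, BMI 22.45 ± 5.00, 58% female, smoking 1.2%, alcohol
  5.2%, physical activity 77%, five income brackets).
- **Outcome** — logistic in the standardized log10 metal terms (defaults =
  the refit coefficients above) plus covariate effects (defaults: smoking
  +1.3, alcohol +0.7, physical activity −0.65 on the log-odds scale —
  matching the direction and rough size of the emulated cohort's excesses;
  age/sex/BMI/income null there). The intercept is found by bisection on
  [−20, 20] so the mean predicted probability over the realized draw equals
  the 5.18% target within 1e−4.
- **PHQ-9 items** (optional) — proportional-odds draws on a latent severity
  (linear predictor + standard logistic noise); the three thresholds are
  spaced (t, t+1.5, t+3) with t calibrated by bisection against the exact
  9-fold convolution of the item distribution so the expected rate of
  item-sum ≥ 10 matches the target; the flag is then re-derived from the
  simulated items.
- A single root seed spawns independent substreams (metals, covariates,
  outcome, items), so stages can be regenerated independently.

What passing tests on this generator do **not** show: robustness to
measurement error, detection limits, batch effects, missing data, or
covariate–exposure dependence — none of which the generator emulates. The
parameter-recovery and selection results say the *estimators* work under
the assumed data-generating process, not that the emulated study's
substantive findings are correct.

## Problem sizes used by the test suite

Simulation-backed checks run at the sizes that make their error bounds
meaningful while keeping the default suite practical: parameter recovery at
n = 50,000 (±3 SE), selection consistency at n = 20,000 with 3× effect
magnitudes plus 25 null datasets at n = 2,000, spline calibration at 100
seeds × n = 20,000, covariate-marginal checks at n = 50,000, prevalence
calibration at n = 100,000.

## Known limitations

- In-sample ERS inference is optimistic (see above); a split-sample mode
  exists but the default mirrors the common single-sample workflow.
- Minimum-deviance CV selection is liberal on null data; the 1-SE rule is
  conservative on weak terms. There is no free lunch between them.
- Quintile cut points are computed on the analysis sample after exclusions;
  heavy ties can collapse groups (error, with achievable sizes reported).
- The spline's conclusions are knot-convention-dependent; defaults follow
  the standard quantile placement but other placements are one argument away.
- Bayesian kernel machine regression is deliberately out of scope; qgcomp
  is the supported mixture sensitivity analysis.
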