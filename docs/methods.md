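# Methods

`markerdyn` analyzes early on-treatment dynamics of serum tumor markers
(CEA in ng/mL, CA-19-9 in U/mL) as prognostic factors for right-censored
survival endpoints (PFS, OS, in months) in small oncology cohorts, and
ships a synthetic cohort generator so that every stage of the analysis is
testable without patient-level data.  This note documents the models, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic validation does and does not establish.

## The marker-dynamics model

For each patient the on-treatment change is

    Δ = (post − baseline) / baseline × 100   (percent),

defined only for strictly positive marker values, hence Δ > −100 always.
Two complementary analyses are built on Δ:

1. **Continuous association.** A Cox proportional-hazards model with Δ as a
   single continuous covariate; the hazard ratio is reported per 10
   percentage points, `exp(10·β)` with CI `exp(10·(β ± z₀.₉₇₅·SE))`.  A
   restricted cubic spline (Harrell basis, default 3 knots at the
   10th/50th/90th percentiles of Δ) added to the linear term gives a
   likelihood-ratio test of nonlinearity on k−2 degrees of freedom.  Δ is
   analyzed on the raw percentage scale; no log transform, matching the
   per-10-percentage-point reporting convention.
2. **Threshold stratification.** Candidate cutoffs c are scanned; at each,
   a Cox model on the indicator I(Δ > c) is fitted.  "Unfavorable" is
   strictly above the cutoff; a change exactly equal to the cutoff is
   favorable.  A candidate is *admissible* when both strata contain at
   least `min_group` patients (default 10) and the Wald p is below `alpha`
   (default 0.05); among admissible candidates the one with minimal AIC
   (= −2·log partial likelihood + 2, one parameter) is selected.  Since the
   null log-likelihood is the same at every cutoff, minimizing AIC is the
   maximally selected likelihood-ratio profile; on clean fixtures its
   maximizer coincides with the maximally selected log-rank statistic, and
   the test suite checks this coincidence.

Two grid dialects exist because practice is ambiguous about which is meant
by a "−50% to +50% in 5% steps" scan that nevertheless reports off-grid
cutoffs: `fixed` (the literal 21-point grid) and `observed` (every unique
observed Δ inside the range — the maximally selected profile, capable of
producing cutoffs like +14.6%).  `observed` is the default.

When PFS and OS scans must yield one cutoff per marker, the default joint
policy minimizes the sum of the two scans' AIC ranks over cutoffs that are
admissible for PFS and have a usable (converged, adequately sized) OS fit;
OS significance is *not* required.  Ties are broken by larger |log HR|,
then by the cutoff nearest 0 (interpretability).  This is one documented
resolution of a genuinely underdetermined combination rule; the full
selection trace is recorded in every scan so the policy's effect is
auditable.

**Known omission, by design:** no minimum-p multiplicity correction
(maxstat-style) is applied to the selected cutoff's p-value.  Data-driven
cutpoint selection overstates significance; the bootstrap and LOOCV layers
exist precisely to expose that instability, and the documentation says so
rather than silently correcting.

## Survival engine

The Cox fitter maximizes the Efron-tie-corrected partial likelihood by
Newton-Raphson with step-halving, tolerance 1e-8 on the parameter step.
Efron rather than Breslow, because monthly clinical time scales produce
heavy ties and Efron is the modern software default.  Subjects censored
exactly at an event time remain in that event time's risk set.  Monotone
likelihood (complete separation) is detected (|β| drifting past 25) and
reported as declared non-convergence, never as a silent estimate.
Per-covariate inference is Wald-based; AIC = −2·logPL + 2k exactly.  The
implementation is vectorized NumPy because the scan/bootstrap/LOOCV stack
refits thousands of single-covariate models per analysis; it is verified
in the test suite against brute-force likelihood-grid maximization on
small fixtures and against lifelines on larger ones.

Kaplan-Meier estimation (with Greenwood variance) stands on lifelines; the
median CI inverts the log-log transformed pointwise bands at 0.5
(Brookmeyer-Crowley style), a choice the package documents because
clinical reports rarely state theirs.  The log-rank test is computed
in-package (the result contract includes observed/expected per group) and
cross-checked against lifelines.  Proportional hazards are checked with
the Grambsch-Therneau scaled-Schoenfeld test via lifelines, using the KM
time transform (the R `cox.zph` default); with fewer than 3 events the
diagnostic is flagged undefined.

## Time-dependent ROC

Discrimination at a fixed horizon (default 6 months) uses the
cumulative-cases / dynamic-controls estimator with inverse probability of
censoring weights (Uno-style): cases (event by the horizon) are weighted
by 1/G(T⁻), controls (followed past the horizon) by 1/G(horizon), where G
is the Kaplan-Meier estimate of the censoring distribution.  Score ties
count 1/2.  With no censoring before the horizon the estimator reduces
exactly to the Mann-Whitney AUC of the binary horizon outcome — an
identity the acceptance tests verify to 1e-10 — and it is cross-checked
against scikit-survival's `cumulative_dynamic_auc`.

## Internal validation

*Bootstrap*: plain nonparametric resampling of patients (not stratified by
event status), default 1000 iterations, rerunning the entire scan +
selection in each resample.  Resampling indexes a canonical ordering by
patient id, so summaries are invariant to input record order.  Iterations
with no admissible cutoff are counted and reported (`n_failed`), never
imputed — imputing would bias the stability estimate.  The headline
statistic is the proportion of successful iterations whose cutoff lies
within ±5 *percentage points* (absolute, on the cutoff scale) of the
original, alongside median, mean, IQR and the 2.5/97.5 percentile CI.

*LOOCV*: the cutoff is re-derived on each n−1 training fold and the
held-out patient classified by it; concordance is the percentage of
classifiable patients whose fold-derived class equals their full-sample
class.  Folds with no admissible cutoff leave the patient unclassifiable
(counted, excluded from the percentage) — a documented decision, since how
published analyses handle such folds is typically unstated.

## Model selection (regression tables)

Univariable screening fits one Cox model per variable (multi-level
categoricals as indicator contrasts with a declared reference; screening
on the joint Wald p) and flags p < 0.10.  The multivariable step supports
two first-class modes: `backward` (iteratively drop the largest
joint-Wald-p block ≥ 0.05; forced variables never dropped; p ties broken
by variable name, so elimination is deterministic) and `forced-full` (all
candidates fitted, nothing eliminated).  Both are reported because
published tables frequently show non-significant markers retained in the
multivariable columns — behavior that corresponds to forced-full, not to
the backward rule stated in methods sections.

## Synthetic cohort generator

The generator is the package's study-conditions definition, not a tuning
dial.  Defaults:

| Parameter | Default | Rationale |
| --- | --- | --- |
| n_patients | 61 | emulated cohort size |
| CEA baseline | log-normal, median 56.5, σ = ln(247/17.9)/(2·z₀.₇₅) ≈ 1.95 | Table-1-style median and IQR |
| CA-19-9 baseline | log-normal, median 58.1, σ ≈ 1.79 | ditto |
| Δ model | shifted log-normal on post/baseline, median +76.6% (CEA), +94.5% (CA-19-9), σ = 1.0 on the log-ratio | reproduces heavy right skew; σ = 1.0 gives an IQR of roughly −10% to +250% at the CEA median, spanning decreases and large increases as real kinetics do |
| effect | `linear` in CEA Δ, 7e-4 per 1% (per-10-point HR ≈ 1.007); `threshold` and `null` modes available | the strongest continuous association the method is designed to detect |
| survival | Weibull PH, shape 1.1, death scale 12 months; progression scale = 0.5 × death scale; PFS = min(progression, death), OS = death; optional shared log-normal frailty (off by default) | OS medians ~6–9 and PFS ~2.5–4 months, the late-line mCRC regime |
| censoring | exponential, rate tuned numerically so the expected censored fraction equals `censoring_rate` (default 0.05), plus administrative cutoff at 50 months | late-line cohorts are nearly fully evented; the censoring proportion is exposed as a free parameter because real reports rarely state it |
| covariates | sex/RAS/line/sidedness drawn independently of outcome (prevalences 0.607/0.655/0.59; left/rectum/right 0.639/0.197/0.164) | matches the null covariate findings the regression layer should reproduce |

A two-component mixture change model (responder/progressor clusters) is
available for sensitivity work.  The generator does **not** model assay
noise, more than two timepoints, treatment switching, or informative
censoring.  Consequently, passing tests demonstrate that the statistical
machinery is correct and well calibrated under a clean proportional-hazards
data-generating process with independent censoring; they do not establish
that any particular clinical dataset satisfies those assumptions.

## Numerical and reproducibility conventions

* One analysis seed drives everything; each stochastic stage derives a
  31-bit child seed as SHA-256 of `"{seed}:{stage_name}"`, so adding a
  stage never perturbs the draws of another.  Reports are byte-identical
  across reruns at fixed config; floats are serialized at 10 significant
  digits.
* Degenerate inputs are contracts, not crashes: all-censored KM gives a
  curve at 1 with undefined median; event-free Cox raises; constant
  covariates raise; scans with no admissible candidate return an undefined
  selection with a trace; a bootstrap in which every resample fails
  reports `n_failed = n_iter` with NaN summaries.
* Simulation scales used by the test suite (chosen as the package's
  standard validation sizes): cutoff recovery at n = 500 with 100
  replicates; spline calibration at n = 300 with 200 replicates; bootstrap
  monotonicity at n = 200 with 100 iterations and 10 paired repetitions;
  generator calibration at n = 5000; the end-to-end determinism check at
  n = 61 with 1000 bootstrap iterations.

## Known limitations

* The per-10-point HR convention assumes Δ is coded in percentage points;
  re-coded inputs (fractions) must be handled by the caller — the Cox
  fitter itself is scale-equivariant, so only the labeling changes.
* Cutoff selection inherits the well-known instability of maximally
  selected statistics in small samples; the bootstrap CI widths produced
  by the pipeline are the honest summary of that instability.
* The spline linearity LRT relies on the asymptotic chi-square null; with
  very heavy-tailed Δ and strong effects its small-sample size can drift
  above nominal (the calibration test pins it at the default effect size).
* No time-varying covariates, stratified Cox, frailty estimation, interval
  censoring, or optimism-corrected (shrinkage/.632) performance measures.
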