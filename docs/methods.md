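# Methods

## Setting

A binary risk model deployed in routine care emits a predicted probability
`p̂` for each admission (here: a malnutrition screening score compared with
a dietitian's confirmed diagnosis).  Even a model with stable discrimination
can drift in *calibration* — the agreement between `p̂` and observed event
frequency — and can drift differently across patient subgroups, which is a
fairness problem as much as an accuracy one.  This package implements the
audit: quantify miscalibration on a hierarchy of strictness, test whether it
differs between subgroups, correct it by recalibration fitted on past
patients, and verify that the correction transfers to later patients.

## Calibration hierarchy

**Weak calibration.**  Fit the logistic calibration model

    logit P(y = 1 | p̂) = α + β · logit(p̂)

by maximum likelihood.  `(α, β) = (0, 1)` is ideal; a negative α means risk
is overestimated, β > 1 means the risk distribution is underfitted (too
narrow).  Calibration-in-the-large (CITL) is α re-estimated with β fixed at
1 (the logit of the prediction enters as an offset).  Both intercept
conventions are computed and labelled, because they answer different
questions: the joint-fit intercept moves when the slope is corrected, CITL
measures the pure level error.  One published description of this model
states the opposite sign convention for the intercept in one sentence and
the standard one elsewhere; this implementation uses the standard convention
(negative ⇒ overestimation) throughout.

Implementation: a two-parameter Newton–Raphson with step-halving and a
single post-convergence "polish" step, stopping on a relative score
tolerance of 1e-8; the polish step drives parameter error to ~1e-14 so that
algebraic invariants (e.g. slope invariance under a constant logit shift)
hold to 1e-8.  Coefficients exceeding 50 in absolute value raise a
separation error.  The fitter accepts per-record case weights so that
multinomial bootstrap resamples can be refit without re-expanding the data;
statsmodels is used in the test suite as an independent oracle, never in the
computation path.

**Moderate calibration.**  A loess curve of outcome on `p̂` (tricube
weights, nearest-neighbour bandwidth `r = ceil(span·n)`, local polynomial
degree 0/1/2; defaults span 0.75, degree 1) is compared with the diagonal:

* `Eavg` (= the integrated calibration index, ICI): mean |curve(p̂ᵢ) − p̂ᵢ|
  over records;
* `Emax`: the maximum of the same deviations;
* Brier score `mean((p̂ − y)²)`, plus the skill-scaled variant
  `1 − Brier/(ȳ(1−ȳ))` (1 perfect, 0 equal to the constant-prevalence
  predictor).  The raw Brier is the primary value; the scaled one is
  emitted alongside because published "rescaled" definitions are ambiguous.

The curve is evaluated at the deduplicated observed predictions; above
`max_eval_points` (default 400) an evenly spaced quantile grid is used and
deviations are interpolated linearly.  Fitted values are clipped to [0, 1].
Degenerate local systems (ties collapsing the window) degrade to the local
weighted mean.

**Strong calibration.**  Moderate calibration within every subgroup cell:
the audit emits one curve and one metric bundle per (recalibration variant,
sample, subgroup level).

## Discrimination

Harrell's c-index computed by midranks (Mann–Whitney form, ties counted
half), which equals the O(n²) pairwise definition exactly and is invariant
under any strictly increasing recalibration map.  Confusion metrics use the
convention `p̂ ≥ threshold` ⇒ positive call; by default each record is
judged at its own site's threshold (the deployment uses site-specific
cutoffs in 0.44–0.58), with a single pooled threshold available.  Zero
denominators yield NaN, never silent zeros.

## Recalibration

Both updating methods are linear maps of the logit fitted on the training
sample only and applied to both samples:

* recalibration-in-the-large: `α = CITL`, `β = 1`;
* logistic recalibration: `(α, β)` = the joint weak-calibration fit.

Fixed points follow from maximum likelihood: refitting weak calibration on
logistically recalibrated training predictions returns (0, 1); after
recalibration-in-the-large the CITL is 0 and the joint-fit slope is
unchanged.  These are enforced as tests at 1e-6/1e-8.  The identity variant
returns its input unchanged rather than round-tripping through the logit.

## Resampling inference

Percentile bootstrap CIs (default B = 100, the deployment study's setting)
resample records with replacement at the original size.  Subgroup
differences use independent resampling within each (disjoint) group and the
two-sided empirical p-value

    p = 2 · min( (1 + #{D* ≤ 0})/(B+1), (1 + #{D* ≥ 0})/(B+1) ),  capped at 1,

whose floor is 2/(B+1): a p-value of exactly 0 is impossible by
construction, so reports render floor values as "< 2/(B+1)".  Consequence
worth knowing: at B = 100 the floor (~0.02) exceeds a Bonferroni-adjusted
threshold like 0.001, so Bonferroni-level decisions need a larger B (e.g.
999).  Multiplicity control divides α by the number of configured tests
(pairs × metrics × variants), or uses a user-fixed threshold.  Percentile
(not BCa) intervals: simplest method consistent with small default B; B is
configurable.

### Bootstrap shortcuts inside the audit

Within one metric cell all metrics share one set of resamples.  Because a
resample only reweights the original records (multinomial counts), three
exact-or-near-exact shortcuts apply:

* weak calibration refits run on fixed logits with count weights —
  algebraically identical to refitting the expanded resample;
* the c-index reuses a precomputed sort/tie structure with per-resample
  weights — also exact;
* loess refits reuse the full-cell bandwidths and tricube weights, so each
  refit is a few matrix–vector products against precomputed moment
  designs.  This freezes the (span-quantile, hence stable) bandwidth
  pattern across resamples — the one approximation, affecting only the
  Eavg/Emax CIs, and it is evaluated on a coarser grid
  (`bootstrap_eval_points`, default 100).

Point estimates always come from the full-resolution fit.  The standalone
`bootstrap_ci` / `bootstrap_diff_pvalue` functions do none of this: they
re-apply the metric to each resample verbatim, and pairwise subgroup
comparisons go through that route.

## Synthetic cohorts

The generator is the ground truth against which everything above is
validated.  For a record in group g, a latent score `z ~ Normal(μ_g, σ_g)`
gives the model prediction `p̂ = expit(z)` and the true event probability
`expit(a_g + b_g·z)`; outcomes are Bernoulli.  By construction the
population weak-calibration parameters within group g are exactly
`(a_g, b_g)` — parameter recovery is therefore a sharp test, not a
plausibility check.  `μ_g` is solved by bracketed root finding on the
numerically integrated prevalence so each group hits a target event rate.

Defaults emulate the audited deployment: 66,930 admissions (≈74% in a
2021–2022 training window, the rest in a 2023 hold-out window), 24% event
rate, the published cohort composition (49.9% female; race 6.6/29.6/28.3/
35.4% Asian/Black/Other/White; 24.1% Hispanic; payor and service-line
shares; five facilities with thresholds 0.44–0.58 and a facility→hospital-
type mapping), gender-specific truth (a, b) = (−1.49, 1.42) for female and
(−0.88, 1.40) for male patients — the published per-gender miscalibration —
and σ = 1.5, which at the solved μ produces a realistic right-skewed risk
distribution and c-index ≈ 0.88.  Randomness uses one master seed with
child streams spawned per attribute and per group, so draws do not depend
on iteration order and equal configurations give byte-identical tables.

Composite mode (several attributes simultaneously) adds intercepts and
multiplies slopes across attributes and averages μ and σ; this is an
approximation, documented as such — exact recovery claims apply to
single-attribute mode, since jointly exact per-gender *and* per-race
parameters are mutually inconsistent.

A longitudinal variant emits daily prediction events and dietitian
assessment events obeying the deployed workflow (predictions suppressed for
three days after a negative assessment, permanently after a positive one),
and the admission-reduction step — maximum prediction followed by at least
one assessment, outcome from the first assessment on or after that
prediction's date (same-day counts as after, matching daily granularity) —
recovers the flat cohort exactly.

What the generator does **not** emulate: the 53 input features of the
underlying random-forest model (scores are generated directly), temporal
drift between windows (truth is time-stable, which is exactly why hold-out
recovery of (0, 1) after logistic recalibration is the expected result),
dependence of label acquisition on the model's own predictions
(verification bias is emulated only at the event-reduction level), repeat
admissions, and missing data beyond optional NA columns in baseline tables.
Passing tests therefore demonstrate internal correctness and statistical
validity of the machinery under known truth — not that any particular real
deployment is well calibrated.

## Baseline tables

Standardized mean differences: binary
`|p₁−p₂| / sqrt((p₁(1−p₁)+p₂(1−p₂))/2)`; continuous
`|m₁−m₂| / sqrt((s₁²+s₂²)/2)`; multicategory via the Mahalanobis form
`sqrt(Tᵀ S⁻¹ T)` over k−1 categories with S the average multinomial
covariance — invariant to category order and dropped category, and equal to
the binary formula at k = 2.  Continuous SMDs use means/SDs even where the
display shows median [IQR].  Missing values get their own row and never
enter an SMD.

## Audit orchestration and numerical choices

`run_audit` fits the recalibration variants on the training sample, then
computes every metric bundle per variant × sample × (overall + subgroup
level), skipping levels below `min_subgroup_n` (default 50, below which
loess and logistic fits are unstable) with a logged reason; individual cell
failures are recorded, never fatal.  Pairwise comparisons default to the
hold-out sample.  Default subgroups are gender and race (the primary
analyses of the motivating deployment); payor and hospital type are
supported via configuration.  Probability clipping uses eps = 1e-6 before
any logit.  Reports carry a config hash, seed, record count and package
version; equal inputs, configuration and seed reproduce the report
byte-for-byte (which is why no wall-clock timestamp is embedded).

Problem sizes used by the validation suite: parameter recovery at
n = 100,000 (tolerance ±0.05); bootstrap size/power checks at B = 199 with
groups of 2,000 (400 Monte-Carlo repeats, type-I ≤ 0.075 at nominal 0.05)
and 5,000 (50 repeats, power ≥ 80% for an intercept gap of 0.61); the
end-to-end audit at n = 50,000 with B = 100.

## Known limitations

* The frozen-bandwidth loess bootstrap slightly understates bandwidth
  variability in Eavg/Emax intervals; pairwise comparisons avoid it.
* Composite-mode truth is approximate by construction.
* Percentile intervals at B = 100 are coarse; raise B for reporting.
* No isotonic/spline recalibration and no model refitting — linear-logit
  updating only, by design.
* The analysis unit is one record per patient id; multiply-admitted
  patients are not modelled.
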