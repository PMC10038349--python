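# Methods

## The analysis problem

A longitudinal observational cohort of allo-HCT recipients contributes
weekly-ish blood draws over the first 100 days posttransplant. Each draw
yields a panel of flow-derived T cell metrics (absolute counts, treated as
logarithmic-scale data, and percentages on 0–100, treated as linear-scale);
each patient carries one of four mutually exclusive outcome labels assigned
by first reportable outcome — relapse, no GVHD, grade 1 GVHD, or grade 2–4
GVHD — with the convention that grade ≥ 2 GVHD wins over a later relapse
(the dual-event rule). The pipeline asks which metrics, measured in a given
posttransplant time window, discriminate future outcomes, and how well a
multivariate combination of them generalizes.

## Screening and ROC

Each metric is screened per contrast with a two-sided test chosen by the
metric's declared scale: Welch's unequal-variance *t* test for linear data,
the Mann-Whitney rank test for logarithmic data. Samples, not patients, are
the screening unit (each draw is a data point); a per-patient aggregation
is available for sensitivity analysis through the cross-validation unit.
The pass rule is strict *p* < α with α = 0.05 and deliberately no
multiplicity adjustment — the screen is a filter feeding the ROC stage, not
a confirmatory family of tests.

AUC is computed from mid-ranks, which is numerically identical to
exhaustive positive–negative pair counting with ties scored ½ (the
Mann-Whitney equivalence). ROC curves sweep thresholds over distinct
values, grouping ties at a single threshold so the trapezoidal area equals
the rank AUC to floating-point accuracy. AUC significance uses the
tie-corrected normal approximation of the U null, two-sided, without
continuity correction:

  z = (U − n₁n₂/2) / σ,  σ² = n₁n₂/12 · [(N+1) − Σ(t³−t)/(N(N−1))].

An exact alternative (`method="exact"`) enumerates all label placements and
reports the fraction whose |AUC − ½| reaches the observed deviation; it is
valid under ties and used when the placement count is feasible.

## The combined score

For each panel metric the empirical CDF is fitted on the pooled training
values of both classes, evaluated with the mid-rank convention
e(x) = (#{v<x} + ½#{v=x})/n and clamped to [1/2n, 1 − 1/2n]. The clamp
matters: a single out-of-support value would otherwise contribute a factor
of exactly 0 or 1 and annihilate or saturate the product. The orientation
of each factor (e or 1 − e) is the one whose single-variable AUC on the
training data is ≥ 0.5, with an exact tie resolved deterministically to
"higher is positive". The combined score is the product of directed
factors. Pooling classes into one ECDF per variable (rather than per-class
ECDFs) keeps the transform a pure reranking device; a per-class variant
would be a likelihood-ratio method, which this is not.

Two consequences are load-bearing and tested: the pipeline is invariant
under strictly increasing transforms of any metric, and reversing a
metric's order flips its fitted direction while leaving every combined
score unchanged to 1e-12 (the mid-rank ECDF complements exactly). The one
exception is an exact training AUC of 0.5, where the deterministic
tie-break keeps the same orientation on both the original and reversed
data.

## Cross-validation

Generalization is estimated by leave-one-out cross-validation. The default
unit is the **patient**: repeated draws from one patient share outcome and
physiology, so sample-level folds would leak patient identity into
training. Everything learned from data — the ECDF support *and* the
per-metric direction — is refitted inside each fold; a global-direction
mode exists for comparison but is not the default. Held-out samples keep
their per-sample scores and the reported AUC is computed over all held-out
scores. A fold that would lose one class entirely is an error naming the
offending unit, and ≥ 2 units per class are required up front.

The no-leakage guarantee is auditable: the fitted per-fold panels can be
retained, and perturbing a patient's values leaves the components of the
fold that scores that patient bit-identical. Note that in LOOCV every
patient also serves as training data for the other folds, so a perturbation
legitimately moves *other* patients' held-out scores; the guarantee is
about the model that does the scoring, not about global insensitivity.

## Time handling

Windows are closed integer-day intervals (days 7–17 by default for the
early window). The second analysis path restricts to days 22–83 and
re-times each sample as day − (GVHD diagnosis day); patients without a
diagnosis day (no-GVHD, and relapse-only patients) are anchored to imputed
day 54, the cohort-average time to diagnosis. A relapse-group patient who
also carries a diagnosis day uses the true diagnosis day.

## Clonality statistics

Clone tables are read from AIRR rearrangement TSVs (clone identity
= (v_call, junction_aa) when both are present, counts from
duplicate_count; duplicate identities are summed) or from minimal
clone_id/count tables. Diversity is Shannon-Weiner H with natural log;
the normalized index H/ln R (Pielou evenness) is base-independent and
defined as 0 for a single-clone table. Top-N fractions break boundary ties
by clone-id lexicographic order for determinism. No rarefaction or depth
correction is applied; populations sequenced at very different depths are
not directly comparable on raw H.

## The synthetic cohort generator

The generator reproduces the *design* of the emulated study, not its data:
35 recipients (default split 8 relapse / 10 no GVHD / 7 grade 1 / 10 grade
2–4 — per-group counts are a plausible choice, as real cohorts rarely print
them), draws scheduled every 4–6 days through day 100 with attendance
probability 0.6, which reconciles the stated draw cadence with an average
of ~12 collected samples per patient; GVHD diagnosis days ~N(54, 18)
clipped to [7, 100]; one dual-event patient injected into the grade 2–4
group by default; relapse days within the first year.

Metric values are strictly increasing transforms of an equal-variance
latent normal z ~ N(δ_g, 1): counts are log-normal exp(μ + σz), frequencies
are logit-normal 100·expit(μ + σz). This family was chosen over a clipped
truncated normal precisely because monotone transforms preserve ranks: the
true AUC between groups g and h is exactly Φ((δ_g − δ_h)/√2), and a
contrast mixing groups on either side has true AUC equal to the
size-weighted average of the pairwise Φ terms. The generator returns this
analytic ground-truth table alongside every cohort.

Default effect pattern: five metrics carry shifts (CD45RO count down in
relapse; DPT% up in GVHD and down in relapse; Treg% down in GVHD; CD8% and
blasting-CD45RO% up in GVHD) with |δ| between 0.5 and 1.1, i.e. true
single-metric AUCs of roughly 0.64–0.78 — the range typical of screened
clinical flow metrics. The remaining six metrics are null. `config.null()`
zeroes every shift and declares the null configuration used for
calibration.

What the generator does **not** model, and what passing tests therefore do
not establish about real data: within-patient serial correlation (a
`patient_sd` latent random effect exists but defaults to 0, because the
declared-null calibration of sample-level tests requires exchangeable
samples — with real repeated measures, sample-level screening p-values are
anticonservative and the patient-level CV unit is the safeguard);
time-varying effect sizes (shifts are constant over the follow-up);
informative missingness (attendance is independent of outcome); and any
mechanistic immunology. Mouse cohorts are likewise purely phenomenological:
arm-specific DPT% location shifts by week, linear-in-week expected weight
loss, and a lethal arm whose mice stop contributing after a death week
drawn around week 8.

The murine GVHD weight score maps weight-loss percent to the published 0–4
scale (0 < 2%, 1 = 2–5%, 2 = 6–9%, 3 = 10–14%, 4 ≥ 15%). The printed scale
is defined on integer percent bands and leaves 5–6% formally unassigned;
inputs are rounded half-up to integer percent before lookup, which closes
the gap.

## Numerical and degenerate-input choices

- Two identical constant groups: screening returns (0, p = 1); zero
  within-group variance with unequal means returns (±inf, p = 0) rather
  than dividing by zero. An all-tied Mann-Whitney pool returns p = 1.
- Degenerate metrics inside a screening sweep yield p = NaN/1 and
  passed = False without aborting the other metrics.
- The ECDF clamp bound 1/(2n) equals the mid-rank value of a point below
  the support, making the clamp active only strictly outside the training
  range.
- Frequency metrics are validated to [0, 100] at parse time with the
  offending metric and row named; unknown patient ids in the samples table
  are an error, never silently dropped.
- Problem sizes in the validation suite: 500 random labeled sets for the
  AUC oracle check, 500 declared-null cohorts for calibration, 100 seeds
  for the combined-vs-single comparison, 2,000 samples per class for the
  closed-form recovery check.

## Known limitations

The combined score is an unweighted product: a metric with no signal
dilutes it (there is no shrinkage or weighting, by design — the method
under study is the plain ECDF product). Screening and direction selection
reuse the same window data, so apparent AUCs are optimistic; the LOOCV AUC
is the quantity to report. The AUC p-value's normal approximation is crude
below ~8 samples per class; use the exact method there.
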