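# tcellpanel

Statistical pipeline for identifying posttransplant T cell metrics as
predictive biomarkers of graft-versus-host disease (GVHD) and relapse after
allogeneic hematopoietic cell transplantation (allo-HCT).

Recipients of allo-HCT face two opposed failure modes — GVHD (donor T cells
attacking recipient tissue) and relapse of the underlying malignancy — and
early, noninvasive prediction of either would let clinicians adjust
immunosuppression before symptoms appear. One candidate signal is the panel
of flow-cytometry-derived T cell metrics measurable in weekly blood draws:
absolute counts and frequencies of antigen-experienced (CD45RO+) T cell
subsets, notably the CD4+/CD8+ double-positive T cell (DPT) frequency,
regulatory T cell (Treg) frequency, CD8 frequency, and blasting fractions.
`tcellpanel` implements, as a reusable and fully tested pipeline, the
statistics used to turn such a longitudinal cohort into biomarker claims:

- **Per-metric screening** of binary outcome contrasts (relapse vs rest,
  any GVHD vs none, grade ≥ 2 GVHD vs rest) with Welch *t* tests for
  linear-scale metrics and Mann-Whitney tests for logarithmic ones; metrics
  reaching *p* < 0.05 proceed to ROC analysis.
- **Rank-based ROC/AUC** with significance from the Mann-Whitney
  equivalence: AUC = P(random positive outranks random negative), ties
  counted ½.
- **A multiplicative combined score.** Each metric *j* is transformed by the
  empirical CDF of its pooled training values, evaluated with the mid-rank
  convention and clamped to [1/2n, 1 − 1/2n]; the orientation (eₓ or
  1 − eₓ) is chosen per metric so its single-variable AUC is ≥ 0.5; the
  combined score is the product ∏ⱼ ẽⱼ(xⱼ). The whole construction is
  rank-based, hence invariant to any monotone rescaling of a metric.
- **Leave-one-out cross-validation** with the *patient* as the default unit
  (repeated samples from one patient are not exchangeable), refitting
  directions and ECDFs inside every fold.
- **Time handling**: closed-interval day windows (e.g. days 7–17) and
  diagnosis-day normalization (days 22–83 re-timed relative to each
  patient's GVHD diagnosis day, imputing day 54 — the cohort-average
  diagnosis day — for patients without one).
- **TCR clonality**: Shannon-Weiner diversity H = −Σ pᵢ ln pᵢ, normalized
  form H/ln R (Pielou evenness), and top-N clone fractions from AIRR-style
  rearrangement TSVs.
- **Synthetic cohorts with known ground truth.** Because the patient-level
  data behind such studies are typically not deposited, the package ships a
  seeded generator emulating the study design (35 recipients, four outcome
  groups, draws every 4–6 days over 100 days, ~12 samples/patient, GVHD
  diagnosis around day 54). Every metric is a strictly increasing transform
  of an equal-variance latent normal with group shift δ, so the true
  single-metric AUC is exactly Φ(δ/√2) and the whole pipeline can be
  validated against closed forms.

## Worked example

```python
import tcellpanel as tp

cohort, truth = tp.simulate_cohort(tp.CohortSimConfig(), seed=1)
window = tp.select_window(cohort, 7, 17)

screen = tp.screen_metrics(cohort, window, tp.DEFAULT_CONTRASTS["grade2plus"])
print(screen[screen.passed].to_string(index=False))

model = tp.CombinedScoreModel(
    cohort, list(screen[screen.passed].metric),
    tp.DEFAULT_CONTRASTS["grade2plus"], window,
)
print(model.fit().summary())
print(model.loocv(unit="patient").summary())
```

prints

```
  metric  n_pos  n_neg  statistic  p_value  passed
 pct_DPT     13     21   3.391298 0.002300    True
pct_Treg     13     21  -3.867299 0.000571    True
Combined ECDF-product score — contrast 'grade2plus' (n=34 samples; apparent AUC 0.9451, p=1.66e-05)
=====================================
 metric      direction      train AUC
-------------------------------------
 pct_DPT higher_is_positive    0.8681
pct_Treg  lower_is_positive    0.8425
-------------------------------------
Leave-one-out cross-validated combined score
===============================
cross-validation unit   patient
       units held out        24
     held-out samples        34
            LOOCV AUC    0.9414
          AUC p-value 1.952e-05
-------------------------------
```

Of the 11 metrics, only DPT% (elevated) and Treg% (depressed) separate
grade ≥ 2 GVHD from the rest in the day 7–17 window of this simulated
cohort — exactly the two metrics the generator endows with the largest
group shifts for that contrast. Their directed ECDF product reaches a
leave-one-patient-out AUC of 0.94; the cross-validated value sitting close
to the apparent one reflects genuine signal (oriented true single-metric
AUCs of 0.70 for DPT% and 0.66 for Treg% on this contrast, per the `truth`
table returned alongside the cohort), though with 24 patients a small
cohort can flatter — which is precisely why the cross-validated, not the
apparent, AUC is the reported quantity.

The same analyses are scriptable from the shell:

```bash
tcellpanel simulate cohort --seed 1 --out-dir sim/
tcellpanel screen sim/samples.tsv sim/patients.tsv --window 7:17 --contrast grade2plus
tcellpanel roc sim/samples.tsv sim/patients.tsv --metric pct_DPT --contrast any_gvhd --direction auto
tcellpanel panel loocv sim/samples.tsv sim/patients.tsv \
    --metrics pct_DPT,pct_Treg --contrast grade2plus --window 7:17 --unit patient
tcellpanel diversity --input clones.tsv --top-n 10
```

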