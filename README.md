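# vatprofiler

Tools for quantifying *how* visceral adipose tissue (VAT) is distributed
along the lumbar spine on abdominal CT — not just how much of it there is —
and for evaluating that distribution as an imaging biomarker that separates
Crohn's disease (CD) from ulcerative colitis (UC).

In CD, hyperplastic mesenteric fat tends to concentrate around inflamed
bowel in the lower lumbar and pelvic region, while in UC and in non-IBD
controls visceral fat is spread fairly evenly from L1 to the pelvis. The
package turns that observation into numbers:

* **VFA** — visceral fat area on one axial slice (cm²), from a HU-window
  fat segmentation;
* **VAT volume** — voxel-summed fat volume (cm³);
* **VAI** — VFA standardized by the squared lumbar height
  (L1-1 to L5-5): `VAI = VFA / height²` (cm²/m²);
* **VAT ratio** — one slice's share of the total volume:
  `(VFA × slice thickness) / volume × 100%`;
* **lumbar CV** — the coefficient of variation of per-slice VFAs across
  the lumbar region, `CV = SD / mean × 100%`. A concentrated (CD-like)
  profile has a high CV; a uniform profile has a CV near zero.

Group discrimination uses the standard clinical battery: t / Mann-Whitney
and ANOVA / Kruskal-Wallis comparisons with a Bonferroni-corrected
three-group alpha of 0.05/3 = 0.0167, chi-square for categorical tables,
multivariable logistic regression (odds ratios with Wald 95% CIs), and ROC
analysis with DeLong variance estimates, confidence intervals and paired
AUC tests.

Because real patient CT volumes cannot ship with the package, a synthetic
phantom module generates CT-like volumes (body / subcutaneous fat /
muscle / visceral fat / bone compartments at realistic HU) whose
craniocaudal fat profile is controlled by a single concentration
parameter, plus simulated cohort tables with group-level distributions
matching published IBD case-control parameters. Every downstream stage is
exercised end-to-end on those phantoms.

## Worked example

Simulate a case-control cohort with published group parameters and fit the
discrimination model (CV enters the linear predictor as a fraction, so its
odds ratio is per unit change of SD/mean):

```python
from vatprofiler import CohortSpec, DiscriminationModel, simulate_cohort

cohort = simulate_cohort(CohortSpec.ibd_defaults(arm="automatic", seed=1))
result = DiscriminationModel.from_dataframe(cohort, positive="CD", negative="UC").fit()
print(result.summary())
```

```
Cohort discrimination analysis
==============================================================
subjects: 606  (positive: 365)

Logistic regression (odds ratios, Wald 95% CI)
--------------------------------------------------------------
  const              OR     8.61 (3.80, 19.52)  p = 0.000
  age_years          OR     0.93 (0.91, 0.94)  p = 0.000
  perianal_disease   OR     6.08 (3.52, 10.50)  p = 0.000
  crp_mg_l           OR     1.01 (1.00, 1.01)  p = 0.000
  esr_mm_hr          OR     1.00 (1.00, 1.01)  p = 0.013
  cv_pct             OR     3.60 (0.75, 17.39)  p = 0.111

ROC analysis
--------------------------------------------------------------
  age_years          AUC 0.752 [0.713, 0.792]  sens 63.29%  spec 75.93%
  perianal_disease   AUC 0.638 [0.607, 0.669]  sens 36.71%  spec 90.87%
  crp_mg_l           AUC 0.717 [0.675, 0.759]  sens 71.23%  spec 64.32%
  esr_mm_hr          AUC 0.610 [0.564, 0.656]  sens 70.41%  spec 48.96%
  cv_pct             AUC 0.541 [0.495, 0.588]  sens 31.51%  spec 78.01%
  combined           AUC 0.829 [0.796, 0.861]  sens 80.82%  spec 70.54%
```

Younger age and perianal disease strongly predict CD, the CV biomarker
adds a positive but modest adjusted effect in this simulated cohort (the
marginals are simulated independently, so the combined AUC is optimistic
relative to correlated real data), and the combined model dominates every
single predictor. Sensitivity/specificity are reported at the
Youden-optimal cutoff.

The imaging path runs the same way from a phantom:

```python
from vatprofiler import (PhantomSpec, ProfileSpec, generate_phantom, threshold_fat,
                         body_mask, separate_compartments, select_slices,
                         subject_metrics, LabelMask)

spec = PhantomSpec(vat_profile=ProfileSpec(family="beta", concentration=2.0), seed=7)
volume, truth, landmarks = generate_phantom(spec)
body = body_mask(volume)
fat = threshold_fat(volume)                       # default window [-190, -30] HU
fat = LabelMask(fat.data & body.data, fat.spacing)
vat, sat = separate_compartments(fat, body)
plan = select_slices(landmarks, spacing_mm=3.0)   # the 35 representative slices
print(subject_metrics(vat, landmarks, plan).summary_row())
```

A caudally concentrated profile (`concentration=2.0`) yields a lumbar CV
near 90%, a uniform one (`concentration=0`) a CV near 0%.

There is also a CLI:
`vat-profiler simulate | segment | plan-slices | metrics | analyze | run`,
with `run` driving a seeded end-to-end pipeline from a JSON config.

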