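# Methods

## Scope and model

The package quantifies the craniocaudal distribution of visceral adipose
tissue (VAT) between the superior boundary of L1 and the pubic symphysis
on abdominal CT, and evaluates the lumbar coefficient of variation (CV)
of per-slice visceral fat areas as a biomarker discriminating Crohn's
disease from ulcerative colitis. Four stages are chained: synthetic
phantom generation, rule-based fat segmentation, landmark-anchored slice
planning with indicator extraction, and the discrimination statistics.
Automatic (CNN-based) segmentation is deliberately out of scope; the
rule-based stage is the deterministic stand-in for a semi-automatic
protocol whose operator steps are not published, so it is a
re-specification rather than a reproduction.

## Phantom generator

Each axial slice is a set of nested ellipses: a body ellipse with
semi-axes (r, 0.72 r) (default r = 140 mm), a subcutaneous fat annulus
(default 15 mm), an abdominal-wall muscle ring (default 10 mm), and a
visceral cavity at soft-tissue attenuation containing a posterior bone
disk (vertebral body). Compartment attenuations are VAT −100 HU, SAT
−105 HU, muscle/organs +40 HU, bone +400 HU, air −1000 HU, each with
additive Gaussian noise of SD 10 HU; both fat classes sit inside the
standard fat window [−190, −30] HU and every other compartment sits well
outside it (≥ 7 noise SDs away, so threshold misclassification is
negligible by construction). Default grid: 3 mm slices, 1 × 1 mm
in-plane — the coarsest slice thickness of routine abdominal protocols.

The craniocaudal VAT profile is a density over normalized position
t ∈ [0, 1] (t = 0 at L1-1, t = 1 at the pubic symphysis), scaled to a
requested total volume. Families: `uniform`; `linear`
(1 + c·(t − ½)); `beta`, the Beta(1 + c, 1) density ∝ t^c whose mass
shifts caudally as the concentration c grows. c = 0 reduces every family
to uniform. The beta family with c ≈ 2 reproduces a CD-like concentrated
profile; c ≲ 0.3 an approximately even UC/control-like profile.

Per-slice areas are realized by an exact pixel budget: the slice's share
of total volume comes from the profile CDF over the slice's t-range, and
that many cavity pixels are taken nearest to a per-slice jittered,
anisotropically stretched centre (jitter SD 5 mm, aspect U(0.75, 1.3)).
This guarantees the ground-truth profile to one pixel per slice and
conserves total volume to well under the 2% voxelization tolerance —
a guarantee free-form rejection-sampled blobs would not give — while
still producing irregular, seed-dependent blob shapes. All randomness
flows from the spec seed through one `numpy` Generator, with a fixed
number of draws per slice, so equal specs give bit-identical phantoms.

Cohort simulation draws variables independently within subject (no
copula), since only marginal group distributions are published: normal
for CV, VAT volume and age; Bernoulli for sex and perianal disease;
lognormal for CRP and ESR with (median, quartiles) matched on the log
scale. The built-in three-group defaults use the published case-control
marginals (e.g. CV 29.42 ± 15.54% CD / 25.69 ± 12.61% UC /
23.42 ± 15.62% control in the semi-automatic arm; 29.73 ± 14.67 /
26.23 ± 12.47 / 23.96 ± 11.09 in the automatic arm; perianal prevalence
129/344 and 18/237; group sizes 365/241/166). Age is published as
median (IQR); a normal approximation with a matched centre is used and
labelled synthetic. Normal draws are not truncated at zero: truncation
would distort the distribution the published means/SDs describe, and
negative CV draws are rare (≈ 3%).

Because variables are independent, simulated multivariable results
(combined AUCs, adjusted ORs) characterize the machinery, not the real
correlated cohort — single-variable distribution-level checks (e.g. the
CV-only AUC) are the quantities that transfer.

## Segmentation

* Fat: inclusive HU window, default [−190, −30], configurable.
* Body: voxels above −500 HU, 3-D hole filling, largest 26-connected
  component.
* Compartments: the body's boundary shell is the rim lost to a
  2-voxel (default) 26-connected erosion with border value 1 (volume
  faces at the stack ends do not count as boundary). Every 26-connected
  fat component touching the shell is subcutaneous; the remainder is
  visceral. A component bridging shell and cavity resolves wholly to
  SAT — deterministic and traversal-order independent.
* Overlap: Dice = 2|∩|/(|A|+|B|), Jaccard = |∩|/|∪|; two empty masks
  score 1.0 (agreement), empty vs non-empty 0.0.

## Anatomy and indicators

Landmarks are stored as seven positions: the superior boundaries
L1-1 … L5-1 of the contiguous lumbar vertebrae, L5-5 (L5 inferior), and
the pubic symphysis; z is in mm and decreases craniocaudally in that
order. The representative plan places n slices per vertebra at the
midpoints of n equal subdivisions of the vertebral span, plus a pelvic
block between L5-5 and the pubic symphysis; the published total of 35
is met by the default split 5 × 5 lumbar + 10 pelvic, both counts
configurable because the exact split is not published. Positions snap to
the nearest acquired slice (slice i spans [i·t, (i+1)·t); boundary ties
go cranially). Lumbar height is |z(L1-1) − z(L5-5)| in meters.

Indicators per subject: per-slice VFA (pixel count × pixel area, cm²),
VAT volume (voxel count × voxel volume, cm³ — algebraically identical to
Σ VFA × thickness over a complete tiling), VAI = VFA/height², VAT ratio
= (VFA × thickness)/volume × 100% with thickness converted mm → cm so the
ratio is dimensionless and a complete tiling sums to exactly 100%. The
lumbar mean/SD/CV use **every acquired slice** whose centre lies between
L1-1 and L5-5; the CV across the 35 representative slices is computed
separately as `cv_35`, since the two statistics genuinely differ and both
are reported in the literature the defaults emulate. SDs use the sample
(n − 1) denominator — unstated in the source material, but conventional
at n ≈ 25–60 slices. CV is flagged undefined (NaN) when the mean is zero.

## Statistics

* Test selection in `auto` mode: Shapiro-Wilk per group at alpha 0.05
  (groups of n < 3 or zero range are treated as normal); parametric
  summaries are mean ± SD, nonparametric median (IQR).
* Three-group follow-ups are judged at 0.05/3 = 0.0167 exactly.
* Chi-square uses Yates continuity correction only for 2×2 tables with
  some expected count below 5.
* Logistic regression: statsmodels maximum likelihood, Wald 95% CIs on
  odds ratios; separation is detected (solver exception, separation
  warning, or |coefficient| > 20) and flagged with CIs marked unreliable.
* AUC is the tie-corrected Mann-Whitney probability computed from
  midranks; its variance and CI use DeLong placement values, and the
  paired AUC comparison is DeLong's z-test with the placement covariance.
  Degenerate case: identical scores give difference 0 and p = 1.
* Operating points maximize Youden's J over observed cutoffs
  (positive ⇔ score ≥ cutoff); ties break toward higher specificity,
  an arbitrary but fixed clinical convention.
* The discrimination model's CV covariate defaults to fraction scale
  (CV/100): per-unit odds ratios on the percent scale would be
  uninformatively close to 1, and published adjusted ORs of order 5–10
  are consistent with fraction-scale coding. Percent scale remains
  available. Covariate coding beyond that (age continuous, raw CRP/ESR)
  is a package choice and configurable, not an assertion about any
  particular published fit. Rows with missing covariates are dropped
  listwise.

## Problem sizes and numerical choices

The test suite and the acceptance script run phantoms on a compact
geometry (120 × 96 × 128 voxels, 58 mm body radius, 150 cm³ VAT) chosen
so a 60-phantom concentration grid completes in seconds while keeping
≥ 3 000 cavity pixels per slice — two orders of magnitude above
voxelization tolerance. Distribution-level checks use 500 simulated
cohort replicates; calibration checks use 2 000 null simulations
(t-test, DeLong) and 200 logistic replicates at n = 600. Tolerances:
volume conservation ≤ 2%; noise-free pipeline Dice ≥ 0.99 and noisy
(SD 10 HU) ≥ 0.95; uniform-profile lumbar CV < 2%; tiling identities to
float precision (1e-9 relative or better).

## Known limitations

* The phantom's elliptical compartments lack organ anatomy, contrast
  enhancement, bowel gas and mesenteric "creeping fat" microstructure;
  passing phantom tests demonstrates the geometry/accounting of the
  pipeline, not radiological realism. On real CT, the fat window and
  compartment separation would face partial-volume voxels and fat
  bridging through the abdominal wall that the phantom does not create.
* The phantom covers only the analysis range (L1 to pubic symphysis),
  not the full abdomen; indicators are insensitive to thoracic slices by
  construction.
* Cohort marginals being independent, simulated joint statistics are
  optimistic; only marginal/distribution-level quantities are compared
  against published values.
* The semi-automatic segmentation protocol is re-specified, not
  reproduced; Dice targets against phantom ground truth are internal
  consistency checks, not operator-agreement estimates.
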