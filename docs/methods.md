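# Methods

`dualpet` implements a concordance-aware, lesion-level quantification and
outcome-analysis pipeline for paired FDG / CXCR4-directed PET studies, plus a
synthetic cohort generator that makes every stage testable without patient
data. This note records the model, the tunable parameters, the numerical
choices, and the places where the design was genuinely open.

## Coordinate and volume conventions

A `ScalarVolume` is a 3-D array with physical spacing: voxel index
`(i, j, k)` (0-based) maps to `origin_mm + index * spacing_mm`. All distances
are computed in physical millimetres under this single convention. Only
axis-aligned NIfTI affines (positive diagonal scaling + translation) are
accepted; oblique or flipped affines are rejected rather than silently
reinterpreted, because every downstream overlap and distance computation
assumes the convention above. PET volumes carry body-weight SUV; the
`to_suv` conversion is `Bq/ml x weight_kg / (dose_MBq x 1000)` and assumes
decay/scatter/attenuation correction was already applied by the scanner.
Masks are resampled with nearest-neighbor interpolation (a mask must stay
binary); PET volumes are never resampled in the default pipeline — lesion
masks are moved onto each PET grid instead, and the pipeline requires the two
tracers' volumes to be co-registered on a common grid.

## Lesion definition and concordance adjudication

Lesions are connected components of the binary segmentation mask under
26-connectivity (configurable to 6); 26 is the standard choice for blob-like
PET uptake. Per lesion we record the voxel list, voxel count, volume
(count x voxel volume, ml) and the intensity-unweighted centroid of voxel
centers.

Cross-tracer matching computes exact voxel intersections between every
FDG/CXCR4 lesion pair. A lesion is **concordant** when at least one pair
exceeds a 10% overlap fraction *strictly* (`> 0.10`); otherwise it is
tracer-only (discordant). Open choices resolved here, all exposed in
configuration:

* **Overlap denominator** — intersection / min(volume A, volume B), default
  `min` (options `a | b | union`). The min-denominator is symmetric in the
  tracer roles and robust when one tracer's delineation is much larger than
  the other's.
* **Strictness** — `>` for concordance, `>=` for the bone-overlap site rule
  (below); both configurable.
* **Many-to-many matches** — category is a per-lesion property (any
  qualifying pair suffices); no one-to-one assignment is forced, because the
  quantity of interest is lesions per tracer per category, not matched pairs.
* **Cohort counting** — a group of mutually qualifying concordant lesions
  (a connected component of the qualifying-pair graph across both tracers)
  counts as ONE concordant lesion, so `concordant + FDG-only + CXCR4-only`
  partitions the distinct-lesion total.

**Site**: a lesion is *medullary* when >= 10% (inclusive) of its voxels fall
inside the bone mask, else *extramedullary*; splenic membership is flagged on
any (>= 1 voxel) overlap with the spleen mask. A simple SUV-threshold
segmenter (`threshold_segment`) is provided as a stand-in lesion detector for
workflows without precomputed masks; it is not a substitute for a real
segmentation model and is off by default (masks are inputs).

## Burden features

Per lesion: SUVmean, SUVmax, MTV (ml), and the intensity-volume product —
TLG = MTV x SUVmean on FDG, TLC = MTV x SUVmean on CXCR4. Patient-level
aggregates are stratified by tracer x site x concordance class and named in
bracket notation, e.g. `TLG[FDG medullary concordant]` (32 imaging columns).

* Subset **SUVmean is voxel-pooled** (volume-weighted mean of lesion means,
  which equals the mean over the union region on a uniform grid), not the
  unweighted mean of lesion means; the pooled mean is what "mean uptake over
  the subset" denotes.
* **Empty subsets** yield *missing* intensity features but *zero* burden
  features: a patient with no lesions in a subset has no uptake level there,
  but genuinely zero tumor volume. This keeps group comparisons well-defined
  while preserving the burden information.
* **sDmax** is the maximum pairwise distance between lesion *centroids* (cm)
  divided by body surface area (m^2). Centroids rather than surface voxels:
  reproducible, cheap, and insensitive to segmentation-boundary noise. BSA
  uses DuBois-DuBois (`0.007184 h^0.725 w^0.425`) by default, Mosteller as an
  option. Fewer than two lesions gives a missing value.
* **Spleen reference** is the mean SUV over spleen voxels excluding voxels in
  either tracer's lesion mask; a fully lesion-covered spleen yields missing.

## Univariate statistics

* **Welch's t-test** (unequal variances, Welch-Satterthwaite df) with the 95%
  CI for the mean difference; **Hedges' g** = J x (mean diff) / pooled SD with
  the small-sample correction J = 1 - 3/(4 df - 1), CI from the normal
  approximation SE^2 = (nx+ny)/(nx ny) + g^2 / (2 df). Missing values are
  dropped per sample with counts reported (complete-case per feature).
* **2x2 tables**: chi-square without continuity correction by default,
  auto-switch to Fisher's exact when any expected cell < 5; odds ratio with
  Haldane-Anscombe +0.5 on zero cells and a Woolf-logit 95% CI.
* **Kaplan-Meier** product-limit with Greenwood variance; the 95% band is
  computed on the log scale, `S exp(+/- 1.96 sqrt(sum d/(n(n-d))))`, clipped
  to [0, 1]. With no censoring the estimate equals the empirical survival
  function exactly.
* **Log-rank** two-group test (1 df).
* **Hazard ratios** are approximated as **event-rate ratios**: events per
  person-time (default) or per unit (`proportion` option). On exponential
  data the person-time ratio converges to the true hazard ratio; the CI is
  `exp(log HR +/- 1.96 sqrt(1/dA + 1/dB))` with +0.5 continuity on zero
  event counts.
* **Median dichotomization**: high = value > cohort median; ties go low;
  missing excluded.

No multiple-testing correction is applied anywhere: with dozens of correlated
imaging features on small cohorts the p-values are descriptive and are meant
to be read together with the effect sizes.

## Outcome models and attribution

Two binary endpoints: therapy response, and survival dichotomized at a
183-day (~6-month) horizon — death before the horizon is "short", units
observed at/after the horizon are "long", units censored alive before the
horizon carry no label and are excluded (count reported).

CART trees (Gini, default `max_depth 3`, `min_samples_leaf 5`) are trained
under repeated stratified 5-fold cross-validation (10 repeats, seeded).
Pruning uses cost-complexity with the alpha chosen on the training split by
inner 3-fold CV (balanced accuracy) under the one-standard-error rule — the
simplest tree within one SE of the best — so pure-noise labels collapse to a
root-only stump. Missing feature values are handled natively by the tree's
learned missing-value routing (`missing_go_to_left`), which the attribution
honors; this replaces ad-hoc "send missing to the majority child" rules with
a routing that is actually fitted to the data and exposed on the model.

**SHAP** attributions are exact Shapley values for a single tree, computed
with the polynomial-time path-dependent recursion; the coalition value
function is the cover-weighted tree-path conditional expectation, so no
background dataset is needed and results are deterministic. Local accuracy
(base value + sum of attributions = predicted probability) holds to
floating-point precision, and the implementation is validated against an
exponential brute-force Shapley enumeration in the test suite. Per-fold
validation samples are explained (a configurable choice; training-fold
attribution would overweight the fit); mean |SHAP| is pooled over all
validation samples across folds. Each fold votes a per-feature direction —
the sign of the within-fold Pearson correlation between feature value and
attribution — abstaining on zero-variance attributions; `sign_agreement` is
the fraction of voting folds matching the modal sign, and features with
>= 0.80 agreement are flagged as directionally stable. Performance is
reported as per-fold AUROC and balanced accuracy, with no single headline
metric.

## Synthetic cohort generator

The generator's defaults are the study conditions of the clinical cohort the
pipeline was designed around (22 units):

| parameter | default | rationale |
| --- | --- | --- |
| lesions per unit | uniform 20–109 | clinical range (median 64.5) |
| concordant fraction | mean 0.40, sd 0.18 (clipped normal per unit) | clinical median 40.0%, range 5.6–87.1% |
| extramedullary fraction | mean 0.40, sd 0.15 | clinical median 39.8%, range 4.8–77.5% |
| CXCR4-only share of discordant | 0.795 | clinical 661 / (661+171) |
| lesion radius | uniform 4–9 mm | typical focal myeloma lesions; no size distribution is published, so chosen once for realistic burden and non-overlapping placement |
| grid | 64 x 64 x 96 @ 4 mm | whole-body PET-like field of view at PET-typical voxel pitch |
| peak SUV | lognormal per tracer/category (FDG mu 1.5, sigma 0.40; CXCR4 mu 1.8, sigma 0.45) on background 1.0 | CXCR4 ligands show higher tumor-to-background contrast than FDG in myeloma |
| baseline hazard | ln2 / 210 per day | calibrated once so the *marginal* median OS under the default coefficient frailty is ~198 days, the clinical cohort's median |
| censoring | 0.15, uniform before the event time | modest administrative censoring |

Anatomy is a minimal analytic body phantom — an ellipsoidal body containing a
spinal column, a pelvic slab and two femur cylinders (the bone compartment)
and a splenic ellipsoid — rendered from the same analytic predicates used to
sample lesion centers, so site truth is exact by construction. Medullary
lesions are sampled uniformly inside bone; extramedullary lesions inside the
body with a clearance margin from bone so the planted site label is clean.
Lesion centers are rejection-sampled with a pairwise separation of the two
radii plus two voxel pitches, which guarantees rendered spheres cannot merge
even through 26-connectivity diagonals; on (rare) sampling failure the lesion
is placed anyway and flagged `overlapping_placement` in the truth table.

Lesions are uniform-SUV spheres by default (MTV/TLG then analytic, which the
tests exploit), with an optional Gaussian taper (sigma = radius/2).
Concordant lesions share a center with independently jittered radii per
tracer (+-15% by default) so cross-tracer overlap fractions vary around the
adjudication threshold; discordant lesions are rendered in exactly one
tracer.

Outcomes are generated from the **planted truth features** (not re-extracted
ones), so extraction error is measurable separately: response is
Bernoulli(logistic) and survival exponential with hazard
`baseline x exp(linear predictor)`, both on cohort-standardized features.
The default coefficients plant the directions of the clinical findings —
responders have lower `SUVmean[FDG * concordant]`; higher
`TLG[FDG medullary concordant]`, `sDmax_FDG` and
`MTV[CXCR4 medullary concordant]` shorten survival, higher BMI lengthens it —
with magnitudes chosen once to give median-split event-rate ratios in the
2.5–4 range. Feature-level simulators (`simulate_group_difference`,
`simulate_survival_groups`, `plant_response_effect`) plant *exact*
standardized differences or rate ratios for recovery testing without
rendering images.

What the phantom deliberately does **not** model: PET noise and
point-spread-function blur, scanner reconstruction, respiratory motion,
deformable anatomy, within-patient correlation between repeated cycles, and
realistic inter-lesion SUV/size dependence. Passing recovery tests therefore
demonstrates the correctness of the quantification and inference machinery
under known truth — not segmentation robustness or clinical validity on real
scans.

## Problem sizes used in validation

The shipped validation suite works at sizes chosen to make the statistical
checks decisive while staying cheap: oracle equivalence on 100 random 20^3
phantom pairs; Welch recovery at 200 replicates of n = 200 with a planted
g = -1; survival recovery at 100 replicates of n = 300 with a planted rate
ratio of 2.6; SHAP brute-force equivalence on 50 random trees (depth <= 3,
<= 6 features) and planted-predictor recovery over 50 generator seeds at
n = 150; type-I error over 2000 null replicates at n = 50 per arm.

## Known limitations

* Analysis units are treated as independent; cohorts where some patients
  contribute two therapy cycles violate this mildly, and no within-patient
  correlation is modeled or corrected for (`analysis_unit` is recorded in the
  configuration for auditability).
* The event-rate-ratio HR is a crude approximation to a Cox hazard ratio and
  is exact only under proportional exponential hazards.
* The Hedges' g CI uses the normal approximation, slightly anticonservative
  below ~n = 20 per arm.
* Tree SHAP is implemented for single trees (the models used here), not
  ensembles.
* The generator's lesion size/uptake distributions are calibrated only to
  published cohort medians and ranges; the joint distribution is invented.
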