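# Methods

This note documents the models, the parameter choices that matter, and
the limits of what the synthetic experiments can show.

## Synthetic cohort generator

Each knee carries a scalar latent osteoarthritis severity z ~ N(0,1).
Everything observable is a noisy function of z; nothing downstream is
allowed to see z except through those observables.

**Grades.** Feature k of the 36-grade reading sheet has a loading
w_k ∈ [0,1] and range 0..G_k.  The grade is the ordinal bin of
w_k·z + ε, ε ~ N(0, σ_g), with bin thresholds placed at fixed quantiles
of the marginal N(0, w_k²+σ_g²) so that most knees grade 0 (70% for 0–1
features; 60/85/95% cuts for 0–3; 45/70/85/95% for the 0–4 global
grade), emulating the sparsity of ordinal radiographic grading.  Default
loadings follow the qualitative tiers reported for real reading sheets:
the global (KL-style) grade highest (0.80), osteophytes/JSN/sclerosis
moderate (0.30–0.55), and chondrocalcinosis, cysts, attrition and tendon
ossification zero — those features are *constructed* to be chance-level
classifiers.  σ_g defaults to 0.6; together with a pain slope of 2.5
(below) this puts the best single grade near 58% AUC and the tier
ordering (global grade > osteophytes > JSN/sclerosis > chance) in place
at n = 2756.  Absolute AUC magnitudes of real cohorts are not
reproducible here: half the synthetic cohort is a widespread-pain
subgroup whose pain is independent of severity by construction, which
compresses every attainable AUC toward 50.

**Pain.** Persistent pain propensity is logistic:
p = σ(−0.85 + 2.5·z + 0.55·z_BMI + 0.45·[female]) for non-widespread
subjects, and a flat 0.45 for the widespread subgroup (fraction 0.5,
matching a cohort in which the widespread-pain exclusion removes about
half the sample).  The BMI and sex terms exist so that demographic
augmentation of the feature set has signal to find; their sizes were
fixed once so that adding sex+BMI to the manual grades produces a small
but consistent AUC improvement.  The three instruments (telephone
screen, questionnaire, clinic interview) each report persistent pain
flipped independently with probability 0.15 — i.i.d. symmetric flips, no
instrument-specific error rates and no time ordering, since none are
identifiable from a cross-sectional design.

**Images.** Rendering is deliberately schematic: spline bone outlines
drawn as bright Gaussian ridges (σ = 1.8 px) on a noisy background, with
three severity effects — the tibia translates toward the femur by
0.02·size px per severity SD (the joint space never closes below
0.015·size), joint-margin landmarks gain outward bumps of
0.012·size px per positive SD (osteophytes), and a bright band under the
tibial plateau scales with σ(1.3·z) (sclerosis).  Between-subject
variation adds a global similarity jitter, small per-bone rigid offsets
and one smooth sinusoidal bending mode per bone.  This is not
photorealism; it provides exactly enough edge structure for patch
regressors and texture models to learn from, with pixel-exact ground
truth.  Consequences: landmark errors here (~0.5 px median) say nothing
about clinical images with exposure artifacts, implants or anatomy the
template lacks; conclusions transfer only about the *machinery*, not
about clinical accuracy.

## Shape model

Generalized Procrustes alignment with similarity transforms only
(closed-form complex least squares per shape, mean re-normalised to
centroid 0 / unit RMS, iterated to 1e-8).  Tangent-space projection is
omitted: synthetic pose variation is a few percent in scale and a few
degrees of rotation, where the spherical/tangent distinction is far
below the model's other error sources.  PCA retains the smallest number
of modes reaching 95% variance by default (98% for the CLM, where extra
shape freedom helps the constraint step).  One caveat discovered while
testing: when the training set is small and jitter includes a scale-like
mode, the mean shape lies almost entirely inside the mode span, and the
(pose, b) decomposition of s = T(x̄+Pb) is no longer unique even though
reconstruction is exact — parameter-recovery checks must therefore
compare reconstructed geometry, not raw coefficients.

## Appearance model

Texture is sampled at every reference-frame pixel inside the Delaunay
triangulation of the mean shape (scaled to a 128 px width by default,
frozen into the model), by barycentric piecewise-affine warp and
bilinear interpolation, with out-of-image reads clamped to the nearest
pixel.  Textures are normalised to zero mean / unit variance, making
features invariant to affine intensity changes.  The combined model
stacks W_s·b_s on b_g with the classical variance-balancing weight
W_s = √(Σλ_tex/Σλ_shape) (W_s := 1 if either block is degenerate) and
retains 95% of the concatenated variance.  The texture region is the
convex hull of the full landmark set, not per-bone masks — a documented
simplification.

## Landmark search (CLM)

A random-forest regressor on 16×16 downsampled intensity + gradient
images predicts the joint bounding box (centre and log-width); the mean
shape is initialised inside it.  Per-landmark random forests (10 trees,
15×15 normalised patches, training offsets uniform in ±16 px, 20 patches
per image) predict the displacement from patch centre to landmark; at
search time a grid (step 2 px, radius 12 px) of patches votes into a
response map, each map's argmax (ties to the smallest row, column) is a
candidate, and pose+parameters are least-squares fitted to the
candidates with |bⱼ| ≤ 3√λⱼ enforced.  Iteration stops when mean
movement < 0.5 px (max 20).  Single resolution throughout — a deliberate
divergence from production coarse-to-fine CLM systems, justified by the
clean synthetic imagery.  All sampling seeds are config.

## Outcomes and feature sets

The three binary pain reports define four outcomes: each instrument
alone, and consistent pain (unanimous yes = positive, unanimous no =
negative, otherwise excluded).  The widespread-pain exclusion drops
flagged rows before label derivation.  Feature sets: each grade alone;
all 36 grades (ordinal values used directly as integers — tree ensembles
split ordinals natively, so no one-hot encoding); grades + sex + BMI
(age exists in the tables but is excluded from the default augmentation,
available behind a config flag); automated shape-only, texture-only or
combined vectors; grades + combined; and "best automated", which selects
among the three automated variants by an inner 3-fold CV on each outer
training split only, so selection never sees test rows.

## Evaluation engine

Random forest, 40 trees, stratified 5-fold CV, 5 repeats; each repeat
refolds (seed + repeat index) and pools its out-of-fold class
probabilities into one Mann–Whitney (midrank) AUC, so the report is mean
± SD over exactly 5 AUCs.  Forest depth is unrestricted but
`min_samples_leaf` is set to 5% of the training split: fully-grown trees
give probability estimates so noisy that pooled out-of-fold AUC loses
several points against the closed-form value in a binormal
single-feature check (Φ(d/√2) for class separation d); leaf smoothing
restores the check to within 2 AUC points while leaving chance-level
features at 50% and all orderings intact.  The leaf setting is recorded
in the result's config echo.

**AUC comparison.** The difference statistic is the mean of the
per-repeat AUC differences.  Its variance is the DeLong (co)variance of
the repeat-averaged out-of-fold scores (paired form when both runs share
rows, labels and fold seed; summed variances otherwise) *plus* the
between-repeat variance of the difference divided by the repeat count —
the DeLong term treats scores as fixed and misses refold/retrain noise,
and without the correction the null test rejects at 2–4× the nominal
rate.  Because the repeat-variance component is estimated with only
n_repeats − 1 degrees of freedom, the squared standardised difference is
referred to a Satterthwaite-matched F(1, ν̂) rather than χ²(1) (the two
coincide as ν̂ → ∞).  The acceptance suite verifies the resulting type-I
error over 100 null cross-validated replicates sits inside the binomial
95% band around 0.05; residual anticonservatism of a point or two can
remain, which is why borderline p-values near 0.05 should not be
over-read.  A permutation alternative would be exact but costs two
orders of magnitude more compute; it was noted and not made the default.

## Problem sizes

The test suite and drivers choose sizes where each check is both
meaningful and quick: tabular cohorts of 600–2756 rows; 20 cohort
replicates for the consistency-gain property; a rendered PA cohort of
90 images (40 train / 50 test) for the CLM checks at 192 px, and 200/60
in the analysis drivers; 100 null replicates at n = 400 for test
calibration.  The full suite runs in a few minutes on one CPU.

## Known limitations

* The widespread subgroup's pain is *pure* noise, so removing it raises
  AUC sharply in the synthetic tables; in real cohorts widespread pain
  is only partially independent of joint pathology and the exclusion has
  much smaller, mixed effects.
* One latent dimension drives geometry, texture, grades and pain, so all
  informative features are mutually correlated; feature-set comparisons
  therefore understate the value of complementary information.
* Grade loadings, the pain link and flip noise are stylised settings
  chosen to reproduce qualitative orderings, not fitted to any cohort;
  printed AUC magnitudes should not be compared numerically with
  clinical studies.
* The renderer has no exposure variation, no left/right laterality
  handling and no pathology beyond the three severity effects.

## Grade-feature naming

Cohort tables use snake-case grade columns; the mapping to the reading
sheet is mechanical: feature type (`osteophytes`, `jsn` = joint space
narrowing, `sclerosis`, `cyst`, `attrition`, `chondrocalcinosis`,
`effusion`, `ossification`, `ossified_loose_body`,
`kl_grade` = global 0–4 grade), then bone and/or sub-location
(`femur`/`tibia`/`patella`, `anterior`/`posterior`,
`superior`/`inferior`, `upper`/`lower`, `medial`/`lateral`), then
compartment (`tf` tibiofemoral, `pf` patellofemoral), then view (`pa`
posteroanterior, `la` lateral).  E.g.
`osteophytes_femur_posterior_pf_la` = osteophyte grade (0–3) on the
posterior femur of the patellofemoral joint, lateral view.  The
canonical order and ranges live in `kneestudy.grading.GRADE_FEATURES`.
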