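# Methods

This note documents the models, conventions and numerical choices behind
`batscan`, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The phantom cohort model

Real BAT studies rest on manually segmented adipose depots from paired
PET-CT; no such data ship here.  The phantom module generates cohorts
with the *statistical structure* the analysis assumes, not anatomical
realism:

* **Geometry.** Each patient is a 14×60×60 lattice at 5×1×1 mm
  (slice, row, column).  Depots are jittered ellipsoids at fixed sites:
  three bilateral pairs (cervical, supraclavicular, axillary), mirrored
  about the mid-column, plus 0–7 midline mediastinal depots, for 6–13
  depots per patient (uniform).  Bilateral depots are always generated as
  left–right pairs, so the symmetry precondition of patient criterion 2
  holds by construction.
* **Tissue contrast.** Depot HU is a Gaussian random field clipped to the
  adipose window [−190, −10].  WAT: mean −110 HU, SD 5, correlation
  length 3 mm.  BAT: mean shifted by +20 HU, SD 12, correlation length
  1.2 mm — denser, rougher texture, motivated by BAT's small lipid
  droplets and high mitochondrial content.  These effect sizes are free
  parameters of the phantom, **not** estimates of biology: no published
  quantitative CT texture contrast between BAT and WAT exists to
  calibrate against.  At the defaults the classes are strongly separable
  (depot AUROC near 1); `bat_mean_hu_shift = 0` is the null.
* **PET.** Depot SUV is a per-depot constant plus small noise, clipped
  into the generating band: BAT ∈ [1.8, 4.0] (entirely ≥ 1.5), WAT ∈
  [0.4, 1.2] (entirely < 1.5).  BARCIST labels therefore round-trip the
  generator's truth exactly — a property the tests verify.
* **BAT assignment.** A patient is BAT-positive with probability
  `bat_prevalence` (default 0.5, matching a 43-vs-43 development
  design).  In positive patients each bilateral pair is jointly BAT with
  probability 0.6 and each mediastinal depot with 0.3 (at least one
  forced), reflecting the predominantly symmetric physiologic
  distribution.
* **Calcium.** Per territory (coronary and thoracic-aorta boxes), a
  patient receives 1–3 single-slice lesions (4–12 voxels, 150–450 HU)
  with probability 0.10 if BAT-positive and 0.35 otherwise — the
  protective-association direction, with rates chosen to give clear
  ordering at cohorts of a few hundred patients.
* **Seeding.** One integer seed drives a `SeedSequence.spawn` hierarchy
  per patient: identical spec + seed reproduces the cohort bit for bit,
  and enlarging `n_patients` leaves earlier patients unchanged.
* **Second rater.** Interobserver segmentation is emulated by flipping
  ~15% of each depot's in-plane boundary voxels (seeded), which keeps
  masks clearly overlapping while perturbing boundary-sensitive features.

What the phantom does **not** emulate: scanner noise spectra, PET
kinetics and partial-volume effects, anatomy (organs, bone, lungs),
depot-shape biology, and site effects beyond a mean-HU shift.  Passing
tests therefore demonstrate correctness of the *machinery* and
recoverability of planted signal — not clinical performance on real CT.

## Preprocessing

* **Resampling.** Target spacing (0, 1, 1) mm: in-plane B-spline (cubic)
  resampling to 1×1 mm with slice spacing preserved (a zero component
  means "keep", the common radiomics-platform convention).  Masks use
  nearest-neighbor and are re-binarized.
* **Display window.** A 40/400 HU window-center/width is carried in the
  config for provenance but never applied before feature extraction:
  it would clip the entire adipose range to a constant and destroy every
  feature.  Features are computed on raw HU.
* **Filter bank — 19 image types.** Original; 8 one-level stationary
  (undecimated) `coif1` wavelet sub-bands (L/H per axis); Laplacian of
  Gaussian at σ ∈ {1,…,5} mm (scale-normalized, sign-flipped so bright
  blobs score positive); square, square-root, logarithm and exponential
  intensity remaps (each rescaled back into the input range, see the
  docstrings for the exact pointwise formulas); gradient magnitude.
  This is the unique standard bank consistent with the per-class census
  (e.g. 22 × 19 = 418 co-occurrence features).
* **Discretization.** Fixed bin width, 25 HU by default, anchored at the
  ROI minimum: level(v) = ⌊(v − min)/w⌋ + 1.  Min-anchoring makes all
  texture features invariant to adding a constant.  On nonlinearly
  filtered images a fixed 25-unit width is meaningless (ranges differ by
  orders of magnitude), so the effective width is widened when needed to
  cap the level count at 64; the original-image discretization is never
  affected.

## Feature definitions and degenerate-case rules

The census is 19 × (18 first-order + 22 GLCM + 16 GLRLM + 16 GLSZM +
14 GLDM + 5 NGTDM) + 14 shape = **1,743** features, of which 19 × 73 =
1,387 are texture.  Conventions:

* GLCM and GLRLM use the 13 unique 3D directions at Chebyshev distance 1
  and are direction-averaged; GLCM matrices are symmetrized and
  normalized per direction.  GLSZM zones are 26-connected.  GLDM
  dependence of a voxel is 1 + the number of identical-level
  26-neighbors (the center counts, so the dependence index starts at 1
  and small-dependence emphasis never divides by zero).  NGTDM excludes
  voxels with no in-ROI neighbor.
* First-order skewness/kurtosis use population moments (kurtosis is the
  raw fourth standardized moment); entropy and uniformity reuse the
  texture discretization.
* Shape uses a marching-cubes mesh for surface/volume/sphericity, PCA
  of voxel-center coordinates for axis lengths (length = 4√λ), and
  pairwise distances (hull-thinned) for maximum diameters; shape is
  computed once, on the original geometry only.
* Degenerate ROIs never produce NaN: a constant ROI has correlation 1,
  contrast 0, maximum probability 1, zero spread measures, skewness and
  kurtosis 0; a single-voxel ROI takes the documented perfect-dependence
  limits.  Extraction raises (naming the depot) if any census entry is
  non-finite.

Every matrix family is verified element-wise against an independent
exhaustive-enumeration oracle on lattices up to 4×4×3 with ≤ 4 levels.

## Selection cascade

1. **ICC filter.** ICC(A,1) — two-way random effects, absolute
   agreement, single measures, the conventional reading of
   "interobserver reproducibility" — computed per feature between the
   two segmentations, from the classic ANOVA mean squares; features with
   ICC < 0.80 are removed.  Exactly identical columns score 1;
   vanishing denominators score 0.  The implementation is cross-checked
   against an independent statistical package in the tests.
2. **Redundancy pruning.** Pairs with |Pearson r| > 0.90 are scanned by
   descending |r| (ties lexicographic by name); within a pair the
   feature with the lower |point-biserial correlation with the BAT
   label| is removed; pairs with an already-removed member are skipped.
   Constant columns have correlation defined as 0.  The order makes the
   result deterministic.
3. **LASSO.** L1-penalized *linear* regression on the 0/1 label
   (standardized features), penalty chosen from a log grid (10⁻³…1, 25
   points) by mean cross-validated AUROC of the linear predictions over
   seeded stratified folds.  Nonzero coefficients survive.  An empty
   selection at every penalty raises with advice to weaken the grid.

The cascade runs on the training depots only, so the internal-validation
split never informs selection.  Each stage is an sklearn transformer
(`fit`/`transform`/`get_support`) and composes in a `Pipeline`.

## Depot model and scoring

RBF-kernel SVM with balanced class weights (the depot classes are
imbalanced) and bandwidth from the median heuristic
(γ = 1/median pairwise squared distance on standardized features).  The
margin is mapped to a radiomics score RS ∈ [0, 1] by held-out logistic
(Platt) calibration over seeded stratified folds.

**Youden cutoff.**  RS\* maximizes J(t) = sensitivity + specificity − 1
over the observed training scores, evaluated with the *same strict rule
used for classification*: positive iff score > t.  Ties break toward the
higher threshold (favoring specificity).  Using one inequality
convention throughout is deliberate: mixing "≥ at selection, > at
classification" would systematically misclassify the depot whose score
equals the cutoff and break the perfect-accuracy property on separable
data.  A cutoff with J ≤ 0 is flagged degenerate.

**Patient criteria.**  Criterion 1: ≥ 1 positive depot.  Criterion 2: a
region among {cervical, supraclavicular, axillary} with both left and
right depots positive, or ≥ 1 positive mediastinal depot.  "Symmetric
pair" is read from the region/laterality labels — same region, opposite
sides, same patient — with no spatial-coordinate check.  The implication
criterion 2 ⇒ criterion 1 is verified over all 2⁶ positivity patterns.

## Calcium scoring

Lesions are connected components (in-plane 8-connectivity, per slice —
Agatston is a per-slice score, so no 3D bridging) of voxels **strictly**
above 130 HU inside the territory, discarding components of fewer than 3
pixels.  Slice score = area (mm²) × weight by maximum HU: 1 for
(130, 200), 2 for [200, 300), 3 for [300, 400), 4 for ≥ 400.  Calcium
volume = lesion voxels × voxel volume.  Scores are computed at whatever
spacing is supplied and the spacing is recorded in the result; no
slice-thickness rescaling is applied (the classic score assumes 3 mm
reconstructions).  Group summaries report incidence over all patients
and mean ± SD over calcium-positive patients only.

## Evaluation

* Proportions (sensitivity, specificity, PPV, NPV, accuracy) carry exact
  Clopper-Pearson 95% CIs.
* AUROC is the tie-corrected rank statistic (concordant-pair fraction,
  ties ½) with a DeLong placement-variance normal CI, clipped to [0, 1].
  A bootstrap alternative was considered and rejected for determinism.
* "AUROC at cutoff" is the rank AUROC of the binary calls, which equals
  (sensitivity + specificity)/2.
* Propensity matching: near-unpenalized logistic regression on
  standardized covariates; greedy 1:1 nearest-neighbor without
  replacement in seeded random case order; caliper 0.1 on the propensity
  scale (as printed, not on the logit).  Complete non-overlap of the
  propensity distributions raises rather than returning vacuous pairs.
* Group comparison: Kolmogorov-Smirnov normality screen routes
  continuous data to Student t or Mann-Whitney; categorical data to
  chi-squared, or Fisher's exact when any expected count is below 5
  (2×2 only); all tests two-sided.

## Cohort handling

The development cohort's depots are split 7:3 (stratified by label,
seeded) into training and internal validation *at the depot level*, as
the study design specifies.  The known caveat — depots of one patient
can land in both splits — is accepted deliberately; patient-level calls
are made on the full development cohort.  External cohorts come from a
different phantom seed with a +5 HU WAT mean shift as a minimal site
effect; this is a modeling choice, not an estimate of scanner
differences.

## Problem sizes

The reference run uses an 86-patient development cohort (~800 depots,
two segmentations each), two 40-patient external cohorts and a
200-patient calcium cohort — the study-scale sample sizes.  The matrix
oracle sweeps use lattices up to 4×4×3 because brute-force enumeration
is exact and fast there while already covering every boundary topology.

## Known limitations

* Phantom realism limits stated above: results on phantoms bound what
  the pipeline can do, not what CT radiomics achieves clinically.
* The filter bank reconstructs a standard 19-type bank from the census
  arithmetic; other banks with the same cardinality would satisfy the
  same counts.
* LASSO on a binary label via linear regression is kept for fidelity to
  the study design; logistic LASSO is a one-line swap via the selector's
  estimator interface.
* SUV is treated as a given scalar field; no body-mass or lean-mass
  normalization is computed.
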