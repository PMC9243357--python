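# Methods

`crsrad` implements a CT-radiomics pipeline for predicting the dichotomized
chemotherapy response score (CRS) of omental tumor deposits in high-grade
serous ovarian carcinoma before neoadjuvant chemotherapy: CRS3 (complete or
near-complete histopathologic response) is the positive class, CRS1–2 the
negative class. This note records the model, its assumptions, the defaults
and the design choices made where the design was genuinely open.

## Feature extraction

**Inputs.** A 3D CT volume in Hounsfield units (HU) with voxel spacing, and
an aligned binary lesion mask, both in `(slice, row, column)` axis order
(axis 0 supero-inferior). NIfTI is the on-disk format.

**Resegmentation and sub-segmentation.** Before intensity and texture
computation, mask voxels outside a closed HU window (default **[−100, 400]
HU**) are removed; this excludes hypodense material (fat, cystic or necrotic
tissue, below −100 HU) and hyperdense material (calcification, above
400 HU) from the intermediately dense soft-tissue component.
`subsegment_tissue` exposes the same thresholds as a three-class label map.
The sub-segmentation thresholds default to the resegmentation bounds — the
soft-tissue window already operationalizes "intermediately dense" — and are
configurable. Shape features are always computed on the **original** mask;
first-order and texture features on the resegmented mask. No voxel
resampling is performed: features are computed at the original voxel sizes,
and anisotropic spacing enters only through physical-coordinate shape
computations, never through texture neighborhoods (common practice for
axial CT with variable slice thickness).

**Quantization.** Gray levels are fixed-width bins whose width follows the
Freedman–Diaconis rule, `w = 2·IQR·n^(−1/3)`, computed on the resegmented
voxel sample; levels are `floor((v − min)/w) + 1` with
`floor((max − min)/w) + 1` levels, anchored at the per-lesion minimum
(consistent with the per-sample nature of the rule; anchoring at the window
lower bound is the main alternative and would change level indices but not
bin width). When the IQR is zero the rule is undefined and a fallback width
of **25 HU** is used (configurable).

**The 107 features.** Seven classes: shape (14), first-order (18), GLCM
(24), GLRLM (16), GLSZM (16), GLDM (14), NGTDM (5), under their
conventional definitions:

- *Shape*: mesh volume and surface area from the 0.5-level marching-cubes
  iso-surface of the (padded) mask; voxel volume; surface-to-volume ratio;
  sphericity `(36π V²)^{1/3}/A`; principal axis lengths `4√λ` from the
  eigenvalues λ1 ≥ λ2 ≥ λ3 of the sample covariance (n−1 denominator) of
  voxel-center physical coordinates; elongation `√(λ2/λ1)`; flatness
  `√(λ3/λ1)`; maximum 3D diameter from mesh vertices (convex-hull
  accelerated); and three maximum 2D diameters computed from surface-voxel
  centers grouped by the out-of-plane index — the "column" diameter lives in
  the plane spanned by the slice and row axes (coronal plane pairing), the
  "slice" diameter in the row–column (axial) plane, the "row" diameter in
  the slice–column (sagittal) plane. Note the elongation formula approaches
  1 for equant shapes and 0 for elongated ones; the implementation follows
  the formula and leaves the verbal interpretation to the reader.
- *First-order*: computed directly on the resegmented HU values; entropy
  and uniformity on the discretized histogram (log base 2, additive
  ε = 1e−16 in all entropy logs); population (biased) skewness and
  non-excess kurtosis; robust MAD over the 10th–90th percentile subsample.
- *GLCM*: symmetric co-occurrence matrices at distance 1 for the 13 unique
  3D directions, each normalized; every feature is evaluated per direction
  and the unweighted mean over directions is reported. IDMN is
  `Σ p(i,j)/(1 + (i−j)²/Ng²)`; difference entropy is
  `−Σ p_{x−y}(k) log2(p_{x−y}(k)+ε)`. Degenerate single-level images give
  IDMN = 1 and difference entropy = 0.
- *GLRLM*: runs along the same 13 directions, features averaged.
- *GLSZM*: zones are 26-connected components of equal gray level (single
  matrix).
- *GLDM*: dependence size = 1 + number of in-mask 26-neighbors whose level
  differs by at most α = 0 (configurable).
- *NGTDM*: absolute difference between a voxel's level and the mean level
  of its in-mask 26-neighbors.

The GLCM/GLRLM distance of 1 voxel, 13 unweighted directions and the
symmetric GLCM are the conventional defaults; nothing in the problem pins
them otherwise.

**The six-term signature.** Maximum 2D diameter (column), least axis
length, elongation, GLCM IDMN, GLCM difference entropy, and whole-lesion
volume in cm³ (voxel count × voxel volume / 1000). `compute_signature`
returns bit-identical values to the corresponding `extract_all` entries.

## Preprocessing

**Univariate AUC.** The AUC of a univariate logistic model equals the rank
AUC of the raw feature (monotone link), orientation-corrected as
`max(a, 1−a)`.

**Redundancy filter** (supervised, hence run only on training partitions):
pairwise Spearman |ρ| with average ranks for ties; while any surviving pair
has |ρ| ≥ 0.90, the strongest pair is taken (exact ties broken by
lexicographic name order) and its lower-AUC member dropped (AUC ties drop
the alphabetically later name). Absolute ρ is used because anti-correlated
duplicates are equally redundant; removing the strongest redundancy first
makes the greedy order deterministic. The survivor set is re-checked to
contain no pair at or above the threshold.

**Robustness filter** (optional, off by default): two-way random-effects
absolute-agreement single-measurement ICC between features extracted from
original and 1-voxel-perturbed masks, retaining ICC ≥ 0.75. This is a
configurable stand-in for a feature-calibration step whose exact recipe is
not public; it is therefore not part of the default pipeline.

**Standardization.** z-scores with training-set mean and sample (n−1)
standard deviation; constant features are removed with a warning; test rows
are always transformed with training parameters.

## Modeling

**Objective.** Penalized logistic regression,
`mean deviance + λ(α‖β‖₁ + (1−α)‖β‖₂²/2)` with an unpenalized intercept.
α = 0.5 by default (only λ is tuned; an equal L1/L2 mix is the neutral
choice when the mixing is not itself optimized) — exposed in
`ElasticNetConfig`. Solved with scikit-learn's saga solver
(`C = 1/(nλ)` maps the objective), warm-started along a descending
log-spaced λ path of 50 values from the smallest all-zero-coefficient λ
down to 10⁻² of it, path tolerance 1e−4. When every coefficient is zero the
intercept is set to its closed-form optimum `logit(prevalence)` (the
solver's stopping rule can quit early in that corner).

**Nested cross-validation.** Outer 5-fold / inner 5-fold, both stratified
(at 21–41% positives, unstratified 5-fold folds are likely to be
degenerate). Per outer fold: each inner fold runs the redundancy filter and
z-scoring on its own inner-training rows, fits the λ path, and scores its
validation rows; λ* minimizes the mean inner-validation deviance (ties go
to the larger, more parsimonious λ — a one-standard-error rule is the
alternative but "minimum deviance" is the stated selection target); the
decision threshold τ maximizes the G-mean of the pooled inner-validation
predictions over midpoints of sorted unique scores (ties to the smallest
τ; all-equal scores return 0.5). G-mean is the threshold criterion because
the evaluation emphasizes imbalance-robust metrics. The deployed per-fold
model is then refit on the full outer-training partition (its own
redundancy filter and standardization), standard nested-CV practice that
maximizes training data per deployed model. Outer-test rows are scored
exactly once and never touch filtering, standardization, λ or τ decisions;
the per-fold train/test row sets are retained for leakage assertions.

**Repetitions.** The whole procedure repeats (default 100×) with fold
assignment re-randomized per repetition; per-repetition seeds derive from
`sha256(base_seed, "rep", r)`, so repetitions are independent yet
reproducible. Defaults give 5 × 100 = 500 fitted model instances.

## Stability signature

Occurrences = number of instances with a non-zero coefficient for the
feature (a feature removed by the redundancy filter in an instance counts
as 0 there). Relevant features are those occurring in **strictly more
than** a fraction 0.6 of instances (the fraction form scales to
non-default repetition counts); whole-lesion volume is force-included for
clinical recognition. The pipeline is refitted on the reduced set with the
same seeds (hence identical partitions; the redundancy filter is skipped
since the set is curated). Mean coefficients are reported in two modes —
averaged over all instances with absent coefficients as 0 (default), and
averaged only over instances carrying the feature — side by side, because
either convention is defensible and they differ exactly by the occurrence
fraction.

## Ensemble evaluation

The deployed predictor for an external cohort is the **majority vote** of
the 5 outer-fold models of one designated nested-CV repetition (odd k, so
no tie path): each member standardizes the external features with its own
training parameters, scores, thresholds at its own τ and votes. The
continuous score for AUC is the mean member probability (vote fraction is
available, off by default). The class depends only on votes, never on the
averaged probability. The distribution over all repetitions (one ensemble
per repetition) is available for error-bar views.

Metrics: rank AUC (ties ½), accuracy, sensitivity, specificity,
G-mean = √(sensitivity × specificity), PPV, NPV. Metrics with an empty
denominator are reported as NaN with a warning rather than coerced to 0,
keeping aggregate means and SDs honest. Where a win/loss comparison against
a baseline needs a convention for undefined NPV, a model that never
predicts a negative is treated as offering no ability to identify
non-responders, so a defined NPV exceeds it.

Paired distributions are compared with the two-sided Wilcoxon signed-rank
test, independent ones with the Wilcoxon rank-sum (Mann–Whitney U) test
(exact where sample sizes permit); families of comparisons are
Holm-adjusted.

**Volumetric baseline.** A single-feature (tumor volume) logistic model run
through the *same* nested CV, threshold optimization and repetition
machinery.

## Synthetic data

The original patient data are not public, so generators emulate the study
conditions; their defaults *are* those conditions and are not tuned.

**Feature-table cohorts.** Defaults: discovery n = 61 at 41% positives,
external n = 48 at 21%. Informative features are iid standard normal with
log-odds effects (default five effects of magnitude 1, mixed signs — strong
but not separating signal at these sample sizes); labels are Bernoulli from
the logistic model with the intercept solved by root-finding so the
expected positive rate equals the requested prevalence (labels as random
outcomes, not quota sampling). Each informative feature heads a block of
redundant copies: for target Spearman ρ = 1 a strictly monotone transform
(`x + 0.25x³`); for ρ < 1 the perturbation scale is bisected on the
realized rank correlation, so the block structure the redundancy filter
assumes (ρ ≥ 0.9) holds by construction. Noise features are independent
standard normal. Where a tumor-volume column is needed, one informative
feature is replaced by `40·exp(0.8·x)` cm³ — a strictly monotone, lognormal
(right-skewed, median 40 cm³, in the range of reported omental disease
volumes) proxy whose label association is inherited from the planted
effect; its effect size (0.7 in the evaluation experiments) encodes
moderately predictive volume, weaker than the full multivariable signal.

**Lesion phantoms.** An ellipsoidal mask (default semi-axes 14/11/8 mm at
1 mm isotropic spacing) on a fat-like background of −90 HU (so HU
sub-segmentation has signal); inside, a stationary correlated Gaussian HU
field (white noise smoothed with a Gaussian kernel of width
`texture_correlation_length_mm`, default 2 mm — the simplest stationary
field with a controllable correlation length) with mean 45 HU and SD 20 HU,
plus randomly placed spherical hypodense (−150 HU) and hyperdense (+600 HU)
blobs filling requested volume fractions within ±2 percentage points.
Requested inclusion fractions summing above 0.9 are rejected as degenerate.
Imaging cohorts draw per-patient parameters from label-conditional
distributions; the default responder shift scales the least semi-axis by
0.6 and the middle by 0.85 (responders: more elongated lesions with a
smaller least axis) and the texture SD by 0.7 (more homogeneous).

**What the phantoms do not emulate**: CT physics (noise spectra, beam
hardening, partial volume), multi-lesion anatomy, scanner variability, and
real radiomic feature distributions. Passing tests on phantoms therefore
demonstrate the *mathematics and plumbing* of the pipeline — not clinical
performance, which requires patient data.

## Numerical choices and degenerate inputs

- Entropies: log base 2, ε = 1e−16 added inside every log.
- Empty resegmented masks raise with advice to widen the window; empty
  masks raise everywhere.
- Single-voxel masks: principal axes reported as 0 with a warning; no
  co-occurring pairs ⇒ GLCM conventions (IDMN = 1, difference entropy 0);
  single run/zone/dependence of size 1.
- Correlation-type GLCM features with zero marginal variance return 1.
- NGTDM coarseness with zero denominator returns 10⁶ (conventional cap).
- All randomness flows from explicit seeds through
  `sha256(base, stage, index)` (31-bit), making every stage independently
  reproducible.

## Problem sizes used in tests and the acceptance script

Tests and the acceptance report run at the study's own scale where the
quantity demands it (the 500-instance population uses the full 100
repetitions at n = 61, on a lean 11-feature cohort since the instance count
does not depend on feature count) and at reduced scale elsewhere: null
calibration uses 20 repetitions; recovery experiments use 3 repetitions per
seeded run (15 instances — occurrence ranking stabilizes well below 500
instances) with coefficient signs read from the reduced refit on the
planted set, exactly as the signature procedure prescribes;
ensemble-vs-baseline win rates use one nested-CV pass per run, which is
exactly the deployed-ensemble configuration. The acceptance script reports
recovery over 10 seeded runs and win rates over 20.

## Known limitations

- The external radiomics cross-check implementation named in the project
  plan is not installable in this environment, so feature-math validation
  rests on the in-repo brute-force enumeration oracles (exhaustive pair,
  run, zone, dependence and neighborhood enumeration on small grids) and on
  analytic solids for shape.
- Mesh-based quantities on binary masks carry staircase bias (a digital
  sphere's sphericity is ≈ 0.91, not 1); tests budget for this
  discretization error.
- The occurrence analysis inherits a structural property of min-deviance
  elastic-net CV worth knowing about: with ample samples the selected λ
  admits noise features that are spuriously correlated with labels in that
  particular cohort, and such features are re-selected in essentially every
  instance because instances share the cohort. Occurrence counts therefore
  separate planted from noise features less cleanly at n = 200 than the
  sparser n = 61 regime; coefficient *signs* of planted features remain
  reliably recovered. R's `cv.glmnet` reproduces the same behavior on
  identical cohorts, so this is a property of the method, not of this
  implementation.
- `robustness_filter` is a labeled stand-in, not a reproduction of any
  published calibration procedure.
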