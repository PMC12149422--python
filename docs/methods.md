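# Methods

This note documents the models, defaults and design choices behind
`habitatomics`, and what the synthetic cohort does and does not emulate.

## Synthetic cohort generator

The generator (`synthetic.py`) produces the complete study: image
volumes with tumor masks and repeat delineations, a clinical table with
grade, TNM, demographics and overall survival, and a gene expression
matrix. Its defaults are the study conditions all tests and the
acceptance computation run under.

**Tumor volumes.** Each tumor is an ellipsoid (axis radii uniform in
7–11 voxels) inside a 48³ image at 1×1×1 mm spacing. Habitat membership
comes from thresholding a Gaussian-smoothed noise field (σ = 2.5 voxels)
at the quantile matching the configured habitat fractions (default
50/50), which yields spatially contiguous blobs per habitat rather than
i.i.d. voxel labels — co-occurrence texture is degenerate under i.i.d.
labels. Voxel intensities are drawn per habitat as

    mean_h + 3·(smooth field, σ = 1.2) + sd_h·(white noise)

with means 40 / 120 HU and noise 10 / 12 HU for the low-/high-density
habitats — roughly parenchymal-phase contrast between necrotic and
enhancing renal tumor tissue. In high-grade patients the low-density
habitat's white-noise amplitude is raised by `grade_effect` (default
+6 HU): the planted, texture-only grade signal. The dominant voxel-wise
noise term makes each habitat's intensity distribution Gaussian to a
good approximation, so the two-habitat tumor really is the two-component
mixture the segmentation model assumes; the small smooth component
provides the spatial correlation texture features need.

**Repeat delineations.** Two extra masks per patient (second pass by
observer 1, independent observer 2) are produced by flipping each
boundary-layer voxel of the primary mask with probability 0.10 —
morphological perturbation standing in for human re-delineation.

**Survival.** Event times are exponential with hazard
`h0·exp(coef·risk)`, h0 = 0.02/month, coef = 0.8 per unit latent risk,
with independent Uniform(0, 120 months) censoring. The latent risk is
the grade indicator plus N(0, 0.5) jitter — the hidden quantity the
radscore estimates. Exponential survival keeps group medians analytically
checkable (median = ln 2 / hazard).

**Expression.** 800 genes × patients; three planted modules of 150, 120
and 100 genes (respecting the 100-gene minimum module size used
downstream). Each module has a per-sample latent factor; member genes are
`0.8·factor + N(0, 1)`. The first module's factor is constructed to
correlate with the (standardized) risk score at −0.5 — the negative sign
mirrors the direction typically reported for radiomics-linked modules —
and the remaining genes are pure noise.

**What the generator does not emulate:** CT physics (beam hardening,
reconstruction kernels, scanner variation), irregular tumor shapes,
partial-volume mixing at habitat interfaces, more than two habitats,
non-proportional hazards, and realistic transcriptome-wide covariance.
Passing tests therefore demonstrate that the pipeline recovers planted
structure under its own modeling assumptions, not clinical performance.

## Habitat segmentation

GMMs are fitted **per patient** on that patient's masked voxels;
cross-patient correspondence comes from relabeling clusters by ascending
mean intensity (label 1 = low density). EM uses full covariances, 5
random restarts, relative log-likelihood tolerance 1e-6, at most 200
iterations, and a variance floor of 1e-6 × the mean data variance added
to covariance diagonals (degenerate clusters shrink, they never raise).
Restarts are initialized by random-point centers followed by one hard
nearest-center assignment so components start from within-cluster
moments; initializing every component with the pooled covariance lets EM
sit at the symmetric saddle point and terminate prematurely. The
log-likelihood is asserted non-decreasing at every iteration.

K is scanned over 2..10 and chosen by minimal BIC with ties broken
toward smaller K. A K whose fits all fail is skipped with a warning;
only if every K fails does segmentation raise.

**Voxel descriptors.** The default descriptor is the raw voxel intensity.
Local neighborhood moments (mean and standard deviation over a cubic
radius, mask-restricted) are available via `feature_radius`, but are not
the default: voxels whose neighborhoods straddle a habitat interface form
a genuinely distinct intermediate population in descriptor space, and BIC
then (correctly) reports more clusters than the number of intensity
populations. With intensity-only descriptors a two-population tumor is a
well-specified two-component mixture and the selected K reflects the
habitat count.

## Feature bank

Images are resampled to 1×1×1 mm (trilinear; nearest-neighbor for masks
and label maps) and each region's intensities are discretized to 25 gray
levels over the region min–max before texture matrices are built. The
bank is 56 features per region: 17 first-order, 7 shape, 8 GLCM (13
unique 3-D directions at distance 1, symmetric matrices, features
averaged over directions), 7 GLRLM (runs per direction, averaged), and 7
GLSZM (26-connected zones). Pairs, runs and zones never cross the region
boundary. Filtered-image (wavelet/LoG) channels are deliberately out of
scope; the bank covers the same families at smaller width, and nothing
downstream depends on bank size. Subregions smaller than 10 voxels are
flagged and excluded from modeling, mirroring cohort exclusion of
unsegmentable subregions.

Numerical conventions worth noting: population variance; skewness and
kurtosis defined as 0 for constant regions; entropy in bits on the
25-level histogram; GLCM correlation defined as 1 for a single-level
region; sphericity computed from face-counted surface area (slightly
below 1 for a digital ball); maximum 3-D diameter from convex-hull
vertices.

## Reproducibility filter

ICC(2,1) — two-way random effects, absolute agreement, single
measurement — is the standard radiomics choice and is computed from
two-way ANOVA mean squares. The filter compares the primary feature
table against the intra-observer repeat and the inter-observer table on
the re-delineated patient subset (first 20 patients in the pipeline) and
keeps features with both ICCs strictly above 0.75. Zero between-subject
variance yields a warning and a non-positive ICC, never an exception.

## Selection, radscore, risk groups

Min–max scaling uses train-set bounds only; applied values outside [0,1]
are not clamped. The Spearman filter drops, from any pair with |ρ| > 0.9,
the feature with the larger mean absolute correlation to the remaining
features (deterministic: features are processed in sorted-name order).
LASSO minimizes mean squared error on the 0/1 grade label over a
log-spaced penalty path from λ_max downward, with stratified 5-fold CV
(folds shrink to the minority-class count, minimum 2, with a warning —
needed for very small cohorts); an L1-logistic variant is available via
`loss="logistic"`. The radscore is the affine combination of the selected
scaled features. The Youden cutoff scans midpoints of adjacent sorted
unique training scores, maximizes J with ties toward the lower cutoff,
and classifies high-risk as score ≥ cutoff; the training-derived cutoff
is applied unchanged to test data. If the CV-optimal penalty selects no
features, the pipeline falls back to the single best univariate feature
with a warning rather than failing the run.

## Classifiers and evaluation

Hyperparameters are pinned, not tuned: RF 500 trees; LR L2 penalty,
C = 1; DT gini, unlimited depth; SVM RBF kernel, C = 1 with
decision-function scores. The positive class is high grade; precision /
recall / F1 default to the positive class with a weighted-average option.
AUC is trapezoidal over all score thresholds (equal to the Mann–Whitney
concordance probability, which is how the tests check it). The cohort
split is stratified 7:3 with the training size rounded down (186 → 130/56).

## Survival analysis

The product-limit estimator and two-group log-rank test are implemented
from their defining formulas (hypergeometric variance at tied event
times, χ² with 1 df); `lifelines` is used as an independent cross-check
in the tests. Clinical comparisons: χ² without continuity correction, or
Fisher's exact test when any expected cell is below 5; Student's t when
both groups pass Shapiro normality at α = 0.05 (groups below n = 3 or
constant are treated as non-normal), otherwise Mann–Whitney U; two
identical constant samples return p = 1 by the midrank convention.

## Coexpression analysis

The network is unsigned (|cor|^β; a signed option exists). β is the
smallest power in 1..20 whose scale-free fit R² — log₁₀ frequency vs
log₁₀ mean connectivity over ~10 bins — reaches 0.8, else the β with the
best R². TOM follows the standard formula with unit diagonal. Modules
come from average-linkage clustering of 1−TOM with a height-scan cut:
the lowest height maximizing the number of clusters of ≥ 100 genes
(a documented simplification of dynamic tree cutting), followed by
module-membership rescue — an unassigned gene joins the module whose
eigengene it correlates with at |kME| ≥ 0.5, the conventional threshold.
Module eigengenes are first principal components of the standardized
module expression, sign-oriented toward positive mean member
correlation. Module–trait association uses Pearson r with the
t-distribution p (df n−2); the reported module minimizes p (ties to
larger |r|). Hub genes rank by degree in the module-induced subgraph of
a user-supplied edge list, falling back to intramodular soft
connectivity; enrichment is a one-sided hypergeometric upper tail over a
user-supplied term→gene annotation with Benjamini–Hochberg correction,
reporting the top five terms with p < 0.05. No live database is queried.

## Pipeline and reproducibility

Stages run in a fixed order and communicate only through declared files.
One run seed fans out to per-stage sub-seeds through named SeedSequence
children, independent of which stages are enabled, so partial reruns
reproduce earlier outputs exactly. Gzipped NIfTI is written with
mtime = 0, making output files — and therefore the SHA-256 manifest —
byte-identical across reruns. A failing stage halts the run with the
stage named; earlier outputs stay on disk.

**Problem sizes.** The default pipeline cohort is 60 patients; the test
suite exercises the full pipeline at 14 patients and habitat-recovery at
20 patients, and the acceptance computation simulates 24 patients —
sizes at which every planted effect is still comfortably detectable.
The coexpression recovery checks use 500 genes (three planted modules
plus background) and 100 samples.

## Known limitations

- Per-patient GMM with intensity-rank relabeling assumes the same two
  habitats exist in every tumor; tumors with more (or fewer) intensity
  populations get extra (or merged) labels, and only labels 1–2 feed the
  region tables.
- Feature values are not numerically identical to any particular
  radiomics platform (direction weighting, edge conventions and bank
  composition differ); they follow the standard matrix definitions and
  are verified against enumeration oracles instead.
- The height-scan tree cut plus kME rescue approximates, but is simpler
  than, full dynamic tree cutting; very unbalanced or nested module
  structures may be cut differently.
- The external-validation arm of the original study design (a second
  independent cohort) is not simulated; the pipeline reports train and
  internal-test splits.
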