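# Methods

This note records the scientific and numerical conventions the package
implements, the defaults and why they were chosen, and what the synthetic
fixtures do and do not establish.

## Inputs and ROIs

The pipeline assumes preprocessed inputs: four coregistered sequences (T1,
T1c, T2, FLAIR) and a tumor segmentation on a common 1 mm isotropic grid.
Registration, bias-field correction, skull stripping and automated
segmentation are upstream concerns and deliberately out of scope; volumes
are treated as voxel-indexed arrays and never resampled.

Two label schemes with identical ROI rules are supported (1/2/4 labels,
differing in what label 1 and 2 denote), plus a whole-tumor-only binary
scheme. ROI1 (WT) is the union of all tumor labels; ROI2 (NET + NCR + ED)
excludes label 4 (enhancing tumor). Under the whole-tumor-only scheme ROI2
is structurally unavailable and requesting it raises an error rather than
silently degrading; cohort-level extraction then emits only the WT feature
block and flags the row. Labels outside the declared scheme are a hard
validation error — silent remapping would corrupt ROI semantics.

## Filter bank

Each sequence produces 12 derived images; intensity features are computed
on the original plus all 12, shape features on the ROI geometry only.

* **Wavelet subbands.** One-level undecimated 2D transform applied
  slice-wise along the third array axis, four subbands (LL, LH, HL, HH) of
  the original shape. The slice-wise 2D (rather than 3D 8-subband) design
  keeps exactly four wavelet image types, which is what the 12-image
  inventory requires. The wavelet family is configurable (`wavelet`,
  default `coif1`); the family is a convention, not a finding, and is
  recorded in the run manifest. Odd slice dimensions are edge-padded to
  even and cropped back.
* **Laplacian of Gaussian.** σ ∈ {2, 3, 4, 5} mm, converted per axis to
  voxel units via the spacing. The operator is computed as the sum of
  three separable convolutions with *analytically sampled* 1D Gaussian /
  second-derivative kernels (truncated at 7σ, mirror boundaries, with
  reflect-padding when an axis is shorter than the kernel radius). This
  makes the discrete impulse response equal the analytic 3D LoG kernel at
  grid points to ~1e-11 of peak, so tests can compare against a directly
  tabulated kernel. Scales below half the voxel size trigger a warning
  (under-resolved), not an error.
* **Intensity maps.** Square, square root, logarithm and exponential, each
  rescaled so the output max-absolute-value equals the input's; square and
  square root are sign-preserving so all four maps are monotone on
  physical (nonnegative) intensity ranges and hence preserve intensity
  rank inside the ROI. The exponential uses c = log(max|x|)/max|x|, which
  is monotone only for max|x| > 1 — MRI-scale intensities in practice. An
  all-zero volume maps to all-zero outputs (degenerate scaling treated as
  identity).

## Feature extraction

Per (ROI, sequence): 14 shape + (18 first-order + 22 GLCM + 16 GLRLM + 16
GLSZM + 14 GLDM + 5 NGTDM) × 13 images = 1197 features, named
`{ROI1|ROI2}_{sequence}_{imagetype}_{class}_{feature}`. The feature
identities are the canonical standard sets for each class; the
cardinalities (14/18/22/16/16/14/5) are the fixed design contract and are
enforced by tests.

* **Discretization.** Fixed bin width (default 25 intensity units),
  anchored at the ROI minimum: level(x) = ⌊(x − min)/w⌋ + 1. One bin
  width serves all image types; derived images are range-matched to the
  original by the filter-bank rescaling, which keeps level counts
  comparable.
* **Texture aggregation.** GLCM and GLRLM are computed per direction over
  the 13 unique 3D offsets at distance 1 and feature values averaged over
  directions. GLSZM zones and GLDM dependences use 26-connectivity; GLDM
  similarity tolerance α = 0 and the dependence size of a voxel counts the
  voxel itself plus its equal-level in-ROI neighbors. NGTDM averages over
  in-ROI 26-neighbors; voxels with no in-ROI neighbor are excluded from
  the table.
* **Degenerate conventions.** Constant (single-level) ROIs: GLCM
  Correlation = 1, IMC1/IMC2 = 0, all entropies = 0, first-order Skewness
  and Kurtosis = 0 (kurtosis is not excess-corrected elsewhere). NGTDM
  Coarseness is capped at 1e6 when its denominator vanishes. NaNs are
  never emitted — silent NaNs would poison downstream selection. All
  conventions are serialized in `RunConfig.conventions`.
* **Shape.** Surface area and mesh volume come from a marching-cubes
  triangulation of the mask after a 1-voxel Gaussian anti-aliasing of the
  binary boundary (binary fallback when the ROI is too small to span the
  0.5 level). The smoothing removes the staircase-surface bias that would
  otherwise depress sphericity of a digitized ball from ~1.0 to ~0.91.
  Axis lengths are 4√λ of the principal moments of the physical voxel
  coordinates; maximum diameters are pairwise distances between boundary
  voxel centers (per plane for the 2D variants). A one-voxel-thick ROI
  warns and meshes the padded mask.
* **Performance.** Extraction crops to the ROI bounding box (+2 voxel
  margin) before filtering; run lengths are counted by shearing the
  volume so any of the 13 directions becomes axis-aligned and
  run-length-encoding all lines in one vectorized pass.

## Boruta selection over balanced subsets

Each iteration appends a column-wise independently permuted shadow copy of
every undecided-or-confirmed feature, fits a random-forest importance
estimator (default 100 trees), and scores a hit when a real feature's
importance exceeds the best shadow's. Confirmation/rejection use one-sided
binomial tests against Bin(n, ½) at α/2 per side with Bonferroni
correction across all features (α default 0.05, `max_iter` default 100).
Constant columns are rejected up front. Rejected features leave the
design; confirmed ones stay so shadows remain representative. Tentative
features are *not* included in the relevant set (conservative reading of
"most relevant").

Because the cohort is imbalanced, selection runs on multiple balanced
subsets (default 20) and aggregates confirmation counts; the relevant set
is features confirmed in ≥ `selection_threshold` (default 0.5, majority
rule) of subsets. If nothing reaches the threshold — expected on very
small smoke cohorts — selection falls back, with a warning, to the top-k
features ranked by confirmation count then accumulated hit count (k
default 10), keeping the downstream pipeline well-defined. Selection runs
per ROI block and on the concatenated blocks ("combined").

Boruta's guarantee is calibrated per feature against its own shadow: on a
fixed finite null sample, a noise feature that is by chance correlated
with the labels is genuinely more informative than any shadow and can be
confirmed. The null simulations therefore track the *confirmed-feature
fraction per run*, which stays well below α, rather than the
per-run any-confirmation probability.

## Two-stage balanced ensemble

Balanced subsets contain every minority sample plus an equal-size uniform
draw of majority samples without replacement (independent across subsets);
if the nominally minority class (mutated) is actually larger, roles swap
with a warning. One classifier is fitted per subset — random forest (500
trees, √p features per split) or XGBoost (300 rounds, depth 4, learning
rate 0.1); these are documented stable baselines, exposed in `RunConfig`.
The ensemble probability is the exact arithmetic mean of member
mutated-class probabilities; hard classifications use a fixed 0.5
threshold, while AUC-based (threshold-free) evaluation is preferred.
Degenerate subset fits are dropped with a warning; training aborts if more
than half the members are lost. The SMOTE comparator interpolates
uniformly between a minority sample and one of its k nearest minority
neighbors (default k = 5) until counts balance.

## Evaluation

AUC uses the rank (Mann–Whitney) formulation with mid-rank ties; ROC
points come from the standard curve construction. DeLong placement values
give var(AUC) = S₁₀/n₁ + S₀₁/n₀ (sample variances, ddof 1); the 95% CI is
a normal approximation on the AUC scale truncated to [0, 1] — no logit
transform. Perfect separation yields SE 0 and a point CI with a warning.
Confusion-matrix metrics with zero denominators are reported as NaN with a
warning, never as 0.

## Synthetic fixtures

Volume cohorts: nested-ellipsoid tumors (necrotic core ⊂ enhancing shell ⊂
edema rim, mildly anisotropic, jittered center) in four sequences built
from smoothed Gaussian random fields plus per-compartment contrast offsets
that mimic typical sequence appearance (e.g. bright enhancing shell on
T1c). The class signal is the *correlation length* of the intratumoral
field (mutated 1.6 voxels vs wild-type 0.5 by default), not a mean shift,
so that texture features rather than first-order statistics carry the
discrimination — this exercises the texture stack, the hard part of the
pipeline; a single GLCM homogeneity-type feature separates the classes
with AUC > 0.95 at n = 100 under the defaults. The mutated fraction
defaults to 0.27, the prevalence regime the framework is designed for, and
label counts are assigned deterministically (round(n·fraction), seeded
order). Tabular cohorts plant mean-shifted informative features in
Gaussian noise at a stated imbalance ratio. All fixtures are bit-for-bit
reproducible from their seed.

What the fixtures do **not** emulate: MRI physics (bias fields, noise
floors, partial volume), realistic tumor morphology, inter-scanner
heterogeneity, or correlated feature structure of real radiomics panels.
Passing tests therefore establish algorithmic correctness and the
framework's statistical properties under controlled conditions — not
clinical-level predictive performance, which requires real cohorts.

## Problem sizes

Simulations are sized for a single desktop CPU: 48³ voxel fixture volumes
with correspondingly scaled tumor radii, 20-patient end-to-end smoke
cohorts, 50-replicate null/bias simulations, 10,000-replicate bootstraps.
The end-to-end smoke run uses a reduced selection configuration (3
balanced subsets, 10 Boruta iterations, 50-tree importance forests, 5
ensemble members) — at 20 patients Boruta cannot make confirmations
anyway, so the smoke run exercises plumbing and determinism while the
dedicated simulations above exercise statistical behavior at adequate n.

## Known limitations

* Feature identities follow the canonical reference sets; supplementary
  per-study settings (exact bin width, wavelet family, classifier
  hyperparameters) are configurable defaults, not reproductions.
* The slice-wise 2D wavelet treats the third array axis as axial; for
  differently oriented volumes the subband labels permute.
* GLCM/GLRLM direction averaging assumes isotropic voxels (distance-1
  offsets mix axis and diagonal physical lengths otherwise) — consistent
  with the 1 mm isotropic input contract.
* The exponential intensity map is non-monotone for volumes whose
  max-absolute intensity is below 1; such inputs do not occur on
  MRI-scale data.
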