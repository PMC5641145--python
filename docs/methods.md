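# Methods

## Scope and data model

`radsig` implements a two-sequence MRI radiomics pipeline for dichotomized
progression prediction: per-patient CET1-w and T2-w volumes co-registered to
one voxel grid with a shared (or per-sequence) binary tumor mask. Volumes
are used as stored — no resampling to isotropic voxels, no intensity
normalization, no bias-field correction; physical voxel spacing (possibly
anisotropic, e.g. 4 mm slices) enters only the shape features. Voxel indices
are 0-based and world coordinates are never needed.

## Feature extraction

**Cardinalities.** 485 features per sequence: 17 first-order + 8 shape + 36
texture on the original image, and (17 + 36) × 8 = 424 on the wavelet
subbands; 970 per patient. These counts are asserted on every extraction.

**First-order (17).** mean, median, minimum, maximum, range, variance, sd,
skewness, kurtosis, energy (Σx²), entropy, uniformity, RMS, mean absolute
deviation, robust MAD (values within [p10, p90]), 10th and 90th percentiles.
Variance/sd/skewness/kurtosis use population (n) normalization; kurtosis is
non-excess; a constant region takes skewness = kurtosis = 0. Entropy and
uniformity use the same fixed binning as the texture features (below);
logarithms are natural throughout.

**Discretization.** In-mask intensities are binned into 32 equal-width
levels spanning the in-mask [min, max]; bins are half-open with the final
bin closed, so the maximum maps to level 32. A constant region maps to level
1 and is flagged degenerate. The bin count is configurable; 32 is the common
radiomics default and keeps the co-occurrence matrices small.

**Texture (36 = 25 GLCM + 11 GLRLM).** Thirteen unique 3D directions
(26-connectivity modulo sign) at distance 1 voxel, in voxel units (spacing is
ignored for texture). The GLCM is accumulated symmetrically over all 13
directions into a single probability matrix; the GLRLM is built per
direction and features are averaged over directions, which makes the
aggregated features invariant to 90° axis-aligned rotations (verified by
test). GLCM roster: energy, contrast, correlation, variance, IDM, sum
average, sum variance, sum entropy, entropy, difference average/variance/
entropy, IMC1, IMC2, autocorrelation, cluster shade/prominence/tendency,
dissimilarity, ID, IDN, IDMN, maximum probability, inverse variance, MCC.
GLRLM roster: SRE, LRE, GLN, RLN, RP, LGLRE, HGLRE, SRLGLE, SRHGLE, LRLGLE,
LRHGLE. Degenerate conventions keep every output finite: 0·log 0 = 0;
correlation = MCC = 1 and IMC1 = 0 for a single-level region. Runs are
maximal same-level sequences of in-mask voxels; out-of-mask voxels break
runs, so Σ count·length equals the in-mask voxel count in every direction —
an invariant checked against brute-force enumeration.

**Shape (8).** Volume (voxel count × voxel volume), surface area from a
triangulated isosurface (marching cubes at level 0.5 on the zero-padded
binary mask), surface-to-volume ratio, sphericity, compactness 1 and 2,
spherical disproportion, and Max3D (greatest pairwise physical distance
between foreground voxel centers; computed on convex-hull vertices for large
masks, brute force otherwise). A voxel-face area estimator is kept as a test
oracle for box-like masks. Note a property of the mesh estimator: marching
cubes on a *binary* mask overestimates a smooth sphere's area by a
near-constant factor, so digitized balls plateau at sphericity ≈ 0.92-0.97
rather than approaching 1; sphericity still ranks shapes correctly
(slab < cube < ball), which is what the feature is used for.

**Wavelet (424).** One-level decimated separable 3D DWT of the mask's
bounding-box region with the coif1 filter, periodic boundary handling (the
orthogonal filter then conserves energy on even-sized regions; Parseval is
verified to 1e-6 in tests). Subbands are indexed 1..8 = LLL..HHH,
lexicographic with L < H per axis — the numeric prefixes in feature names
(`T2-w_4_fos_mean`) refer to this order, 0 denoting the original image. Each
decimated subband is mapped back to the original grid by nearest-neighbor ×2
upsampling and cropping before mask-restricted feature computation. The
bounding box must span at least the filter length (6 voxels) per axis. The
decimated (rather than stationary) transform is a deliberate choice: it is
cheap, and the undecimated variant is not uniquely defined by the feature
names alone.

**Naming.** `<modality>_<subband>_<family>_<metric>` (e.g.
`CET1-w_5_fos_median`); shape features carry no subband token
(`T2-w_Max3D`). Canonical column order is (family, subband, metric) per
modality, CET1-w block first — a pure function of the feature dictionary,
never of input order.

## Signature selection and the Rad-score

Features are standardized to zero mean / unit sd; the penalty path is 40
log-spaced values from the analytic λ_max (all coefficients zero) down to
λ_max/100 (n < p). Cross-validation uses deterministic stratified folds
keyed by patient id and seed, so fold membership — and hence the selection —
is invariant to row order. Held-out binomial deviance is averaged per
patient across folds; the chosen λ minimizes it (ties resolve to the sparser
model; a one-standard-error rule is available as `lambda_rule="1se"`). At or
above λ_max the L1 solution is computed in closed form (coefficients zero,
intercept = log-odds of prevalence); interior λ values use liblinear with a
large intercept scaling so the intercept is effectively unpenalized. The
returned model is re-expressed on the original feature scale, which makes
the whole procedure equivariant to rescaling any feature column.

The frozen published model applies its eight printed coefficients to raw
feature values with no standardization block, as the printed formula shows.
The source that printed it is internally inconsistent in two places — the
formula names subband 1 for the GLCM correlation term while the selection
list names subband 5, and the selection list includes a GLRLM SRE feature
absent from the formula; the formula (the only fully specified object) is
treated as authoritative and frozen verbatim, with the one obvious
typographical omission (a missing `-w` in one T2 name) normalized.

## Endpoint, cohorts and evaluation

Progression is dichotomized at 36 months: event at or before the cutoff → 1;
event-free follow-up beyond it → 0; event-free follow-up shorter than the
cutoff → the class is unknowable, and such patients are **excluded** by
default (a `censored="zero"` switch labels them 0 instead). Cohort splitting
is uniform random without stratification, seeded.

AUC is the Mann-Whitney concordance probability with ties counted 1/2. The
95% CI uses the DeLong structural-component variance with a normal
approximation, clipped to [0, 1]; a seeded bootstrap (2000 resamples) is the
alternative. Per-feature group differences use the classical two-sided
two-sample t test flagged at p < 0.05 with no multiplicity correction by
default (a Benjamini-Hochberg switch exists and is off), matching the
workflow the package reproduces.

## Synthetic phantoms

The generator makes the study conditions testable without patient data.
Default cohort: 80 training + 33 validation patients, prevalence 0.3.
Each phantom: a 44 × 44 × 16 grid at (1, 1, 4) mm spacing; an axis-aligned
ellipsoidal tumor with per-axis semi-axes drawn from 14-18 mm, center
jittered by ≤ 1 voxel; within-mask intensity = class mean + a Gaussian
random field (white noise convolved with an isotropic Gaussian kernel,
renormalized to sd 10) whose correlation length is 2 mm (class 0) vs 3.5 mm
(class 1); class 1 additionally gets a +10 mean shift (1 noise sd). The two
sequences share the mask but draw independent fields. Background voxels are
independent noise at mean 40 and are never read by extraction. Intensity
scales are arbitrary — no public tumor intensity distributions exist to
match — and only effect sizes relative to the noise sd matter downstream.
Follow-up: progressors Uniform(3, 36) months, non-progressors
Uniform(37, 89), matching the 3-89 month observed range and making the
cutoff rule unambiguous. Identical (config, seed) reproduces a cohort
bit-for-bit via per-patient spawned RNG streams.

The phantoms deliberately omit MRI physics (bias fields, partial volume,
acquisition noise structure, multi-lesion anatomy), so passing calibration
tests demonstrates correctness and sensitivity of the *pipeline*, not
clinical performance on real images.

A second, feature-level generator plants informative columns directly in a
970-feature standard-normal matrix (default: 4 per modality, +1 sd shift,
prevalence 0.35). It drives the selection-calibration studies: planted
features are recovered with mean sensitivity ≥ 0.75 over 20 seeds; with no
planted effect the minimum-deviance Lasso returns an empty model in about
half the replicates (the minimum-λ rule sits at the null boundary, so this
fraction is intrinsically near 0.5, not a tuned quantity); and the combined
two-modality model's validation AUC dominates both single-modality models in
the large majority of seeds.

## Problem sizes in the test suite

Image-level end-to-end checks run on reduced phantoms (24 × 24 × 12 grids at
(1, 1, 2) mm, 8-10 mm tumors, cohorts of 30 + 15, 3 replicates) — chosen as
the smallest sizes at which tumors comfortably contain the wavelet filter
support and Lasso fits are well-posed. Feature-level selection studies run
at full size (80 + 33 patients × 970 features, 20 seeds). Texture builders
are verified exactly against brute-force enumerators on 100 random 4×4×4
instances.

## Known limitations

- The headline clinical AUCs of the originating study were measured on 113
  real patients whose images are not public; nothing here reproduces them,
  and the synthetic cohorts make no attempt to mimic real NPC intensity
  distributions.
- Exact feature formulas of the original MATLAB implementation were never
  published; the rosters here are fixed by the printed counts (17/8/36/424)
  and the printed feature names, with conventions documented above. Values
  for an individual feature may differ from other radiomics toolkits by
  convention (binning, direction aggregation, surface estimator).
- No GLSZM/NGTDM texture families, no Laplacian-of-Gaussian filter bank, no
  multi-level wavelets, no feature interactions, and no time-to-event
  modeling — the endpoint is dichotomized by design.
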