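# Methods

## Polarimetric model

Light states are Stokes vectors `S = [S0, S1, S2, S3]` with angles
measured counter-clockwise from horizontal looking toward the source and
`S3 > 0` meaning right circular.  Reconstruction from the six ideal
analyzer projections uses the unique linear analyzer model that makes it
exact: `I0 = (S0+S1)/2`, `I90 = (S0−S1)/2`, and correspondingly for the
±45° and circular pairs.  A four-camera division-of-amplitude polarimeter
measures four channels `I = A·S` instead; inversion requires a calibrated
4×4 analyzer matrix `A`.  No such calibration is public for the instrument
class this package models, so the default is the ideal stand-in

    A = 1/2 · [[1,1,0,0], [1,−1,0,0], [1,0,1,0], [1,0,0,1]]   (rows H, V, 45°, RCP)

which is invertible (2-norm condition number ≈ 3.23, computed by SVD) and
consistent with the six-projection model.  Inversion refuses matrices with
condition number above 1e12, naming the condition number in the error.

Derived parameters per vector: `DOP = √(S1²+S2²+S3²)/S0`,
`DOLP = √(S1²+S2²)/S0`, `DOCP = |S3|/S0`, anisotropy
`r = 2S1/(3S0−S1) ∈ [−0.5, 1]`.  DOCP is reported unsigned because its
conventional display range is 0–1; the signed ratio `S3/S0` is retained as
`docp_signed` for users who need handedness.  In per-pixel maps, pixels
with `S0 ≤ 1e-12·max(S0)` are masked rather than divided.

Physicality (`S1²+S2²+S3² ≤ S0²`) is checked with a relative tolerance of
1e-6; vectors violating it (as noisy measurements will) are flagged by a
predicate, never rejected.

## Mueller assembly

The four probe states H=[1,1,0,0], P=[1,0,1,0], V=[1,−1,0,0], R=[1,0,0,1]
span Stokes space, so the sample matrix follows exactly from the four
measured output vectors: column 1 = (S_H+S_V)/2, column 2 = (S_H−S_V)/2,
column 3 = S_P − column 1, column 4 = S_R − column 1.  This closed form is
the pseudo-inverse solution specialized to these states; no separate
least-squares solver is provided.  Per-pixel assembly assumes the four
state images are co-registered; no registration step is implemented.
Element names `M(i,j)` are 1-based throughout.  Elementary element
constructors (rotated linear retarder, linear diattenuator with unit
transmittance, diagonal depolarizer) use the standard forms with
`M(1,1) = 1`; overall brightness is carried by the phantom's intensity
scale, not by the element matrices, since analysis normalizes by `M(1,1)`
anyway.

## Lu–Chipman decomposition

`M = M_Δ·M_R·M_D` with the diattenuator applied first.  Construction: the
diattenuation vector is the first row, `D = [M(1,2),M(1,3),M(1,4)]/M(1,1)`;
`M_D` is built from `D` in closed form; `M' = M·M_D⁻¹`; with `m'` the lower
3×3 block of `M'` and λ₁..λ₃ the eigenvalues of `m'm'ᵀ`,

    m_Δ = ± [m'm'ᵀ + (√(λ1λ2)+√(λ2λ3)+√(λ3λ1)) I]⁻¹
            [(√λ1+√λ2+√λ3) m'm'ᵀ + √(λ1λ2λ3) I],     sign = sign(det m')

the depolarizer's polarizance column is `(P − m·D)/(1−d²)`, and
`m_R = m_Δ⁻¹ m'`.  Scalars: `d = |D|`; `Δ = 1 − |tr(m_Δ)|/3`;
`δ = arccos(√((M_R(2,2)+M_R(3,3))² + (M_R(3,2)−M_R(2,3))²) − 1)`;
total retardance `arccos(tr(M_R)/2 − 1)`; optical rotation
`ψ = atan2(M_R(3,2)−M_R(2,3), M_R(2,2)+M_R(3,3))/2`.  Retardances are
radians (the tissue-scale values, e.g. δ ≈ 2.373, only fit the arccos
range in radians).

Numerical fallbacks, each recorded as a flag rather than an exception:
eigenvalues of `m'm'ᵀ` below −1e-9 are clamped to 0 (`clamped-eigenvalue`);
`d ≥ 1 − 1e-9` short-circuits to a pure-polarizer path (retarder taken as
identity, residual absorbed by the depolarizer, `pure-diattenuator`);
singular systems fall back to pseudo-inverses (`singular-depolarizer`).
The factor product reconstructs the input to 1e-8 on noiseless composed
matrices.  The decomposition is exact only for matrices composed in the
Δ·R·D order; reversed-order products still reconstruct but their recovered
scalars need not equal the composing parameters.

A fully depolarizing pixel (`Δ = 1`) annihilates the polarized signal:
`m' = 0`, and the retarder factor — hence δ — is mathematically
undetermined there.  Such pixels are flagged singular and excluded from
region summaries; callers comparing per-pixel retardance against ground
truth should likewise restrict to unflagged pixels.

The image path (`decompose_image`) runs the identical construction with
batched linear algebra over an `(H, W, 4, 4)` field and agrees with the
scalar path to 1e-10.  Region summaries are arithmetic means of each
scalar over unflagged pixels (a median option is the obvious extension but
the mean is the reported statistic).  Whether published region-level
scalars of this kind come from per-pixel means or from decomposing one
region-average matrix is generally ambiguous; both paths are provided
(`decompose_image` and `lu_chipman` on an averaged matrix).

## Phantom generator

The generator defines the study conditions for all downstream validation.
Class presets (normal d=0.043, δ=2.373, Δ=0.644; tumour d=0.11, δ=0.748,
Δ=0.826) are the region-level decomposition values reported for healthy
versus ductal-carcinoma breast tissue under transmission polarimetry.
Per pixel, `M = M_Δ·M_R·M_D` is composed from textured parameter fields,
applied to the four probe states, and projected through the ideal analyzer
matrix; intensities live on a [0, 1] full scale.

Invented knobs (no instrument or tissue figures exist for them; chosen
once as plausible for collagenous tissue at ~20–40× magnification and
declared here):

| parameter | default | rationale |
|---|---|---|
| image size | 256×256 px | typical analysis crop; divisible by the 4×4 patch grid |
| regions per class | 4 | matches the 4 normal + 4 tumour study design |
| texture amplitude | 0.10 (relative) | visible heterogeneity without saturating clips |
| correlation length | 24 px normal / 6 px tumour | ordered stroma varies smoothly; tumour is patchy |
| orientation | 5° jitter about 30° (normal); uniform per-cell (tumour) | aligned vs randomly oriented collagen |
| read noise σ | 0.005 of full scale | quiet scientific CMOS detector |
| shot noise | off (option: Poisson at 10⁴ photons/px) | read noise dominates at these levels |

Texture is multiplicative — parameter = preset × (1 + 0.1·G) with G a
unit-variance Gaussian random field (white noise blurred at σ =
corr_length/2, wrap boundary, restandardised) — and clipped to each
parameter's physical range, so class contrast is physically mediated
through the optics rather than painted onto the images.  Clipping means
tumour Δ occasionally saturates at 1 (see the decomposition note above).
Every region derives a 31-bit sub-seed from SHA-256 of
`(dataset seed, class, region index)`; identical configuration and seed
reproduce the dataset bit for bit.

What the phantom does *not* emulate: optical blur/PSF, defocus, spectral
effects, scattering-angle structure, slide artefacts, or H&E appearance.
Passing tests therefore demonstrate the correctness of the algebra and the
pipeline plumbing, and a separability the phantom's class contrast makes
fairly easy — not classifier performance on real stained-tissue imagery.

## Texture features and classification

Augmentation is original + horizontal flip + vertical flip (3 versions —
the count that makes 8 regions × 3 × 16 patches = 384 records per
parameter, and 6144 over the 16 Mueller elements).  Patching center-crops
to multiples of 4 and cuts a 4×4 row-major grid.  GLCMs are 8×8,
symmetric, normalized, averaged over the four unit-distance offsets
(0°, 45°, 90°, 135°; co-occurrence counting via
`skimage.feature.graycomatrix`).  Quantization bins over the parameter's
*physical* range (0–1 for DOP/DOLP/DOCP, −0.5–1 for anisotropy, −1–1 for
Mueller elements), never per-patch min/max, which would erase inter-patch
contrast.

The 20 features are Haralick's set plus standard extras: contrast,
dissimilarity, homogeneity, energy (= angular second moment), correlation,
entropy, variance, sum average, sum variance, sum entropy, difference
variance, difference entropy, the two information measures of correlation,
autocorrelation, cluster shade, cluster prominence, maximum probability,
inverse difference, inverse difference moment.  Conventions: logs are
base 2 with 0·log 0 = 0; sum variance is taken about the sum average;
a zero-variance GLCM gets correlation 0; since classic inverse difference
moment coincides with homogeneity, the inverse-difference pair uses the
Clausi normalized forms (|i−j|/L and (i−j)²/L² in the denominators) so all
20 features are distinct.  Every feature is validated against an
independent brute-force double-loop oracle to 1e-10.

The SVM is an RBF `SVC(C=1, gamma="scale")` behind a `StandardScaler`
fitted on training data only; all parameter models share these
hyperparameters.  The default split holds out whole region images
(stratified 80/20 at the region level) so augmented copies and sibling
patches of one region never straddle train and test; a `patch` split
(stratified at the patch level, mimicking published 308/77-style splits)
is available for comparison but leaks augmented near-duplicates across the
boundary and inflates accuracy.  Validation metrics use stratified 5-fold
cross-validation on the training portion; test metrics use the held-out
portion.  Metrics: sensitivity, precision, specificity, accuracy and F1 as
percentages from the confusion counts, with zero-denominator ratios
reported as 0 and flagged.  "Tumour" is the positive class.

## Problem sizes and determinism

Default validation runs use the full study conditions (8 regions of
256×256); the end-to-end exactness check uses one 64×64 region per class
with noise off, where the pipeline recovers ground-truth fields to
machine precision.  All randomness flows through explicit seeds
(`numpy.random.default_rng`), so metrics and rendered datasets are
reproducible run to run; run manifests record config hashes and per-file
checksums to make that verifiable.

## Known limitations

- The ideal analyzer matrix stands in for an unpublished instrument
  calibration; real four-camera data would need its measured `A`.
- No image registration across the four state stacks.
- No physical-realizability filtering (e.g. Cloude) and no alternative
  decompositions (reverse-order, symmetric, differential).
- The classifier threshold property (≥80 % held-out accuracy on the
  default phantom) is a property of the phantom's declared contrast, not a
  claim about clinical performance.
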