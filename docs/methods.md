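# Methods

## The volumetric CoV model

The quantity of interest is the temporal coefficient of variation of
the OCTA signal at a fixed retinal location, estimated from N = 10
consecutively acquired volumes of the same field.  For voxel (x, z; y)
— fast-scan x, depth z, B-scan index y —

    Ī(x,z;y)   = (1/N) Σₖ Iₖ(x,z;y)
    σ(x,z;y)   = sqrt( (1/(N−1)) Σₖ [Iₖ(x,z;y) − Ī(x,z;y)]² )
    CoV(x,z;y) = σ / Ī

CoV is defined as 0 where Ī = 0 (such voxels carry no signal and are
always sub-threshold) and is exactly 0 wherever σ = 0.  The estimator
is scale-free: multiplying every repeat by a constant leaves it
unchanged, which is why the package treats OCTA intensities as
arbitrary linear units and never applies a log/dB conversion.

Two 2D baselines are implemented with the identical mean/std/ratio
definitions for comparison: Protocol A operates on a stack of
device-style contrast-refined en face images, Protocol B on per-repeat
maximum intensity projections of the volume.  Protocol B's failure
mode is made measurable by `depth_index_variability`: the per-repeat
argmax depth per A-scan (ties broken to the smallest z) and its sample
STD across repeats, nonzero exactly where the MIP mixes depths.

## Noise masking

For each B-scan y the noise floor is estimated on the *averaged*
volume over a background band R(y) spanning 10–30 px anterior to the
per-A-scan ILM (the band is in the vitreous, hence signal-free).  Both
offsets are inclusive, the mean uses the 1/|R| denominator and the
standard deviation 1/(|R|−1).  The binary mask keeps voxels with
Ī strictly greater than

    T(y) = Ī_noise(y) + σ_noise(y) + δ

and the filtered volume is V = CoV ⊙ M.  A band that would extend
above z = 0 is clipped with a logged warning; an empty band is an
error.

The offset δ defaults to automatic calibration: δ is scanned over a
grid, each candidate mask is projected through the analysis slab, and
the projection's Dice overlap with a reference vessel mask (phantom
truth, or an external segmentation) is scored.  The selected δ is the
largest value whose Dice stays within 0.02 of the best — i.e. the most
aggressive noise suppression that does not erode the vasculature.  A
numeric δ in the configuration bypasses calibration.

## En face projection

The filtered CoV volume is projected per A-scan by the median over a
half-open layer slab [upper, lower), with the even-count median
defined as the mean of the central pair.  Two variants exist:

* the plain slab median (the basic operation);
* a median over only the mask-retained (positive) voxels of the slab,
  used by the Protocol C pipeline.  A capillary a few voxels thick
  would otherwise be outvoted by the masked-out zeros around it and
  vanish from the map; restricting the median to retained voxels keeps
  the map's support equal to the projected vasculature, with 0 where an
  A-scan holds no retained voxel.

Slab boundaries are named (`ilm`, `nfl`, `opl` for the ILM, NFL-lower
and OPL-lower surfaces); the default analysis slab is ILM→OPL-lower,
which covers both vascular plexuses.  An optional vessel-probability
map can be applied afterwards; a probability of exactly 0.5 counts as
vessel (the threshold is the 50% confidence level for identifying a
pixel as vasculature).

## Registration

Residual inter-volume motion is corrected in three stages against a
template repeat chosen automatically: the quality score is the mean
gradient magnitude of the en face projection (sharpness) minus the
largest adjacent-B-scan discontinuity (a mid-scan saccade produces one
big row-to-row jump); ties resolve to the lowest index and a manual
override is supported.

1. **Transverse rigid.** Keypoints are detected on en face projections
   by two complementary schemes — a binary corner detector/descriptor
   (ORB, Hamming matching) and a float gradient detector (SIFT,
   Euclidean matching).  The two match pools are merged and a single
   similarity transform is estimated by RANSAC (min 3 samples, 2 px
   residual threshold, ≥ 6 inliers required, scale restricted to
   [0.9, 1.1]); the final model is refit on all inliers.
2. **Transverse non-rigid.** A diffeomorphic demons displacement field
   (100 iterations, field smoothing σ = 2 px) refines the rigidly
   aligned en face pair.  The field must not worsen the mean squared
   difference: if the warped MSD exceeds the input MSD the identity
   field is returned instead (the pair is already at the noise floor),
   and a large field that still increases MSD raises a convergence
   error.
3. **Axial.** Per A-scan, the integer depth shift maximizing the 1D
   cross-correlation of mean-removed structural OCT profiles within a
   ±10 px search range; OCT is used because its layered bands carry
   far more depth structure than OCTA.  Flat A-scans get confidence 0
   and are imputed from the median of confident neighbors; the map is
   then median-filtered (5×5).  Shifts stay integer so depth is never
   blurred by interpolation.

One 2D transverse transform per repeat is applied identically to every
z-slice of both the OCT and OCTA volume (depth-invariant transverse
motion model; per-slice transforms would decorrelate depth).  Feature
images for stages 1–2 are *full-depth* mean projections rather than
layer-slab projections: axial mismatch is only corrected in stage 3,
and a layer-bounded slab would let it leak content changes (not just
geometric ones) into the feature images.  Registration alters
intensities only through linear interpolation; out-of-field samples
are padded with a configurable background value.  Finally a fixed
margin (default 20 px) is cropped from every transverse side so all
subjects share identical final dimensions.

## Lognormal mixture and vessel classification

The histogram of nonzero en face CoV values (zeros are masked
background; default 100 bins over the data range, density-normalized)
is fitted with a weighted sum of two lognormal densities by bounded
nonlinear least squares on the bin densities (not maximum likelihood —
the histogram is the data).  Starting values: λ₁ = λ₂ = 0.5,
σ₁ = σ₂ = 0.5, μ₁ = ln(mean of bin centers), μ₂ = 1.5·μ₁.  Because
CoV < 1 makes ln v̄ negative, the μ₂ start lies *below* μ₁; the rule is
applied verbatim and the components are reordered by μ after the fit.
Bounds: λ ∈ [0, 10], σ ∈ [10⁻³, 10], μ ∈ [−10, 5].  Non-convergence
returns the best-so-far parameters with a warning.

The classification threshold v* is the crossing point of the two
weighted component densities, bracketed between the component modes
exp(μᵢ − σᵢ²) and found by Brent root finding on the log-CoV axis
(with equal σ and λ this reduces to exp((μ₁+μ₂)/2)).  If the weighted
densities do not cross in the bracket (extreme weight imbalance), a
dense-grid minimum of the absolute difference is used with a warning.
Pixels with CoV ≤ v* form the main arteriole/venule mask, CoV > v*
the branching-capillary mask; the two masks partition the nonzero
support.

## Intersession repeatability

S session CoV maps are rigidly aligned to the first and cropped to
their common support.  For every unordered session pair the per-pixel
sample variance (a − b)²/2 is computed — the n = 2 case of the same
N−1 convention used throughout — giving S(S−1)/2 variance maps per
subject (3 for S = 3; 24 across 8 subjects).  A joint S-session
variance map is also available.

Spatial structure is summarized in FAZ-centered regions: z0 is the FAZ
mask itself, z1 the annulus within 0.5 mm of the z0 boundary, z2 the
annulus between 0.5 mm and 1 mm.  Distances are Euclidean distances to
the z0 region computed by a distance transform in physical units via
the pixel spacing.  Each ring's summary is the spatial mean of each
pair's variance map within the ring, then the mean and sample STD of
those per-pair means; pixels with zero CoV in any session (background)
can be excluded and are logged.

## The synthetic phantom

The phantom is the ground-truth source for every test.  It emulates a
fovea-centered raster scan on a (z, x, y) = (64, 96, 96) grid with
(6, 23.4, 23.4) μm voxels by default (a 2.25 mm transverse field — a
scaled-down version of a clinical 3 mm scan, chosen so the full ring
analysis fits in the field while volumes stay small enough for
many-seed simulation studies):

* smooth layer surfaces (ILM at ~36 px with a gentle sinusoidal
  undulation, NFL-lower 8 px and OPL-lower 24 px below it), deep
  enough that the 10–30 px noise band above the ILM always exists;
* four vessel populations as tube primitives on two plexus planes:
  large arterioles/venules (radius 35 μm, intensity 200, CoV 0.10),
  superficial and deep capillary meshes (10 μm, 120, 0.30) and a ring
  of shunt vessels hugging the FAZ margin (12 μm, 130, 0.50) — the
  CoV range 0.1–0.5 spans quiet trunk vessels to highly variable
  shunts and produces the bimodal CoV histogram the mixture analysis
  targets.  Geometric realism is a non-goal;
* a FAZ of radius 0.25 mm kept avascular;
* background noise with mean 10 and STD 2 (well below every vessel
  intensity), drawn from a zero-truncated normal.

Temporal fluctuation model: every vessel voxel's intensity in each
repeat is an independent draw from normal(mean, CoV·mean) truncated at
zero — independence across repeats is the minimal assumption
consistent with a CoV summary.  Truncation slightly raises the mean
and shrinks the STD, so for large CoV the realized CoV of the
generative law is below the nominal parameter (0.458 for a nominal
0.5).  The truth carrier stores the exact truncated-law CoV per voxel
and per class (closed form from the truncated-normal moments); that
value, not the nominal parameter, is what an unbiased estimator should
recover.  Speckle, shadowing and projection artifacts are not
simulated — additive sub-threshold background noise is sufficient to
exercise the noise-floor masking.

Motion injection (off by default; the motion-free configuration is the
reference condition for CoV recovery) applies to every non-template
repeat a transverse rigid shift (≤ 5 px) and rotation (≤ 0.5°), an
optional smooth sinusoidal deformation, and a constant integer axial
shift, all drawn per repeat; linear interpolation with
background-value padding keeps registration tests at known tolerance.
These magnitudes are configuration, not claims about real fixation
behavior.

The device-style en face emulation is a slab mean projection followed
by a monotone contrast refinement (percentile stretch to [0, 1] plus
gamma 0.6): rank order is preserved but the intensity distribution is
reshaped, reproducing the Protocol A bias mechanism.

**What passing tests do and do not show.**  The phantom establishes
that the estimators are correct and the pipeline recovers known
transforms and known temporal statistics.  It does not establish
performance on real OCTA: real data add speckle, projection artifacts,
pulsatile (non-independent) flow fluctuations, segmentation errors and
intra-volume motion, none of which are simulated.

## Problem sizes and numerical choices

Simulation studies use the default 64×96×96 phantom (CoV recovery: 20
seeds × 10 repeats), 64×128×128 fields for feature-based registration
(denser keypoints), and 64×64×64 sessions for the 8-subject × 3-session
design.  Tolerances asserted in the tests: 1e−10 relative for oracle
equivalence, 0.5 px / 0.2° / 0.5 px RMS / 1 px for
shift/rotation/warp/axial recovery, ±0.05 for class CoV recovery, 1e−6
for the closed-form mixture intersection.  Degenerate inputs are
handled explicitly: constant histograms open a small positive bin
window, argmax ties resolve to the smallest z, two-value variances use
the N−1 convention, flat A-scans are imputed, and CoV at zero mean is
defined as zero.

## Known limitations

* The rigid stage needs textured en face images; featureless inputs
  raise a registration error with diagnostics rather than guessing.
* Axial matching is integer-resolution by design; sub-voxel axial
  mismatch survives and slightly inflates per-voxel CoV near steep
  layer slopes.
* The sample CoV at N = 10 is biased low by a few percent (the
  c₄-type bias of the sample standard deviation); the package reports
  the raw estimator, as the method prescribes, and the bias is visible
  in the worked example (0.288 measured vs 0.299 truth).
* δ calibration scores vascular integrity through an en face presence
  projection, which tolerates some interior voxel erosion at large δ;
  the 0.02 Dice tolerance bounds that erosion.
* FAZ delineation is an input (phantom truth or external); the package
  does not segment the FAZ from data.
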