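# Methods

This note documents the models, parameter choices, numerical details and
limitations of `fusionwmh`.  The package quantifies white-matter
hyperintensity (WMH) burden from T1/FLAIR MRI, regional cerebral blood
flow (rCBF) from ⁹⁹ᵐTc-ECD SPECT, fuses both per subject, and runs the
cohort-level statistics relating them to cognition.

## Conventions

All world coordinates are RAS+ millimetres: x to the subject's right, y
anterior, z superior.  Every image is a `Volume3D` (voxel array + 4×4
voxel→world affine + units tag).  Rigid transforms are stored in the
pull-back convention — they map *target* world points into *moving* world
points, which is the direction interpolation actually needs — so
`resample(moving, target, T)` and `register_rigid` compose without
inversions.  Label volumes are always resampled nearest-neighbour.
NIfTI-1 is the on-disk format; DICOM series directories are import-only.

## MRI arm

**Lesion filling.**  WMH lesions are hypointense on T1 and would bias
tissue segmentation.  Lesion-prior voxels are replaced, per connected
component, by draws from a Normal fitted to the non-lesion white-matter
intensities within a 10 mm ring around the component (ring width
configurable).  The generator is seeded, so filling is bit-reproducible.
When no prior is supplied, `run_mri` derives one in a first pass: segment
the raw T1, take FLAIR statistics of the resulting WM class, and
threshold FLAIR over the whole brain mask.  Thresholding the whole brain
rather than the first-pass GM∪WM matters: lesion voxels whose noisy T1
intensity falls below the CSF/GM boundary are mislabelled CSF in the
first pass and would otherwise escape filling, then resurface as spurious
interior "ventricle" components.

**Coregistration.**  `register_rigid` maximizes normalized mutual
information, (H(a)+H(b))/H(a,b), on a 32-bin joint histogram, over the
six rigid parameters (Euler angles about the fixed-volume centre +
translation), with Gaussian pre-smoothing (σ = 1 voxel) and a two-level
pyramid (×2 downsampled Powell search, then a capped full-resolution
polish).  On smooth phantoms it recovers 3 mm translations and 5°
rotations to ≈0.01 mm/0.01°, far inside the 0.5 mm/0.5° tolerance used in
tests.  Histogram NMI is a deliberate choice over intensity correlation
because T1→FLAIR is a cross-modality problem.

**Tissue segmentation.**  A 3-class (CSF/GM/WM) univariate Gaussian
mixture fitted by EM on intensities within the brain mask; means
initialized at the 0.1/0.5/0.9 intensity quantiles, at most 100
iterations, relative log-likelihood tolerance 1e-6, variance floor at
1e-8 of the data variance (degenerate fits raise rather than silently
collapse).  Classes are relabelled post hoc so mean(CSF) < mean(GM) <
mean(WM), making the output invariant to EM initialization order.

**Ventricles.**  CSF connected components (26-connectivity) that do not
touch the brain-mask boundary and whose centroid lies in the central 50%
of the brain bounding box along every axis.  This separates ventricular
from sulcal/surface CSF without an atlas; it will miss very enlarged
ventricles that reach the cortex and will accept any central CSF cavity,
which is the intended phantom-testable behaviour.

**WMH extraction.**  Normal-appearing WM statistics are estimated
robustly: two passes of excluding voxels above mean + k·σ before the
final mean/σ.  WMH voxels are those in the WM domain with FLAIR above
mean + k·σ (default k = 3.0, exposed on the CLI since the operation is
semi-automated in practice).  Components smaller than 5 voxels (default)
are discarded as noise.  With Gaussian FLAIR noise, isolated
suprathreshold noise voxels are expected at a ~1e-3 rate; the size filter
removes them unless they abut a true lesion, which bounds the phantom
recovery error well under the 5% volumetric tolerance.

**PVH/DWMH.**  A component is periventricular iff its minimum Euclidean
distance (via a world-mm distance transform of the ventricle mask) to any
ventricle voxel is ≤ d (default 3.0 mm, inclusive); otherwise deep.  The
distance rule is the standard convention where a contiguity-vs-distance
definition is not otherwise fixed; d is configurable.

**Four-area partition.**  Two world planes: the midsagittal plane
x = x₀ (longitudinal fissure, default 0 after alignment) and a coronal
plane y = y₀ through the central sulcus.  y₀ is subject-specific and must
be supplied; there is deliberately no default.  Voxels exactly on a plane
count as right/anterior.  Volumes are voxel counts × voxel volume / 1000
(cc); a component spanning a plane contributes voxelwise to each side, so
the eight cells always sum exactly to the total.

## SPECT arm

**TACs and BPI.**  Time–activity curves are ROI means per frame.  The
brain perfusion index is the Patlak-plot slope: regress y = Cb/Ca on
x = ∫₀ᵗCa/Ca (trapezoidal integration) over frames in the fit window,
default 4–14 s after the aortic peak (argmax of the aortic TAC).  For
curves generated as Cb = K·∫Ca + V·Ca the slope equals K exactly and
r² = 1; r² is reported from the fit and defined as 1 when both residual
and total variance vanish (e.g. Cb ≡ 0).

**Calibration.**  mCBF = a·BPI + b.  Site calibration constants are
scanner-dependent and not derivable from first principles here, so the
default is the identity (a = 1, b = 0) with a loud CLI warning; phantoms
carry their own self-consistent constants (a = mean flow / K), so tests
never depend on the default.

**Lassen linearization.**  ECD uptake saturates with flow:
R = αF/(1+(α−1)F) for the count ratio R and flow ratio F relative to a
reference.  The correction inverts this exactly: F = R/(α−(α−1)R),
strictly increasing, fixed point at R = 1, defined on 0 ≤ R < α/(α−1).
Default α = 2.59, the literature linearization factor for ⁹⁹ᵐTc-ECD;
configurable.  In `counts_to_rcbf`, ratios are taken against the
whole-brain mean (default) or a supplied reference mask; voxels at or
beyond the saturation bound are clamped to bound − 1e-6 and counted
(logged), rather than aborting on isolated hot voxels.  The corrected
flow field is rescaled so the brain-mask mean equals mCBF to machine
precision, which also makes the map invariant to any positive rescaling
of the raw counts.

**ROI template.**  A synthetic stereotactic template stands in for
commercial ROI sets whose anatomy is proprietary: 636 ROIs (318 per
hemisphere) partitioning an ellipsoidal brain in template space (64×80×64
at 2 mm), grouped into 13 named regions per hemisphere sized by ROI
count, with the bilateral parietal, temporal and posterior cingulate
regions forming the six analysis segments (all other ROIs map to an
explicit "other" segment so the ROI→segment map is total).  Only the
counting structure and the aggregation identities (segment mean =
voxel-weighted mean of member ROI means) are meaningful; the geometry is
not anatomical.  ROIs with no overlapping voxels after resampling report
NaN, never a silent zero.

## Phantoms

The generators define the conditions every test runs under.

*MRI*: 128³ at 1 mm (default), brain ellipsoid semi-axes (52, 60, 50) mm
with a surface CSF rim (outside 0.95 scale), GM mantle, WM core (0.85
scale) and two ventricle cavities at x = ±11 mm, semi-axes (7, 22, 9) mm.
Default lesions: one DWMH per quadrant ≥ 9 mm from the ventricle surface
(6 mm clear of the 3 mm decision boundary) and one PVH per quadrant
overlapping the ventricle wall (clipped at the wall, so they touch it);
radii 5–6.5 mm, scalable by 0.9–1.1 without violating the WM-shell or
inter-lesion separation margins (separations exceed the 26-connectivity
bridging distance so components never merge).  T1 intensities are
Gaussian per tissue (30/70/110, σ 5; lesions hypointense at 60); FLAIR is
Gaussian per tissue (CSF suppressed at 30, GM 90, WM 100, σ 2) with
lesion voxels at the deterministic WM mean + 6σ so threshold extraction
has an exact expected voxel set.  Truth volumes are voxel counts of the
generated masks.

*SPECT*: a gamma-variate aortic input (onset 8 s, shape 3, scale 3 s) and
a brain curve K·∫Ca + V·Ca (K = 0.12, V = 0.3) over 120 frames at 1-s
intervals on a 128×128 matrix; optional additive Gaussian noise with
σ = noise_level × max(Cb) (default 1%), clipped at zero.  Static counts
are the saturation law applied to flow ratios, with the reference flow
solved (Brent) so the whole-brain mean count ratio is exactly 1 — the
same convention the inversion assumes — making the forward→inverse chain
exact to machine precision.  Default regional flows are realistic
resting AD-cohort values (27–47 mL/100 g/min by region).

*Cohort*: predictors drawn from truncated Normals with memory-clinic
scale (age 73.1 ± 7.9 y; anterior/posterior PVH/DWMH volumes in cc;
bilateral segment flows), outcomes drawn from Poisson or Gamma with mean
exp(intercept + Σβ(x−μ)); centring at the population means keeps the
intercept interpretable as the outcome scale.  Default coefficients are
ratio-scale effects of realistic magnitude (0.89–1.17 per unit).

What the phantoms do *not* emulate: partial-volume effects, bias fields,
anatomical shape variation, scatter/attenuation physics, or outcome
missingness patterns.  Passing tests therefore demonstrate algorithmic
correctness (thresholds, distances, inversions, estimators), not
robustness to those real-data effects.

## Cohort statistics

**Repeated-measures ANOVA.**  The four region categories (PVH/DWMH ×
anterior/posterior, hemispheres summed) are within-subject conditions:
F = MS₍cond₎/MS₍cond×subj₎ with df = (k−1, (k−1)(n−1)); for n = 29,
k = 4 this is F(3, 84).  The design is forced to repeated measures by
that df pattern.  No sphericity correction is applied (a documented
limitation); the statistic is invariant to adding per-subject constants
and to relabelling conditions, and matches a definition-level
sums-of-squares oracle to 1e-10.

**Ryan's procedure.**  Condition means are ordered; the pair spanning m
ordered means is tested by a paired t-test at
α′(m) = 2α/(k(m−1)) (for k = 4, α = 0.05: 0.0253̄/0.0125/0.00833̄), and is
significant only if every encompassing pair is.  For k = 2 this reduces
to a single paired t-test at α.  Simulated familywise error under the
null (n = 20, k = 4, 2000 replicates) is ≈0.045 at nominal 0.05.

**Log-link GLMs.**  Each outcome is regressed on age, PVH(A), PVH(P),
DWMH(A), DWMH(P) and the three bilateral segment flows via statsmodels
IRLS with a log link — Gamma for positive continuous outcomes (times),
Poisson for counts/scores, Gaussian-log available.  Coefficients are
reported as exp(β) with Wald 95% CIs exp(β ± 1.96·SE) and two-sided Wald
p (the log link is what makes ratio-scale reporting coherent; Wald
rather than profile CIs is a documented choice).  Designs are rejected
when the column-normalized condition number exceeds 1e10 or when
n ≤ p + 1.  Missing data policy: complete case per response, no
imputation.  Significance is flagged at 0.05/0.01/0.001.

## Problem sizes in tests

Unit tests run on 48³–64³ phantoms at 2–2.75 mm; the volumetric
acceptance suite uses ten phantoms at the default 128³/1 mm; the Ryan
familywise simulation uses 2000 null replicates; GLM recovery uses 200
cohorts of n = 2000.  These sizes were chosen so the full suite
characterizes each property with comfortable statistical margin while
remaining a routine local run.

## Known limitations

- The WMH threshold is global per subject; no bias-field correction
  beyond the two-pass robust estimate.
- The ventricle rule is geometric, not anatomical.
- The ROI template is synthetic; regional values are only meaningful
  relative to its own geometry.
- BPI→mCBF defaults to the identity calibration and must be configured
  per site.
- No sphericity correction in the ANOVA; no multiplicity correction
  across outcomes (matching common practice for this design).
- DICOM support is read-only and assumes a single-series directory.
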