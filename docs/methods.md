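# Methods

## Overview

`bonemap` converts a CT scan into a voxel-wise Young's modulus map suitable
for patient-specific finite-element (FE) models of bone. The chain has three
stages, each an elementwise map over the voxel grid:

1. **Phantom calibration (stored grayscale → QCT density).** A calibration
   phantom — a scanned object containing tissue-equivalent inserts of
   manufacturer-specified bone-mineral-equivalent density ρ_CT (mg/cm³) — is
   measured insert by insert. Ordinary least squares with the insert mean
   stored grayscale as predictor and ρ_CT as response gives a linear map
   ρ_CT = a·g + b applied to every voxel.
2. **QCT density → wet apparent density (Lotz relation).**
   ρ_app (g/cm³) = 0.0012·ρ_CT (mg/cm³) + 0.17.
3. **Apparent density → Young's modulus.** A three-branch piecewise law:
   - ρ_app ≤ 0 → E = 1 MPa (air pockets; a realistically negligible but
     FE-stable stiffness),
   - 0 < ρ_app ≤ ρ_cut → E = 11 417.6 · ρ_app^1.89 MPa (trabecular power
     law; the coefficient is the Morgan-style base 8920 scaled by a 1.28
     transverse-stiffness factor),
   - ρ_app > ρ_cut → E = 17 000 MPa (constant cortical modulus),
   with cutoff ρ_cut = 1 g/cm³ by default and user-settable.

## Scales and units

The calibration regression runs on **stored values**, the raw DICOM integer
pixels, not on Hounsfield units. HU relate to stored values by the affine
rescale HU = m·stored + b read from tags (0028,1052)/(0028,1053); because
that map is affine, working in either scale changes only the fitted
coefficients, never the densities produced — what matters is internal
consistency between the calibration measurements and the voxel data they
are applied to. `stored_to_hu`/`hu_to_stored` convert for users whose
phantom measurements were taken on the HU scale. When rescale tags are
absent we default to m = 1, b = 0 (the DICOM default) and warn loudly.

Units are fixed through the chain: stored values (dimensionless integers) →
ρ_CT in mg/cm³ → ρ_app in g/cm³ → E in MPa. The Lotz slope 0.0012 has units
(g/cm³)/(mg/cm³), which pins the QCT scale to mg/cm³.

## Boundary assignment and the modulus floor

The published branch inequalities (ρ < 0, 0 < ρ < 1, ρ > 1) leave ρ = 0 and
ρ = ρ_cut unassigned. We assign ρ ≤ 0 → air and 0 < ρ ≤ ρ_cut → trabecular:
a measure-zero choice, with the cutoff kept on the trabecular side so the
upward jump to the cortical plateau is never applied one floating-point ULP
early. With default constants the law is discontinuous at the cutoff — E
jumps from 11 417.6 to 17 000 MPa — and the conversion summary reports this
jump magnitude explicitly.

A `modulus_floor` (default 1 MPa, equal to the air modulus) clamps the
trabecular branch so vanishing positive densities cannot receive sub-air
stiffness, which would ill-condition FE solves. Set `modulus_floor: 0` in
the law file to evaluate the bare power law. The floor preserves
monotonicity: with defaults, E is non-decreasing in density over the whole
range.

All constants live in one `MaterialLaw` configuration (YAML-serializable);
no constant is hard-coded in the operation bodies. `MaterialLaw.from_morgan`
lets users supply an unadjusted base coefficient and have the transverse
factor applied explicitly.

## Sampling phantom inserts

Two estimators of an insert's mean grayscale are provided:

- **Profile line**: stored values are trilinearly interpolated at uniform
  steps along a user-drawn segment (default step: half the smallest voxel
  spacing — fine enough that no voxel on the path is skipped, coarse enough
  that neighboring samples are not fully redundant).
- **Cylindrical ROI**: the mean over all voxel centers inside a finite
  cylinder. Pooling an entire insert volume suppresses noise roughly as
  1/√n and is the preferred estimator.

Both return mean, SD and count; multiple measurements of one insert are
pooled by a count-weighted mean with combined within/between variance.

## Calibration uncertainty

`CalibrationModel` carries the usual OLS diagnostics (R², residual SE,
coefficient SEs). A warning is logged when R² < 0.99: phantom density
scales are linear by construction, so a poor fit almost always means a
mis-measured insert rather than real nonlinearity.

For *coverage* statements about the fitted line, the residual-based OLS
standard errors are a poor instrument: with a typical five-insert phantom
they rest on 3 degrees of freedom, so a ±3·SE interval has Student-t, not
Gaussian, coverage (~94% per coefficient). `propagated_coefficient_se`
instead propagates each insert's known measurement uncertainty (ROI
SD/√n, estimated from thousands of voxels) through the OLS estimator to
first order, treating the manufacturer densities as exact:

SE(a) = |a|·√(Σ dᵢ²sᵢ²)/S_xx,  SE(b) = √(Σ (a(x̄dᵢ/S_xx − 1/n))² sᵢ²),

with dᵢ = xᵢ − x̄, S_xx = Σ dᵢ², sᵢ = SDᵢ/√nᵢ. These intervals carry
near-Gaussian coverage, and the package's parameter-recovery study
(`calibration_recovery_study`) uses them.

## Synthetic data

No scan ships with the package; the generators in `bonemap.synthetic`
fabricate the two inputs the pipeline needs, each with exact ground truth.

**Phantom** (`make_phantom_volume`): cylindrical inserts of specified
density in a uniform background. Stored values are
round((ρ − b_true)/a_true) plus i.i.d. Gaussian noise on the stored-value
scale, re-rounded to integers and clipped to the int16 range (clip events
counted). All randomness comes from NumPy's PCG64 generator seeded from
the design, and the seed is recorded in the output. The default design has
five inserts at 0/100/200/400/800 mg/cm³ — the spread of commercial
tissue-equivalent insert sets — on the line ρ = 2·g − 100, chosen so
noiseless stored values are exact integers and a noiseless acquisition is
lossless; each ROI holds ≈1400 voxels. The default noise scale for studies
is SD = 20 stored units, i.e. tens-of-HU noise on a slope-1 rescale,
matching the magnitude of between-scanner HU variation reported for soft
tissue. The ground truth carries the density implied by the *rounded*
noiseless stored values, so generator and calibration line are mutually
exact and closure tests can demand bit-equality.

**Bone-like volume** (`make_bone_volume`): a cortical-density block with an
ellipsoidal trabecular core (voxelwise uniform-random densities) and an
optional central spherical air pocket, encoded with an identity
(1 mg/cm³ per stored unit) calibration. Densities are validated against
the law's branch windows so the fixture always exercises every branch it
claims to. Ground-truth moduli are computed with the same closed-form law.

What the generators deliberately omit: beam hardening, scatter, partial
volume, spatially correlated noise, scanner transfer functions, and large
metal artifacts. Passing tests therefore validate the calibration and
conversion arithmetic — not robustness of the method to CT physics, which
must come from scanning a real phantom alongside the anatomy.

## I/O and encodings

DICOM series are read with pydicom: single series enforced, consistent
in-plane geometry enforced, slices ordered by the projection of
ImagePositionPatient onto the slice normal (filenames are unreliable).
NIfTI-1 and MetaImage go through SimpleITK; its LPS world convention
matches the DICOM patient coordinate system used internally, so geometry
round-trips bit-exactly. Floats written to NIfTI/MetaImage are lossless.

Writing a float modulus map back to DICOM requires a quantization: we use
unsigned 16-bit stored values with intercept 0 and slope max(E)/(2¹⁶−1),
rounded to the 10 significant digits the DS tag carries, recorded in tags
(0028,1053)/(0028,1052). Maximum quantization error is one slope step
(≈0.26 MPa for a 17 GPa range). Negative values are rejected by this
encoding (modulus maps are non-negative by construction).

## FEA export

`bin_materials` reduces the voxel map to a small set of isotropic
materials: air voxels always occupy reserved bin 0, the constant cortical
modulus its own top bin, and the trabecular range is split into `n_bins`
(default 10) equal-width intervals in E, or in ρ_app via inversion of the
power law. Representatives are bin means, so bin labels are strictly
monotone in modulus and counts always sum to the voxel total. The Poisson
ratio in solver snippets is a user-supplied constant (default 0.3) and the
output header marks it as not derived from imaging.

## Problem sizes used in tests

Closure and round-trip checks run on 32×48×48 bone volumes and 24×64×64
phantoms (~100k voxels) — large enough that every branch and every insert
is populated by hundreds of voxels, small enough that the full suite runs
in seconds. The parameter-recovery study uses 100 seeded phantoms at noise
SD 20; its hit criterion (both coefficients within 3 propagated SEs) was
verified at 99–100/100 across disjoint seed blocks.

## Known limitations

- The calibration is scanner- and protocol-specific by design; no attempt
  is made to transfer a fitted line across scanners.
- Only additive Gaussian stored-value noise is modeled synthetically (see
  above); artifact-laden scans must be handled upstream.
- Single-frame CT DICOM only; enhanced multi-frame objects and compressed
  transfer syntaxes beyond pydicom's native support are out of scope.
- The material model is isotropic; site-specific or orthotropic laws are
  not provided.
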