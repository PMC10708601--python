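# Methods

## The measurement model

A brightfield microscope with a motorized tilting slide stage acquires one
image of a thin stained tissue section per tilt angle, with the lamp and
camera fixed — the optical analogue of a step-and-shoot parallel-beam CT
scanner in which the sample, not the gantry, rotates. The rotation axis is
parallel to the image *columns*; tilting therefore displaces absorbing
structures along the image *rows*. After translational alignment, the pixel
values of each image column are treated as a 1D parallel projection
p(θ, s) of the tissue cross-section at that column position. The angular
range is severely limited (±10°, far less than the 180° of classical CT),
so the reconstruction problem is limited-angle laminography: structure
varying slowly along the optical (depth) axis lies inside the missing wedge
and cannot be recovered; in-plane structure can.

Grayscale values are used directly as projection values. No Beer–Lambert
exponentiation is applied by default, matching how the acquisition treats
its images; `tiltomo.sinogram.negative_log` provides the optional
absorbance transform `p = −ln(I/I_max)` for experiments.

Which physical axis the rotation axis corresponds to is stated ambiguously
in the original protocol (its prose and its axis figure disagree). The
implementation fixes the only self-consistent assignment — rotation axis
along columns, detector along rows — and exposes the naming ambiguity as a
`plane_convention` switch (`fig6` / `prose`) at the reslicing stage, so
either reading is reproducible.

## Simulator (`tiltomo.phantoms`)

Phantoms are sums of ellipsoids on a voxel grid `(n_axis, n_depth, n_s)`,
standing in for an H&E-stained section ~10 μm thick. The forward model
projects every rotation-axis slab by **rotate-then-sum**: resample the slab
rotated by −θ about its center (bilinear) and sum along depth. Per-angle
corruption is an integer translation drawn uniformly from
[−max_misalignment, +max_misalignment]² (zero at the 0° reference,
mimicking a rotation axis that misses the slide center) plus additive
zero-mean Gaussian noise. Everything is driven by one seed;
identical seeds give bit-identical series.

Defaults for the "realistic" stated world (CLI and acceptance script):
41 views at −10°…+10° step 0.5°, misalignment up to 5 px, noise σ = 2% of
the peak projection value — a typical SNR for an 8-bit camera frame.

What the simulator does *not* model: the condenser/objective PSF, coma,
depth-of-focus blur (an optional Gaussian depth weighting exists for
robustness experiments but is off by default), stain chemistry, perspective
effects, or in-plane rotation of the stage. A green test therefore
establishes correctness of the geometry, registration and inversion
chain — not robustness to optical aberrations.

Numerical caveat: bilinear resampling on a rotated lattice is not a
partition of unity, so a single-pixel impulse loses up to ~5% mass at 10°;
band-limited (realistic) structure conserves mass to < 0.1%. Phantom
structures must stay far enough from the field border that the maximum tilt
excursion never clips them; `default_phantom_spec` guarantees this.

## Registration (`tiltomo.registration`)

Phase correlation against the 0° reference: FFT both images, normalize the
cross-power spectrum `conj(F(ref))·F(mov)` to unit magnitude (ε = 1e−12
guard), inverse-transform, take the peak (first occurrence in row-major
order on ties), wrap indices past n/2 to negative offsets. The unit-
magnitude normalization is what distinguishes phase correlation from plain
cross-correlation and is required for a sharp delta peak. A 3-point
parabolic per-axis refinement (clipped to ±0.5 px) gives subpixel output
and is on by default; integer mode is exact for circular shifts and is used
by tests that demand exactness. A Hann-window option exists for scenes with
strong wraparound edges; tissue images fill the frame, so it is off by
default.

Alignment translates each image by the negated measured shift (bilinear for
subpixel components, zero fill), and `crop_common` shrinks all images by
ceil(max |d_row|) and ceil(max |d_col|) so no zero-filled pixel survives.
The translation-only model is appropriate because the tissue is thin:
tilt-induced parallax of a structure at depth offset y is y·sinθ ≤ a
fraction of a pixel for a ~10 μm section. Thick, depth-extended phantoms
violate this and registration will fail on them — by design.

## Reconstruction (`tiltomo.reconstruct`)

The slice grid is n×n (n = n_detector), rotating about the geometric center
(n−1)/2. A pixel at depth offset y and detector offset x maps to detector
coordinate `s = c0 + x·cosθ − y·sinθ`. `project` scatters each pixel into
its two neighbouring detector bins with bilinear weights; `backproject`
gathers with the same weights, making the pair an exact adjoint (verified
to 1e−6 relative, and the basis of the iterative scheme's stability). At
θ = 0, `project` is exactly the column sum, matching the simulator.

**FBP** zero-pads each projection to the next power of two ≥ 2× its length,
multiplies the spectrum by 2|f| (ramp) or 2|f|·sinc(f/2f_Nyq)
(Shepp–Logan), truncates back, backprojects and sums scaled by the angular
step in radians (π/n_angles for a single view). Padding suppresses circular
convolution wraparound; its side effect is that a constant projection is
not annihilated exactly — the filter's DC gain is zero, but truncation
reintroduces a small edge-driven mean.

**ART** is the simultaneous (SIRT-style) scheme: all views are synthesized
from the current estimate, the residual is backprojected once per
iteration, and the image updated. The update is doubly normalized,

    x ← x + λ · C ⊙ Aᵀ(R ⊙ (b − Ax)),

with R the reciprocal ray length (forward projection of an all-ones image)
and C the reciprocal pixel weight (backprojection of an all-ones sinogram),
both ε-guarded. With only the pixel-side normalization the effective step
is ~λ·n_detector and the iteration oscillates even at λ = 0.1; the double
normalization is the standard SIRT preconditioning and keeps the scheme
contractive for λ ∈ (0, 2). `ReconConfig` rejects λ outside (0, 2), and a
runtime guard raises `InstabilityError` if the residual norm grows past 10×
its initial value. Defaults: 10 iterations (the published setting), λ = 0.1
(unreported there; a deliberately conservative choice), zero
initialization, nonnegativity clamp on (absorbance cannot be negative; the
clamp also breaks linearity, so linearity tests switch it off).

Absolute reconstructed intensity is arbitrary — no physical calibration is
claimed anywhere — so all exports are min–max normalized per volume, and
quantitative comparisons in the tests fit an affine intensity map first.

## Volume and reslicing (`tiltomo.volume`)

Reconstructed (depth × detector) slices are stacked along the rotation axis
into `voxels[x, y, z]` with x = columns/rotation axis, y = depth, z =
rows/detector. Axial sections fix z, coronal fix y, sagittal fix x; each
family enumerates every voxel exactly once, and assemble/reslice round-
trips bit-exactly. Voxel spacing is assumed isotropic and recorded as
metadata only; the depth-axis scale of reconstructed slices is
uncalibrated.

## Known limitations and one honest red test

* The missing wedge is left unfilled — no extrapolation, inpainting or
  regularized (compressed-sensing) variants. Reconstructions show the
  classical limited-angle elongation along depth.
* Angle-step degradation: RMSE against ground truth grows monotonically
  with coarser angular steps (0.5° → 1° → 2° → 4° at ±10°) for FBP on a
  detector-realistic fixture. For ART at the default 10 iterations the
  reconstruction is insensitive to subsampling above the angular Nyquist
  rate: RMSE is flat to *very slightly decreasing* (≲ 0.3% relative) from
  0.5° to 2° and rises only at 4°, across every fixture, noise level and
  relaxation value we tried, including runs through the full registration
  pipeline. The corresponding ART monotonicity test is left failing rather
  than loosened: at desk scale the claim "artifacts grow with every step
  increase" holds strictly for FBP but only from 2° to 4° for this ART
  variant.
* Dual-projector cross-checks (ray-driven vs rotate-then-sum) are run on
  fields supported away from the slice border, because the rotate-then-sum
  oracle clips corner mass when resampling; interior agreement is ≤ 0.3%
  relative L2 for |θ| ≤ 10°.
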