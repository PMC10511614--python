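# Methods

`aaastrain` implements a wall-motion analysis chain for time-resolved 3D
("4D") ultrasound of abdominal aortic aneurysms (AAA): repeated manual
segmentations of one acquisition are fused into an averaged motion model,
local in-plane strains are computed over the cardiac cycle, the ultrasound
geometry is registered to a CT-derived wall and calcification point cloud,
and strain distributions of calcified vs. non-calcified wall regions are
compared statistically.  This note records the models, the numerical
choices, and what the synthetic validation does and does not demonstrate.

## Data model

A segmentation is a structured grid of tracked material points: `n` rings
("heights") along the vessel of 36 circumferential points each, with one 3D
position (mm) per point and frame.  Frame 0 is end-diastole and serves as
the reference configuration; it is itself a pre-strained in vivo state, so
all strains are relative to end-diastole, not to an unloaded vessel.
Quadrilateral elements connect circumferentially adjacent points of
neighboring rings, closed around the circumference; element `(i, j)` holds
nodes `(i,j), (i,j+1), (i+1,j+1), (i+1,j)` with `j+1` modulo 36.  The
artificial closed cap that tracking software produces inside the vessel
("pseudo-apex") is trimmed as contiguous runs of rings at the grid ends.

## Averaged motion models

Different segmentations of the same recording have different node counts
and independent masking errors.  Averaging nearest nodes directly would
distort the mesh, so the fusion works in an unwrapped cylindrical plane:

1. **Axis.** A straight reference axis is fitted as the first principal
   direction of the first segmentation's end-diastolic node cloud (sign
   fixed along the global axis of greatest extent, orientation flipped if
   needed so ring index increases along the axis).  The same axis is used
   for every segmentation of the acquisition so the angular coordinate is
   comparable across them.  A curved centerline is deliberately not used;
   for the vessel lengths involved (~40–65 mm) a straight axis keeps the
   unwrap bijective.
2. **Unwrap and interpolation.**  Reference nodes are transformed to
   `(x, phi, R)` about the axis.  The radius is interpolated bilinearly over
   the structured `(x, phi)` grid (periodic in `phi`; elements spanning the
   branch cut are duplicated at `phi ± 2π`), and 3D positions are
   reconstructed from `(x, phi, R)`.  Interpolating `R` as a scalar rather
   than interpolating 3D positions keeps a cylinder a cylinder: query points
   between nodes do not collapse onto mesh chords.  Fold-over (non-monotone
   `x` along a circumferential column) is rejected with the offending ring
   pair named.
3. **Homogeneous grid.**  Targets are laid out uniformly: 36 angles, and
   `n_H = min(n_k)` axial stations spanning the common axial interval of all
   segmentations, inset by half a mean axial element length so every target
   is strictly interior (this guarantees point location succeeds, and never
   up-samples beyond the measured resolution).
4. **Anchoring.**  Each target is located in its host quadrilateral of each
   segmentation by inverse bilinear mapping — damped Newton iteration on the
   forward map (residual tolerance 1e-10, ≤50 iterations, 5×5 multi-start
   fallback), candidate elements proposed by a k-d tree over unwrapped
   element centers.  The local coordinates `(r, s) ∈ [−1, 1]²` use the
   standard bilinear shape functions `N_a = ¼(1 + r r_a)(1 + s s_a)` with
   corners ordered like the element nodes.
5. **Tracking and averaging.**  Each anchored point rides on its host
   element through the cycle, `H^t = Σ_a N_a(r_H, s_H) x_a^t`, and the
   averaged model is the unweighted arithmetic mean of the K tracked
   trajectories per target and frame (no outlier rejection).  The anchored
   reference position is reported from the cylindrical interpolant; tracked
   positions live on the bilinear element surface, which differs from it by
   at most the chord sagitta (~0.05 mm at this resolution) — a constant
   geometric offset that cancels in strain.

Averaging K independent segmentations reduces node-level random error by
~1/√K; the re-meshing floor (chord sagitta, interpolation) is a few
hundredths of a millimetre and does not shrink with K.

## In-plane Biot strain

Strain is evaluated per element at the centroid integration point
`r = s = 0`, in a local orthonormal frame with the 1-axis longitudinal and
the 2-axis circumferential: `e2` is the normalized mean of the two
circumferential edges, `e1` the mean of the two longitudinal edges
Gram-Schmidt-orthogonalized against `e2`, origin at the node mean.  The
frame is rebuilt for every deformed configuration, which removes solid-body
motion.  Nodes of each configuration are projected into their own frame
(out-of-plane warp is discarded — wall thickness is not measurable in these
data, so only the in-plane membrane strain is meaningful), the 2×2
deformation gradient `F` follows from the shape-function derivatives and the
reference Jacobian, and the Biot tensor is

    eps = U − I,   U = sqrt(FᵀF),

computed with the closed form `U = (C + √(det C) I) / √(tr C + 2√(det C))`
(eigendecomposition fallback when the denominator is near zero).  `eps` is
reported in the reference local frame (right-stretch convention).  Because
`U` depends on `F` only through `FᵀF`, the result is objective: rigid
motions of either configuration leave it unchanged to machine precision.
Elements with edge aspect ratio > 100 or area < 1e-6 mm² are flagged and
excluded from the distribution indices (their count is reported).

Per-element **peak-to-peak amplitudes** reduce the cycle to one number per
component: max over frames minus min over frames, each component reduced
independently (the extremes may occur at different instants).  This choice
makes the downstream comparison independent of which cardiac phase the CT
was acquired in.

## Registration to CT

The moving ultrasound cloud is aligned to the static CT wall cloud by ICP:
nearest-neighbor pairing (k-d tree, ties to the lowest index) alternating
with bounded nonlinear least squares on the transform parameters
(`scipy.optimize.least_squares`, trust-region reflective), stopping when the
RMSE changes by < 1e-6 mm or after 100 iterations.  The rigid transform is
`R_x(α) R_y(β) R_z(γ)` plus translation; the affine transform composes
scale, rotation and shear, `τ_A = M_s M_r M_h`, and is refined from the
rigid solution to stabilize the nine extra parameters.  Initialization
superimposes the two centroids; default bounds are ±30° rotation, ±20 mm
translation about the centroid-superposition init, scales in [0.8, 1.2] and
shears within ±0.2 — the rough alignment between the modalities is known,
so the bounds are a trust region against unphysiological optima on nearly
axisymmetric fusiform shapes.  Note the affine parameter tuple is
overparametrized (12 parameters, 9 matrix degrees of freedom): only the
composed matrix is identifiable, and tests compare matrices, not tuples.

Agreement metrics: RMSE over assigned pairs (ultrasound → CT) and the
Hausdorff distance (largest local deviation).  Whether the Hausdorff
distance should be directed is a convention choice; the symmetric value is
reported as the headline number and both directed values are included in
every result.  Because the CT acquisition phase within the cardiac cycle is
unknown, every ultrasound frame is registered independently and the frame
with the smallest RMSE is selected.  Rigid registration is used for
geometry comparison (best/worst segmentation are defined by rigid RMSE);
affine registration is used to map calcifications onto the wall mesh.

## Calcified-region classification and statistics

Each element is sampled on a 10×10 `(r, s)` lattice (cell centers) through
the shape functions; the coverage fraction is the share of sample points
within a capture radius of any calcification point, and an element is
calcified when coverage ≥ 0.5 — the half-area threshold applied
deterministically instead of by eye.  Connected calcified patches smaller
than `min_patch_elements` are cleared (calcifications too small to cover an
element are neglected).  The low-level default capture radius is half the
calcification cloud's median nearest-neighbor spacing; the pipeline widens
it by twice the affine registration RMSE, because the classification must
tolerate the residual wall-to-wall registration error, which is an order of
magnitude larger than the cloud spacing.

Distribution indices per region and component, computed from the amplitude
distribution in percent: mean, maximum, local strain ratio (max/mean) and
heterogeneity index (coefficient of variation, sample sd with n−1 over the
mean — the sd convention is configurable but sample sd is the default), plus
median and quartiles for reporting.  Regions with zero mean report ratio
and heterogeneity as undefined rather than infinite; heterogeneity needs
n ≥ 2.

The group comparison is a left-tailed Mann-Whitney U test of the null of
equal medians against the alternative that calcified-area strains are
smaller: exact enumeration when n₁ + n₂ ≤ 20 without ties, otherwise the
normal approximation with tie and continuity correction
(`scipy.stats.mannwhitneyu`).  Significance is starred at the 5%, 1% and
0.1% levels.  A Kolmogorov-Smirnov check against a normal fitted to each
sample is logged to motivate the nonparametric choice; it uses the plain KS
statistic with estimated parameters (no Lilliefors correction), matching
common statistics-package behavior, and is informational only.

## Synthetic phantom

The phantom provides exact ground truth for every stage.  Geometry: a tube
of base radius 12 mm with a Gaussian axial bulge (amplitude 8 mm, center
30 mm, width 10 mm) and a circumferential asymmetry factor 0.3 on the bulge
— AAAs bulge asymmetrically, and a perfectly axisymmetric surface would
make rotation about the vessel axis unobservable to registration — over a
60 mm length on a 22 × 36 grid (~45 mm peak diameter, mean element edge
~3 mm, in the range of clinical exports).  Motion: radial pulsation
`R(t) = ρ(x, φ)(1 + A c(x, φ) w(t))` with a raised-cosine waveform over 20
frames and peak circumferential strain A = 1.2%; two rectangular calcified
patches (together ~117 of 756 elements) carry compliance κ = 0.75, so their
true amplitude is exactly κA.  True per-element amplitudes are computed from
edge chord-length ratios between the waveform extremes — plain arithmetic,
independent of the shape-function strain path.  Optional uniform axial
stretch is available but off by default, keeping the analytic truth exact.

Segmentation noise (sd parameter σ = 0.3 mm) has four components per
segmentation, all independent between segmentations: (1) i.i.d. per-node
masking offsets of sd σ, constant over the cycle — manual masking error is
a geometry error and moves the whole trajectory, so it barely affects
strain; (2) a smooth radial bias field of amplitude σ/2 (observer-dependent
masking); (3) temporally smooth (two Fourier modes) spatially independent
tracking jitter of sd σ/12; and (4) a temporally and spatially smooth
regional tracking error of sd σ/4, representing the template-scale
correlation of speckle-tracking errors, which shows up as slowly varying
apparent-strain waves of the same order as the strains being measured.
Tracking components scale with the local radius so their apparent strain is
homogeneous over the surface (otherwise narrow sections would show
systematically larger spurious strains, a geometric confound for the
regional comparison).  The σ/12 and σ/4 factors were calibrated once against
the modality's reported repeatability — single-segmentation circumferential
strain IQR above 1%, averaged-model mean amplitudes in the physiologic
0.5–3% band, and regional comparisons that succeed on roughly a third to a
half of single segmentations but consistently on the averaged model — and
are fixed defaults.

CT-like clouds are drawn uniformly per unit area on the phantom surface at
a quarter-cycle frame (the CT phase is treated as unknown), calcification
points only on calcified elements, both mapped by a configurable
rigid/affine transform and jittered.

What the phantom does **not** emulate: imaging physics (speckle, shadowing,
angular dependence), anisotropic spatial resolution, wall thickness, ILT,
curved centerlines, or non-stationary noise across the field of view.
Passing tests therefore demonstrate the correctness and noise behavior of
the computational chain under a plausible error model — not the clinical
accuracy of the modality.

## Problem sizes and determinism

Default validation sizes are chosen so the whole suite runs on a laptop
CPU: ~500–3000-point clouds for registration studies, 20–100 seeded
replicates for Monte-Carlo checks, and the 22 × 36 × 20 default phantom.
All randomness flows through explicit integer seeds (`numpy.random.
default_rng`); reruns with the same configuration and seed are bit-identical.

## Known limitations

* The averaged model inherits a small inward chord-sagitta bias from
  bilinear tracking; it is constant in time and invisible to strain.
* Strain at patch boundaries mixes calcified and normal nodes, so boundary
  elements show intermediate amplitudes; classification blur near patch
  edges is of the same order as the capture radius.
* Amplitudes are biased upward by noise (a max-minus-min statistic), so
  observed calcified/non-calcified differences are compressed relative to
  the true compliance contrast.
* The affine registration can absorb a small part of genuine pulsation
  (global scale); it is used only for calcification mapping, as intended.
* No multiple-testing correction is applied across components or datasets.
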