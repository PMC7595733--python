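# Methods

This note documents the models, estimators and numerical choices behind
`cardioem`, and what the synthetic phantoms do and do not establish about
real data.

## Coordinate convention and geometry

Volumes are arrays indexed `[i, j, k]` (image row, column, slice). Index
maps to physical position as x = j·s<sub>x</sub>, y = i·s<sub>y</sub>,
z = k·s<sub>z</sub>, with x the in-plane circumferential (wall-parallel)
direction, y the in-plane radial direction, and z the sectioning
(longitudinal) direction. The default spacing is (10, 10, 40) nm — the
SBF-SEM acquisition grid of 10 nm lateral pixels and 40 nm sections — so
voxels are 4× anisotropic in z. All distance, orientation and volume
computations convert to physical coordinates first; nothing downstream
assumes isotropy. Angles are reported in degrees on the folded axial range
[0°, 180°): myofibrils are unoriented axes, so 175° and −5° denote the same
direction and 180° folds to 0°.

## EM phantom generator

`generate_em_volume` emulates the statistical structure the analysis
assumes, not SEM physics. A phantom is assembled in a fixed order:

1. **Nuclei**: ellipsoids (default semiaxes 800 × 500 × 500 nm at desk
   scale) with a random in-plane rotation.
2. **Myofibrils**: cylinders whose axis is built from a transmural angle
   θ ~ N(θ̄, σ<sub>θ</sub>) and an elliptical angle Φ ~ N(Φ̄, σ<sub>Φ</sub>),
   both folded modulo 180°. The direction vector is
   (1, tan θ, tan Φ)/‖·‖, which by construction has x–y projection angle θ
   and x–z projection angle Φ.
3. **Mitochondria**: ellipsoidal blobs with semiaxes jittered ±30% around
   (220, 160, 160) nm.
4. **Extracellular phase**: carved from the remaining cytoplasm by
   thresholding a smoothed Gaussian random field (lateral smoothing scale
   12 voxels, scaled on z to be isotropic in physical units) at the exact
   count matching the requested fraction of the total grid. The realized
   fraction therefore equals the target up to one voxel.

Objects are placed by bounded rejection sampling (default 100 retries per
object, then an explicit `PackingError` naming the class). Later objects
never overwrite earlier ones, and accepted objects additionally block a
one-voxel dilated neighbourhood, so every fibril is guaranteed to be its own
26-connected component — which makes connected-component splitting an exact
inverse of generation and lets every orientation estimate be checked against
a per-fibril ground truth. Object centers are sampled so the object's
bounding box lies inside the grid; phantoms contain no boundary-clipped
fibrils, whose truncation would bias orientation estimates.

Intensity is a per-class constant mean (extracellular 210, nucleus 60,
mitochondrion 95, myofibril 135, other cytoplasm 170 on a 0–255 scale) plus
i.i.d. Gaussian noise (default SD 8), an optional per-slice brightness
offset to exercise intensity matching, and optional integer per-slice
translation jitter (circular shifts, slice 0 fixed) to exercise alignment;
the true shifts are returned. Jitter displaces only the grayscale stack —
ground-truth labels stay in the aligned frame so recovery can be scored.

Defaults: a 400 × 600 × 100 voxel grid (≈ 4 × 6 × 4 µm³), mimicking a
sub-ROI footprint at reduced depth to stay at desk-scale memory. Fibril
radius 60 nm and length 1500 nm are free parameters chosen so that rods have
aspect ratio ≥ 5 (enough for stable axis estimation) and 200 fibrils occupy
under 15% of the grid, where rejection packing converges quickly; real
embryonic myofibril diameter/length distributions are not encoded. The
default angle parameters (θ 45° ± 32°, Φ 70° ± 36°) match the control-heart
summaries this pipeline is designed to compute.

**What passing phantom tests shows — and does not.** The phantoms validate
the measurement chain: exact label bookkeeping, anisotropy-corrected
orientation recovery, fraction arithmetic, ratio morphometry, shift and
transform recovery. They do not validate robustness to real EM nuisances:
stain gradients, charging, membrane texture, touching/branching fibrils, or
segmentation errors from external tools. Accuracy numbers obtained on
phantoms are therefore upper bounds for real data.

## Heart phantom

`generate_heart_phantom` rasterizes two ellipsoidal lumens (LV, RV) with an
ellipsoidal tissue shell of configurable wall thickness around each; shells
may merge into a septum, lumens may not overlap (checked after
rasterization, error on violation). Voxel-center rasterization of an
ellipsoid with ≥ 20 voxels across is within 3% of the analytic volume
(4/3)·π·abc, so phantoms built via `rv_semiaxes_for_ratio` (all semiaxes
scaled by ratio^⅓) carry a known analytic RV/LV ratio. Default grid
160³ at 20 µm spacing, i.e. a ~3.2 mm field of view.

## Preprocessing

* **Alignment** is translation-only: each slice is registered to its
  predecessor by the cross-correlation peak (Fourier upsampling ×10 for
  subvoxel resolution), and pairwise shifts are cumulatively chained to the
  frame of slice 0. Rotation/scale between consecutive block-face sections
  is assumed negligible — the dominant artifact is stage drift. Cumulative
  shifts are *not* detrended by default: a linear drift correction would
  also remove genuinely oblique structures that cross sections at an angle.
  Constant slices, where correlation is undefined, get a zero shift and a
  NaN score flag. Integer shifts are applied as exact circular shifts;
  subvoxel shifts use bilinear interpolation.
* **Denoising** is non-local means strictly per 2D slice (no cross-slice
  mixing); the filter strength is expressed relative to the slice's value
  range, with 0 an exact identity. The slice noise SD fed to the filter is
  estimated from half the variance of horizontal first differences.
* **Intensity matching** is the affine grayscale map a·I + b with
  a = σ<sub>ref</sub>/σ<sub>in</sub>, b = μ<sub>ref</sub> − a·μ<sub>in</sub>
  — invertible and loggable, unlike histogram equalization. Label volumes
  are rejected; a zero-variance input with a varying reference is an error.

## Segmentation and evaluation

The extracellular phase is segmented by thresholding: a fixed threshold, an
automatic bimodal-valley (Otsu) threshold — refused, with advice, when the
smoothed 64-bin histogram does not show two peaks — or a quantile rule that
selects a given fraction of brightest (or darkest) voxels. Cleanup applies
closing → hole filling → small-object removal (26-connectivity), in that
fixed order; the composite is idempotent. Trained segmenters are out of
scope by design: externally produced label volumes are ingested through a
validating reader that rejects undeclared label values.

`evaluate_segmentation` reports per-class accuracy as truth-class recall
(correct voxels of a class / voxels of that class), in percent, alongside
overall pixel accuracy and the full confusion table; a class absent from the
truth is reported as undefined, not 0%. Recall-style accuracy is one
reasonable reading of per-class "accuracy" figures quoted for segmentation
models; since such phrasing is ambiguous (pixelwise vs object-wise vs Dice),
both per-class recall and overall accuracy are always emitted and labelled.

## Fractions and slice sampling

Counts are exact integer tallies; ignore-labelled voxels are excluded from
S<sub>T</sub>. When a region is entirely extracellular
(S<sub>T</sub> = S<sub>E</sub>) the organelle fractions are reported as
undefined (null), never as 0. The slice-sampling rule takes every
`stride`-th index starting at 0 and always appends the final slice: on an
800-slice stack at stride 50 this yields 17 indices and on a 1000-slice
stack 21 — matching the counts quoted for evenly spaced sampling of such
stacks, which a bare "every 50th" rule (16 and 20) does not. Aggregation
uses the sample SD (n − 1); single-report aggregates get SD 0 with n = 1
recorded. Per-slice aggregation is the default; rectangular crops may be
supplied for per-region aggregation, and each report records its crop for
provenance.

## Orientation

The per-object axis estimator is 3D: the leading eigenvector of the
second-moment matrix of voxel physical coordinates, sign-normalized to
x ≥ 0 (ties broken toward y ≥ 0, then z ≥ 0) so every folded angle is
unique. Objects whose top two eigenvalues agree within 1e-9 relative are
flagged orientation-indeterminate and excluded from angle statistics, as are
θ for axes parallel to z and Φ for axes parallel to y (vanishing
projections). The 3D estimator uses all voxels of an object; a literal
re-slicing route (`resample_to_xz`: nearest-neighbour upsampling of z to the
lateral spacing, then axis permutation so slices lie in the x–z plane) is
retained as an independent check of Φ — for rods with aspect ≥ 5 the two
routes agree within 5° for ≥ 90% of objects, the disagreements concentrating
near vanishing x–z projections.

Histograms use 18 bins of 10° over [0°, 180°). Two summary modes are
computed: **linear** (arithmetic mean and sample SD of the folded values,
the default, matching how 0–180° histogram summaries are usually quoted)
and **circular-axial** (angles doubled, averaged as unit vectors, halved
back; SD is the circular SD of the doubled sample, halved — for a wrapped
normal this recovers the generating σ exactly). Linear statistics on folded
data are distorted when the sample straddles the 0°/180° wrap (e.g. {5°,
175°} has linear mean 90° but axial mean 0°); summaries carry a
`wrap_warning` flag whenever the axial mean is within 20° of the wrap while
the linear mean is not. Default minimum object size is 100 voxels
(suppresses speckle whose axis is noise); default connectivity 26, because
oblique fibrils fragment under 6-connectivity across 40 nm sections.

## Correlative registration

Frame-to-frame maps are similarity transforms q = s·R·p + t estimated in
closed form (SVD of the centered cross-covariance, reflection excluded by
sign correction), appropriate because physical sections rotate, translate
and shrink approximately isotropically. Residual RMS is reported per
coordinate. Degenerate configurations (coincident points, collinear 3D
points, fewer pairs than dimensions) raise errors naming the degeneracy.
Maps carry explicit source/target frame ids; composition and point mapping
check frame compatibility, and chains compose associatively to 1e-9.
Landmark files declare frame and unit columns explicitly — no unit
inference.

## Problem sizes and tolerances

The test suite and the acceptance script run at desk scale: 200-fibril
phantoms on the default grid for angle recovery, twenty 96 × 96 × 40
phantoms for fraction recovery, 100 random cylinders for the orientation
oracle, 160³ heart phantoms. Key tolerances: orientation oracle < 2°
against the exact generating axis; angle-summary recovery within 3° (mean)
and 4° (SD) of the generator's realized sample statistics; fraction MAE
< 0.02 over 20 regions; ventricular ratios within 3% of analytic; integer
alignment shifts exact; similarity parameters to 1e-6 noiselessly.

## Known limitations

* No elastic/nonrigid section registration, destriping, or charging
  artifact simulation.
* Branching or touching myofibrils are treated as single connected
  components; no instance splitting beyond connectivity.
* The bimodal-valley detector is heuristic (peak counting on a smoothed
  histogram); borderline histograms should use a fixed threshold.
* Angle summaries assume the folded-axial convention throughout; data
  recorded on (−90°, 90°] must be folded before ingestion.
* `resample_to_xz` uses nearest-neighbour interpolation only (exact label
  preservation, at the cost of staircase artifacts on oblique boundaries).
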