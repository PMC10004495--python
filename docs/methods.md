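# Methods

This note documents the models and numerical procedures implemented in
`musclereg`, the parameters that matter, and the boundaries of what the
synthetic tests demonstrate.

## Problem setting

The package targets T1-weighted MR stacks of the lower limb, in which fat is
bright, muscle intermediate, and cortical bone dark. Segmenting the
individual muscles by hand is slow and operator-dependent; the approach here
transfers the labels of an already-segmented *reference* subject onto a new
*target* subject through deformable image registration, optionally combining
several references (multi-atlas). All volumes are represented on 3D grids
with axis 2 longitudinal (inferior→superior), 0-based indices, and the
voxel-centre convention `world = origin + index · spacing`.

## Sequence stacking and resampling

Limb acquisitions arrive as several longitudinal sequences with different
in-plane resolution. Each sequence is first resampled to a common isotropic
spacing by tri-linear interpolation (exact on affine intensity fields, which
the tests verify to 1e-6). Fields of view are equated by zero-padding,
using the stored world origins to preserve relative position. Where
consecutive sequences overlap along the limb, half of the overlapping slices
are dropped from each — the distal (later) sequence loses the extra slice
when the overlap is odd — and the sequences are concatenated without
blending; slices near sequence ends are the most bias-affected, so dropping
rather than averaging is deliberate. A gap larger than half a voxel between
consecutive sequences is an error.

## Fat homogenisation

Differences in subcutaneous fat thickness between subjects dominate the
image mismatch and pull the registration away from the muscle tissue. Each
longitudinal slice is therefore rebuilt so every subject presents the same
fat geometry:

1. **Body detection.** A Canny detector (σ = 2 voxels; hysteresis thresholds
   at the 70th/90th intensity percentiles of the slice) marks the air–skin
   boundary; the enclosed region is filled. Because the Canny ridge
   straddles the true edge by up to a voxel (and gap-closing morphology
   dilates it further), the mask is refined with a half-maximum cut — the
   intensity midway between the interior and exterior medians — and
   re-filled. On synthetic disks this reproduces the generating shape
   exactly. All-air slices yield an empty mask with a flag rather than an
   error.
2. **Tissue thresholds.** The histogram of body voxels (256 bins, moving
   average of width 5) is scanned for its two dominant modes at least 20
   bins apart — muscle (lower) and fat (upper). The muscle/fat threshold is
   the histogram minimum between them; the fat peak mean/sd are computed
   from voxels above the threshold. Thresholds are estimated once per
   volume for coherence along the limb. A histogram without two such modes
   raises an error directing the user to the manual `muscle_upper` override.
3. **Fat wrapping.** The muscle mask is all body tissue at or below the
   threshold (dark bone included — excluding it would carve holes the
   registration would have to explain). A shell of depth equal to the
   registration nodal spacing (5 mm, measured by the in-slice Euclidean
   distance transform) is kept around the muscle: within the body the
   subject's own fat intensities are retained; outside it artificial fat is
   drawn i.i.d. from U[μ_fat − σ_fat, μ_fat + σ_fat]. Everything else
   becomes air (0). One seeded generator per volume, consumed in slice
   order, makes the output reproducible; muscle voxels are bit-identical
   before and after, so muscle volume, shape and fat infiltration are
   untouched by construction.

## Registration

Displacement unknowns live on an isotropic hexahedral node grid of pitch
`NS` (default 5 mm) extending one node beyond every face of the fixed image.
The dense field is the tri-linear interpolation of the node values, and the
objective is

    E(u) = Σ_x [F(x) − M(x + u(x))]²  +  λ Σ_(a,b)∈edges ‖u_a − u_b‖²

with the second sum over 6-neighbour node pairs (a graph-Laplacian membrane
penalty — the simplest smoothing operator consistent with penalising
node-to-node displacement differences). The field is a *backward* map
defined on the fixed grid and pulling from the moving image, which makes
resampling well-posed. Samples outside the moving domain take intensity 0
(air), consistent with the zero-padded fields of view.

The solver is damped Gauss–Newton starting from zero displacement: the
moving image is linearised at the current field (gradients sampled at the
warped positions), the sparse normal equations over all node displacements
(plus λ-weighted Laplacian and a tiny Tikhonov term, ~1e-8 of the mean
Hessian diagonal, for rank safety in flat regions) are solved directly, and
the step is halved until the regularised cost strictly decreases (at most 12
halvings). Iteration stops at a relative decrease below `tolerance`
(default 1e-4), at `max_iterations` (default 50), or when no step is
accepted. The iteration log records the cost of every accepted step, so
monotonicity is checkable after the fact.

**Pyramid.** By default the solve runs coarse-to-fine over 3 levels: images
are Gaussian-smoothed and downsampled by powers of two, `NS` is doubled per
level, and each level's node field seeds the next by tri-linear
prolongation. This widens the capture range for displacements comparable to
`NS`; `pyramid_levels=1` disables it.

**Smoothing coefficient.** λ defaults to `0.1·NS²` (units: intensity² per
mm² of node-difference), a value settled on phantom recovery experiments; an
optional geometric sweep re-runs the registration over
{0.01, 0.1, 1, 10}·λ and keeps the field with the lowest final SSD.

**Label warping.** Propagating a label map uses one one-hot channel per
label (background included), each warped with the same tri-linear kernel,
followed by an arg-max; ties resolve to the lower label id and fully
out-of-domain voxels to background. Warping can shrink but never invent
labels.

## Multi-atlas fusion

N candidate segmentations of one target (each from a different reference)
are combined in two steps. The probability map records, per voxel and per
label, the fraction of candidates voting for it. Voxels with full agreement
(fraction 1, background included) are settled. Every disputed voxel is
assigned by local image similarity: the sum of squared differences between
each candidate's registered image and the target inside a cubic window
(default 25³ voxels, truncated at image borders so no intensities are
invented) is computed with exact separable sliding sums, and the voxel takes
the label of the candidate with the smallest windowed SSD there, ties going
to the lowest candidate index. An optional agreement threshold below 1
settles voxels at majority fractions; the default requires unanimity.

## Evaluation metrics

For automatic segmentation A and manual segmentation M:

- `RVE_i = 100·(V_A,i − V_M,i)/V_M,i` (signed, per muscle); `TVE` applies
  the same formula to the summed muscle volumes (signed; the absolute value
  is also exposed).
- `DSC = 2|A∩M|/(|A|+|M|)` in [0, 1]; both-empty is defined as 1
  (identical), exactly-one-empty as 0.
- Hausdorff distance: the exact symmetric maximum of directed
  minimum distances between voxel centres, in mm, spacing-scaled, computed
  with Euclidean distance transforms (verified against the brute-force
  double loop; no percentile variant).
- Cohort variability of a muscle: `100·(max − min)/mean` of its volumes.
- Registration overlays render the target slice in red and the registered
  slice in green (each min-max normalised); well-registered tissue appears
  yellow.

## Augmentation and quality control

An augmented dataset warps a segmented reference — image and labels with the
*identical* field, no pre-processing — producing a fully labelled volume
distinct from both subjects of the registration. Credibility screening
automates three of the four visual criteria:

- (a) **boundary smoothness**: the per-slice body mask (intensity threshold,
  holes filled, specks below `min_component_voxels` ignored) must be a
  single connected component, and consecutive-slice perimeters must not jump
  by more than `perimeter_jump_factor` (default 1.5);
- (b) **joint plausibility** is inherently visual and reported
  `not-evaluated`;
- (c) **labels reflect structure**: the mean image intensity inside each
  label must fall within the configured muscle band;
- (d) **relative positions**: configured ordered pairs of label centroids
  must satisfy an axis inequality with a margin (default 2 voxels) — the
  minimal formalisation of "muscle X must be lateral to muscle Y".

A dataset passes overall iff no evaluated criterion fails. All thresholds
are configuration with the stated defaults; none comes from a reference
measurement, so pass rates are properties of this screen, not reproductions
of any manually-checked acceptance rate. Cohort volume spread is summarised
as each subject's percent deviation from the per-muscle database mean
(mean-centred by construction), allowing original and augmented databases to
be compared on one scale.

## Synthetic phantoms

The generator emulates the structure of a limb cross-section stack: a
cylindrical body of configurable radius, a bright fat ring of configurable
thickness, a dark central bone, and K angular-sector muscle compartments
with similar-but-distinct mean intensities (default 80 + 8k against fat at
210, noise sd 4). Compartment boundaries are Gaussian-smoothed and
re-assigned by arg-max so that muscle–muscle edges carry the weak gradients
that make real muscle registration hard; honest tests depend on this.
Cohorts draw per-subject body radius, fat thickness and sector widths from
configured ranges, with each subject's noise seed derived from its drawn
anatomy so zero-width ranges reproduce identical phantoms. Random test
deformations are node fields drawn i.i.d. normal, smoothed by one
neighbour-averaging pass and rescaled so the dense maximum magnitude equals
the requested value exactly.

What the phantoms do **not** model: anatomically shaped muscles, MR bias
fields, partial-volume effects, intensity non-uniformity along the limb,
joints, or inter-subject differences beyond radius/fat/sector geometry.
Passing phantom tests therefore demonstrates the correctness and stability
of the algorithms — exact metric computation, recovery of known smooth
deformations (median endpoint error below one voxel for fields up to ~0.6·NS
on 64³ grids), invariant preservation — not clinical segmentation accuracy
on patient data, which depends on contrast, anatomy and reference choice.

## Numerical choices and degenerate inputs

- Tri-linear interpolation throughout (images, labels via one-hot,
  displacement densification); out-of-domain image samples are 0, labels
  background.
- Overlap/gap tolerance in stacking: half a voxel; odd overlaps drop the
  extra slice from the distal sequence.
- Local-SSD windows truncate at borders; window size must be odd.
- Tie-breaks are deterministic and documented: lowest label id in label
  warping, lowest candidate index in fusion.
- Empty voxel sets: DSC handles them by convention; the Hausdorff distance
  refuses them with a dedicated error.
- Problem sizes in the shipped tests and the acceptance script (48–64 voxel
  grids, cohorts of 4–10 phantoms) were chosen as the smallest sizes at
  which every mechanism — pyramid levels, fat-shell scenarios on both sides
  of 5 mm, disputed-voxel arbitration — is genuinely exercised.

## Known limitations

- The smoothing operator is a first-difference membrane penalty; a
  plate/curvature penalty would penalise shear differently.
- The registration is not guaranteed diffeomorphic; strong fields can fold.
  The QC boundary criterion catches gross folding in augmented data, but
  nothing prevents it during segmentation.
- λ is fixed per run (or swept geometrically); no per-region adaptation.
- Histogram threshold detection assumes a bimodal muscle/fat histogram;
  heavily infiltrated muscle may need the manual override.
- The Hausdorff distance is computed between voxel centres, not meshed
  surfaces; values are quantised to the voxel lattice.
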