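# musclereg

Atlas-based segmentation of lower-limb muscles from volumetric MR-like
images, built around deformable node-grid image registration.

Manual segmentation of the ~35 muscles of a human lower limb from an MR
stack takes an expert on the order of ten hours per subject and suffers from
operator variability. `musclereg` implements an automatic alternative:
given one (or several) already-segmented *reference* subjects, it registers
each reference image to a new *target* subject and propagates the reference
labels through the recovered deformation, producing a full muscle
segmentation with no manual input. The same machinery warps a segmented
reference into new, anatomically plausible *augmented* datasets — synthetic
fully-labelled volumes useful as training data for learning-based
segmentation.

## What is inside

- **`volumes_io`** — NIfTI volume/label I/O, tri-linear resampling to
  isotropic resolution, and stacking of overlapping longitudinal imaging
  sequences into one continuous volume (half of each overlap removed from
  each sequence).
- **`preprocess_fat`** — fat homogenisation: per-slice body detection
  (Canny skin boundary + hole filling), muscle/fat threshold estimation from
  the bimodal body histogram, and wrapping of a fixed-depth fat shell
  (subject fat where available, synthetic fat from
  U[μ_fat − σ_fat, μ_fat + σ_fat] where not). Muscle voxels are
  bit-preserved.
- **`registration`** — deformable registration with displacement unknowns on
  an isotropic hexahedral node grid of pitch NS (default 5 mm), minimising

      E(u) = Σ_x [F(x) − M(x + u(x))]² + λ Σ_(a,b) ‖u_a − u_b‖²

  by damped Gauss–Newton with a graph-Laplacian membrane penalty over
  6-neighbour node pairs and an optional coarse-to-fine pyramid. The dense
  field is the tri-linear interpolation of the node displacements; images
  warp by backward tri-linear sampling and label maps through one-hot
  channels with an arg-max decision.
- **`multiatlas`** — fusion of N candidate segmentations: voxels where all
  candidates agree keep their label; disputed voxels take the label of the
  candidate whose registered image best matches the target by sum of squared
  differences inside a 25³ window.
- **`seg_metrics`** — per-muscle relative volume error
  RVE = 100·(V_A − V_M)/V_M, whole-body total volume error TVE, Dice
  similarity coefficient DSC = 2|A∩M|/(|A|+|M|), exact symmetric Hausdorff
  distance in mm, cohort volume variability (range/mean), and red/green
  registration overlays.
- **`augmentation`** — registration-based augmented dataset generation
  (image and labels warped by the same field) with an automated four-point
  anatomical-credibility screen.
- **`phantom`** — seeded synthetic limb phantoms (muscle sectors, bone, fat
  ring, noise) plus smooth random deformation fields, so the whole pipeline
  is testable offline.
- **`cli`/`pipeline`** — a `musclereg` command with subcommands
  (`phantom`, `preprocess`, `register`, `segment`, `fuse`, `metrics`,
  `augment`, `run-multi`) and end-to-end orchestration with run manifests.

## Worked example

Segment one synthetic subject from another and evaluate against the known
ground truth:

```python
from musclereg.phantom import PhantomSpec, CohortVariation, make_cohort
from musclereg.pipeline import PipelineConfig, run_single_atlas
from musclereg.preprocess_fat import PreprocessConfig
from musclereg.registration import RegistrationConfig

cohort = make_cohort(
    2,
    PhantomSpec(shape=(48, 48, 24), body_radius_mm=19.0, fat_thickness_mm=4.0, seed=1),
    CohortVariation(body_radius_mm=(18.0, 21.0), fat_thickness_mm=(2.0, 8.0), sector_jitter=0.15),
    seed=1,
)
(target, target_manual), (reference, reference_labels) = cohort

config = PipelineConfig(
    preprocess=PreprocessConfig(seed=1),
    registration=RegistrationConfig(nodal_spacing_mm=5.0),
)
result = run_single_atlas(target, reference, reference_labels, config,
                          target_manual=target_manual)
print(result.report.per_muscle.round(3).to_string(index=False))
print(f"TVE = {result.report.tve_pct:+.2f} %")
```

Output:

```
        muscle  v_auto_cm3  v_manual_cm3  rve_pct   dsc  hd_mm
compartment_01       2.330         1.944   19.856 0.892  2.828
compartment_02       2.039         2.520  -19.087 0.865  3.000
compartment_03       2.036         2.016    0.992 0.914  3.000
compartment_04       2.350         2.160    8.796 0.948  1.000
TVE = +1.33 %
```

Each row is one muscle compartment: the automatically propagated volume, the
ground-truth volume, their signed relative error in percent, the Dice
overlap (1 = identical) and the Hausdorff distance in millimetres. The
whole-body total volume error is far smaller than the per-muscle errors —
volume mistakes at muscle–muscle boundaries largely cancel when summed,
while each individual boundary is the hardest part of the problem (weak
grey-level gradient between muscles of similar intensity).

The same run from the shell:

```bash
musclereg phantom --out-prefix ref_ --seed 3 --shape 48,48,24
musclereg phantom --out-prefix tgt_ --seed 4 --shape 48,48,24
musclereg segment tgt_image.nii.gz ref_image.nii.gz ref_labels.nii.gz --out auto.nii.gz
musclereg metrics auto.nii.gz tgt_labels.nii.gz --out report.csv
```

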