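"""Registration-based data augmentation and automated quality control.

An augmented dataset is produced by warping a segmented reference subject
(image AND labels, with the identical displacement field) towards a target
subject: the result is a fully segmented volume dissimilar to both inputs.
Anatomical credibility is screened with a four-point criterion; here three of
the four points get automated proxies with configurable thresholds:

  (a) the skin boundary must be smooth and continuous — the per-slice body
      mask must be a single connected component and the slice-to-slice
      perimeter series must not jump by more than a configured factor;
  (b) joint plausibility is inherently a visual check and is reported as
      not-evaluated;
  (c) the muscle labels must reflect muscle structure — the mean image
      intensity inside each label must fall in the configured muscle band;
  (d) relative muscle positions must be realistic — configured ordered pairs
      of label centroids must satisfy their axis inequality with a margin.

A dataset passes overall iff no evaluated criterion fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_fill_holes, label as cc_label
from skimage.measure import perimeter as skim_perimeter

from .registration import NodeDisplacementField, warp_image, warp_labels
from .volumes_io import GreyVolume, LabelVolume

__all__ = [
    "SpatialRelation",
    "QCConfig",
    "CriterionResult",
    "QCReport",
    "generate_augmented",
    "qc_augmented",
    "volume_distribution",
]


def generate_augmented(
    ref_image: GreyVolume, ref_labels: LabelVolume, field: NodeDisplacementField
) -> tuple[GreyVolume, LabelVolume]:
    """Warp a reference image and its labels with the same field.

    No pre-processing is applied; the outputs share the field's target
    geometry, and a zero field reproduces the reference pair bit-exactly.
    """
    if not ref_image.same_grid(ref_labels):
        from .errors import GeometryMismatchError

        raise GeometryMismatchError("reference image and labels must share a grid")
    return warp_image(ref_image, field), warp_labels(ref_labels, field)


@dataclass
class SpatialRelation:
    """Centroid ordering constraint: muscle_a's centroid must be on the
    ``relation`` side of muscle_b's along ``axis``, by >= ``margin_voxels``."""

    muscle_a: int
    muscle_b: int
    axis: int  # 0 or 1 in-plane, 2 longitudinal
    relation: str  # "less" or "greater"
    margin_voxels: float = 2.0


@dataclass
class QCConfig:
    body_threshold: float = 30.0  # intensity above which a voxel counts as body
    min_component_voxels: int = 8  # ignore specks smaller than this per slice
    perimeter_jump_factor: float = 1.5
    muscle_intensity_band: tuple[float, float] | None = None
    relations: list[SpatialRelation] = field(default_factory=list)


@dataclass
class CriterionResult:
    status: str  # "pass" | "fail" | "not-evaluated"
    evidence: dict


@dataclass
class QCReport:
    criteria: dict[str, CriterionResult]

    @property
    def overall(self) -> bool:
        return not any(c.status == "fail" for c in self.criteria.values())


def _slice_body_mask(slice2d: np.ndarray, config: QCConfig) -> np.ndarray:
    mask = slice2d > config.body_threshold
    mask = binary_fill_holes(mask)
    lab, n = cc_label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    keep = np.flatnonzero(sizes >= config.min_component_voxels)
    return np.isin(lab, keep)


def _check_boundary(image: GreyVolume, config: QCConfig) -> CriterionResult:
    n_components = []
    perims = []
    for z in range(image.shape[2]):
        mask = _slice_body_mask(image.data[:, :, z], config)
        if not mask.any():
            continue
        _, n = cc_label(mask)
        n_components.append(n)
        perims.append(float(skim_perimeter(mask)))
    if not perims:
        return CriterionResult("fail", {"reason": "no body found in any slice"})
    max_components = max(n_components)
    jumps = [
        max(p1, p2) / max(min(p1, p2), 1e-9) for p1, p2 in zip(perims[:-1], perims[1:])
    ]
    max_jump = max(jumps) if jumps else 1.0
    ok = max_components == 1 and max_jump <= config.perimeter_jump_factor
    return CriterionResult(
        "pass" if ok else "fail",
        {"max_components_per_slice": max_components, "max_perimeter_jump": max_jump},
    )


def _check_intensity(image: GreyVolume, labels: LabelVolume, config: QCConfig) -> CriterionResult:
    if config.muscle_intensity_band is None:
        return CriterionResult("not-evaluated", {"reason": "no muscle intensity band configured"})
    lo, hi = config.muscle_intensity_band
    means = {}
    bad = []
    for k in labels.present_labels():
        mean = float(image.data[labels.data == k].mean())
        means[k] = mean
        if not lo <= mean <= hi:
            bad.append(k)
    status = "pass" if not bad else "fail"
    return CriterionResult(status, {"per_muscle_mean": means, "outside_band": bad})


def _check_relations(labels: LabelVolume, config: QCConfig) -> CriterionResult:
    if not config.relations:
        return CriterionResult("not-evaluated", {"reason": "no spatial relations configured"})
    violations = []
    checked = []
    for rel in config.relations:
        ma = labels.data == rel.muscle_a
        mb = labels.data == rel.muscle_b
        if not ma.any() or not mb.any():
            violations.append((rel.muscle_a, rel.muscle_b, "missing label"))
            continue
        ca = np.mean(np.nonzero(ma)[rel.axis])
        cb = np.mean(np.nonzero(mb)[rel.axis])
        gap = (ca - cb) if rel.relation == "greater" else (cb - ca)
        checked.append({"pair": (rel.muscle_a, rel.muscle_b), "gap_voxels": float(gap)})
        if gap < rel.margin_voxels:
            violations.append((rel.muscle_a, rel.muscle_b, float(gap)))
    status = "pass" if not violations else "fail"
    return CriterionResult(status, {"checked": checked, "violations": violations})


def qc_augmented(
    image: GreyVolume, labels: LabelVolume, config: QCConfig | None = None
) -> QCReport:
    """Run the automated four-point credibility screen on an augmented pair."""
    from .errors import GeometryMismatchError

    config = config or QCConfig()
    if not image.same_grid(labels):
        raise GeometryMismatchError("image and labels must share a grid")
    criteria = {
        "a_boundary_smoothness": _check_boundary(image, config),
        "b_joint_plausibility": CriterionResult(
            "not-evaluated", {"reason": "joint articulation requires visual review"}
        ),
        "c_labels_reflect_structure": _check_intensity(image, labels, config),
        "d_relative_positions": _check_relations(labels, config),
    }
    return QCReport(criteria=criteria)


def volume_distribution(cohort_volumes: pd.DataFrame) -> pd.DataFrame:
    """Percent deviation of each subject's muscle volume from the cohort mean.

    ``cohort_volumes``: rows = subjects, columns = muscles, values in cm^3.
    For muscle i with mean mu_i, subject j's deviation is
    ``100 * (V_ij - mu_i) / mu_i``; per-muscle deviations are mean-centred.
    """
    df = pd.DataFrame(cohort_volumes)
    means = df.mean(axis=0)
    if (means <= 0).any():
        bad = list(means.index[means <= 0])
        raise ValueError(f"zero or negative mean volume for muscles {bad}")
    return 100.0 * (df - means) / means
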