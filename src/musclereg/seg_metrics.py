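"""Segmentation evaluation metrics.

For an automatic segmentation A and a manual (ground-truth) segmentation M of
the same subject the package reports, per muscle i:

    RVE_i = 100 * (V_A,i - V_M,i) / V_M,i                   (signed %)
    DSC_i = 2 |A_i ∩ M_i| / (|A_i| + |M_i|)                 (in [0, 1])
    HD_i  = max( max_a min_m d(a, m), max_m min_a d(m, a) ) (mm)

plus a whole-body total volume error over the summed muscle volumes,

    TVE = 100 * (Σ V_A,i - Σ V_M,i) / Σ V_M,i               (signed %),

and, across a cohort, the variability of a muscle's volume as the range/mean
ratio.  Distances are Euclidean between voxel centres, scaled by the voxel
spacing; the Hausdorff distance is the exact symmetric maximum (no percentile
variant), computed with distance transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .errors import EmptySegmentationError, GeometryMismatchError
from .volumes_io import GreyVolume, LabelVolume

__all__ = [
    "SegmentationReport",
    "muscle_volume",
    "rve",
    "tve",
    "dsc",
    "hausdorff",
    "cohort_variability",
    "evaluate",
    "render_overlay",
]


def muscle_volume(labels: LabelVolume, muscle_id: int) -> float:
    """Volume of one muscle label in cm^3 (voxel count x voxel volume)."""
    if muscle_id not in labels.label_names and muscle_id not in labels.present_labels():
        raise KeyError(f"unknown muscle id {muscle_id}")
    count = int(np.count_nonzero(labels.data == muscle_id))
    return count * labels.voxel_volume_mm3 / 1000.0


def rve(v_auto: float, v_manual: float) -> float:
    """Signed relative volume error in percent."""
    if v_manual <= 0:
        raise ValueError("manual volume must be positive")
    return 100.0 * (v_auto - v_manual) / v_manual


def tve(v_auto_list, v_manual_list) -> float:
    """Signed total volume error (%) over the summed muscle volumes."""
    va, vm = list(v_auto_list), list(v_manual_list)
    if not va or len(va) != len(vm):
        raise ValueError("volume lists must be non-empty and of equal length")
    total_m = float(np.sum(vm))
    if total_m <= 0:
        raise ValueError("summed manual volume must be positive")
    return 100.0 * (float(np.sum(va)) - total_m) / total_m


def dsc(a: np.ndarray, m: np.ndarray) -> float:
    """Dice similarity coefficient of two boolean voxel sets on one grid.

    Both empty is treated as identical (1.0); exactly one empty gives 0.0.
    """
    a = np.asarray(a, dtype=bool)
    m = np.asarray(m, dtype=bool)
    if a.shape != m.shape:
        raise GeometryMismatchError("voxel sets must share a grid")
    na, nm = int(a.sum()), int(m.sum())
    if na + nm == 0:
        return 1.0
    inter = int(np.count_nonzero(a & m))
    return 2.0 * inter / (na + nm)


def hausdorff(a: np.ndarray, m: np.ndarray, spacing) -> float:
    """Exact symmetric Hausdorff distance (mm) between voxel-centre sets."""
    a = np.asarray(a, dtype=bool)
    m = np.asarray(m, dtype=bool)
    if a.shape != m.shape:
        raise GeometryMismatchError("voxel sets must share a grid")
    if not a.any() or not m.any():
        raise EmptySegmentationError("Hausdorff distance is undefined for an empty set")
    spacing = np.asarray(spacing, dtype=float)
    d_to_m = distance_transform_edt(~m, sampling=spacing)
    d_to_a = distance_transform_edt(~a, sampling=spacing)
    return float(max(d_to_m[a].max(), d_to_a[m].max()))


def cohort_variability(volumes) -> float:
    """Range/mean ratio of a muscle's volumes across a cohort, in percent."""
    v = np.asarray(list(volumes), dtype=float)
    if v.size < 2:
        raise ValueError("need at least two volumes")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("mean volume must be positive")
    return 100.0 * (v.max() - v.min()) / mean


@dataclass
class SegmentationReport:
    """Per-muscle RVE/DSC/HD plus the whole-body TVE for one subject."""

    per_muscle: pd.DataFrame  # columns: muscle_id, muscle, v_auto_cm3, v_manual_cm3, rve_pct, dsc, hd_mm
    tve_pct: float
    notes: list[str] = field(default_factory=list)

    @property
    def abs_tve_pct(self) -> float:
        return abs(self.tve_pct)

    def to_csv(self, path) -> None:
        """CSV with one row per muscle and a TVE footer row."""
        df = self.per_muscle.copy()
        footer = pd.DataFrame(
            [{"muscle": "TVE", "rve_pct": self.tve_pct}], columns=df.columns
        )
        pd.concat([df, footer], ignore_index=True).to_csv(path, index=False)


def evaluate(auto: LabelVolume, manual: LabelVolume) -> SegmentationReport:
    """Full per-muscle evaluation of an automatic against a manual label map.

    Muscles absent from both volumes are skipped with a note; a muscle absent
    from exactly one gets DSC 0 and NaN for the undefined RVE/HD.
    """
    if not auto.same_grid(manual):
        raise GeometryMismatchError("automatic and manual volumes must share a grid")
    vocab = sorted(
        set(auto.label_names) | set(manual.label_names) | set(auto.present_labels()) | set(manual.present_labels())
    )
    vocab = [k for k in vocab if k != 0]
    rows, notes = [], []
    va_list, vm_list = [], []
    for k in vocab:
        mask_a = auto.data == k
        mask_m = manual.data == k
        name = manual.label_names.get(k, auto.label_names.get(k, f"label_{k}"))
        if not mask_a.any() and not mask_m.any():
            notes.append(f"muscle {k} ({name}) absent from both volumes; skipped")
            continue
        v_a = mask_a.sum() * auto.voxel_volume_mm3 / 1000.0
        v_m = mask_m.sum() * manual.voxel_volume_mm3 / 1000.0
        row = {
            "muscle_id": k,
            "muscle": name,
            "v_auto_cm3": v_a,
            "v_manual_cm3": v_m,
            "rve_pct": rve(v_a, v_m) if v_m > 0 else np.nan,
            "dsc": dsc(mask_a, mask_m),
            "hd_mm": hausdorff(mask_a, mask_m, auto.spacing)
            if mask_a.any() and mask_m.any()
            else np.nan,
        }
        if v_m == 0:
            notes.append(f"muscle {k} ({name}) absent from the manual volume; RVE/HD undefined")
        elif not mask_a.any():
            notes.append(f"muscle {k} ({name}) absent from the automatic volume; HD undefined")
        rows.append(row)
        va_list.append(v_a)
        vm_list.append(v_m)
    df = pd.DataFrame(
        rows,
        columns=["muscle_id", "muscle", "v_auto_cm3", "v_manual_cm3", "rve_pct", "dsc", "hd_mm"],
    )
    total = tve(va_list, vm_list) if va_list and float(np.sum(vm_list)) > 0 else np.nan
    return SegmentationReport(per_muscle=df, tve_pct=total, notes=notes)


def _normalise(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros_like(img, dtype=float)
    return (img - lo) / (hi - lo)


def render_overlay(
    registered: GreyVolume, target: GreyVolume, slice_index: int, axis: int = 2
) -> np.ndarray:
    """Red/green registration overlay for one slice.

    Red = min-max normalised target, green = normalised registered, blue = 0;
    well-registered regions therefore appear yellow.  Returns an RGB float
    array in [0, 1].
    """
    if not registered.same_grid(target):
        raise GeometryMismatchError("registered and target must share a grid")
    if not 0 <= slice_index < registered.shape[axis]:
        raise IndexError(f"slice {slice_index} out of range for axis {axis}")
    sl = [slice(None)] * 3
    sl[axis] = slice_index
    red = _normalise(target.data[tuple(sl)])
    green = _normalise(registered.data[tuple(sl)])
    return np.stack([red, green, np.zeros_like(red)], axis=-1)
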