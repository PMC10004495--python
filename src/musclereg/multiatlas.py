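"""Multi-atlas label fusion.

N candidate segmentations of one target (each produced by propagating a
different reference's labels through its own registration) are combined by
agreement: voxels where all candidates assign the same label — background
included — keep it.  Every other (disputed) voxel is arbitrated by local
image similarity: it takes the label of the candidate whose registered image
has the lowest sum of squared differences to the target inside a cubic window
centred on the voxel (default 25^3; the window is truncated at image borders
so no intensities are invented).  Ties go to the lowest candidate index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

from .errors import GeometryMismatchError
from .volumes_io import GreyVolume, LabelVolume

__all__ = ["ProbabilityMap", "build_probability_map", "local_ssd_map", "fuse"]


@dataclass
class ProbabilityMap:
    """Per-muscle voxel agreement fractions across N candidate segmentations.

    ``fractions[k]`` holds, for label k (background 0 included), the fraction
    of candidates labelling each voxel k; values lie in {0, 1/N, ..., 1} and
    sum to 1 over labels at every voxel.
    """

    fractions: dict[int, np.ndarray]
    n_atlases: int

    def disputed(self) -> np.ndarray:
        """Boolean grid of voxels whose candidates do not all agree."""
        stacked = np.stack(list(self.fractions.values()))
        return stacked.max(axis=0) < 1.0 - 1e-12


def _check_geometry(volumes) -> None:
    first = volumes[0]
    for v in volumes[1:]:
        if not first.same_grid(v):
            raise GeometryMismatchError("all volumes must share grid geometry")


def build_probability_map(candidates: list[LabelVolume]) -> ProbabilityMap:
    """Voxel-wise agreement fractions over the candidates' label vocabulary."""
    if not candidates:
        raise ValueError("empty candidate list")
    _check_geometry(candidates)
    stack = np.stack([c.data for c in candidates])
    ids = sorted({0} | {k for c in candidates for k in c.present_labels()})
    n = len(candidates)
    fractions = {k: (stack == k).sum(axis=0) / n for k in ids}
    return ProbabilityMap(fractions=fractions, n_atlases=n)


def local_ssd_map(
    registered: GreyVolume, target: GreyVolume, window_voxels: int = 25
) -> np.ndarray:
    """Windowed SSD between a registered image and the target, per voxel.

    The value at x is the sum of squared intensity differences over the
    ``window_voxels``-cubed neighbourhood of x, truncated at image borders.
    Computed with a separable box filter (exact sliding sums).
    """
    if window_voxels < 1 or window_voxels % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window_voxels}")
    if not registered.same_grid(target):
        raise GeometryMismatchError("registered and target must share grid geometry")
    d2 = (registered.data - target.data) ** 2
    kernel = np.ones(window_voxels)
    out = d2
    for axis in range(3):
        out = correlate1d(out, kernel, axis=axis, mode="constant", cval=0.0)
    return out


def fuse(
    candidates: list[LabelVolume],
    registered_images: list[GreyVolume],
    target: GreyVolume,
    window_voxels: int = 25,
    agreement_threshold: float = 1.0,
) -> LabelVolume:
    """Consensus segmentation by full agreement + local-SSD arbitration.

    A voxel where the top agreement fraction reaches ``agreement_threshold``
    (default 1.0: all candidates agree) keeps the majority label; every other
    voxel takes the label of the candidate with the minimal windowed SSD
    there (ties -> lowest candidate index).
    """
    if len(candidates) != len(registered_images) or not candidates:
        raise ValueError("need equally many candidates and registered images (>= 1)")
    if not 0 < agreement_threshold <= 1:
        raise ValueError("agreement threshold must lie in (0, 1]")
    _check_geometry(list(candidates) + list(registered_images) + [target])

    stack = np.stack([c.data for c in candidates])
    n = len(candidates)
    if agreement_threshold >= 1.0:
        settled = np.all(stack == stack[0], axis=0)
        settled_label = stack[0]
    else:
        pmap = build_probability_map(list(candidates))
        ids = np.asarray(sorted(pmap.fractions), dtype=np.int32)
        frac = np.stack([pmap.fractions[k] for k in ids])
        top = np.argmax(frac, axis=0)
        settled = np.take_along_axis(frac, top[None], axis=0)[0] >= agreement_threshold - 1e-12
        settled_label = ids[top]

    out = np.where(settled, settled_label, 0).astype(np.int32)
    if not np.all(settled):
        ssd = np.stack(
            [local_ssd_map(r, target, window_voxels) for r in registered_images]
        )
        best = np.argmin(ssd, axis=0)  # first minimum -> lowest candidate index
        disputed = ~settled
        winner = np.take_along_axis(stack, best[None], axis=0)[0]
        out[disputed] = winner[disputed]

    names: dict[int, str] = {}
    for c in candidates:
        for k, v in c.label_names.items():
            names.setdefault(k, v)
    return LabelVolume(out, target.spacing.copy(), target.origin.copy(), names)
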