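"""Volume containers and NIfTI I/O.

The package works on 3D grids with a fixed axis convention: axes 0 and 1 are
in-plane, axis 2 is longitudinal (inferior -> superior).  Indices are 0-based
and a voxel's world position is ``origin + index * spacing`` (voxel-centre
convention).  Grey volumes hold scanner intensities; label volumes hold
non-negative integer muscle ids (0 = background) plus an id -> name map that
is persisted as a JSON sidecar next to the NIfTI file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from .errors import FormatError, GeometryMismatchError, SequenceGapError

__all__ = [
    "GreyVolume",
    "LabelVolume",
    "read_volume",
    "read_labels",
    "write_volume",
    "resample_isotropic",
    "resample_to_spacing",
    "stack_sequences",
]

LONGITUDINAL_AXIS = 2


def _as_triple(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape == ():
        a = np.full(3, float(a))
    if a.shape != (3,):
        raise ValueError(f"expected a scalar or 3-vector, got shape {a.shape}")
    return a


@dataclass
class GreyVolume:
    """A 3D scalar intensity grid with voxel spacing (mm) and world origin (mm).

    ``origin`` is the world coordinate of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if self.data.ndim != 3:
            raise FormatError(f"volume data must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise FormatError("volume must have at least one voxel per axis")
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensity values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def extent_mm(self) -> np.ndarray:
        """World distance between the first and last voxel centres, per axis."""
        return (np.asarray(self.shape) - 1) * self.spacing

    def voxel_centres_world(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(*shape, 3)``."""
        axes = [self.origin[d] + self.spacing[d] * np.arange(self.shape[d]) for d in range(3)]
        grid = np.meshgrid(*axes, indexing="ij")
        return np.stack(grid, axis=-1)

    def same_grid(self, other: "GreyVolume | LabelVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def with_data(self, data: np.ndarray) -> "GreyVolume":
        return replace(self, data=data)


@dataclass
class LabelVolume:
    """A 3D integer label grid (0 = background, k >= 1 a muscle id)."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        data = np.asarray(self.data)
        if not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data)):
                raise FormatError("label data must be integer-valued")
            data = np.round(data).astype(np.int32)
        self.data = data.astype(np.int32, copy=False)
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if self.data.ndim != 3:
            raise FormatError(f"label data must be 3D, got {self.data.ndim}D")
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")
        self.label_names = {int(k): str(v) for k, v in self.label_names.items()}
        present = self.present_labels()
        missing = [k for k in present if k not in self.label_names]
        for k in missing:
            self.label_names[k] = f"label_{k}"

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def present_labels(self) -> list[int]:
        """Sorted non-zero label ids present in the grid."""
        vals = np.unique(self.data)
        return [int(v) for v in vals if v != 0]

    def mask(self, label_id: int) -> np.ndarray:
        return self.data == label_id

    def same_grid(self, other, atol: float = 1e-6) -> bool:
        return GreyVolume.same_grid(self, other, atol=atol)  # type: ignore[arg-type]

    def with_data(self, data: np.ndarray) -> "LabelVolume":
        return replace(self, data=data)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _affine(vol: GreyVolume | LabelVolume) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vol.spacing)
    aff[:3, 3] = vol.origin
    return aff


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".labels.json")
    return path.with_name(name + ".labels.json")


def _load_nifti(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several flavours
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D scalar volume, got {data.ndim}D")
    if data.dtype.fields is not None:
        raise FormatError(f"{path}: non-scalar voxel type {data.dtype}")
    aff = img.affine
    spacing = np.linalg.norm(aff[:3, :3], axis=0)
    origin = aff[:3, 3].astype(float)
    return np.asarray(data), spacing, origin


def read_volume(path) -> GreyVolume:
    """Read a scalar NIfTI volume (.nii/.nii.gz) into a :class:`GreyVolume`."""
    data, spacing, origin = _load_nifti(path)
    return GreyVolume(data.astype(np.float64), spacing, origin)


def read_labels(path) -> LabelVolume:
    """Read an integer NIfTI label volume plus its ``*.labels.json`` sidecar."""
    data, spacing, origin = _load_nifti(path)
    names: dict[int, str] = {}
    sidecar = _sidecar_path(Path(path))
    if sidecar.exists():
        names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return LabelVolume(data, spacing, origin, names)


def write_volume(vol: GreyVolume | LabelVolume, path) -> None:
    """Write a volume as NIfTI.

    Label volumes are stored with an integer codec (lossless); grey volumes at
    full float64 precision.  Label names go to a JSON sidecar.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(vol, LabelVolume):
        img = nib.Nifti1Image(vol.data.astype(np.int32), _affine(vol))
        img.header.set_data_dtype(np.int32)
        nib.save(img, str(path))
        names = {str(k): v for k, v in sorted(vol.label_names.items())}
        _sidecar_path(path).write_text(json.dumps(names, indent=1))
    else:
        img = nib.Nifti1Image(vol.data.astype(np.float64), _affine(vol))
        img.header.set_data_dtype(np.float64)
        nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling and longitudinal stacking
# ---------------------------------------------------------------------------


def resample_to_spacing(vol: GreyVolume, target_spacing) -> GreyVolume:
    """Resample onto a grid with the given spacing via tri-linear interpolation.

    The output keeps the input origin; the number of voxels per axis is chosen
    so the world extent is preserved to within one voxel.
    """
    t = _as_triple(target_spacing)
    if not np.all(t > 0):
        raise ValueError(f"target spacing must be positive, got {t}")
    old_shape = np.asarray(vol.shape)
    new_shape = np.maximum(1, np.round((old_shape - 1) * vol.spacing / t).astype(int) + 1)
    if np.array_equal(new_shape, old_shape) and np.allclose(vol.spacing, t):
        return GreyVolume(vol.data.copy(), t, vol.origin.copy())
    # index coordinates of the new voxel centres in the old grid
    axes = [(np.arange(new_shape[d]) * t[d]) / vol.spacing[d] for d in range(3)]
    coords = np.meshgrid(*axes, indexing="ij")
    out = map_coordinates(vol.data, coords, order=1, mode="nearest")
    return GreyVolume(out, t, vol.origin.copy())


def resample_isotropic(vol: GreyVolume, target_spacing: float) -> GreyVolume:
    """Resample to an isotropic grid of pitch ``target_spacing`` mm."""
    if np.ndim(target_spacing) != 0:
        raise ValueError("resample_isotropic takes a scalar spacing")
    if target_spacing <= 0:
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    return resample_to_spacing(vol, float(target_spacing))


def stack_sequences(sequences: list[GreyVolume], tol_voxels: float = 0.5) -> GreyVolume:
    """Concatenate longitudinal imaging sequences into one continuous volume.

    All sequences must already share one isotropic spacing.  Their in-plane
    fields of view are equated by padding with zero intensity, using the world
    origins to keep relative position.  Where consecutive sequences overlap
    along the longitudinal axis, half of the overlapping slices are removed
    from each: the later (distal) sequence loses the first ``ceil(v/2)``
    overlap slices, the earlier one the remaining ``floor(v/2)``.
    """
    if not sequences:
        raise ValueError("no sequences to stack")
    spacing = sequences[0].spacing
    for s in sequences[1:]:
        if not np.allclose(s.spacing, spacing, atol=1e-6):
            raise GeometryMismatchError(
                f"spacing mismatch while stacking: {s.spacing} vs {spacing}"
            )
    t = spacing[LONGITUDINAL_AXIS]

    # common in-plane field of view (zero-padded), aligned on the voxel lattice
    origins = np.array([s.origin for s in sequences])
    base_xy = origins[:, :2].min(axis=0)
    offsets = []
    for s in sequences:
        off = (s.origin[:2] - base_xy) / spacing[:2]
        off_i = np.round(off).astype(int)
        if np.any(np.abs(off - off_i) > tol_voxels):
            raise GeometryMismatchError(
                "in-plane origins are not aligned on a common voxel lattice"
            )
        offsets.append(off_i)
    plane_shape = np.max(
        [np.asarray(s.shape[:2]) + o for s, o in zip(sequences, offsets)], axis=0
    )

    def padded(s: GreyVolume, off: np.ndarray) -> np.ndarray:
        out = np.zeros((plane_shape[0], plane_shape[1], s.shape[2]), dtype=np.float64)
        out[off[0] : off[0] + s.shape[0], off[1] : off[1] + s.shape[1], :] = s.data
        return out

    blocks = [padded(s, o) for s, o in zip(sequences, offsets)]
    z_starts = [s.origin[2] for s in sequences]

    stacked = blocks[0]
    z_end = z_starts[0] + (blocks[0].shape[2] - 1) * t  # z of last kept slice
    for blk, z0 in zip(blocks[1:], z_starts[1:]):
        v_float = (z_end - z0) / t + 1.0
        v = int(round(v_float))
        if v_float < -tol_voxels:
            raise SequenceGapError(
                f"gap of {z0 - z_end - t:.2f} mm between consecutive sequences"
            )
        v = max(v, 0)
        if v > min(stacked.shape[2], blk.shape[2]):
            raise SequenceGapError("overlap exceeds a full sequence length")
        drop_prev = v // 2  # earlier sequence loses the trailing floor(v/2)
        drop_next = v - drop_prev  # later sequence loses the leading ceil(v/2)
        if drop_prev:
            stacked = stacked[:, :, :-drop_prev]
        stacked = np.concatenate([stacked, blk[:, :, drop_next:]], axis=2)
        z_end = z0 + (blk.shape[2] - 1) * t

    origin = np.array([base_xy[0], base_xy[1], sequences[0].origin[2]])
    return GreyVolume(stacked, spacing.copy(), origin)
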