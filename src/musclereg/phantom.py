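"""Synthetic limb phantoms for testing the segmentation pipeline.

A phantom emulates a T1-weighted lower-limb cross-section stack: a roughly
cylindrical body with a bright subcutaneous fat ring of configurable
thickness, a dark central bone, and several "muscle" compartments of similar
but distinct intensity arranged as angular sectors.  Compartment boundaries
are Gaussian-smoothed and re-assigned so muscle-muscle edges carry the weak
grey-level gradient characteristic of real muscle MRI, which keeps
registration tests honest.  All randomness flows from a single seeded
generator, so a spec + seed pair is fully deterministic.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter

from .errors import ConfigurationError
from .registration import NodeDisplacementField, densify, make_node_grid
from .volumes_io import GreyVolume, LabelVolume

__all__ = [
    "PhantomSpec",
    "CohortVariation",
    "make_limb_phantom",
    "make_random_field",
    "make_cohort",
]


@dataclass
class PhantomSpec:
    """Geometry and intensity model of one synthetic limb.

    Intensities follow the T1 ordering bone < muscle < fat; defaults mimic the
    package's working range of scanner units (muscle ~80-125, fat ~210).
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    body_radius_mm: float = 26.0
    fat_thickness_mm: float = 5.0
    bone_radius_mm: float = 5.0
    n_compartments: int = 4
    sector_fractions: tuple[float, ...] | None = None  # defaults to equal sectors
    sector_rotation_rad: float = 0.0
    air_mean: float = 0.0
    bone_mean: float = 40.0
    muscle_means: tuple[float, ...] | None = None  # defaults to 80 + 8*k
    fat_mean: float = 210.0
    noise_sd: float = 4.0
    boundary_smooth_vox: float = 1.5
    seed: int = 0

    def resolved_fractions(self) -> np.ndarray:
        if self.sector_fractions is None:
            return np.full(self.n_compartments, 1.0 / self.n_compartments)
        f = np.asarray(self.sector_fractions, dtype=float)
        if len(f) != self.n_compartments or np.any(f <= 0):
            raise ConfigurationError("sector_fractions must be positive, one per compartment")
        return f / f.sum()

    def resolved_muscle_means(self) -> np.ndarray:
        if self.muscle_means is None:
            return 80.0 + 8.0 * np.arange(self.n_compartments)
        m = np.asarray(self.muscle_means, dtype=float)
        if len(m) != self.n_compartments:
            raise ConfigurationError("muscle_means must have one entry per compartment")
        return m

    def validate(self) -> None:
        if self.n_compartments < 1:
            raise ConfigurationError("need at least one muscle compartment")
        if self.bone_radius_mm + self.fat_thickness_mm >= self.body_radius_mm:
            raise ConfigurationError(
                "bone radius + fat thickness must leave room for muscle inside the body radius"
            )
        if self.fat_mean <= self.resolved_muscle_means().max():
            raise ConfigurationError("fat must be brighter than every muscle compartment (T1)")
        if min(self.shape) < 4 or min(self.spacing) <= 0:
            raise ConfigurationError("invalid grid")
        half_fov = min(
            (self.shape[0] - 1) * self.spacing[0], (self.shape[1] - 1) * self.spacing[1]
        ) / 2.0
        if self.body_radius_mm > half_fov:
            raise ConfigurationError("body does not fit in the in-plane field of view")


def make_limb_phantom(spec: PhantomSpec) -> tuple[GreyVolume, LabelVolume]:
    """Generate one phantom and its ground-truth muscle labels.

    Muscle compartments carry labels 1..K; bone, fat and air are background
    (label 0).  Gaussian noise (sd ``spec.noise_sd``) is added everywhere and
    intensities are clipped at zero.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    sx, sy, _ = spec.spacing
    cx, cy = (nx - 1) / 2.0 * sx, (ny - 1) / 2.0 * sy
    X = np.arange(nx)[:, None] * sx - cx
    Y = np.arange(ny)[None, :] * sy - cy
    r = np.hypot(X, Y)
    theta = np.mod(np.arctan2(Y, X) - spec.sector_rotation_rad, 2 * np.pi)

    body = r <= spec.body_radius_mm
    bone = r <= spec.bone_radius_mm
    fat = body & (r > spec.body_radius_mm - spec.fat_thickness_mm)
    muscle = body & ~bone & ~fat

    fractions = spec.resolved_fractions()
    edges = np.concatenate([[0.0], np.cumsum(fractions)]) * 2 * np.pi
    onehot = np.stack(
        [((theta >= lo) & (theta < hi)).astype(float) for lo, hi in zip(edges[:-1], edges[1:])]
    )
    if spec.boundary_smooth_vox > 0 and spec.n_compartments > 1:
        onehot = np.stack(
            [gaussian_filter(c, spec.boundary_smooth_vox, mode="nearest") for c in onehot]
        )
    comp2d = np.argmax(onehot, axis=0)  # 0..K-1

    means = spec.resolved_muscle_means()
    slice_int = np.full((nx, ny), spec.air_mean)
    slice_int[muscle] = means[comp2d[muscle]]
    slice_int[fat] = spec.fat_mean
    slice_int[bone] = spec.bone_mean

    slice_lab = np.zeros((nx, ny), dtype=np.int32)
    slice_lab[muscle] = comp2d[muscle] + 1

    intensity = np.repeat(slice_int[:, :, None], nz, axis=2)
    labels = np.repeat(slice_lab[:, :, None], nz, axis=2)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=(nx, ny, nz))
    intensity = np.clip(intensity, 0.0, None)

    grey = GreyVolume(intensity, spec.spacing, (0.0, 0.0, 0.0))
    names = {k + 1: f"compartment_{k + 1:02d}" for k in range(spec.n_compartments)}
    lab = LabelVolume(labels, spec.spacing, (0.0, 0.0, 0.0), names)
    return grey, lab


def make_random_field(
    geometry: GreyVolume,
    nodal_spacing_mm: float,
    max_magnitude_mm: float,
    seed: int,
) -> NodeDisplacementField:
    """Seeded smooth node displacement field over ``geometry``.

    Node displacements are drawn i.i.d. normal, smoothed with one
    neighbour-averaging pass, then rescaled so the densified field's maximum
    magnitude over the voxel grid equals ``max_magnitude_mm`` exactly.
    """
    if max_magnitude_mm < 0:
        raise ValueError("max_magnitude_mm must be non-negative")
    field = make_node_grid(geometry, nodal_spacing_mm)
    if max_magnitude_mm == 0:
        return field
    rng = np.random.default_rng(seed)
    disp = rng.standard_normal(field.displacements.shape)
    for d in range(3):
        disp[..., d] = uniform_filter(disp[..., d], size=3, mode="nearest")
    field = replace(field, displacements=disp)
    dense = densify(field, geometry)
    peak = float(np.max(np.linalg.norm(dense, axis=-1)))
    if peak == 0.0:
        return replace(field, displacements=np.zeros_like(disp))
    return replace(field, displacements=disp * (max_magnitude_mm / peak))


@dataclass
class CohortVariation:
    """Per-subject variation ranges for :func:`make_cohort`.

    ``sector_jitter`` draws a multiplier in ``[1-j, 1+j]`` per compartment's
    angular width (renormalised to the full circle), so realised compartment
    volumes stay within ``[(1-j)/(1+j), (1+j)/(1-j)]`` of the base share.
    Ranges left as ``None`` default to the base spec's value (zero width).
    """

    body_radius_mm: tuple[float, float] | None = None
    fat_thickness_mm: tuple[float, float] | None = None
    sector_jitter: float = 0.0

    def validate(self) -> None:
        for rng_ in (self.body_radius_mm, self.fat_thickness_mm):
            if rng_ is not None and rng_[1] < rng_[0]:
                raise ConfigurationError("variation range must have lo <= hi")
        if not 0 <= self.sector_jitter < 1:
            raise ConfigurationError("sector_jitter must be in [0, 1)")


def make_cohort(
    n_subjects: int,
    base_spec: PhantomSpec,
    variation: CohortVariation | None = None,
    seed: int = 0,
) -> list[tuple[GreyVolume, LabelVolume]]:
    """Generate ``n_subjects`` phantoms with per-subject anatomy drawn from
    the variation ranges; deterministic per seed."""
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    variation = variation or CohortVariation()
    variation.validate()
    rng = np.random.default_rng(seed)
    cohort = []
    base_fracs = base_spec.resolved_fractions()
    radius_range = variation.body_radius_mm or (base_spec.body_radius_mm,) * 2
    fat_range = variation.fat_thickness_mm or (base_spec.fat_thickness_mm,) * 2
    for _ in range(n_subjects):
        radius = rng.uniform(*radius_range)
        fat = rng.uniform(*fat_range)
        j = variation.sector_jitter
        mult = rng.uniform(1 - j, 1 + j, size=len(base_fracs))
        fracs = base_fracs * mult
        fracs = fracs / fracs.sum()
        # noise seed derives from the drawn anatomy: identical parameters
        # (zero-width ranges) reproduce bit-identical phantoms
        key = np.array([seed, base_spec.seed, radius, fat, *fracs], dtype=float)
        sub_seed = int(zlib.crc32(key.tobytes()) % (2**31 - 1))
        spec = replace(
            base_spec,
            body_radius_mm=float(radius),
            fat_thickness_mm=float(fat),
            sector_fractions=tuple(fracs),
            seed=sub_seed,
        )
        cohort.append(make_limb_phantom(spec))
    return cohort
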