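"""Node-grid deformable image registration.

Displacement unknowns live on an isotropic hexahedral node grid of pitch
``NS`` (the nodal spacing) overlapping the fixed image; the dense voxel-wise
field is obtained by tri-linear interpolation between nodes.  Registration
minimises

    E(u) = SSD(fixed, moving o (id + u)) + lambda * sum_edges ||u_a - u_b||^2

by damped Gauss-Newton: at each iteration the moving image is linearised
around the current field, the sparse normal equations over node displacements
(with the graph-Laplacian smoothing term) are solved, and the step is
backtracked until the regularised cost decreases.  The field is a backward
map: u is defined on the fixed (target) grid and pulls intensities from the
moving (reference) image, which makes resampling well-posed.  An optional
coarse-to-fine image pyramid (NS doubled per level) improves the capture
range; set ``pyramid_levels=1`` to disable it.

Warping a label map goes through per-label one-hot channels warped with the
same tri-linear kernel, then an arg-max (ties to the lower label id), so the
propagated segmentation stays crisp without inventing labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.ndimage import gaussian_filter, map_coordinates

from .errors import ConfigurationError, CoverageError, GeometryMismatchError, NumericalError
from .volumes_io import GreyVolume, LabelVolume, resample_to_spacing

__all__ = [
    "RegistrationConfig",
    "NodeDisplacementField",
    "make_node_grid",
    "densify",
    "ssd_cost",
    "register",
    "warp_image",
    "warp_labels",
    "save_field",
    "load_field",
]


@dataclass
class RegistrationConfig:
    """Parameters of the node-grid registration.

    ``smoothing_coefficient`` (lambda) defaults to ``0.1 * NS**2``; the
    optional ``smoothing_sweep`` multiplies that default by a geometric range
    and keeps the field with the lowest final SSD.
    """

    nodal_spacing_mm: float = 5.0
    smoothing_coefficient: float | None = None
    max_iterations: int = 50
    tolerance: float = 1e-4
    pyramid_levels: int = 3
    smoothing_sweep: tuple[float, ...] | None = None  # e.g. (0.01, 0.1, 1, 10)

    def __post_init__(self):
        if self.nodal_spacing_mm <= 0:
            raise ConfigurationError("nodal spacing must be positive")
        if self.smoothing_coefficient is not None and self.smoothing_coefficient < 0:
            raise ConfigurationError("smoothing coefficient must be non-negative")
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be positive")
        if self.max_iterations < 1 or self.pyramid_levels < 1:
            raise ConfigurationError("max_iterations and pyramid_levels must be >= 1")

    @property
    def resolved_smoothing(self) -> float:
        if self.smoothing_coefficient is not None:
            return self.smoothing_coefficient
        return 0.1 * self.nodal_spacing_mm**2


@dataclass
class NodeDisplacementField:
    """3-vector displacements (mm) on an isotropic node grid.

    The grid covers the fixed image with at least one node beyond every face.
    ``target_*`` record the fixed-image geometry the field was built for, so
    warps can reproduce the fixed grid without carrying the image around.
    """

    node_origin: np.ndarray  # world position of node (0,0,0), mm
    node_spacing: float  # NS, mm
    displacements: np.ndarray  # (mx, my, mz, 3), mm
    target_shape: tuple[int, int, int]
    target_spacing: np.ndarray
    target_origin: np.ndarray
    cost_history: list[dict] = dc_field(default_factory=list)

    def __post_init__(self):
        self.node_origin = np.asarray(self.node_origin, dtype=float)
        self.target_spacing = np.asarray(self.target_spacing, dtype=float)
        self.target_origin = np.asarray(self.target_origin, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 4 or self.displacements.shape[-1] != 3:
            raise ValueError("displacements must have shape (mx, my, mz, 3)")

    @property
    def node_shape(self) -> tuple[int, int, int]:
        return self.displacements.shape[:3]

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.node_shape))

    def target_geometry(self) -> GreyVolume:
        """An empty volume carrying the fixed-image grid geometry."""
        return GreyVolume(
            np.zeros(self.target_shape), self.target_spacing, self.target_origin
        )


def make_node_grid(fixed: GreyVolume, nodal_spacing_mm: float) -> NodeDisplacementField:
    """Zero-initialised node grid covering ``fixed`` with one node of margin."""
    ns = float(nodal_spacing_mm)
    if ns <= 0:
        raise ConfigurationError("nodal spacing must be positive")
    extent = fixed.extent_mm()
    if np.any(ns > np.maximum(extent, fixed.spacing)):
        raise ConfigurationError(
            f"nodal spacing {ns} mm exceeds the image extent {extent} mm"
        )
    counts = np.ceil(extent / ns).astype(int) + 3
    origin = fixed.origin - ns
    disp = np.zeros((counts[0], counts[1], counts[2], 3))
    return NodeDisplacementField(
        node_origin=origin,
        node_spacing=ns,
        displacements=disp,
        target_shape=fixed.shape,
        target_spacing=fixed.spacing.copy(),
        target_origin=fixed.origin.copy(),
    )


def _node_coords(field: NodeDisplacementField, points_world: np.ndarray) -> np.ndarray:
    """World points -> continuous node-grid index coordinates, with coverage check."""
    g = (points_world - field.node_origin) / field.node_spacing
    hi = np.asarray(field.node_shape) - 1
    if np.any(g < -1e-9) or np.any(g > hi + 1e-9):
        raise CoverageError("node grid does not cover the requested geometry")
    return np.clip(g, 0.0, hi)


def _basis_matrix(field: NodeDisplacementField, points_world: np.ndarray) -> sp.csr_matrix:
    """Sparse (n_points x n_nodes) tri-linear basis weights."""
    g = _node_coords(field, points_world)
    shape = np.asarray(field.node_shape)
    i0 = np.minimum(np.floor(g).astype(int), shape - 2)
    f = g - i0
    npts = g.shape[0]
    rows = np.repeat(np.arange(npts), 8)
    cols = np.empty(npts * 8, dtype=np.int64)
    vals = np.empty(npts * 8)
    c = 0
    for dx in (0, 1):
        wx = f[:, 0] if dx else 1 - f[:, 0]
        for dy in (0, 1):
            wy = f[:, 1] if dy else 1 - f[:, 1]
            for dz in (0, 1):
                wz = f[:, 2] if dz else 1 - f[:, 2]
                idx = np.ravel_multi_index(
                    (i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz), tuple(shape)
                )
                cols[c::8] = idx
                vals[c::8] = wx * wy * wz
                c += 1
    B = sp.csr_matrix((vals, (rows, cols)), shape=(npts, int(np.prod(shape))))
    return B


def densify(field: NodeDisplacementField, target: GreyVolume) -> np.ndarray:
    """Tri-linearly interpolate node displacements onto ``target``'s voxel grid.

    Returns an array of shape ``(*target.shape, 3)`` in mm.
    """
    pts = target.voxel_centres_world().reshape(-1, 3)
    g = _node_coords(field, pts)
    coords = np.ascontiguousarray(g.T)
    out = np.empty((pts.shape[0], 3))
    for d in range(3):
        out[:, d] = map_coordinates(field.displacements[..., d], coords, order=1, mode="nearest")
    return out.reshape(target.shape + (3,))


def _sample(vol_data: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Tri-linear sample at continuous index coords (n,3); outside -> 0."""
    return map_coordinates(vol_data, np.ascontiguousarray(idx.T), order=1, mode="constant", cval=0.0)


def ssd_cost(fixed: GreyVolume, moving: GreyVolume, field: NodeDisplacementField) -> float:
    """Sum of squared intensity differences under the current field.

    The moving image is sampled at ``x + u(x)`` by tri-linear interpolation;
    samples outside its domain contribute intensity 0 (air).
    """
    if not np.allclose(fixed.spacing, moving.spacing, atol=1e-6):
        raise GeometryMismatchError("fixed and moving must share spacing (pre-resample)")
    dense = densify(field, fixed)
    pts = fixed.voxel_centres_world().reshape(-1, 3) + dense.reshape(-1, 3)
    idx = (pts - moving.origin) / moving.spacing
    samp = _sample(moving.data, idx)
    r = fixed.data.ravel() - samp
    return float(r @ r)


def _grid_laplacian(shape: tuple[int, int, int]) -> sp.csr_matrix:
    """Graph Laplacian of the 6-neighbour node lattice (membrane penalty)."""

    def path(n: int) -> sp.csr_matrix:
        if n == 1:
            return sp.csr_matrix((1, 1))
        main = np.full(n, 2.0)
        main[0] = main[-1] = 1.0
        off = -np.ones(n - 1)
        return sp.diags([off, main, off], [-1, 0, 1]).tocsr()

    mx, my, mz = shape
    Ix, Iy, Iz = (sp.identity(m, format="csr") for m in shape)
    L = (
        sp.kron(sp.kron(path(mx), Iy), Iz)
        + sp.kron(sp.kron(Ix, path(my)), Iz)
        + sp.kron(sp.kron(Ix, Iy), path(mz))
    )
    return L.tocsr()


def _downsample(vol: GreyVolume, factor: int) -> GreyVolume:
    if factor == 1:
        return vol
    smoothed = gaussian_filter(vol.data, sigma=factor / 2.0, mode="nearest")
    return resample_to_spacing(vol.with_data(smoothed), vol.spacing * factor)


def _gauss_newton_level(
    fixed: GreyVolume,
    moving: GreyVolume,
    field: NodeDisplacementField,
    lam: float,
    config: RegistrationConfig,
    level: int,
    history: list[dict],
) -> NodeDisplacementField:
    pts = fixed.voxel_centres_world().reshape(-1, 3)
    B = _basis_matrix(field, pts)
    L = _grid_laplacian(field.node_shape)
    n_nodes = field.n_nodes
    fvals = fixed.data.ravel()
    grads = np.gradient(moving.data, *moving.spacing)

    U = field.displacements.reshape(-1, 3).copy()

    def eval_cost(Um: np.ndarray):
        warped = pts + B @ Um
        idx = (warped - moving.origin) / moving.spacing
        r = fvals - _sample(moving.data, idx)
        reg = lam * sum(float(Um[:, d] @ (L @ Um[:, d])) for d in range(3))
        return float(r @ r) + reg, r, idx

    cost, r, idx = eval_cost(U)
    if not np.isfinite(cost):
        raise NumericalError(f"non-finite cost at pyramid level {level}")
    history.append({"level": level, "iteration": 0, "cost": cost})

    for it in range(1, config.max_iterations + 1):
        g_samp = [
            _sample(g, idx) for g in grads
        ]  # moving-image gradient at the warped positions
        G = sp.hstack(
            [B.multiply(gs[:, None]).tocsr() for gs in g_samp], format="csr"
        )  # d(sampled moving)/d(node displacement)
        H = (G.T @ G).tocsc()
        Lu = np.concatenate([L @ U[:, d] for d in range(3)])
        rhs = G.T @ r - lam * Lu
        L3 = sp.block_diag([L, L, L], format="csc")
        mu = 1e-8 * (H.diagonal().mean() + 1.0)
        A = H + lam * L3 + mu * sp.identity(3 * n_nodes, format="csc")
        try:
            delta = spla.spsolve(A, rhs)
        except RuntimeError as exc:
            raise NumericalError(f"linear solve failed: {exc}") from exc
        if not np.all(np.isfinite(delta)):
            raise NumericalError("non-finite Gauss-Newton step")
        dU = delta.reshape(3, n_nodes).T

        accepted = False
        alpha = 1.0
        for _ in range(12):
            cand = U + alpha * dU
            c_cand, r_cand, idx_cand = eval_cost(cand)
            if c_cand < cost:
                rel = (cost - c_cand) / max(cost, 1e-300)
                U, cost, r, idx = cand, c_cand, r_cand, idx_cand
                history.append({"level": level, "iteration": it, "cost": cost})
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        if rel < config.tolerance:
            break

    return replace(field, displacements=U.reshape(field.displacements.shape))


def register(
    fixed: GreyVolume, moving: GreyVolume, config: RegistrationConfig | None = None
) -> NodeDisplacementField:
    """Estimate node displacements aligning ``moving`` to ``fixed``.

    Starts from zero displacement.  With ``pyramid_levels > 1`` the solve runs
    coarse-to-fine: images are downsampled by powers of two, NS is doubled per
    level, and each level's solution seeds the next via tri-linear
    prolongation.  The returned field carries an iteration log
    (``cost_history``) whose regularised cost is non-increasing within each
    level.
    """
    config = config or RegistrationConfig()
    if not (np.all(np.isfinite(fixed.data)) and np.all(np.isfinite(moving.data))):
        raise NumericalError("non-finite intensities in registration input")
    if not np.allclose(fixed.spacing, moving.spacing, atol=1e-6):
        raise GeometryMismatchError("fixed and moving must share spacing (pre-resample)")

    if config.smoothing_sweep:
        best = None
        for mult in config.smoothing_sweep:
            sub = replace(
                config,
                smoothing_coefficient=mult * config.resolved_smoothing,
                smoothing_sweep=None,
            )
            f = register(fixed, moving, sub)
            s = ssd_cost(fixed, moving, f)
            if best is None or s < best[0]:
                best = (s, f)
        return best[1]

    lam = config.resolved_smoothing
    history: list[dict] = []
    field: NodeDisplacementField | None = None
    for level in range(config.pyramid_levels - 1, -1, -1):
        factor = 2**level
        ns_level = config.nodal_spacing_mm * factor
        f_l = _downsample(fixed, factor)
        m_l = _downsample(moving, factor)
        try:
            level_field = make_node_grid(f_l, ns_level)
        except ConfigurationError:
            continue  # level too coarse for this image; skip
        if field is not None:
            # prolong the coarser solution onto this level's node positions
            node_pts = _node_world_positions(level_field)
            g = (node_pts - field.node_origin) / field.node_spacing
            g = np.clip(g, 0, np.asarray(field.node_shape) - 1)
            disp = np.empty_like(level_field.displacements)
            coords = np.ascontiguousarray(g.reshape(-1, 3).T)
            for d in range(3):
                disp[..., d] = map_coordinates(
                    field.displacements[..., d], coords, order=1, mode="nearest"
                ).reshape(level_field.node_shape)
            level_field = replace(level_field, displacements=disp)
        field = _gauss_newton_level(f_l, m_l, level_field, lam, config, level, history)

    if field is None:
        raise ConfigurationError("no pyramid level was solvable for this geometry")
    # re-target the finest field to the full-resolution fixed grid
    field = replace(
        field,
        target_shape=fixed.shape,
        target_spacing=fixed.spacing.copy(),
        target_origin=fixed.origin.copy(),
        cost_history=history,
    )
    return field


def _node_world_positions(field: NodeDisplacementField) -> np.ndarray:
    axes = [
        field.node_origin[d] + field.node_spacing * np.arange(field.node_shape[d])
        for d in range(3)
    ]
    grid = np.meshgrid(*axes, indexing="ij")
    return np.stack(grid, axis=-1)


def warp_image(
    moving: GreyVolume, field: NodeDisplacementField, target: GreyVolume | None = None
) -> GreyVolume:
    """Resample ``moving`` onto the fixed grid through the field (backward warp).

    The value at fixed voxel x is the tri-linear sample of ``moving`` at
    ``x + u(x)``; samples outside the moving domain are 0.
    """
    geom = target if target is not None else field.target_geometry()
    dense = densify(field, geom)
    pts = geom.voxel_centres_world().reshape(-1, 3) + dense.reshape(-1, 3)
    idx = (pts - moving.origin) / moving.spacing
    out = _sample(moving.data, idx).reshape(geom.shape)
    return GreyVolume(out, geom.spacing.copy(), geom.origin.copy())


def warp_labels(
    labels: LabelVolume, field: NodeDisplacementField, target: GreyVolume | None = None
) -> LabelVolume:
    """Propagate a label map through the field.

    Each label (background included) is warped as a one-hot channel with
    tri-linear interpolation and the output takes the arg-max channel; ties go
    to the lower label id and out-of-domain voxels to background.
    """
    geom = target if target is not None else field.target_geometry()
    dense = densify(field, geom)
    pts = geom.voxel_centres_world().reshape(-1, 3) + dense.reshape(-1, 3)
    idx = (pts - labels.origin) / labels.spacing
    ids = sorted(set([0] + labels.present_labels()))
    scores = np.empty((len(ids), pts.shape[0]))
    for i, k in enumerate(ids):
        scores[i] = _sample((labels.data == k).astype(np.float64), idx)
    best = np.argmax(scores, axis=0)  # first max -> lowest label id on ties
    out = np.asarray(ids, dtype=np.int32)[best].reshape(geom.shape)
    # fully out-of-domain voxels have all-zero scores; argmax -> index 0 -> background
    return LabelVolume(out, geom.spacing.copy(), geom.origin.copy(), dict(labels.label_names))


# ---------------------------------------------------------------------------
# Field persistence: NIfTI vector volume + JSON sidecar
# ---------------------------------------------------------------------------


def _field_sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".field.json")
    return path.with_name(name + ".field.json")


def save_field(field: NodeDisplacementField, path) -> None:
    """Store node displacements as a 3-component NIfTI plus a JSON sidecar."""
    import nibabel as nib

    path = Path(path)
    aff = np.eye(4)
    aff[:3, :3] = np.diag([field.node_spacing] * 3)
    aff[:3, 3] = field.node_origin
    img = nib.Nifti1Image(field.displacements.astype(np.float64), aff)
    nib.save(img, str(path))
    meta = {
        "node_origin": field.node_origin.tolist(),
        "node_spacing": field.node_spacing,
        "target_shape": list(field.target_shape),
        "target_spacing": field.target_spacing.tolist(),
        "target_origin": field.target_origin.tolist(),
    }
    _field_sidecar(path).write_text(json.dumps(meta, indent=1))


def load_field(path) -> NodeDisplacementField:
    import nibabel as nib

    path = Path(path)
    meta = json.loads(_field_sidecar(path).read_text())
    img = nib.load(str(path))
    disp = np.asanyarray(img.dataobj).astype(float)
    return NodeDisplacementField(
        node_origin=np.asarray(meta["node_origin"]),
        node_spacing=float(meta["node_spacing"]),
        displacements=disp,
        target_shape=tuple(meta["target_shape"]),
        target_spacing=np.asarray(meta["target_spacing"]),
        target_origin=np.asarray(meta["target_origin"]),
    )
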