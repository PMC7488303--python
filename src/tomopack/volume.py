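"""Density-map rendering and noise for simulated tomograms.

A packed scene is rasterized onto a regular voxel grid by giving every
ball an isotropic Gaussian kernel whose FWHM equals the target resolution
(default 4 nm = 40 internal units at 1 nm = 10-unit voxels) and whose
integral equals the ball's mass, so total density is conserved.  Rigid
structures are rendered once in their initial orientation and then rotated
and translated into place by their extracted pose; deformable structures
are rendered directly from their final ball positions with zero rotation.
The simulated tomogram is the clean map plus zero-mean white Gaussian
noise scaled to a requested signal-to-noise ratio, defined throughout as
``Var(signal) / Var(noise)``.

Grids are stored Z,Y,X-major: the world coordinate of the center of voxel
``(i, j, k)`` is ``origin + (k + 0.5, j + 0.5, i + 0.5) * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dynamics import Scene
from .pose import Pose
from .structures import Structure

__all__ = [
    "DensityVolume",
    "NoiseParams",
    "FWHM_TO_SIGMA",
    "DEFAULT_VOXEL_SIZE",
    "DEFAULT_RESOLUTION",
    "rasterize_structure",
    "rasterize_balls",
    "compose_scene_map",
    "add_noise",
    "measure_snr",
]

#: FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
#: 1 nm voxels and 4 nm resolution, in internal units (~ Å).
DEFAULT_VOXEL_SIZE = 10.0
DEFAULT_RESOLUTION = 40.0
#: Gaussian kernels are evaluated out to this many sigma, then normalized.
_KERNEL_TRUNC = 4.0


@dataclass
class DensityVolume:
    """A 3D scalar grid with voxel size and world origin."""

    grid: np.ndarray
    voxel_size: float = DEFAULT_VOXEL_SIZE
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    resolution: float = DEFAULT_RESOLUTION

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-dimensional")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid values must be finite")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def integral(self) -> float:
        """Total density times voxel volume (equals total rendered mass)."""
        return float(self.grid.sum() * self.voxel_size**3)

    def voxel_centers_world(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (x, y, z) of voxel centers given (i, j, k) rows."""
        idx = np.asarray(indices, dtype=float).reshape(-1, 3)
        return self.origin + (idx[:, ::-1] + 0.5) * self.voxel_size

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional (i, j, k) grid indices of world points (x, y, z)."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        return ((pts - self.origin) / self.voxel_size - 0.5)[:, ::-1]


@dataclass(frozen=True)
class NoiseParams:
    snr: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be > 0")


# ---------------------------------------------------------------------------
# rasterization


def rasterize_balls(
    grid: np.ndarray,
    origin: np.ndarray,
    voxel_size: float,
    centers: np.ndarray,
    masses: np.ndarray,
    resolution: float,
) -> None:
    """Add one mass-normalized Gaussian per ball into ``grid`` in place.

    Kernels are evaluated in a local window out to 4 sigma and then scaled
    so each ball's discretely integrated density equals its mass exactly.
    """
    sigma = resolution * FWHM_TO_SIGMA
    nz, ny, nx = grid.shape
    h = voxel_size
    half = _KERNEL_TRUNC * sigma
    centers = np.asarray(centers, float).reshape(-1, 3)
    masses = np.asarray(masses, float).reshape(-1)
    for (cx, cy, cz), mass in zip(centers, masses):
        # voxel-index window covering center +- 4 sigma, clipped to the grid
        kx0 = max(int(np.floor((cx - half - origin[0]) / h - 0.5)), 0)
        kx1 = min(int(np.ceil((cx + half - origin[0]) / h - 0.5)) + 1, nx)
        ky0 = max(int(np.floor((cy - half - origin[1]) / h - 0.5)), 0)
        ky1 = min(int(np.ceil((cy + half - origin[1]) / h - 0.5)) + 1, ny)
        kz0 = max(int(np.floor((cz - half - origin[2]) / h - 0.5)), 0)
        kz1 = min(int(np.ceil((cz + half - origin[2]) / h - 0.5)) + 1, nz)
        if kx0 >= kx1 or ky0 >= ky1 or kz0 >= kz1:
            continue
        xs = origin[0] + (np.arange(kx0, kx1) + 0.5) * h
        ys = origin[1] + (np.arange(ky0, ky1) + 0.5) * h
        zs = origin[2] + (np.arange(kz0, kz1) + 0.5) * h
        gx = np.exp(-((xs - cx) ** 2) / (2 * sigma**2))
        gy = np.exp(-((ys - cy) ** 2) / (2 * sigma**2))
        gz = np.exp(-((zs - cz) ** 2) / (2 * sigma**2))
        kernel = gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        total = kernel.sum() * h**3
        if total > 0:
            grid[kz0:kz1, ky0:ky1, kx0:kx1] += kernel * (mass / total)


def rasterize_structure(
    structure: Structure,
    voxel_size: float = DEFAULT_VOXEL_SIZE,
    resolution: float = DEFAULT_RESOLUTION,
    centers: np.ndarray | None = None,
) -> DensityVolume:
    """Render one structure on a tight grid (structure extent + kernel pad)."""
    if structure.n_balls == 0:
        raise ValueError("cannot rasterize an empty structure")
    c = structure.centers if centers is None else np.asarray(centers, float)
    sigma = resolution * FWHM_TO_SIGMA
    pad = 3.0 * sigma
    lo = (c - structure.radii[:, None]).min(axis=0) - pad
    hi = (c + structure.radii[:, None]).max(axis=0) + pad
    shape_xyz = np.ceil((hi - lo) / voxel_size).astype(int)
    grid = np.zeros(shape_xyz[::-1])
    rasterize_balls(grid, lo, voxel_size, c, structure.masses, resolution)
    return DensityVolume(grid, voxel_size=voxel_size, origin=lo,
                         resolution=resolution)


def _rotate_reference_into(
    out_grid: np.ndarray,
    out_origin: np.ndarray,
    ref: DensityVolume,
    rotation: np.ndarray,
    centroid_init: np.ndarray,
    centroid_final: np.ndarray,
    order: int = 3,
) -> None:
    """Add a rotated + translated copy of a reference map into ``out_grid``.

    The reference map (rendered around ``centroid_init``) is rotated about
    that centroid by ``rotation`` and its centroid moved to
    ``centroid_final``; a single inverse affine map from output voxel
    indices to reference indices performs rotation and subvoxel
    translation in one interpolation pass (cubic B-spline by default;
    ``order=1`` selects trilinear).
    """
    h = ref.voxel_size
    r_inv = np.asarray(rotation, float).T  # inverse of a rotation
    # work in xyz index space: idx_xyz = (world - origin)/h - 0.5
    # ref_idx = R^-1 @ (out_world - c_final)/h + (c_init - ref.origin)/h - 0.5
    a_out = out_origin + 0.5 * h
    offset_world = r_inv @ (a_out - centroid_final) + centroid_init
    matrix_xyz = r_inv
    offset_xyz = (offset_world - ref.origin) / h - 0.5
    # grids are stored z,y,x: conjugate the affine map with the axis reversal
    J = np.eye(3)[::-1]
    matrix_zyx = J @ matrix_xyz @ J
    offset_zyx = offset_xyz[::-1]
    contrib = ndimage.affine_transform(
        ref.grid, matrix_zyx, offset=offset_zyx, output_shape=out_grid.shape,
        order=order, mode="constant", cval=0.0, prefilter=(order > 1),
    )
    out_grid += contrib


def compose_scene_map(
    scene: Scene,
    poses: list[Pose],
    voxel_size: float = DEFAULT_VOXEL_SIZE,
    resolution: float = DEFAULT_RESOLUTION,
    order: int = 3,
    box_pad: float | None = None,
) -> DensityVolume:
    """Render a packed scene to a density map covering its box.

    Rigid structures are rendered once in their t=0 orientation and mapped
    into place with their extracted rotation and final centroid; deformable
    structures are rendered directly from their final ball positions (their
    annotated rotation is zero).
    """
    if len(poses) != len(scene.structures):
        raise ValueError("poses must align 1:1 with scene structures")
    sigma = resolution * FWHM_TO_SIGMA
    pad = 3.0 * sigma if box_pad is None else box_pad
    lo = scene.center - scene.box / 2 - pad
    hi = scene.center + scene.box / 2 + pad
    shape_xyz = np.ceil((hi - lo) / voxel_size).astype(int)
    grid = np.zeros(shape_xyz[::-1])

    for idx, (s, pose) in enumerate(zip(scene.structures, poses)):
        if s.deformable:
            rasterize_balls(grid, lo, voxel_size,
                            scene.structure_positions(idx), s.masses, resolution)
        else:
            init = scene.structure_positions(idx, initial=True)
            ref = rasterize_structure(
                s, voxel_size=voxel_size, resolution=resolution, centers=init
            )
            _rotate_reference_into(
                grid, lo, ref, pose.rotation_matrix,
                pose.centroid_init, pose.centroid_final, order=order,
            )
    return DensityVolume(grid, voxel_size=voxel_size, origin=lo,
                         resolution=resolution)


# ---------------------------------------------------------------------------
# noise


def add_noise(volume: DensityVolume, params: NoiseParams) -> DensityVolume:
    """Add zero-mean white Gaussian noise at the requested SNR.

    Noise variance is ``Var(signal) / snr`` (variance-ratio SNR
    convention); reproducible under the seed.
    """
    var = float(volume.grid.var())
    if var == 0.0:
        raise ValueError("signal has zero variance: SNR undefined")
    rng = np.random.default_rng(params.seed)
    noise = rng.normal(0.0, np.sqrt(var / params.snr), size=volume.grid.shape)
    return DensityVolume(volume.grid + noise, voxel_size=volume.voxel_size,
                         origin=volume.origin.copy(), resolution=volume.resolution)


def measure_snr(clean: DensityVolume, noisy: DensityVolume) -> float:
    """Variance-ratio SNR of a noisy volume against its clean signal."""
    if clean.grid.shape != noisy.grid.shape:
        raise ValueError("volumes must share a grid shape")
    noise_var = float((noisy.grid - clean.grid).var())
    if noise_var == 0.0:
        return float("inf")
    return float(clean.grid.var()) / noise_var
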