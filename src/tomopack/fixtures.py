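"""Synthetic inputs: atom clouds and blob phantoms.

These generators stand in for deposited PDB structures so every pipeline
stage is testable offline.  Cloud shapes cover the morphologies the
simulator cares about — globular complexes, elongated rods (where the
multi-ball model saves the most volume over a single bounding sphere),
thin slabs and dumbbells.  Default extents mirror typical macromolecule
sizes (overall size 60-250 internal units, mostly 120-160).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .groundtruth import GroundTruthEntry
from .structures import AtomCloud, Structure, build_filament, build_membrane, coarse_grain
from .volume import DensityVolume

__all__ = [
    "SynthSpec",
    "synth_atom_cloud",
    "synth_blob_volume",
    "fixture_structure_library",
]

SHAPES = ("globular", "rod", "planar", "dumbbell")


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic atom cloud."""

    shape: str
    n_atoms: int
    extent: float = 140.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; pick from {SHAPES}")
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")
        if self.extent <= 0:
            raise ValueError("extent must be > 0")


def synth_atom_cloud(spec: SynthSpec) -> AtomCloud:
    """Sample a deterministic atom cloud of the requested shape.

    ``extent`` is the overall size: the sphere diameter for globular
    clouds, the rod length (aspect ratio >= 5 on the diameter), the slab
    width, or the dumbbell end-to-end length.  All samplers are bounded,
    so the cloud never exceeds ``extent``.
    """
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_atoms, spec.extent

    def ball(count: int, radius: float) -> np.ndarray:
        # uniform in a solid sphere
        u = rng.normal(size=(count, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        return u * radius * rng.random(count)[:, None] ** (1 / 3)

    if spec.shape == "globular":
        coords = ball(n, L / 2)
    elif spec.shape == "rod":
        radius = L / 10.0  # aspect ratio 5 on the diameter
        x = rng.uniform(-L / 2, L / 2, size=n)
        r = radius * np.sqrt(rng.random(n))
        phi = rng.uniform(0, 2 * np.pi, size=n)
        coords = np.column_stack([x, r * np.cos(phi), r * np.sin(phi)])
    elif spec.shape == "planar":
        xy = rng.uniform(-L / 2, L / 2, size=(n, 2))
        z = rng.uniform(-L / 20, L / 20, size=n)
        coords = np.column_stack([xy, z])
    else:  # dumbbell: two solid spheres joined along x
        half = rng.random(n) < 0.5
        coords = ball(n, L / 4)
        coords[:, 0] += np.where(half, -L / 4, L / 4)
    return AtomCloud(coords, source_id=f"synth-{spec.shape}-{spec.n_atoms}")


def synth_blob_volume(
    centers: np.ndarray,
    sigma: float,
    grid_shape: tuple[int, int, int],
    voxel_size: float = 1.0,
    require_separated: bool = True,
) -> tuple[DensityVolume, list[GroundTruthEntry]]:
    """A volume of unit-mass Gaussian blobs plus its matching truth table.

    ``centers`` are world coordinates (x, y, z) with the grid origin at
    zero.  Truth radii are 3 sigma.  With ``require_separated`` the
    centers must be pairwise at least 6 sigma apart (the well-separated
    picking fixture).
    """
    centers = np.asarray(centers, float).reshape(-1, 3)
    if len(centers) == 0:
        raise ValueError("need at least one blob center")
    shape = tuple(int(s) for s in grid_shape)
    extent = np.array(shape[::-1], float) * voxel_size  # (x, y, z)
    if np.any(centers < 0) or np.any(centers >= extent):
        raise ValueError("blob center outside the grid")
    if require_separated and len(centers) > 1:
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        if d.min() < 6 * sigma:
            raise ValueError("blob centers closer than 6 sigma")

    grid = np.zeros(shape)
    axes = [
        (np.arange(shape[2 - a]) + 0.5) * voxel_size for a in range(3)
    ]  # x, y, z coordinate vectors
    for c in centers:
        gx = np.exp(-((axes[0] - c[0]) ** 2) / (2 * sigma**2))
        gy = np.exp(-((axes[1] - c[1]) ** 2) / (2 * sigma**2))
        gz = np.exp(-((axes[2] - c[2]) ** 2) / (2 * sigma**2))
        blob = gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        total = blob.sum() * voxel_size**3
        grid += blob / total

    vol = DensityVolume(grid, voxel_size=voxel_size, origin=np.zeros(3),
                        resolution=sigma / 0.42466)
    entries = [
        GroundTruthEntry(
            label=f"blob{i}",
            kind="rigid",
            centroid=c,
            displacement=np.zeros(3),
            euler_deg=(0.0, 0.0, 0.0),
            bounding_radius=3 * sigma,
        )
        for i, c in enumerate(centers)
    ]
    return vol, entries


def fixture_structure_library(
    n_rigid: int = 5,
    n_atoms: int = 12000,
    extent: float = 140.0,
    seed: int = 0,
    include_filament: bool = False,
    include_membrane: bool = False,
    filament_balls: int = 9,
    membrane_shape: tuple[int, int] = (5, 5),
) -> list[Structure]:
    """A ready-made structure library built from synthetic clouds.

    ``n_rigid`` coarse-grained rigid structures of alternating shapes,
    optionally followed by a bead-chain filament and a bead-mesh membrane
    with the default bead diameters (40 and 80 units).
    """
    shapes = ["globular", "rod", "dumbbell", "planar"]
    lib: list[Structure] = []
    for i in range(n_rigid):
        spec = SynthSpec(shape=shapes[i % len(shapes)], n_atoms=n_atoms,
                         extent=extent, seed=seed + 101 * i)
        s = coarse_grain(synth_atom_cloud(spec), seed=seed + 7 * i)
        s.label = f"{spec.shape}-{i}"
        lib.append(s)
    if include_filament:
        lib.append(build_filament(filament_balls))
    if include_membrane:
        lib.append(build_membrane(*membrane_shape))
    return lib
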