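"""Multi-ball models of macromolecules and deformable ultrastructures.

A macromolecule is coarse-grained from its atomic coordinates into a small
number of balls by k-means clustering: every cluster becomes a ball whose
center is the cluster centroid and whose radius is the distance to the
farthest member atom, so the balls jointly cover all atoms.  Balls of a
rigid macromolecule are fully connected by stiff harmonic bonds, which
fixes their relative positions; filaments (bead chains) and membranes
(bead meshes) carry sparser topologies with free bond angles, which makes
them inextensible but bendable.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "AtomCloud",
    "Ball",
    "Topology",
    "Structure",
    "parse_pdb_atoms",
    "cluster_count",
    "coarse_grain",
    "build_filament",
    "build_membrane",
    "write_ball_pdb",
    "write_topology",
    "read_topology",
    "mc_union_volume",
    "ATOMS_PER_BALL",
    "BALL_MASS",
    "DEFAULT_KB",
    "FILAMENT_BALL_DIAMETER",
    "MEMBRANE_BALL_DIAMETER",
]

#: One ball represents this many atoms; also the mass assigned to each ball.
ATOMS_PER_BALL = 5000
BALL_MASS = 5000.0
#: Harmonic bond stiffness shared by rigid and deformable structures.
DEFAULT_KB = 2000.0
#: Default bead diameters for deformable ultrastructures (internal units ~ Å).
FILAMENT_BALL_DIAMETER = 40.0
MEMBRANE_BALL_DIAMETER = 80.0


def mc_union_volume(
    centers: np.ndarray,
    radii: np.ndarray,
    n_samples: int = 200_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo estimate of the union volume of a set of spheres.

    Samples uniformly in the bounding box of the spheres and counts hits.
    Used to quantify how much space a multi-ball model saves over the
    single bounding-sphere model.
    """
    centers = np.asarray(centers, float).reshape(-1, 3)
    radii = np.asarray(radii, float).reshape(-1)
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    rng = np.random.default_rng(seed)
    pts = lo + rng.random((n_samples, 3)) * (hi - lo)
    d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
    inside = np.any(d <= radii[None, :], axis=1)
    return float(np.prod(hi - lo) * inside.mean())


class PDBParseError(ValueError):
    """Raised when a structure file yields no usable atom coordinates."""


@dataclass(frozen=True)
class AtomCloud:
    """Raw atomic coordinates (Å) read from a structure file or synthesized."""

    coords: np.ndarray  # (n, 3) float
    source_id: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError("AtomCloud needs an (n, 3) array with n >= 1")
        if not np.all(np.isfinite(coords)):
            raise ValueError("AtomCloud coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[0])


@dataclass(frozen=True)
class Ball:
    """A pseudo-particle: cluster centroid, covering radius, mass."""

    center: np.ndarray
    radius: float
    mass: float = BALL_MASS

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float).reshape(3)
        if self.radius < 0:
            raise ValueError("ball radius must be >= 0")
        if self.mass <= 0:
            raise ValueError("ball mass must be > 0")
        object.__setattr__(self, "center", center)


@dataclass
class Topology:
    """Bond (pair) and angle (triple) terms with equilibrium values.

    ``bonds`` rows are ``(i, j, r0, kb)`` with ``i < j``; ``angles`` rows are
    ``(i, j, k, theta0, ktheta)`` with the vertex at the middle ball ``j``.
    Indices are 0-based and local to the owning structure.
    """

    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))
    angles: np.ndarray = field(default_factory=lambda: np.empty((0, 5)))

    def __post_init__(self) -> None:
        self.bonds = np.asarray(self.bonds, dtype=float).reshape(-1, 4)
        self.angles = np.asarray(self.angles, dtype=float).reshape(-1, 5)
        pairs = {(int(i), int(j)) for i, j, *_ in self.bonds}
        if len(pairs) != len(self.bonds):
            raise ValueError("duplicate bonds in topology")
        for i, j, r0, _ in self.bonds:
            if int(i) == int(j):
                raise ValueError("bond endpoints must be distinct")
            if r0 <= 0:
                raise ValueError("bond equilibrium length must be > 0")
        for *_, theta0, _k in self.angles:
            if not (0 < theta0 <= math.pi + 1e-12):
                raise ValueError("equilibrium angle must lie in (0, pi]")

    @property
    def n_bonds(self) -> int:
        return int(self.bonds.shape[0])

    def degrees(self, n_balls: int) -> np.ndarray:
        """Bond degree of each of ``n_balls`` balls."""
        deg = np.zeros(n_balls, dtype=int)
        for i, j, *_ in self.bonds:
            deg[int(i)] += 1
            deg[int(j)] += 1
        return deg


@dataclass
class Structure:
    """A named multi-ball model with its bonded topology.

    ``kind`` is ``"rigid"`` (fully connected, non-deformable), ``"filament"``
    (chain) or ``"membrane"`` (mesh).  ``cluster_labels`` maps each source
    atom to its ball for coarse-grained structures.
    """

    kind: str
    balls: list[Ball]
    topology: Topology
    label: str = ""
    cluster_labels: np.ndarray | None = None

    KINDS = ("rigid", "filament", "membrane")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown structure kind {self.kind!r}")

    @property
    def n_balls(self) -> int:
        return len(self.balls)

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.balls], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([b.radius for b in self.balls], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.balls], dtype=float)

    @property
    def deformable(self) -> bool:
        return self.kind != "rigid"

    def bounding_radius(self, centers: np.ndarray | None = None) -> float:
        """Radius of the sphere around the centroid covering every ball."""
        c = self.centers if centers is None else np.asarray(centers, float)
        centroid = c.mean(axis=0)
        return float(np.max(np.linalg.norm(c - centroid, axis=1) + self.radii))


# ---------------------------------------------------------------------------
# parsing


def parse_pdb_atoms(pdb_text: str, source_id: str = "") -> AtomCloud:
    """Extract atom coordinates (Å) from PDB-format text.

    Both ATOM and HETATM records are kept; alternate locations keep the
    first occurrence; only the first MODEL is read.  Coordinates come from
    the fixed columns 31-54 of the record.
    """
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(io.StringIO(pdb_text))
    try:
        atoms = f.get_structure(model=1, altloc="first")
    except Exception as exc:  # no coordinate records at all
        raise PDBParseError(
            f"no ATOM/HETATM coordinates in {source_id or 'input'}"
        ) from exc
    if atoms.array_length() == 0:
        raise PDBParseError(f"no ATOM/HETATM coordinates in {source_id or 'input'}")
    return AtomCloud(np.asarray(atoms.coord, dtype=float), source_id=source_id)


# ---------------------------------------------------------------------------
# coarse graining


def cluster_count(n_atoms: int) -> int:
    """Number of balls for a macromolecule of ``n_atoms`` atoms.

    One ball per started block of 5000 atoms, floored at three so the model
    always yields two linearly independent internal vectors for pose
    extraction.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    return max(3, math.ceil(n_atoms / ATOMS_PER_BALL))


def coarse_grain(
    cloud: AtomCloud,
    k: int | None = None,
    seed: int = 0,
    collinear_tol: float = 1e-8,
) -> Structure:
    """Coarse-grain an atom cloud into a rigid multi-ball model.

    Atoms are partitioned into ``k`` clusters by k-means on their
    coordinates; each cluster becomes a ball at the cluster centroid with
    radius equal to the largest centroid-to-member distance.  Every ball
    carries mass 5000 (one ball per 5000 atoms).  The balls are fully
    connected by stiff bonds whose equilibrium lengths are the initial
    center-center distances, which makes the model rigid.

    Raises if ``k`` exceeds the atom count or if the resulting centers are
    collinear (pose extraction needs two linearly independent vectors).
    """
    if k is None:
        k = cluster_count(cloud.n_atoms)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > cloud.n_atoms:
        raise ValueError(f"k={k} exceeds atom count {cloud.n_atoms}")

    km = KMeans(n_clusters=k, init="random", n_init=1, max_iter=300,
                random_state=_wrap_seed(seed))
    labels = km.fit_predict(cloud.coords)
    centers = km.cluster_centers_

    balls = []
    for ci in range(k):
        member = cloud.coords[labels == ci]
        # recompute the centroid exactly from the final assignment
        center = member.mean(axis=0)
        radius = float(np.max(np.linalg.norm(member - center, axis=1)))
        balls.append(Ball(center=center, radius=radius, mass=BALL_MASS))
        centers[ci] = center

    _check_not_collinear(centers, collinear_tol)

    bonds = []
    for i in range(k):
        for j in range(i + 1, k):
            r0 = float(np.linalg.norm(centers[i] - centers[j]))
            if r0 <= 0:
                raise ValueError(
                    "degenerate cloud: two cluster centers coincide"
                )
            bonds.append((i, j, r0, DEFAULT_KB))
    return Structure(
        kind="rigid",
        balls=balls,
        topology=Topology(bonds=np.array(bonds)),
        label=cloud.source_id,
        cluster_labels=labels,
    )


def _wrap_seed(seed: int) -> int:
    return int(seed) % (2**32)


def _check_not_collinear(centers: np.ndarray, tol: float) -> None:
    if len(centers) < 3:
        return
    v = centers[1:] - centers[0]
    # rank < 2 means all centers lie on one line (or point)
    if np.linalg.matrix_rank(v, tol=tol * max(1.0, np.abs(v).max())) < 2:
        raise ValueError(
            "cluster centers are collinear; cannot form two linearly "
            "independent vectors for pose extraction"
        )


# ---------------------------------------------------------------------------
# deformable builders


def build_filament(
    n_balls: int,
    ball_radius: float = FILAMENT_BALL_DIAMETER / 2,
    spacing: float | None = None,
    origin: np.ndarray | tuple = (0.0, 0.0, 0.0),
    axis: np.ndarray | tuple = (1.0, 0.0, 0.0),
    label: str = "filament",
) -> Structure:
    """A straight bead chain of ``n_balls`` equal balls.

    Consecutive beads are bonded (stiff, equilibrium = spacing) so the chain
    cannot stretch; interior angle terms carry zero stiffness so it bends
    freely.  ``spacing`` defaults to the bead diameter (beads touching).
    """
    if n_balls < 2:
        raise ValueError("a filament needs at least 2 balls")
    if spacing is None:
        spacing = 2.0 * ball_radius
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    origin = np.asarray(origin, dtype=float)

    balls = [
        Ball(center=origin + i * spacing * axis, radius=ball_radius)
        for i in range(n_balls)
    ]
    bonds = [(i, i + 1, spacing, DEFAULT_KB) for i in range(n_balls - 1)]
    angles = [
        (i - 1, i, i + 1, math.pi, 0.0) for i in range(1, n_balls - 1)
    ]
    return Structure(
        kind="filament",
        balls=balls,
        topology=Topology(bonds=np.array(bonds, float).reshape(-1, 4),
                          angles=np.array(angles, float).reshape(-1, 5)),
        label=label,
    )


def build_membrane(
    m: int,
    n: int,
    ball_radius: float = MEMBRANE_BALL_DIAMETER / 2,
    spacing: float | None = None,
    origin: np.ndarray | tuple = (0.0, 0.0, 0.0),
    normal: np.ndarray | tuple = (0.0, 0.0, 1.0),
    label: str = "membrane",
) -> Structure:
    """A planar m x n bead mesh.

    Every bead is bonded to its four axial and four diagonal neighbours
    (each bond listed once), so corner beads have degree 3, non-corner edge
    beads degree 5 and interior beads degree 8.  Bonds are stiff with
    equilibrium equal to the initial distance; angle stiffness is zero, so
    the sheet bends but does not stretch.
    """
    if m < 2 or n < 2:
        raise ValueError("a membrane needs m >= 2 and n >= 2")
    if spacing is None:
        spacing = 2.0 * ball_radius
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    origin = np.asarray(origin, dtype=float)

    # two in-plane unit vectors orthogonal to the normal
    trial = np.array([1.0, 0.0, 0.0])
    if abs(normal @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    u = trial - (trial @ normal) * normal
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)

    def idx(a: int, b: int) -> int:
        return a * n + b

    centers = [
        origin + a * spacing * u + b * spacing * v
        for a in range(m)
        for b in range(n)
    ]
    balls = [Ball(center=c, radius=ball_radius) for c in centers]

    bonds = []
    for a in range(m):
        for b in range(n):
            for da, db in ((0, 1), (1, 0), (1, 1), (1, -1)):
                aa, bb = a + da, b + db
                if 0 <= aa < m and 0 <= bb < n:
                    i, j = idx(a, b), idx(aa, bb)
                    r0 = float(np.linalg.norm(centers[i] - centers[j]))
                    bonds.append((min(i, j), max(i, j), r0, DEFAULT_KB))
    angles = []
    for a in range(m):
        for b in range(1, n - 1):
            angles.append((idx(a, b - 1), idx(a, b), idx(a, b + 1), math.pi, 0.0))
    for b in range(n):
        for a in range(1, m - 1):
            angles.append((idx(a - 1, b), idx(a, b), idx(a + 1, b), math.pi, 0.0))
    return Structure(
        kind="membrane",
        balls=balls,
        topology=Topology(bonds=np.array(bonds, float).reshape(-1, 4),
                          angles=np.array(angles, float).reshape(-1, 5)),
        label=label,
    )


# ---------------------------------------------------------------------------
# pseudo-atom / topology file output


def write_ball_pdb(structure: Structure, path, centers: np.ndarray | None = None) -> None:
    """Write a ball model as a pseudo-atom PDB (radius in the B-factor)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    c = structure.centers if centers is None else np.asarray(centers, float)
    arr = struc.AtomArray(structure.n_balls)
    arr.coord = c.astype(np.float32)
    arr.chain_id[:] = "A"
    arr.res_id[:] = np.arange(1, structure.n_balls + 1)
    arr.res_name[:] = "BAL"
    arr.atom_name[:] = "C"
    arr.element[:] = "C"
    arr.hetero[:] = True
    arr.set_annotation("b_factor", structure.radii.astype(float))
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))


def write_topology(structure: Structure, path) -> None:
    """Plain-text topology: one ``BOND i j r0 kb`` / ``ANGLE i j k theta0 kt``
    line per term, 0-based indices."""
    with open(path, "w") as fh:
        for i, j, r0, kb in structure.topology.bonds:
            fh.write(f"BOND {int(i)} {int(j)} {r0:.6f} {kb:.6f}\n")
        for i, j, k, t0, kt in structure.topology.angles:
            fh.write(f"ANGLE {int(i)} {int(j)} {int(k)} {t0:.6f} {kt:.6f}\n")


def read_topology(path) -> Topology:
    bonds, angles = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "BOND":
                i, j, r0, kb = parts[1:5]
                bonds.append((int(i), int(j), float(r0), float(kb)))
            elif parts[0] == "ANGLE":
                i, j, k, t0, kt = parts[1:6]
                angles.append((int(i), int(j), int(k), float(t0), float(kt)))
            else:
                raise ValueError(f"unrecognised topology record: {parts[0]}")
    return Topology(bonds=np.array(bonds, float).reshape(-1, 4),
                    angles=np.array(angles, float).reshape(-1, 5))
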