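"""Force field and packing engine.

Structures are packed by moving every ball under three force classes:

* bonded terms — harmonic bond stretching ``U = k_b (r - r0)^2`` and
  harmonic angle bending ``U = k_theta (theta - theta0)^2``;
* non-bonded terms — a Lennard-Jones potential
  ``U = eps [(Rmin/r)^12 - 2 (Rmin/r)^6]`` with a linear switching taper
  between the switch distance S and the cutoff C, acting between all
  non-bonded ball pairs to prevent overlap;
* an external centripetal field pulling every ball toward the scene
  center: magnitude ``10 * ||x||`` inside radius 300, constant 3000 beyond
  (continuous at the boundary), zero exactly at the center.

The integrator follows the update rule ``v = a * dt``, ``dx = v * dt`` with
the acceleration recomputed from the instantaneous force each step and no
velocity carried between steps — an overdamped, first-order scheme whose
fixed points are force balances and which drives the monotone inward drift
that produces crowding.  All lengths are a single internal unit (~ Å);
time and mass are internal units (dt = 1, ball mass 5000).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structures import Structure

__all__ = [
    "ForceFieldParams",
    "Scene",
    "Trajectory",
    "external_force",
    "bond_energy",
    "bond_forces",
    "angle_energy",
    "angle_forces",
    "lj_energy",
    "lj_forces",
    "total_forces",
    "step",
    "place_structures",
    "run_packing",
]


@dataclass(frozen=True)
class ForceFieldParams:
    """Force-field constants, in internal units (lengths ~ Å).

    Defaults reproduce the published packing protocol: stiff bonds
    (k_b = 2000) rigidify fully connected macromolecules and make chains
    and meshes inextensible; zero angle stiffness leaves them bendable;
    the LJ well depth is 1 with the pair minimum at contact
    (Rmin = r_i + r_j); the switch/cutoff pair is 600/610; the external
    field ramps at 10 per unit length up to 3000 at radius 300.
    """

    k_b: float = 2000.0
    k_theta: float = 0.0
    epsilon: float = 1.0
    switchdist: float = 600.0
    cutoff: float = 610.0
    ext_inner_radius: float = 300.0
    ext_slope: float = 10.0
    ball_mass: float = 5000.0
    dt: float = 1.0
    n_substeps: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.switchdist < self.cutoff):
            raise ValueError("need 0 < switchdist < cutoff")
        if self.ext_inner_radius <= 0 or self.ext_slope < 0:
            raise ValueError("external-field parameters must be positive")
        if self.n_substeps < 1:
            raise ValueError("n_substeps must be >= 1")

    @property
    def ext_max(self) -> float:
        """Plateau force; equals slope * inner radius so the field is
        continuous at the inner-radius boundary."""
        return self.ext_slope * self.ext_inner_radius


# ---------------------------------------------------------------------------
# individual potential terms


def external_force(
    position: np.ndarray,
    params: ForceFieldParams,
    center: np.ndarray = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Centripetal field force on a ball at ``position``.

    Magnitude ``slope * d`` for distance d inside the inner radius and the
    constant plateau beyond it; direction toward ``center``; exactly zero
    at the center.
    """
    position = np.asarray(position, dtype=float)
    center = np.asarray(center, dtype=float)
    rel = position - center
    d = float(np.linalg.norm(rel))
    if d == 0.0:
        return np.zeros(3)
    mag = params.ext_slope * d if d < params.ext_inner_radius else params.ext_max
    return -mag * rel / d


def bond_energy(r: float, r0: float, k_b: float) -> float:
    """Harmonic bond energy ``k_b (r - r0)^2``."""
    if r <= 0:
        raise ValueError("bond length must be > 0")
    return k_b * (r - r0) ** 2


def bond_forces(
    xi: np.ndarray, xj: np.ndarray, r0: float, k_b: float
) -> tuple[np.ndarray, np.ndarray]:
    """Forces on the two balls of a bond; equal and opposite along the axis."""
    xi = np.asarray(xi, float)
    xj = np.asarray(xj, float)
    d = xi - xj
    r = float(np.linalg.norm(d))
    if r == 0.0:
        raise ValueError("coincident ball centers: bond force undefined")
    f = -2.0 * k_b * (r - r0) * d / r
    return f, -f


def angle_energy(theta: float, theta0: float, k_theta: float) -> float:
    """Harmonic angle energy ``k_theta (theta - theta0)^2``."""
    return k_theta * (theta - theta0) ** 2


def angle_forces(
    xi: np.ndarray, xj: np.ndarray, xk: np.ndarray, theta0: float, k_theta: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forces on an angle triple with the vertex at the middle ball ``j``.

    Gradient of the harmonic angle energy over the three positions; the
    three forces sum to zero and exert no net torque.  ``k_theta = 0``
    (the deformable default) short-circuits to zero forces.
    """
    xi, xj, xk = (np.asarray(a, float) for a in (xi, xj, xk))
    u = xi - xj
    v = xk - xj
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise ValueError("degenerate angle: zero-length bond vector")
    if k_theta == 0.0:
        z = np.zeros(3)
        return z, z.copy(), z.copy()
    uh, vh = u / nu, v / nv
    c = float(np.clip(uh @ vh, -1.0, 1.0))
    s = max(np.sqrt(1.0 - c * c), 1e-12)
    theta = float(np.arccos(c))
    dU = 2.0 * k_theta * (theta - theta0)
    dth_di = (c * uh - vh) / (nu * s)
    dth_dk = (c * vh - uh) / (nv * s)
    fi = -dU * dth_di
    fk = -dU * dth_dk
    return fi, -(fi + fk), fk


def _lj_unswitched(r: np.ndarray, rmin: np.ndarray, eps: float):
    q6 = (rmin / r) ** 6
    u = eps * (q6 * q6 - 2.0 * q6)
    # dU/dr
    du = -12.0 * eps / r * (q6 * q6 - q6)
    return u, du


def lj_energy(r: float, rmin: float, params: ForceFieldParams) -> float:
    """Switched Lennard-Jones pair energy at separation ``r``.

    Full LJ below the switch distance, linearly tapered to zero between
    switch distance and cutoff, identically zero beyond the cutoff.
    """
    if r <= 0:
        raise ValueError("pair distance must be > 0")
    S, C = params.switchdist, params.cutoff
    if r >= C:
        return 0.0
    u, _ = _lj_unswitched(np.asarray(r, float), np.asarray(rmin, float), params.epsilon)
    if r < S:
        return float(u)
    return float(u * (C - r) / (C - S))


def lj_forces(
    xi: np.ndarray, xj: np.ndarray, rmin: float, params: ForceFieldParams
) -> tuple[np.ndarray, np.ndarray]:
    """Pair forces of the switched LJ potential (equal and opposite)."""
    xi = np.asarray(xi, float)
    xj = np.asarray(xj, float)
    d = xi - xj
    r = float(np.linalg.norm(d))
    if r == 0.0:
        raise ValueError("coincident ball centers: LJ force undefined")
    S, C = params.switchdist, params.cutoff
    if r >= C:
        z = np.zeros(3)
        return z, z.copy()
    u, du = _lj_unswitched(np.asarray(r, float), np.asarray(rmin, float), params.epsilon)
    if r < S:
        dtot = du
    else:
        sw = (C - r) / (C - S)
        dtot = du * sw - u / (C - S)
    f = -float(dtot) * d / r
    return f, -f


# ---------------------------------------------------------------------------
# scene


@dataclass
class Scene:
    """A set of structures placed in a box, with evolving ball positions.

    Positions are stored in one global ``(N, 3)`` array; each structure
    owns the contiguous slice ``offsets[s] : offsets[s+1]``.  The snapshot
    taken at construction (t = 0) is kept immutable for pose extraction.
    The external field is anchored at ``center``.
    """

    structures: list[Structure]
    positions: np.ndarray
    box: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    initial_positions: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        n = sum(s.n_balls for s in self.structures)
        if self.positions.shape[0] != n:
            raise ValueError("position array length != total ball count")
        if self.initial_positions is None:
            self.initial_positions = self.positions.copy()
        self.initial_positions.setflags(write=False)
        self._build_tables()

    def _build_tables(self) -> None:
        offs = np.cumsum([0] + [s.n_balls for s in self.structures])
        self.offsets = offs
        bonds, angles = [], []
        radii, masses = [], []
        for s, o in zip(self.structures, offs[:-1]):
            for i, j, r0, kb in s.topology.bonds:
                bonds.append((int(i) + o, int(j) + o, r0, kb))
            for i, j, k, t0, kt in s.topology.angles:
                angles.append((int(i) + o, int(j) + o, int(k) + o, t0, kt))
            radii.append(s.radii)
            masses.append(s.masses)
        self.bond_table = np.array(bonds, float).reshape(-1, 4)
        self.angle_table = np.array(angles, float).reshape(-1, 5)
        self.ball_radii = np.concatenate(radii) if radii else np.empty(0)
        self.ball_masses = np.concatenate(masses) if masses else np.empty(0)
        self.excluded_pairs = {
            (min(int(b[0]), int(b[1])), max(int(b[0]), int(b[1])))
            for b in self.bond_table
        }

    @property
    def n_balls(self) -> int:
        return int(self.positions.shape[0])

    def structure_slice(self, idx: int) -> slice:
        return slice(int(self.offsets[idx]), int(self.offsets[idx + 1]))

    def structure_positions(self, idx: int, initial: bool = False) -> np.ndarray:
        src = self.initial_positions if initial else self.positions
        return src[self.structure_slice(idx)]


@dataclass
class Trajectory:
    """Ordered position snapshots of a packing run."""

    frames: list[tuple[int, np.ndarray]] = field(default_factory=list)

    def add(self, step_index: int, positions: np.ndarray) -> None:
        if self.frames and step_index <= self.frames[-1][0]:
            raise ValueError("frame step indices must be strictly increasing")
        self.frames.append((step_index, positions.copy()))

    def write_xyz(self, path) -> None:
        with open(path, "w") as fh:
            for step_index, pos in self.frames:
                fh.write(f"{len(pos)}\nstep {step_index}\n")
                for x, y, z in pos:
                    fh.write(f"C {x:.4f} {y:.4f} {z:.4f}\n")


# ---------------------------------------------------------------------------
# force summation and integration


def total_forces(
    scene: Scene,
    params: ForceFieldParams,
    neighbor: str = "kdtree",
) -> np.ndarray:
    """Per-ball sum of bonded, non-bonded and external forces.

    ``neighbor`` selects the non-bonded pair search: ``"kdtree"`` (cutoff
    query; default) or ``"all"`` (exhaustive all-pairs reference).  Both
    yield identical forces since pairs beyond the cutoff contribute zero.
    """
    x = scene.positions
    n = scene.n_balls
    forces = np.zeros((n, 3))

    # bonds, vectorized
    bt = scene.bond_table
    if len(bt):
        bi = bt[:, 0].astype(int)
        bj = bt[:, 1].astype(int)
        d = x[bi] - x[bj]
        r = np.linalg.norm(d, axis=1)
        if np.any(r == 0.0):
            k = int(np.argmin(r))
            raise FloatingPointError(
                f"coincident bonded balls {bi[k]} and {bj[k]}"
            )
        f = (-2.0 * bt[:, 3] * (r - bt[:, 2]) / r)[:, None] * d
        np.add.at(forces, bi, f)
        np.add.at(forces, bj, -f)

    # angles (zero-stiffness terms skipped)
    at = scene.angle_table
    for i, j, k, t0, kt in at:
        if kt == 0.0:
            continue
        fi, fj, fk = angle_forces(x[int(i)], x[int(j)], x[int(k)], t0, kt)
        forces[int(i)] += fi
        forces[int(j)] += fj
        forces[int(k)] += fk

    # non-bonded switched LJ
    if neighbor == "kdtree":
        pairs = cKDTree(x).query_pairs(params.cutoff, output_type="ndarray")
    elif neighbor == "all":
        ii, jj = np.triu_indices(n, k=1)
        pairs = np.column_stack([ii, jj])
    else:
        raise ValueError(f"unknown neighbor mode {neighbor!r}")
    if len(pairs):
        keep = np.array(
            [
                (int(i), int(j)) not in scene.excluded_pairs
                for i, j in np.sort(pairs, axis=1)
            ]
        )
        pairs = pairs[keep]
    if len(pairs):
        pi, pj = pairs[:, 0], pairs[:, 1]
        d = x[pi] - x[pj]
        r = np.linalg.norm(d, axis=1)
        if np.any(r == 0.0):
            k = int(np.argmin(r))
            raise FloatingPointError(
                f"coincident non-bonded balls {pi[k]} and {pj[k]}"
            )
        rmin = scene.ball_radii[pi] + scene.ball_radii[pj]
        S, C = params.switchdist, params.cutoff
        inside = r < C
        u, du = _lj_unswitched(r, rmin, params.epsilon)
        sw_zone = (r >= S) & inside
        sw = np.where(sw_zone, (C - r) / (C - S), 1.0)
        dtot = np.where(sw_zone, du * sw - u / (C - S), du)
        dtot = np.where(inside, dtot, 0.0)
        f = (-dtot / r)[:, None] * d
        np.add.at(forces, pi, f)
        np.add.at(forces, pj, -f)

    # external centripetal field
    rel = x - scene.center
    dist = np.linalg.norm(rel, axis=1)
    mag = np.where(dist < params.ext_inner_radius,
                   params.ext_slope * dist, params.ext_max)
    nonzero = dist > 0
    forces[nonzero] -= (mag[nonzero] / dist[nonzero])[:, None] * rel[nonzero]
    return forces


def step(scene: Scene, params: ForceFieldParams, neighbor: str = "kdtree") -> np.ndarray:
    """Advance the scene one time step in place; returns the displacements.

    Per ball: ``a = F / m``, ``v = a * dt``, ``dx = v * dt``; velocity is
    re-derived from the instantaneous force and never carried between
    steps, making the update an overdamped first-order flow.  The step is
    integrated in ``n_substeps`` explicit-Euler substeps of the same flow:
    for a ball in a smooth field the displacement per step is unchanged
    (e.g. exactly ``(F/m) dt^2`` under a constant force), while stiff
    bonds — whose one-shot update would over-shoot and oscillate
    divergently — relax smoothly toward equilibrium.
    """
    start = scene.positions.copy()
    frac = 1.0 / params.n_substeps
    for _ in range(params.n_substeps):
        forces = total_forces(scene, params, neighbor=neighbor)
        if not np.all(np.isfinite(forces)):
            bad = int(np.argwhere(~np.isfinite(forces))[0, 0])
            raise FloatingPointError(f"non-finite force on ball {bad}")
        scene.positions += forces / scene.ball_masses[:, None] * params.dt**2 * frac
    return scene.positions - start


def place_structures(
    library: list[Structure],
    counts: list[int],
    box,
    seed: int = 0,
    center=(0.0, 0.0, 0.0),
    max_tries: int = 2000,
) -> Scene:
    """Place ``counts[i]`` copies of ``library[i]`` at random in a box.

    Each copy gets a uniform random orientation (uniform over the rotation
    group) and a uniform random centroid position such that all copies'
    bounding spheres are pairwise disjoint and inside the box; rejection
    sampling with a bounded retry budget.  Deterministic under ``seed``.
    """
    if len(counts) != len(library):
        raise ValueError("counts must align with library")
    box = np.asarray(box, dtype=float).reshape(3)
    center = np.asarray(center, dtype=float).reshape(3)
    rng = np.random.default_rng(seed)

    inst: list[tuple[Structure, float]] = []
    for s, c in zip(library, counts):
        inst.extend([(s, s.bounding_radius())] * int(c))
    for s, rad in inst:
        if np.any(2 * rad > box):
            raise ValueError(
                f"structure {s.label!r} (bounding diameter {2*rad:.1f}) "
                "does not fit in the box"
            )
    sphere_vol = sum(4.0 / 3.0 * np.pi * r**3 for _, r in inst)
    if sphere_vol > float(np.prod(box)):
        raise ValueError("box too small: bounding spheres exceed box volume")

    # place largest bounding spheres first; restart the whole scene if a
    # sphere cannot be fitted (sequential rejection can paint itself into
    # a corner in tight boxes)
    order = sorted(range(len(inst)), key=lambda i: -inst[i][1])
    centers_by_idx: dict[int, np.ndarray] = {}
    for _ in range(max(1, max_tries // 100)):
        centers_by_idx.clear()
        placed: list[tuple[np.ndarray, float]] = []
        failed = False
        for idx in order:
            rad = inst[idx][1]
            lo = -box / 2 + rad
            hi = box / 2 - rad
            for _ in range(100):
                pos = center + lo + rng.random(3) * (hi - lo)
                if all(
                    np.linalg.norm(pos - pc) >= rad + pr for pc, pr in placed
                ):
                    placed.append((pos, rad))
                    centers_by_idx[idx] = pos
                    break
            else:
                failed = True
                break
        if not failed:
            break
    else:
        raise RuntimeError("placement failed after retries; use a larger box")

    structures: list[Structure] = []
    blocks: list[np.ndarray] = []
    for idx, (s, _) in enumerate(inst):
        local = s.centers - s.centers.mean(axis=0)
        rot = Rotation.random(random_state=rng).as_matrix()
        structures.append(s)
        blocks.append(local @ rot.T + centers_by_idx[idx])
    positions = (
        np.concatenate(blocks) if blocks else np.empty((0, 3))
    )
    return Scene(structures=structures, positions=positions, box=box, center=center)


def run_packing(
    scene: Scene,
    params: ForceFieldParams,
    max_steps: int = 2000,
    snapshot_every: int = 100,
    tol: float = 1e-3,
    window: int = 50,
    neighbor: str = "kdtree",
) -> Trajectory:
    """Iterate the integrator until crowding converges or ``max_steps``.

    Stops early when the mean per-ball displacement magnitude averaged
    over a trailing ``window`` of steps falls below ``tol``.  Snapshots
    (including the initial state and the final state) are recorded every
    ``snapshot_every`` steps.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    traj = Trajectory()
    traj.add(0, scene.positions)
    recent: list[float] = []
    t = 0
    for t in range(1, max_steps + 1):
        dx = step(scene, params, neighbor=neighbor)
        recent.append(float(np.linalg.norm(dx, axis=1).mean()))
        if len(recent) > window:
            recent.pop(0)
        if t % snapshot_every == 0:
            traj.add(t, scene.positions)
        if len(recent) == window and np.mean(recent) < tol:
            break
    if traj.frames[-1][0] != t:
        traj.add(t, scene.positions)
    return traj
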