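# Methods

This note records the model, the parameter choices, the numerical
decisions, and what the synthetic fixtures do and do not establish.

## Units

All lengths live in one internal unit, nominally 1 Å; printed constants
are used as-is (field radius 300, switch distance 600, cutoff 610, box
edges 500 or 1200, ball radii tens of units). Voxels default to 10 units
(1 nm) and the rendering resolution to 40 units (4 nm). Mass (5000 per
ball) and the time step (δt = 1) are internal units as well; together
with the force constants they define a consistent overdamped dynamics,
not a physical unit system, and every value is overridable through
`ForceFieldParams` and the run configuration.

## Coarse graining

Atoms are read from PDB text (ATOM and HETATM records, first model,
first alternate location) or synthesized. k-means (scikit-learn,
`init="random"` so the initial centers are drawn from the atoms,
`n_init=1`, max 300 iterations, seeded) partitions the coordinates into
k = max(3, ⌈n/5000⌉) clusters. The ball radius is the exact maximum
centroid-to-member distance, so the balls cover every atom by
construction; the centroid is recomputed from the final assignment so
the covering property holds exactly rather than up to k-means'
convergence tolerance. Ball mass is fixed at 5000 — with one ball per
5000 atoms the rendered mass is proportional to the atom count. Centers
that end up collinear (rank < 2 of the center differences) are rejected
because pose extraction needs two linearly independent internal vectors;
the k ≥ 3 floor exists for the same reason.

Rigid bodies carry no explicit angle terms: full bond connectivity with
stiff bonds already fixes the internal geometry (verified by the
rigidity tests). `k_theta` is exposed for experiments but defaults to
zero everywhere.

## Deformable builders

Filaments default to bead diameter 40 and membranes to 80, with bead
spacing equal to the diameter: touching beads neither overlap initially
nor leave gaps along the contour. Bonds get the shared stiffness 2000 and
equilibrium equal to the construction spacing; interior angle triples
(chain) and row/column triples (mesh) are recorded with equilibrium π
and zero stiffness. The mesh bonds run to the four axial and four
diagonal neighbours, giving the degree pattern 3 (corner) / 5 (edge) / 8
(interior); the diagonals are what resist in-plane shear while leaving
out-of-plane bending free.

## Force field and integrator

* Bond: U = k_b (r − r0)², force −dU/dr along the pair axis.
* Angle: U = k_θ (θ − θ0)² with the vertex at the middle ball of the
  triple; the analytic gradient distributes over the three positions
  with zero net force and torque. (A printed formula elsewhere places
  the vertex at the first particle of the triple; the figure and the
  chain triples (i−1, i, i+1) imply the middle ball, which is what we
  implement. With k_θ = 0 defaults the choice is inert.)
* Lennard-Jones: U = ε[(Rmin/r)¹² − 2(Rmin/r)⁶], pair minimum at
  contact (Rmin = r_i + r_j), well depth ε = 1, multiplied by a linear
  switching factor between S = 600 and C = 610 and zero beyond C. The
  force includes the switching derivative, so analytic force equals
  −dU/dr everywhere except the measure-zero kinks at S and C.
  Electrostatics is omitted (all charges zero). LJ is skipped for
  directly bonded pairs only; non-bonded intra-chain and intra-mesh
  pairs do interact, which is what stops a curling filament from passing
  through itself.
* External field: magnitude 10·‖x‖ below radius 300, constant 3000
  beyond, direction toward the scene center, zero at the center; the
  two branches agree at the boundary.

The integrator re-derives velocity from the instantaneous force every
step (v = a·δt, Δx = v·δt) and never carries it, i.e. a first-order
overdamped update Δx = (F/m)·δt². Applied in a single shot this update
is unstable for stiff bonded networks: for a fully connected triangle
the breathing mode has an amplification factor of −1.4 per step at the
default constants, and perturbations grow until bonded balls collide.
We therefore integrate each time step as `n_substeps` (default 20)
explicit-Euler substeps of the same flow. For a ball in a smooth field
the per-step displacement is unchanged (a free ball beyond the plateau
radius moves exactly (3000/5000)·δt² = 0.6 per step), while the stiff
modes now relax monotonically; the default handles bond degrees up to
roughly 25 with margin, and the parameter is exposed for denser
connectivity.

Non-bonded pairs come from a k-d tree query at the cutoff; the force sum
is tested for exact agreement against an exhaustive all-pairs reference.
Placement draws uniform positions and uniform random rotations (uniform
over SO(3), not uniform Euler angles) with rejection until all bounding
spheres are pairwise disjoint. The packing loop stops at `max_steps` or
when the mean per-ball displacement over a 50-step window drops below
1e−3 units/step (empirical default, configurable; there is no published
stopping rule).

## Pose extraction

The rotation of a rigid structure is recovered from its first three ball
centers (non-collinear by the coarse-graining contract): the minimal
rotation taking the initial A→B direction onto the final one, composed
with the spin about the final A→B axis that carries the intermediate
image of A→C onto the final A→C. For exact rigid motions this
reproduces the true rotation to machine precision (tested over 1000
random motions). The matrix is factored as R = Rz(α)Ry(β)Rz(γ) with
β ∈ [0, π]; at gimbal lock (sin β below 1e−7) γ is set to zero and the
full spin folded into α, so matrices still round-trip. Antiparallel
inputs to the two-vector rotation use a deterministic perpendicular
axis (the unit axis along the smallest component of a, orthogonalized).
The displacement annotation follows the published sign convention
initial − final; a `forward` flag yields the geometric final − initial
vector. Deformable structures are annotated with zero rotation because
their density is rendered from the final bead positions directly.

## Rendering and noise

Each ball contributes an isotropic Gaussian with FWHM equal to the
target resolution, evaluated within 4σ and then normalized so its
discrete integral equals the ball mass exactly — mass conservation holds
to rounding regardless of truncation. Grids are Z,Y,X-major with voxel
centers at origin + (k+0.5, j+0.5, i+0.5)·voxel. Rigid structures are
rendered once in their initial orientation and mapped into the scene by
one inverse affine interpolation pass (rotation about the initial
centroid + subvoxel translation to the final centroid). The
interpolation default is cubic B-spline: with kernels of σ ≈ 1.7 voxels,
trilinear interpolation leaves ~5% voxel-wise RMS error against
re-rasterized balls while cubic leaves ~0.1%; `order=1` remains
available. SNR is the variance ratio Var(signal)/Var(noise) — the
definition matters for quoting SNR 1000/200 and is applied consistently
by `add_noise` and `measure_snr`. No missing wedge or CTF is modelled;
the noise is white by construction.

## Picking and scoring

The DoG uses scipy's separable 3-D Gaussian filters; the absolute
normalization of the kernel is irrelevant because only peak ranking and
the relative threshold T = m + t(M − m)/20 enter the result. Peaks are
strict 26-neighbourhood maxima; exact-tie plateaus that dominate their
boundary contribute their lexicographically smallest voxel, and a
constant volume has no peaks. Matching is one-to-one by distance,
implemented as a minimum-distance maximum-cardinality assignment over
the within-radius pairs, which coincides with a brute-force bipartite
matching (a purely greedy nearest-first scan can drop a match when two
particles compete for one pick; the assignment formulation cannot). A
permissive any-pick-within-radius mode exists for sensitivity analysis.
The fixed-count protocol (keep the K strongest peaks, K = number of
truth particles) makes precision, recall and F-score coincide, which is
the setting in which a 32/400 hit count yields P = R = F = 0.08.

## Synthetic fixtures and their limits

The fixture clouds (globular, rod, planar, dumbbell) are bounded
samplers whose `extent` is the true overall size, defaulting to 140
units — the middle of the 120–160 range typical of the macromolecules
the simulator targets, so force-field defaults behave comparably.
They have uniform internal density and no secondary structure, so tests
passing on them establish the geometry and dynamics contracts (ball
counts, coverage, rigidity, curling, scoring), not biological realism of
particle shapes. Real structures enter through `pdb_paths` in the run
configuration; the full published protocol (20 deposited structures,
20 copies each, 1200-unit box) is runnable but needs the PDB files and
hours of compute, so the shipped tests and the acceptance script use the
desk-scale analogues: 5-structure scenes in a 500-unit box packed for
2000 steps, a 9-bead filament and a 5×5 membrane run for 1500/800 steps,
64³ noise grids, and 20-blob picking phantoms.

## Known limitations

* The overdamped dynamics has no thermostat, no Brownian noise and no
  periodic boundaries; it is a packing engine, not a physical MD.
* Structures denser than ~25 bonds per ball need `n_substeps` raised.
* Rendering ignores the electron-optical chain (CTF, detector, missing
  wedge); the tomogram model is low-pass + white noise.
* The membrane's angle triples only span rows and columns, not
  diagonals; its bending stiffness comes entirely from bond geometry.
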