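import numpy as np
import pytest

from tomopack.dynamics import (
    ForceFieldParams,
    Scene,
    angle_energy,
    angle_forces,
    bond_energy,
    bond_forces,
    external_force,
    lj_energy,
    lj_forces,
    place_structures,
    run_packing,
    step,
    total_forces,
)
from tomopack.structures import Ball, Structure, Topology, build_filament

PARAMS = ForceFieldParams()


def two_ball_structure(r0=100.0, radius=30.0):
    balls = [Ball(center=(0, 0, 0), radius=radius), Ball(center=(r0, 0, 0), radius=radius)]
    topo = Topology(bonds=np.array([[0, 1, r0, 2000.0]]))
    return Structure(kind="filament", balls=balls, topology=topo)


class TestExternalField:
    def test_zero_at_center(self):
        np.testing.assert_array_equal(external_force((0, 0, 0), PARAMS), np.zeros(3))

    def test_linear_ramp_inside(self):
        f = external_force((100, 0, 0), PARAMS)
        np.testing.assert_allclose(f, [-1000.0, 0, 0])

    def test_plateau_outside(self):
        f = external_force((0, 500, 0), PARAMS)
        np.testing.assert_allclose(f, [0, -3000.0, 0])

    def test_continuous_at_boundary(self):
        inner = external_force((0, 0, 300 - 1e-9), PARAMS)
        outer = external_force((0, 0, 300 + 1e-9), PARAMS)
        assert np.linalg.norm(inner) == pytest.approx(3000.0, rel=1e-8)
        assert np.linalg.norm(outer) == pytest.approx(3000.0, rel=1e-8)


class TestBond:
    def test_equilibrium(self):
        assert bond_energy(100.0, 100.0, 2000.0) == 0.0
        fi, fj = bond_forces((0, 0, 0), (100, 0, 0), 100.0, 2000.0)
        np.testing.assert_allclose(fi, 0.0)
        np.testing.assert_allclose(fj, 0.0)

    def test_unit_stretch_energy(self):
        assert bond_energy(101.0, 100.0, 2000.0) == pytest.approx(2000.0)

    def test_coincident_centers_raise(self):
        with pytest.raises(ValueError):
            bond_forces((1, 1, 1), (1, 1, 1), 10.0, 2000.0)

    def test_newton_third_law(self, rng):
        for _ in range(20):
            xi, xj = rng.normal(size=(2, 3)) * 50
            fi, fj = bond_forces(xi, xj, 40.0, 2000.0)
            np.testing.assert_allclose(fi + fj, 0.0, atol=1e-9)


class TestAngle:
    def test_zero_stiffness_zero_force(self, rng):
        for _ in range(10):
            x = rng.normal(size=(3, 3)) * 10
            fi, fj, fk = angle_forces(x[0], x[1], x[2], 1.0, 0.0)
            assert not np.any(fi) and not np.any(fj) and not np.any(fk)

    def test_equilibrium_energy_zero(self):
        assert angle_energy(1.2, 1.2, 500.0) == 0.0

    def test_triple_forces_sum_and_torque_zero(self, rng):
        for _ in range(50):
            x = rng.normal(size=(3, 3)) * 20
            fi, fj, fk = angle_forces(x[0], x[1], x[2], 1.0, 300.0)
            np.testing.assert_allclose(fi + fj + fk, 0.0, atol=1e-9)
            torque = np.cross(x[0], fi) + np.cross(x[1], fj) + np.cross(x[2], fk)
            np.testing.assert_allclose(torque, 0.0, atol=1e-7)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            angle_forces((0, 0, 0), (0, 0, 0), (1, 0, 0), 1.0, 10.0)


class TestLennardJones:
    def test_well_depth_at_rmin(self):
        assert lj_energy(80.0, 80.0, PARAMS) == pytest.approx(-1.0)

    def test_zero_crossing(self):
        r = 80.0 * 2 ** (-1 / 6)
        assert lj_energy(r, 80.0, PARAMS) == pytest.approx(0.0, abs=1e-12)

    def test_zero_beyond_cutoff(self):
        assert lj_energy(611.0, 80.0, PARAMS) == 0.0
        fi, fj = lj_forces((0, 0, 0), (611.0, 0, 0), 80.0, PARAMS)
        assert not np.any(fi) and not np.any(fj)

    def test_switching_tapers_linearly(self):
        S, C = PARAMS.switchdist, PARAMS.cutoff
        mid = (S + C) / 2
        full = lj_energy(mid, 80.0, ForceFieldParams(switchdist=1000.0, cutoff=1001.0))
        assert lj_energy(mid, 80.0, PARAMS) == pytest.approx(full * 0.5)

    def test_r_zero_raises(self):
        with pytest.raises(ValueError):
            lj_energy(0.0, 80.0, PARAMS)


class TestGradientConsistency:
    """Analytic forces must equal minus the numeric energy gradient."""

    def test_bond_force_matches_numeric_gradient(self, rng):
        h = 1e-6
        for _ in range(100):
            r0 = rng.uniform(20, 200)
            r = r0 * rng.uniform(0.5, 1.5)
            fi, _ = bond_forces((r, 0, 0), (0, 0, 0), r0, 2000.0)
            num = -(bond_energy(r + h, r0, 2000.0) - bond_energy(r - h, r0, 2000.0)) / (2 * h)
            assert fi[0] == pytest.approx(num, rel=1e-6, abs=1e-6)

    def test_angle_forces_match_numeric_gradient(self, rng):
        h = 1e-6
        for _ in range(100):
            x = rng.normal(size=(3, 3)) * 30
            theta0 = rng.uniform(0.5, np.pi - 0.5)
            k = rng.uniform(10, 1000)

            def energy(flat):
                p = flat.reshape(3, 3)
                u = p[0] - p[1]
                v = p[2] - p[1]
                c = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                return angle_energy(np.arccos(np.clip(c, -1, 1)), theta0, k)

            analytic = np.concatenate(angle_forces(x[0], x[1], x[2], theta0, k))
            flat = x.ravel().copy()
            numeric = np.empty(9)
            for d in range(9):
                fp = flat.copy(); fp[d] += h
                fm = flat.copy(); fm[d] -= h
                numeric[d] = -(energy(fp) - energy(fm)) / (2 * h)
            np.testing.assert_allclose(analytic, numeric, rtol=1e-5, atol=1e-6)

    def test_lj_force_matches_numeric_gradient(self, rng):
        h = 1e-5
        for _ in range(100):
            rmin = rng.uniform(40, 120)
            # avoid the derivative kinks at S and C
            zone = rng.random()
            if zone < 0.7:
                r = rng.uniform(0.85 * rmin, PARAMS.switchdist - 1)
            else:
                r = rng.uniform(PARAMS.switchdist + 1, PARAMS.cutoff - 1)
            fi, fj = lj_forces((r, 0, 0), (0, 0, 0), rmin, PARAMS)
            num = -(lj_energy(r + h, rmin, PARAMS) - lj_energy(r - h, rmin, PARAMS)) / (2 * h)
            assert fi[0] == pytest.approx(num, rel=1e-6, abs=1e-8)
            np.testing.assert_allclose(fi + fj, 0.0, atol=1e-12)


class TestTotalForces:
    def test_single_ball_feels_only_external(self):
        s = Structure(kind="rigid", balls=[Ball((0, 0, 0), 30), Ball((100, 0, 0), 30), Ball((0, 100, 0), 30)],
                      topology=Topology(bonds=np.array([[0, 1, 100.0, 2000.0], [0, 2, 100.0, 2000.0], [1, 2, np.sqrt(2) * 100, 2000.0]])))
        pos = s.centers + np.array([1000.0, 0, 0])
        scene = Scene(structures=[s], positions=pos, box=(4000, 4000, 4000))
        f = total_forces(scene, PARAMS)
        expected = np.array([external_force(p, PARAMS) for p in pos])
        np.testing.assert_allclose(f, expected, atol=1e-9)

    def test_bonded_pair_at_equilibrium_at_center(self):
        s = two_ball_structure(r0=100.0)
        pos = s.centers - np.array([50.0, 0, 0])  # symmetric about origin
        scene = Scene(structures=[s], positions=pos, box=(1000, 1000, 1000))
        f = total_forces(scene, PARAMS)
        # bond at equilibrium contributes nothing; the symmetric external
        # pulls cancel over the pair and act along x only
        assert np.linalg.norm(f[:, 1:]) == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(f[0], -f[1], atol=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        """KDTree neighbor search equals an independent all-pairs summation."""
        balls = [Ball(center=rng.uniform(-200, 200, 3), radius=rng.uniform(20, 60)) for _ in range(10)]
        topo = Topology(bonds=np.array([[i, i + 1, 80.0, 2000.0] for i in range(4)]))
        s = Structure(kind="filament", balls=balls[:5], topology=topo)
        s2 = Structure(kind="filament", balls=balls[5:], topology=topo)
        scene = Scene(structures=[s, s2], positions=np.array([b.center for b in balls]),
                      box=(800, 800, 800))
        f_tree = total_forces(scene, PARAMS, neighbor="kdtree")
        f_all = total_forces(scene, PARAMS, neighbor="all")
        np.testing.assert_allclose(f_tree, f_all, atol=1e-9)

        # independent oracle: naive loops over the published force terms
        x = scene.positions
        oracle = np.array([external_force(p, PARAMS) for p in x])
        for i, j, r0, kb in scene.bond_table:
            fi, fj = bond_forces(x[int(i)], x[int(j)], r0, kb)
            oracle[int(i)] += fi
            oracle[int(j)] += fj
        for i in range(10):
            for j in range(i + 1, 10):
                if (i, j) in scene.excluded_pairs:
                    continue
                rmin = scene.ball_radii[i] + scene.ball_radii[j]
                fi, fj = lj_forces(x[i], x[j], rmin, PARAMS)
                oracle[i] += fi
                oracle[j] += fj
        np.testing.assert_allclose(f_tree, oracle, atol=1e-9)


def lone_ball(position):
    """A structure of a single unbonded ball (isolated-particle fixture)."""
    s = Structure(kind="filament", balls=[Ball(position, 20)], topology=Topology())
    return Scene(structures=[s], positions=np.asarray([position], float),
                 box=(20000, 20000, 20000))


class TestStep:
    def test_free_ball_moves_point_six_toward_center(self):
        scene = lone_ball((2000.0, 0.0, 0.0))
        dx = step(scene, PARAMS)
        # beyond the plateau radius: displacement (3000/5000)*dt^2 = 0.6
        np.testing.assert_allclose(np.linalg.norm(dx, axis=1), 0.6, rtol=1e-9)
        np.testing.assert_allclose(scene.positions[0], [2000.0 - 0.6, 0, 0], atol=1e-9)

    def test_ball_at_center_stays(self):
        scene = lone_ball((0.0, 0.0, 0.0))
        step(scene, PARAMS)
        np.testing.assert_allclose(scene.positions[0], [0, 0, 0], atol=1e-12)

    def test_deterministic(self, small_library):
        a = place_structures(small_library[:2], [1, 1], box=(500, 500, 500), seed=5)
        b = place_structures(small_library[:2], [1, 1], box=(500, 500, 500), seed=5)
        step(a, PARAMS)
        step(b, PARAMS)
        np.testing.assert_array_equal(a.positions, b.positions)


class TestPlacement:
    def test_counts_and_disjoint_bounding_spheres(self, small_library):
        scene = place_structures(small_library, [2] * 5, box=(900, 900, 900), seed=3)
        assert len(scene.structures) == 10
        cents = [scene.structure_positions(i).mean(axis=0) for i in range(10)]
        rads = [s.bounding_radius() for s in scene.structures]
        for i in range(10):
            for j in range(i + 1, 10):
                assert np.linalg.norm(cents[i] - cents[j]) >= rads[i] + rads[j] - 1e-9

    def test_empty_counts_empty_scene(self, small_library):
        scene = place_structures(small_library, [0] * 5, box=(500, 500, 500), seed=0)
        assert scene.n_balls == 0

    def test_same_seed_identical(self, small_library):
        a = place_structures(small_library, [1] * 5, box=(600, 600, 600), seed=7)
        b = place_structures(small_library, [1] * 5, box=(600, 600, 600), seed=7)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_box_too_small_raises(self, small_library):
        with pytest.raises((ValueError, RuntimeError)):
            place_structures(small_library, [1] * 5, box=(150, 150, 150), seed=0)


class TestPacking:
    def test_rejects_zero_steps(self, small_library):
        scene = place_structures(small_library[:1], [1], box=(500, 500, 500), seed=0)
        with pytest.raises(ValueError):
            run_packing(scene, PARAMS, max_steps=0)

    def test_structures_approach_and_stay_rigid(self, small_library):
        scene = place_structures(small_library[:3], [1] * 3, box=(450, 450, 450), seed=2)
        run_packing(scene, PARAMS, max_steps=300, snapshot_every=100)
        c0 = [scene.structure_positions(i, initial=True).mean(axis=0) for i in range(3)]
        c1 = [scene.structure_positions(i).mean(axis=0) for i in range(3)]
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(c1[i] - c1[j]) < np.linalg.norm(c0[i] - c0[j])
        for i in range(3):
            p0 = scene.structure_positions(i, initial=True)
            p1 = scene.structure_positions(i)
            iu = np.triu_indices(len(p0), 1)
            d0 = np.linalg.norm(p0[:, None] - p0[None, :], axis=2)[iu]
            d1 = np.linalg.norm(p1[:, None] - p1[None, :], axis=2)[iu]
            assert np.max(np.abs(d1 - d0) / d0) < 0.01

    def test_centripetal_monotone_single_structure(self, small_library):
        scene = place_structures(small_library[:1], [1], box=(700, 700, 700), seed=8)
        dist = [np.linalg.norm(scene.positions.mean(axis=0))]
        for _ in range(50):
            step(scene, PARAMS)
            dist.append(np.linalg.norm(scene.positions.mean(axis=0)))
        assert all(b <= a + 1e-9 for a, b in zip(dist, dist[1:]))

    def test_trajectory_frames_monotone_and_anchored(self, small_library):
        scene = place_structures(small_library[:2], [1, 1], box=(500, 500, 500), seed=1)
        init = scene.positions.copy()
        traj = run_packing(scene, PARAMS, max_steps=120, snapshot_every=50)
        steps = [f[0] for f in traj.frames]
        assert steps[0] == 0
        assert steps == sorted(steps)
        np.testing.assert_array_equal(traj.frames[0][1], init)


class TestFilamentBehavior:
    def test_filament_curls_without_stretching(self):
        fil = build_filament(9)
        pos = fil.centers - fil.centers.mean(axis=0) + np.array([0.0, 150.0, 0.0])
        scene = Scene(structures=[fil], positions=pos, box=(500, 500, 500))
        run_packing(scene, PARAMS, max_steps=1500, snapshot_every=500)
        p0, p1 = scene.initial_positions, scene.positions
        # contour inextensible once the chain has settled near the center
        for i, j, r0, _ in fil.topology.bonds:
            assert abs(np.linalg.norm(p1[int(i)] - p1[int(j)]) / r0 - 1) < 0.01
        e0 = np.linalg.norm(p0[0] - p0[-1])
        e1 = np.linalg.norm(p1[0] - p1[-1])
        assert e1 < e0  # contour conserved, end-to-end free to shrink
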