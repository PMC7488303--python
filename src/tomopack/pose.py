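"""Rigid-pose annotation: displacement vectors and ZYZ Euler angles.

Each rigid structure's final orientation is recovered from three
non-collinear ball centers by a two-vector construction: first the
minimal rotation taking the initial A→B direction onto the final A→B
direction, then the residual spin about the final A→B axis fixed by the
third point C.  The resulting matrix is factored as
``R = Rz(alpha) @ Ry(beta) @ Rz(gamma)`` (ZYZ convention, beta in [0, pi]).
Deformable structures are rendered in their final shape, so their ground
truth carries zero rotation by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Pose",
    "structure_centroid",
    "displacement_vector",
    "rotation_between_vectors",
    "rotation_about_axis",
    "extract_rigid_rotation",
    "euler_zyz_from_matrix",
    "matrix_from_euler_zyz",
    "extract_pose",
]


@dataclass(frozen=True)
class Pose:
    """Per-structure motion annotation from the t=0 to the final state."""

    centroid_init: np.ndarray
    centroid_final: np.ndarray
    displacement: np.ndarray
    euler_zyz: tuple[float, float, float]
    rotation_matrix: np.ndarray


def structure_centroid(centers: np.ndarray) -> np.ndarray:
    """Arithmetic mean of ball centers."""
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    if len(centers) == 0:
        raise ValueError("cannot take the centroid of zero balls")
    return centers.mean(axis=0)


def displacement_vector(
    init: np.ndarray, final: np.ndarray, forward: bool = False
) -> np.ndarray:
    """Displacement annotation between two centroids.

    The default follows the published convention ``init - final``; pass
    ``forward=True`` for the geometric initial-to-final vector
    ``final - init``.
    """
    init = np.asarray(init, dtype=float)
    final = np.asarray(final, dtype=float)
    return final - init if forward else init - final


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError(f"zero {what}")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a (unit) axis by ``angle`` (Rodrigues)."""
    a = _unit(axis, "rotation axis")
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def rotation_between_vectors(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal-angle rotation mapping direction ``a`` onto direction ``b``.

    The axis is ``a x b``; for antiparallel inputs (axis undefined) a
    deterministic perpendicular axis is chosen: the unit vector along the
    smallest-magnitude component of ``a``, orthogonalized against ``a``.
    """
    ah = _unit(a)
    bh = _unit(b)
    c = float(np.clip(ah @ bh, -1.0, 1.0))
    axis = np.cross(ah, bh)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: any axis perpendicular to a works; pick deterministically
        e = np.zeros(3)
        e[int(np.argmin(np.abs(ah)))] = 1.0
        perp = _unit(e - (e @ ah) * ah)
        return rotation_about_axis(perp, np.pi)
    return rotation_about_axis(axis / n, float(np.arctan2(n, c)))


def extract_rigid_rotation(
    a0: np.ndarray,
    b0: np.ndarray,
    c0: np.ndarray,
    a1: np.ndarray,
    b1: np.ndarray,
    c1: np.ndarray,
) -> np.ndarray:
    """Rotation carrying the initial triple (A0,B0,C0) onto (A1,B1,C1).

    Two-stage construction: ``R_AB`` rotates the A0→B0 direction onto
    A1→B1 (fixing everything but the spin about that axis); the spin is
    then resolved by rotating the intermediate image of A0→C0 about the
    A1→B1 axis onto A1→C1.  The input points must be non-collinear.  If
    the two configurations are not exactly related by a rigid motion the
    result is the exact-on-AB, best-about-axis fit of the same
    construction.
    """
    a0, b0, c0, a1, b1, c1 = (np.asarray(p, float) for p in (a0, b0, c0, a1, b1, c1))
    ab0 = b0 - a0
    ac0 = c0 - a0
    ab1 = b1 - a1
    ac1 = c1 - a1
    if np.linalg.norm(np.cross(ab0, ac0)) <= 1e-12 * max(
        np.linalg.norm(ab0) * np.linalg.norm(ac0), 1.0
    ):
        raise ValueError("collinear reference points: rotation underdetermined")

    r_ab = rotation_between_vectors(ab0, ab1)
    axis = _unit(ab1)
    c_mid = r_ab @ ac0
    # components of the C vectors perpendicular to the AB axis fix the spin
    p_mid = c_mid - (c_mid @ axis) * axis
    p_fin = ac1 - (ac1 @ axis) * axis
    if np.linalg.norm(p_mid) < 1e-12 or np.linalg.norm(p_fin) < 1e-12:
        raise ValueError("degenerate configuration: C lies on the AB axis")
    ph_mid = p_mid / np.linalg.norm(p_mid)
    ph_fin = p_fin / np.linalg.norm(p_fin)
    cosang = float(np.clip(ph_mid @ ph_fin, -1.0, 1.0))
    sinang = float(np.cross(ph_mid, ph_fin) @ axis)
    r_ac = rotation_about_axis(axis, float(np.arctan2(sinang, cosang)))
    return r_ac @ r_ab


def matrix_from_euler_zyz(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Compose ``Rz(alpha) @ Ry(beta) @ Rz(gamma)``."""

    def rz(t):
        c, s = np.cos(t), np.sin(t)
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])

    def ry(t):
        c, s = np.cos(t), np.sin(t)
        return np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])

    return rz(alpha) @ ry(beta) @ rz(gamma)


def euler_zyz_from_matrix(R: np.ndarray, tol: float = 1e-6) -> tuple[float, float, float]:
    """Factor a rotation matrix as ZYZ Euler angles.

    Returns ``(alpha, beta, gamma)`` with ``beta`` in [0, pi] and the
    z-angles in (-pi, pi].  At gimbal lock (beta = 0 or pi) the gamma
    angle is set to zero and the full spin folded into alpha.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=tol) or \
            not np.isclose(np.linalg.det(R), 1.0, atol=tol):
        raise ValueError("input is not a proper rotation matrix")
    beta = float(np.arccos(np.clip(R[2, 2], -1.0, 1.0)))
    if np.sin(beta) > 1e-7:
        alpha = float(np.arctan2(R[1, 2], R[0, 2]))
        gamma = float(np.arctan2(R[2, 1], -R[2, 0]))
    else:
        gamma = 0.0
        if R[2, 2] > 0:  # beta ~ 0: R ~ Rz(alpha + gamma)
            alpha = float(np.arctan2(R[1, 0], R[0, 0]))
        else:  # beta ~ pi: R ~ Rz(alpha - gamma) @ Ry(pi)
            alpha = float(np.arctan2(-R[1, 0], -R[0, 0]))
    return alpha, beta, gamma


def extract_pose(
    init_centers: np.ndarray,
    final_centers: np.ndarray,
    deformable: bool = False,
    forward_displacement: bool = False,
) -> Pose:
    """Full pose annotation for one structure from its t=0 and final centers.

    Rigid structures use the first three ball centers (guaranteed
    non-collinear by the coarse-graining contract); deformable structures
    get the identity rotation by convention.
    """
    init_centers = np.asarray(init_centers, float).reshape(-1, 3)
    final_centers = np.asarray(final_centers, float).reshape(-1, 3)
    ci = structure_centroid(init_centers)
    cf = structure_centroid(final_centers)
    if deformable or len(init_centers) < 3:
        R = np.eye(3)
    else:
        R = extract_rigid_rotation(
            init_centers[0], init_centers[1], init_centers[2],
            final_centers[0], final_centers[1], final_centers[2],
        )
    return Pose(
        centroid_init=ci,
        centroid_final=cf,
        displacement=displacement_vector(ci, cf, forward=forward_displacement),
        euler_zyz=euler_zyz_from_matrix(R),
        rotation_matrix=R,
    )
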