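"""Low-level geometry kernels.

All public interfaces take and return degrees; radians appear only inside
these kernels.  Coordinates are numpy arrays of shape (n, 3) in Angstrom.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.transform import Rotation


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize a vector; raises on near-zero input."""
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize near-zero vector")
    return v / n


def rotation_about_axis(
    points: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle_deg: float
) -> np.ndarray:
    """Rotate points about the line through `origin` with direction `axis`.

    Right-handed rotation by `angle_deg` degrees.
    """
    k = unit(np.asarray(axis, float))
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    p = np.atleast_2d(np.asarray(points, float)) - origin
    out = p * c + np.cross(k, p) * s + np.outer(p @ k, k) * (1.0 - c) + origin
    return out.reshape(np.shape(points))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    # scalar arithmetic: this sits on the hot path of side-chain building
    a0x, a0y, a0z = (float(v) for v in p0)
    a1x, a1y, a1z = (float(v) for v in p1)
    a2x, a2y, a2z = (float(v) for v in p2)
    a3x, a3y, a3z = (float(v) for v in p3)
    b0 = (a0x - a1x, a0y - a1y, a0z - a1z)
    b1 = (a2x - a1x, a2y - a1y, a2z - a1z)
    b2 = (a3x - a2x, a3y - a2y, a3z - a2z)
    n1 = math.sqrt(b1[0] ** 2 + b1[1] ** 2 + b1[2] ** 2)
    if n1 < 1e-12:
        raise ValueError("degenerate dihedral: central bond has zero length")
    u = (b1[0] / n1, b1[1] / n1, b1[2] / n1)
    d0 = b0[0] * u[0] + b0[1] * u[1] + b0[2] * u[2]
    d2 = b2[0] * u[0] + b2[1] * u[1] + b2[2] * u[2]
    v = (b0[0] - d0 * u[0], b0[1] - d0 * u[1], b0[2] - d0 * u[2])
    w = (b2[0] - d2 * u[0], b2[1] - d2 * u[1], b2[2] - d2 * u[2])
    x = v[0] * w[0] + v[1] * w[1] + v[2] * w[2]
    cx = (u[1] * v[2] - u[2] * v[1], u[2] * v[0] - u[0] * v[2], u[0] * v[1] - u[1] * v[0])
    y = cx[0] * w[0] + cx[1] * w[1] + cx[2] * w[2]
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 at vertex p1 in degrees."""
    v1 = unit(np.asarray(p0, float) - np.asarray(p1, float))
    v2 = unit(np.asarray(p2, float) - np.asarray(p1, float))
    return float(np.degrees(np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0))))


def place_atom(p_a, p_b, p_c, bond_length: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement: position atom D given atoms A, B, C and internal coordinates.

    D is at `bond_length` from C, with angle B-C-D = `angle_deg` and dihedral
    A-B-C-D = `dihedral_deg`.
    """
    a, b, c = (np.asarray(x, float) for x in (p_a, p_b, p_c))
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(dihedral_deg)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition of `mobile` onto `reference`.

    Returns (R, t, rmsd) such that mobile @ R.T + t approximates reference.
    Raises ValueError for degenerate (collinear / <3 point) mappings.
    """
    mob = np.asarray(mobile, float)
    ref = np.asarray(reference, float)
    if mob.shape != ref.shape or mob.shape[0] < 3:
        raise ValueError("superposition needs >= 3 mapped atom pairs of equal count")
    ref_c = ref - ref.mean(axis=0)
    # Collinearity test on the reference: a rank-<2 centered matrix leaves a
    # free rotation about the line, so the transform is not identifiable.
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("reference mapping atoms are collinear or coincident")
    mob_mean = mob.mean(axis=0)
    ref_mean = ref.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref_c, mob - mob_mean)
    R = rot.as_matrix()
    t = ref_mean - R @ mob_mean
    rmsd = float(rssd / np.sqrt(mob.shape[0]))
    return R, t, rmsd


def optimal_rotation_angle(
    current: np.ndarray, target: np.ndarray, origin: np.ndarray, axis: np.ndarray
) -> float:
    """Angle (degrees) about the given axis minimizing sum |R(a) current - target|^2.

    Closed form: decompose each point into components parallel and
    perpendicular to the axis; the objective is const - 2(A cos a + B sin a),
    maximized at a = atan2(B, A).
    """
    a = unit(np.asarray(axis, float))
    cur = np.atleast_2d(current) - origin
    tgt = np.atleast_2d(target) - origin
    cur_perp = cur - np.outer(cur @ a, a)
    tgt_perp = tgt - np.outer(tgt @ a, a)
    A = float(np.sum(cur_perp * tgt_perp))
    B = float(np.sum(np.cross(a, cur_perp) * tgt_perp))
    if abs(A) < 1e-15 and abs(B) < 1e-15:
        return 0.0
    return float(np.degrees(np.arctan2(B, A)))


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    a = (float(deg) + 180.0) % 360.0 - 180.0
    if a <= -180.0:
        a += 360.0
    return a
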