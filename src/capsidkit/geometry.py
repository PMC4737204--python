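"""Low-level geometric primitives shared across the package.

Internal-coordinate atom placement (the NeRF construction), rigid
superposition, rotation helpers and the deterministic sphere point set used
by the surface-area calculator.
"""

from __future__ import annotations

import math

import numpy as np


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond_length: float, bond_angle_deg: float,
               torsion_deg: float) -> np.ndarray:
    """Position atom D from internal coordinates relative to atoms A-B-C.

    D is placed so that |C-D| = bond_length, angle(B,C,D) = bond_angle and
    torsion(A,B,C,D) = torsion_deg.  This is the standard NeRF construction.
    """
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        # colinear reference frame: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)

    ang = math.radians(bond_angle_deg)
    tor = math.radians(torsion_deg)
    d_local = np.array([
        -bond_length * math.cos(ang),
        bond_length * math.sin(ang) * math.cos(tor),
        bond_length * math.sin(ang) * math.sin(tor),
    ])
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about a (unit) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c = math.cos(angle_rad)
    s = math.sin(angle_rad)
    t = 1.0 - c
    return np.array([
        [t * x * x + c, t * x * y - s * z, t * x * z + s * y],
        [t * x * y + s * z, t * y * y + c, t * y * z - s * x],
        [t * x * z - s * y, t * y * z + s * x, t * z * z + c],
    ])


def kabsch(reference: np.ndarray, mobile: np.ndarray):
    """Optimal rigid superposition of `mobile` onto `reference`.

    Returns (rotation, translation, rmsd) with the proper-rotation
    constraint (determinant +1) enforced, so reflections are never used.
    The transform maps mobile coordinates as ``x @ R.T + t``.
    """
    reference = np.asarray(reference, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if reference.shape != mobile.shape:
        raise ValueError(
            f"selection size mismatch: {reference.shape} vs {mobile.shape}")
    ref_c = reference.mean(axis=0)
    mob_c = mobile.mean(axis=0)
    p = mobile - mob_c
    q = reference - ref_c
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    moved = p @ rot.T + ref_c
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    t = ref_c - rot @ mob_c
    return rot, t, rmsd


def spiral_sphere_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (spiral lattice).

    The golden-angle spiral gives reproducible quadrature nodes for
    Shrake-Rupley surface sampling; no randomness is involved.
    """
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def dodecahedron_face_normals() -> np.ndarray:
    """Unit normals of the 12 faces of a regular dodecahedron.

    Standard orientation: 2-fold axes along x, y, z and 3-fold axes along
    the body diagonals, i.e. the orientation in which the tetrahedral
    rotation group (and hence the I23 point group) permutes the faces.
    """
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    normals = []
    for s1 in (1, -1):
        for s2 in (1, -1):
            normals.append([0.0, s1 * 1.0, s2 * phi])
            normals.append([s1 * 1.0, s2 * phi, 0.0])
            normals.append([s2 * phi, 0.0, s1 * 1.0])
    arr = np.array(normals)
    return arr / np.linalg.norm(arr, axis=1, keepdims=True)
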