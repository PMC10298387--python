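"""Low-level vector geometry: internal-coordinate atom placement, virtual
angles/dihedrals and rotations.

All lengths are in nm, all angles in degrees at the API boundary (radians
internally where noted).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "place_atom",
    "bond_angle",
    "dihedral",
    "rotation_about_axis",
    "principal_axis",
]


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Place a new point ``d`` from three predecessors (NeRF construction).

    ``d`` satisfies |d-c| = bond, angle(b, c, d) = angle_deg and
    dihedral(a, b, c, d) = torsion_deg.
    """
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("collinear predecessors: torsion frame undefined")
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed torsion angle a-b-c-d in degrees, in (-180, 180]."""
    b0 = b - a
    b1 = c - b
    b2 = d - c
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def rotation_about_axis(axis: np.ndarray, theta_rad: float) -> np.ndarray:
    """3x3 rotation matrix for a right-handed rotation about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c = np.cos(theta_rad)
    s = np.sin(theta_rad)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def principal_axis(points: np.ndarray) -> np.ndarray:
    """Dominant principal axis (unit vector) of a point cloud.

    Raises ValueError for degenerate (coincident) clouds.
    """
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    if np.max(np.linalg.norm(centered, axis=1)) < 1e-9:
        raise ValueError("degenerate point cloud: all points coincide")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]
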