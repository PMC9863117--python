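"""Low-level vector geometry: internal-coordinate atom placement and torsions.

All routines broadcast over arbitrary leading axes so that a whole trajectory
of frames can be built or measured in one call.  Coordinates are in Angstrom,
angles in degrees unless noted.
"""

from __future__ import annotations

import numpy as np

__all__ = ["place_atom", "dihedral", "bond_angle", "rotation_matrix"]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float | np.ndarray,
    angle: float | np.ndarray,
    torsion: float | np.ndarray,
) -> np.ndarray:
    """Place atom D given reference atoms A, B, C (natural extension frame).

    D is at distance ``bond`` from C, with bond angle B-C-D equal to ``angle``
    and torsion A-B-C-D equal to ``torsion`` (degrees).  Inputs of shape
    (..., 3) are broadcast; ``bond``/``angle``/``torsion`` may be scalars or
    arrays of shape (...,).
    """
    a, b, c = np.asarray(a, float), np.asarray(b, float), np.asarray(c, float)
    ang = np.deg2rad(np.asarray(angle, float))
    tor = np.deg2rad(np.asarray(torsion, float))
    r = np.asarray(bond, float)

    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))  # normal of the A-B-C plane
    m = np.cross(n, bc)             # completes right-handed frame (bc, m, n)

    comps = np.broadcast_arrays(
        -r * np.cos(ang),
        r * np.sin(ang) * np.cos(tor),
        r * np.sin(ang) * np.sin(tor),
    )
    d_local = np.stack(comps, axis=-1)
    return c + (
        d_local[..., :1] * bc + d_local[..., 1:2] * m + d_local[..., 2:3] * n
    )


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed torsion angle p0-p1-p2-p3 in degrees, broadcasting over (..., 3)."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = _unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    return np.degrees(np.arctan2(y, x))


def bond_angle(p0, p1, p2) -> np.ndarray:
    """Bond angle p0-p1-p2 in degrees, broadcasting over (..., 3)."""
    p0, p1, p2 = (np.asarray(p, float) for p in (p0, p1, p2))
    v1 = _unit(p0 - p1)
    v2 = _unit(p2 - p1)
    cosang = np.clip(np.sum(v1 * v2, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_deg`` degrees."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = np.deg2rad(angle_deg)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(t) * k + (1.0 - np.cos(t)) * (k @ k)
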