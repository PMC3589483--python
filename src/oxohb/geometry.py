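"""Small vector-geometry helpers shared across modules."""
from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def angle_deg(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    u = unit(np.asarray(a) - np.asarray(b))
    w = unit(np.asarray(c) - np.asarray(b))
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def dihedral_deg(a, b, c, d) -> float:
    """Signed dihedral a-b-c-d in degrees, in (-180, 180]."""
    b0 = np.asarray(b) - np.asarray(a)
    b1 = np.asarray(c) - np.asarray(b)
    b2 = np.asarray(d) - np.asarray(c)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, unit(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def rotation_between(frame_from: np.ndarray, frame_to: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping one orthonormal frame (rows) onto another."""
    return frame_to.T @ frame_from


def orthonormal_frame(x_dir: np.ndarray, xy_dir: np.ndarray) -> np.ndarray:
    """Right-handed frame (rows e1,e2,e3) with e1 along x_dir and xy_dir in
    the e1-e2 half plane (positive e2 component)."""
    e1 = unit(x_dir)
    v = np.asarray(xy_dir, dtype=float)
    v = v - np.dot(v, e1) * e1
    e2 = unit(v)
    e3 = np.cross(e1, e2)
    return np.vstack([e1, e2, e3])


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal rotation/translation superposing mobile onto target.

    Returns (R, t) such that mobile @ R.T + t approximates target in the
    least-squares sense.
    """
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t
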