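"""Low-level chain geometry shared across the package.

All structural reasoning in this package happens on the CA trace plus a
side-chain centroid pseudo-atom per residue.  This module provides the
primitives for that: internal (bond / angle / torsion) coordinates of a
polyline chain, NeRF-style reconstruction from internal coordinates,
virtual CA torsions, pseudo-CB directions, and Kabsch superposition.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral",
    "virtual_torsions",
    "internal_coords",
    "rebuild_chain",
    "pseudo_cb_directions",
    "kabsch",
    "superpose",
]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        return v
    return v / n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (radians, in (-pi, pi]) of four points."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, _unit(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return float(np.arctan2(-y, x))


def virtual_torsions(ca: np.ndarray) -> np.ndarray:
    """Virtual torsion tau_i over CA windows (i, i+1, i+2, i+3), radians.

    Returns an array of length n-3 (empty for n < 4).
    """
    ca = np.asarray(ca, dtype=float)
    n = len(ca)
    if n < 4:
        return np.zeros(0)
    return np.array([dihedral(ca[i], ca[i + 1], ca[i + 2], ca[i + 3]) for i in range(n - 3)])


def internal_coords(points: np.ndarray):
    """Internal coordinates (bond lengths, bond angles, torsions) of a chain.

    Returns ``(d, theta, tau)`` with ``len(d) = n-1``, ``len(theta) = n-2``
    (angle at interior point i+1) and ``len(tau) = n-3``.
    """
    p = np.asarray(points, dtype=float)
    n = len(p)
    d = np.linalg.norm(p[1:] - p[:-1], axis=1)
    theta = np.zeros(max(n - 2, 0))
    for i in range(n - 2):
        v1 = _unit(p[i] - p[i + 1])
        v2 = _unit(p[i + 2] - p[i + 1])
        theta[i] = np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0))
    tau = virtual_torsions(p)
    return d, theta, tau


def _place(a, b, c, bond, angle, torsion) -> np.ndarray:
    """NeRF placement of the next point given the previous three."""
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def rebuild_chain(d, theta, tau) -> np.ndarray:
    """Rebuild a chain from internal coordinates (inverse of internal_coords
    up to a rigid motion)."""
    d = np.asarray(d, dtype=float)
    theta = np.asarray(theta, dtype=float)
    tau = np.asarray(tau, dtype=float)
    n = len(d) + 1
    p = np.zeros((n, 3))
    if n >= 2:
        p[1] = [d[0], 0.0, 0.0]
    if n >= 3:
        p[2] = p[1] + d[1] * np.array([-np.cos(theta[0]), np.sin(theta[0]), 0.0])
    for i in range(3, n):
        p[i] = _place(p[i - 3], p[i - 2], p[i - 1], d[i - 1], theta[i - 2], tau[i - 3])
    return p


def pseudo_cb_directions(ca: np.ndarray) -> np.ndarray:
    """Unit direction from each CA toward its side chain, built from the trace.

    For interior residues the direction is the negated bisector of the two
    chain bonds (pointing away from the backbone); chain termini copy their
    neighbour's direction.  A degenerate (collinear) bisector falls back to
    any perpendicular of the local chain direction.
    """
    ca = np.asarray(ca, dtype=float)
    n = len(ca)
    dirs = np.zeros((n, 3))
    for i in range(1, n - 1):
        v = -((ca[i - 1] - ca[i]) + (ca[i + 1] - ca[i]))
        if np.linalg.norm(v) < 1e-8:
            axis = _unit(ca[i + 1] - ca[i - 1])
            v = np.cross(axis, [0.0, 0.0, 1.0])
            if np.linalg.norm(v) < 1e-8:
                v = np.cross(axis, [0.0, 1.0, 0.0])
        dirs[i] = _unit(v)
    if n >= 2:
        dirs[0] = dirs[1] if n > 2 else _unit(np.cross(ca[1] - ca[0], [0.0, 0.0, 1.0]))
        dirs[-1] = dirs[-2]
    elif n == 1:
        dirs[0] = [0.0, 0.0, 1.0]
    return dirs


def kabsch(P: np.ndarray, Q: np.ndarray):
    """Optimal rotation R and translation t minimizing ||(P @ R.T + t) - Q||.

    Returns ``(R, t)`` such that ``P @ R.T + t`` superposes P onto Q.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def superpose(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """P superposed onto Q with the Kabsch rotation fitted on all points."""
    R, t = kabsch(P, Q)
    return np.asarray(P) @ R.T + t
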