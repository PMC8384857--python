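"""Differentiable collective variables: torsion measurement and rigid-branch rotation.

A :class:`DihedralCV` names four atoms (a, b, c, d) defining the signed
torsion about the b-c bond, together with the molecular bond graph.  The
rotating set — every atom carried along when the torsion changes — is derived
from connectivity: it is the connected component containing atom d once the
b-c edge is removed.  Backmapping realizes a CV displacement as a sequence of
rigid Rodrigues rotations, and :func:`backmap_with_jacobian` propagates
forward-mode tangents so attack gradients can flow through the operation.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import networkx as nx
import numpy as np

__all__ = [
    "DihedralCV",
    "measure_dihedral",
    "dihedral_and_gradient",
    "rotate_dihedral",
    "backmap",
    "backmap_with_jacobian",
    "bonds_from_distance_cutoff",
    "wrap_angle",
]

_COLLINEAR_TOL = 1e-10


def wrap_angle(theta):
    """Reduce angles to the interval (-pi, pi]."""
    theta = np.asarray(theta, float)
    wrapped = -((-theta + np.pi) % (2 * np.pi) - np.pi)
    return wrapped if wrapped.ndim else float(wrapped)


def _torsion_vectors(R: np.ndarray, indices) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    a, b, c, d = indices
    b1 = R[b] - R[a]
    b2 = R[c] - R[b]
    b3 = R[d] - R[c]
    return b1, b2, b3


def measure_dihedral(R: np.ndarray, indices: Sequence[int]) -> float:
    """Signed torsion angle in (-pi, pi]; cis = 0, trans = pi.

    Uses the atan2 construction on the two bond-plane normals, which is
    numerically stable away from collinear triples.
    """
    b1, b2, b3 = _torsion_vectors(np.asarray(R, float), indices)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.dot(n1, n1) < _COLLINEAR_TOL or np.dot(n2, n2) < _COLLINEAR_TOL:
        raise ValueError("undefined torsion: collinear atom triple")
    m = np.cross(b2 / np.linalg.norm(b2), n1)
    angle = float(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))
    return np.pi if angle == -np.pi else angle


def dihedral_and_gradient(R: np.ndarray, indices: Sequence[int]):
    """Torsion angle and its analytic gradient with respect to all coordinates.

    Returns ``(angle, grad)`` with ``grad`` of shape (n, 3), nonzero only on
    the four defining atoms.  The gradient follows the classic rigid-rotation
    derivation used by molecular-mechanics codes.
    """
    R = np.asarray(R, float)
    a, b, c, d = indices
    angle = measure_dihedral(R, indices)
    F = R[a] - R[b]
    G = R[b] - R[c]
    H = R[d] - R[c]
    A = np.cross(F, G)
    B = np.cross(H, G)
    nG = np.linalg.norm(G)
    A2 = np.dot(A, A)
    B2 = np.dot(B, B)
    ga = -nG / A2 * A
    gd = nG / B2 * B
    gb = nG / A2 * A + np.dot(F, G) / (A2 * nG) * A - np.dot(H, G) / (B2 * nG) * B
    gc = np.dot(H, G) / (B2 * nG) * B - np.dot(F, G) / (A2 * nG) * A - nG / B2 * B
    grad = np.zeros_like(R)
    grad[a], grad[b], grad[c], grad[d] = ga, gb, gc, gd
    return angle, grad


class DihedralCV:
    """Torsion CV (a, b, c, d) about bond b-c with a connectivity-derived rotating set."""

    def __init__(self, indices: Sequence[int], bonds: Sequence[Tuple[int, int]]):
        indices = tuple(int(i) for i in indices)
        if len(indices) != 4 or len(set(indices)) != 4:
            raise ValueError("a dihedral needs four distinct atom indices")
        a, b, c, d = indices
        graph = nx.Graph(bonds)
        if not graph.has_edge(b, c):
            raise ValueError("atoms b and c must be bonded")
        graph.remove_edge(b, c)
        components = list(nx.connected_components(graph))
        comp_d = next(comp for comp in components if d in comp)
        if b in comp_d:
            raise ValueError("bond b-c lies on a ring; torsion rotation undefined")
        self.indices = indices
        self.rotating_set = np.array(sorted(comp_d), dtype=int)

    def measure(self, R: np.ndarray) -> float:
        return measure_dihedral(R, self.indices)


def _rodrigues(axis: np.ndarray, theta: float) -> np.ndarray:
    K = np.array(
        [[0.0, -axis[2], axis[1]], [axis[2], 0.0, -axis[0]], [-axis[1], axis[0], 0.0]]
    )
    return (
        np.cos(theta) * np.eye(3)
        + np.sin(theta) * K
        + (1.0 - np.cos(theta)) * np.outer(axis, axis)
    )


def rotate_dihedral(R: np.ndarray, cv: DihedralCV, delta: float) -> np.ndarray:
    """Rigidly rotate the CV's rotating set about the b->c axis by ``delta`` rad.

    Increases the measured torsion by exactly ``delta`` (mod 2 pi); all other
    atoms are untouched.
    """
    R = np.asarray(R, float).copy()
    if delta == 0.0:
        return R
    _, b, c, _ = cv.indices
    axis = R[c] - R[b]
    axis = axis / np.linalg.norm(axis)
    rot = _rodrigues(axis, float(delta))
    sel = cv.rotating_set
    R[sel] = R[b] + (R[sel] - R[b]) @ rot.T
    return R


def backmap(R: np.ndarray, cvs: Sequence[DihedralCV], delta: Sequence[float]) -> np.ndarray:
    """Apply each CV displacement in declaration order; the inverse-CV map s^-1."""
    delta = np.asarray(delta, float).ravel()
    if delta.size != len(cvs):
        raise ValueError("delta length must equal the number of CVs")
    out = np.asarray(R, float).copy()
    for cv, d in zip(cvs, delta):
        out = rotate_dihedral(out, cv, d)
    return out


def backmap_with_jacobian(R: np.ndarray, cvs: Sequence[DihedralCV], delta: Sequence[float]):
    """Backmap plus forward-mode tangents d(coords)/d(delta_k).

    Returns ``(coords, T)`` with ``T`` of shape (n_cvs, n, 3).  Tangents are
    propagated exactly through every rotation, including the motion of later
    rotation axes caused by earlier rotations, so nested rotating sets are
    handled correctly.
    """
    R = np.asarray(R, float).copy()
    delta = np.asarray(delta, float).ravel()
    K = len(cvs)
    if delta.size != K:
        raise ValueError("delta length must equal the number of CVs")
    T = np.zeros((K, R.shape[0], 3))
    eye = np.eye(3)
    for j, (cv, theta) in enumerate(zip(cvs, delta)):
        _, b, c, _ = cv.indices
        omega = R[c] - R[b]
        L = np.linalg.norm(omega)
        axis = omega / L
        ct, st = np.cos(theta), np.sin(theta)
        Kx = np.array(
            [[0.0, -axis[2], axis[1]], [axis[2], 0.0, -axis[0]], [-axis[1], axis[0], 0.0]]
        )
        rot = ct * eye + st * Kx + (1.0 - ct) * np.outer(axis, axis)
        drot_dtheta = -st * eye + ct * Kx + st * np.outer(axis, axis)
        sel = cv.rotating_set
        rel = R[sel] - R[b]  # positions before this rotation
        proj = eye - np.outer(axis, axis)
        for k in range(K):
            dpb = T[k, b].copy()
            dpc = T[k, c].copy()
            daxis = proj @ (dpc - dpb) / L
            dKx = np.array(
                [
                    [0.0, -daxis[2], daxis[1]],
                    [daxis[2], 0.0, -daxis[0]],
                    [-daxis[1], daxis[0], 0.0],
                ]
            )
            drot = st * dKx + (1.0 - ct) * (np.outer(daxis, axis) + np.outer(axis, daxis))
            if k == j:
                drot = drot + drot_dtheta
            T[k, sel] = dpb + rel @ drot.T + (T[k, sel] - dpb) @ rot.T
        R[sel] = R[b] + rel @ rot.T
    return R, T


def bonds_from_distance_cutoff(R: np.ndarray, cutoff: float = 1.8) -> List[Tuple[int, int]]:
    """Infer a bond list by a pairwise distance cutoff (default 1.8 Angstrom)."""
    R = np.asarray(R, float)
    n = R.shape[0]
    bonds = []
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(R[i] - R[j]) <= cutoff:
                bonds.append((i, j))
    return bonds
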