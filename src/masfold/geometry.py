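"""Vectorized internal-coordinate geometry: values and analytic gradients.

All angles are in radians internally; callers converting from tables in
degrees do so at the boundary. Gradient conventions: every function returns
d(value)/d(coordinates) for each atom of the tuple, so energy terms chain
through them without re-deriving vector calculus.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def bond_lengths(coords: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    d = coords[pairs[:, 1]] - coords[pairs[:, 0]]
    return np.linalg.norm(d, axis=1)


def bond_length_grads(coords: np.ndarray, pairs: np.ndarray):
    """Return (lengths, unit) where d(len)/d(atom1) = unit, d/d(atom0) = -unit."""
    d = coords[pairs[:, 1]] - coords[pairs[:, 0]]
    r = np.linalg.norm(d, axis=1)
    unit = d / np.maximum(r, _EPS)[:, None]
    return r, unit


def angle_values(coords: np.ndarray, triples: np.ndarray) -> np.ndarray:
    u = coords[triples[:, 0]] - coords[triples[:, 1]]
    v = coords[triples[:, 2]] - coords[triples[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cosang = np.einsum("ij,ij->i", u, v) / np.maximum(nu * nv, _EPS)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def angle_grads(coords: np.ndarray, triples: np.ndarray):
    """Return (theta, g_a, g_b, g_c) with g_x = d(theta)/d(x)."""
    a, b, c = triples[:, 0], triples[:, 1], triples[:, 2]
    u = coords[a] - coords[b]
    v = coords[c] - coords[b]
    nu = np.maximum(np.linalg.norm(u, axis=1), _EPS)
    nv = np.maximum(np.linalg.norm(v, axis=1), _EPS)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    cosang = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    theta = np.arccos(cosang)
    sin = np.maximum(np.sin(theta), 1e-8)
    g_a = (cosang[:, None] * uh - vh) / (nu * sin)[:, None]
    g_c = (cosang[:, None] * vh - uh) / (nv * sin)[:, None]
    g_b = -(g_a + g_c)
    return theta, g_a, g_b, g_c


def dihedral_values(coords: np.ndarray, quads: np.ndarray) -> np.ndarray:
    b1 = coords[quads[:, 1]] - coords[quads[:, 0]]
    b2 = coords[quads[:, 2]] - coords[quads[:, 1]]
    b3 = coords[quads[:, 3]] - coords[quads[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.maximum(np.linalg.norm(b2, axis=1), _EPS)[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m, n2)
    return -np.arctan2(y, x)


def dihedral_grads(coords: np.ndarray, quads: np.ndarray):
    """Return (phi, g_a, g_b, g_c, g_d) with g in rad/Angstrom.

    Near-collinear central bonds raise: the torsion is undefined there.
    """
    a, b, c, d = (quads[:, k] for k in range(4))
    b1 = coords[b] - coords[a]
    b2 = coords[c] - coords[b]
    b3 = coords[d] - coords[c]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    nb2 = np.linalg.norm(b2, axis=1)
    if np.any(n1sq < 1e-14) or np.any(n2sq < 1e-14):
        raise ValueError("degenerate (collinear) atoms in a dihedral")
    m = np.cross(n1, b2 / nb2[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m, n2)
    phi = -np.arctan2(y, x)
    g_a = -(nb2 / n1sq)[:, None] * n1
    g_d = (nb2 / n2sq)[:, None] * n2
    dot12 = np.einsum("ij,ij->i", b1, b2) / (nb2 ** 2)
    dot32 = np.einsum("ij,ij->i", b3, b2) / (nb2 ** 2)
    g_b = -(1.0 + dot12)[:, None] * g_a + dot32[:, None] * g_d
    g_c = dot12[:, None] * g_a - (1.0 + dot32)[:, None] * g_d
    return phi, g_a, g_b, g_c, g_d


def wrap_angle(delta):
    """Wrap angle differences (radians) into (-pi, pi]."""
    return -np.remainder(-np.asarray(delta) + np.pi, 2.0 * np.pi) + np.pi


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position D bonded to C with |CD| = bond,
    angle(B,C,D) = angle and dihedral(A,B,C,D) = torsion (radians)."""
    bc = c - b
    bc /= max(np.linalg.norm(bc), _EPS)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _EPS:
        # arbitrary perpendicular for collinear history
        n = np.cross(bc, [1.0, 0.0, 0.0])
        if np.linalg.norm(n) < _EPS:
            n = np.cross(bc, [0.0, 1.0, 0.0])
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def kabsch(ref: np.ndarray, mobile: np.ndarray):
    """Least-squares rigid superposition of `mobile` onto `ref`.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` best fits ``ref`` and
    det(rotation) = +1 (proper rotation).
    """
    ref = np.asarray(ref, float)
    mobile = np.asarray(mobile, float)
    if ref.shape != mobile.shape or ref.shape[0] < 3:
        raise ValueError("superposition needs two equal selections of >= 3 atoms")
    cref = ref.mean(axis=0)
    cmob = mobile.mean(axis=0)
    P = ref - cref
    Q = mobile - cmob
    # degenerate (collinear/coincident) selections have rank < 2
    if np.linalg.matrix_rank(np.vstack([P, Q]), tol=1e-8) < 2:
        raise ValueError("degenerate selection: fewer than 3 non-collinear atoms")
    H = Q.T @ P
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = cref - R @ cmob
    diff = (mobile @ R.T + t) - ref
    rmsd = float(np.sqrt((diff ** 2).sum() / ref.shape[0]))
    return R, t, rmsd


def rmsd_after_superposition(ref: np.ndarray, mobile: np.ndarray) -> float:
    return kabsch(ref, mobile)[2]
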