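"""Slater-Koster rotation of two-center integrals into the lab frame.

Basis ordering per atom: s | p(y, z, x) | d(xy, yz, z2, xz, x2-y2), i.e. real
spherical harmonics with m = -l..l.  A diatomic-frame table (bond along +z)
is rotated with the real-harmonic representation matrices D^l(R), built for
p from the Cartesian rotation itself and for d from the quadratic-form
transformation Q -> R Q R^T of the harmonic polynomials.
"""

from __future__ import annotations

import numpy as np

# d-orbital quadratic forms, all with Frobenius norm^2 = 1/2 so that the
# representation matrix is D2[m, m'] = 2 tr(Q_m' R Q_m R^T)
_SQRT3 = np.sqrt(3.0)
_Q = [
    np.array([[0, 0.5, 0], [0.5, 0, 0], [0, 0, 0]]),            # xy
    np.array([[0, 0, 0], [0, 0, 0.5], [0, 0.5, 0]]),            # yz
    np.array([[-0.5, 0, 0], [0, -0.5, 0], [0, 0, 1.0]]) / _SQRT3,  # z2
    np.array([[0, 0, 0.5], [0, 0, 0], [0.5, 0, 0]]),            # xz
    np.array([[0.5, 0, 0], [0, -0.5, 0], [0, 0, 0]]),           # x2-y2
]
_PERM = (1, 2, 0)  # p ordering (y, z, x) -> Cartesian (x, y, z) index


def rotation_to_z(direction: np.ndarray) -> np.ndarray:
    """Proper rotation R with R @ [0,0,1] = direction (unit vector)."""
    n = np.asarray(direction, dtype=float)
    n = n / np.linalg.norm(n)
    # pick the least-aligned axis to build an orthonormal triad
    a = np.zeros(3)
    a[np.argmin(np.abs(n))] = 1.0
    u = np.cross(a, n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return np.column_stack([u, v, n])


def real_sh_rotation(l: int, R: np.ndarray) -> np.ndarray:
    """Representation D^l with Y_m(R^-1 r) = sum_m' D[m, m'] Y_m'(r)."""
    if l == 0:
        return np.ones((1, 1))
    if l == 1:
        D = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                D[i, j] = R[_PERM[j], _PERM[i]]  # R^T in permuted indices
        return D
    if l == 2:
        D = np.empty((5, 5))
        for m in range(5):
            RQ = R @ _Q[m] @ R.T
            for mp in range(5):
                D[m, mp] = 2.0 * np.sum(_Q[mp] * RQ)
        return D
    raise ValueError("only spd supported")


def _orbital_slices(lvals: list) -> list:
    """Offsets of each l-block in the atom's orbital vector."""
    out, off = [], 0
    for l in sorted(lvals):
        out.append((l, off))
        off += 2 * l + 1
    return out


def sk_rotate(
    table_ab,
    table_ba,
    displacement: np.ndarray,
    lvals_a: list,
    lvals_b: list,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the (H0, S) blocks for orbitals of atom a vs atom b.

    ``displacement`` points from a to b (bohr).  ``table_ab`` holds the
    canonical channels with a's orbital first; channels with l_a > l_b are
    taken from ``table_ba`` using the midpoint-inversion parity
    (-1)^(la+lb).  Raises if |displacement| is below the table start.
    """
    d = float(np.linalg.norm(displacement))
    if d < 1e-12:
        raise ValueError("zero displacement: on-site blocks are not tabulated")
    na = sum(2 * l + 1 for l in lvals_a)
    nb = sum(2 * l + 1 for l in lvals_b)
    H0 = np.zeros((na, nb))
    S0 = np.zeros((na, nb))
    # diatomic frame: bond along +z, matrix diagonal in m
    for (la, offa) in _orbital_slices(lvals_a):
        for (lb, offb) in _orbital_slices(lvals_b):
            for m in range(min(la, lb) + 1):
                if la <= lb:
                    hv = table_ab.interpolate("h", (la, lb, m), d)
                    sv = table_ab.interpolate("s", (la, lb, m), d)
                else:
                    par = (-1.0) ** (la + lb)
                    hv = par * table_ba.interpolate("h", (lb, la, m), d)
                    sv = par * table_ba.interpolate("s", (lb, la, m), d)
                for sgn in ([0] if m == 0 else [-m, m]):
                    ia = offa + la + sgn
                    ib = offb + lb + sgn
                    H0[ia, ib] = hv
                    S0[ia, ib] = sv
    R = rotation_to_z(displacement)
    DA = _block_diag([real_sh_rotation(l, R) for l in sorted(lvals_a)])
    DB = _block_diag([real_sh_rotation(l, R) for l in sorted(lvals_b)])
    # matrix elements transform with D(R^T) = D(R)^T on each side
    H = DA.T @ H0 @ DB
    S = DA.T @ S0 @ DB
    return H, S


def _block_diag(mats: list) -> np.ndarray:
    n = sum(m.shape[0] for m in mats)
    out = np.zeros((n, n))
    off = 0
    for m in mats:
        k = m.shape[0]
        out[off : off + k, off : off + k] = m
        off += k
    return out
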