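"""Non-SCC tight-binding band structures for elemental crystals.

Bloch sums H(k) = sum_R exp(ik.R) H0(R) over the real-space neighbor shells
within the Slater-Koster cutoff, then a generalized eigenproblem per
k-point.  The self-consistent charge terms vanish for elemental crystals
(all sites equivalent, so Mulliken fluctuations are zero by symmetry),
which is why the plain H0 suffices for the confinement fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh

from .constants import HARTREE_TO_EV
from .engine import ParameterSet
from .rotations import sk_rotate
from .structure import Structure


@dataclass
class BandStructure:
    kpoints: np.ndarray            # fractional coordinates, (nk, 3)
    energies: np.ndarray           # (nk, nbands), eV, ascending per k
    fermi_energy: float            # eV
    labels: list = field(default_factory=list)

    @property
    def n_bands(self) -> int:
        return self.energies.shape[1]

    def aligned(self) -> np.ndarray:
        """Band energies with the Fermi level shifted to zero."""
        return self.energies - self.fermi_energy


def _lattice_translations(lattice: np.ndarray, cutoff: float) -> np.ndarray:
    """All lattice vectors R with |R| - diameter <= cutoff (generous bound)."""
    inv_norms = np.linalg.norm(np.linalg.inv(lattice), axis=0)
    nmax = np.ceil(cutoff * inv_norms).astype(int) + 1
    grids = [np.arange(-n, n + 1) for n in nmax]
    pts = np.array(np.meshgrid(*grids, indexing="ij")).reshape(3, -1).T
    return pts


def band_structure(
    crystal: Structure,
    params: ParameterSet,
    kpath: np.ndarray,
    *,
    labels: list | None = None,
    fermi_grid: int = 8,
) -> BandStructure:
    """Bands along fractional k-points ``kpath`` for a periodic crystal.

    The Fermi energy is determined by zone-sampling the same Hamiltonian on
    a uniform ``fermi_grid``^3 Monkhorst-Pack-style mesh and filling the
    valence electrons.
    """
    if not crystal.periodic:
        raise ValueError("band_structure requires a lattice")
    kpath = np.atleast_2d(np.asarray(kpath, dtype=float))
    hk, sk, n_elec = _bloch_builder(crystal, params)
    energies = []
    for k in kpath:
        eps = _solve_k(hk, sk, k)
        energies.append(eps)
    energies = np.array(energies) * HARTREE_TO_EV
    # Fermi level from a uniform mesh
    mesh = np.stack(
        np.meshgrid(*[(np.arange(fermi_grid) + 0.5) / fermi_grid] * 3,
                    indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    all_eps = np.concatenate([_solve_k(hk, sk, k) for k in mesh])
    all_eps = np.sort(all_eps) * HARTREE_TO_EV
    # each level holds 2 electrons per k-point of the mesh
    n_fill = int(round(n_elec / 2.0 * len(mesh)))
    if n_fill >= len(all_eps):
        fermi = float(all_eps[-1])
    else:
        fermi = float(0.5 * (all_eps[n_fill - 1] + all_eps[n_fill]))
    return BandStructure(
        kpoints=kpath, energies=energies, fermi_energy=fermi,
        labels=labels or [],
    )


def _bloch_builder(crystal: Structure, params: ParameterSet):
    params.check_closed(crystal.symbols)
    lat = crystal.lattice
    pos = crystal.positions
    syms = crystal.symbols
    sizes = [sum(2 * l + 1 for l in params.lvals(s)) for s in syms]
    offsets = np.concatenate([[0], np.cumsum(sizes)])[:-1]
    ntot = int(sum(sizes))
    cutoff = max(t.cutoff for t in params.tables.values())
    cells = _lattice_translations(lat, cutoff + np.ptp(pos) + 1.0)

    # precompute real-space blocks: list of (cell_index_frac, a, b, H, S)
    blocks = []
    min_d = np.inf
    for cell in cells:
        Rvec = cell @ lat
        for a in range(len(syms)):
            for b in range(len(syms)):
                disp = pos[b] + Rvec - pos[a]
                d = np.linalg.norm(disp)
                if d < 1e-9:
                    continue  # on-site handled separately
                if d > cutoff:
                    continue
                min_d = min(min_d, d)
                ta = params.table(syms[a], syms[b])
                if d < ta.start:
                    raise ValueError(
                        f"lattice places atoms at {d:.3f} bohr, below the "
                        f"table start {ta.start:.3f}"
                    )
                h, s = sk_rotate(
                    ta, params.table(syms[b], syms[a]), disp,
                    params.lvals(syms[a]), params.lvals(syms[b]),
                )
                blocks.append((cell.astype(float), a, b, h, s))

    H_on = np.zeros((ntot, ntot))
    for a, sym in enumerate(syms):
        ons = params.onsite(sym)
        i = offsets[a]
        for l in params.lvals(sym):
            for _m in range(2 * l + 1):
                H_on[i, i] = ons.get(l, 0.0)
                i += 1

    n_elec = sum(params.neutral_electrons(s) for s in syms)

    def hk(k):
        H = H_on.astype(complex).copy()
        S = np.eye(ntot, dtype=complex)
        for cell, a, b, h, s in blocks:
            phase = np.exp(2j * np.pi * (k @ cell))
            ia, ib = offsets[a], offsets[b]
            H[ia : ia + h.shape[0], ib : ib + h.shape[1]] += phase * h
            S[ia : ia + h.shape[0], ib : ib + h.shape[1]] += phase * s
        return H, S

    return hk, None, n_elec


def _solve_k(hk, _sk, k):
    H, S = hk(k)
    # hermitize against tiny numerical asymmetry
    H = 0.5 * (H + H.conj().T)
    S = 0.5 * (S + S.conj().T)
    eps = eigh(H, S, eigvals_only=True)
    return np.sort(eps.real)


def hcp_cell(a: float, c: float, symbol: str) -> Structure:
    """Two-atom hcp cell (space group 194) with lattice constants in bohr."""
    lat = np.array(
        [
            [a, 0.0, 0.0],
            [-0.5 * a, np.sqrt(3.0) / 2.0 * a, 0.0],
            [0.0, 0.0, c],
        ]
    )
    frac = np.array([[1 / 3, 2 / 3, 1 / 4], [2 / 3, 1 / 3, 3 / 4]])
    return Structure([symbol, symbol], frac @ lat, lattice=lat)


def hcp_kpath(n_per_segment: int = 30):
    """Gamma-M-K-Gamma-A path in fractional coordinates of the hcp cell."""
    pts = {
        "G": np.array([0.0, 0.0, 0.0]),
        "M": np.array([0.5, 0.0, 0.0]),
        "K": np.array([1 / 3, 1 / 3, 0.0]),
        "A": np.array([0.0, 0.0, 0.5]),
    }
    names = ["G", "M", "K", "G", "A"]
    kpts, labels = [], []
    for p, q in zip(names[:-1], names[1:]):
        seg = np.linspace(pts[p], pts[q], n_per_segment, endpoint=False)
        kpts.extend(seg)
        labels.append(p)
    kpts.append(pts[names[-1]])
    labels.append(names[-1])
    return np.array(kpts), names
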