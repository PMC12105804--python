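"""Element data: symbols, masses, and neutral ground-state configurations.

Configurations are spherically averaged, spin-unpolarized occupations
(n, l, f) sufficient for all-electron radial Kohn-Sham calculations up to
Z = 56.  Aufbau ordering follows the Madelung rule with the usual d-block
exceptions tabulated explicitly (Cr, Cu, Nb, Mo, Ru, Rh, Pd, Ag).
Zirconium is [Kr] 4d2 5s2.
"""

from __future__ import annotations

SYMBOLS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
    "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr",
    "Rb", "Sr", "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd",
    "In", "Sn", "Sb", "Te", "I", "Xe", "Cs", "Ba",
]

ATOMIC_NUMBER = {s: z for z, s in enumerate(SYMBOLS)}

# Standard atomic weights (u); enough for .skf headers.
MASS = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
    "Sc": 44.956, "Ti": 47.867, "V": 50.942, "Cr": 51.996, "Mn": 54.938,
    "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546, "Zn": 65.38,
    "Ga": 69.723, "Ge": 72.630, "As": 74.922, "Se": 78.971, "Br": 79.904,
    "Kr": 83.798, "Rb": 85.468, "Sr": 87.62, "Y": 88.906, "Zr": 91.224,
    "Nb": 92.906, "Mo": 95.95, "Tc": 98.0, "Ru": 101.07, "Rh": 102.91,
    "Pd": 106.42, "Ag": 107.87, "Cd": 112.41, "In": 114.82, "Sn": 118.71,
    "Sb": 121.76, "Te": 127.60, "I": 126.90, "Xe": 131.29,
    "Cs": 132.91, "Ba": 137.33,
}

# Covalent radii (Angstrom, Cordero et al. compilation) for bond detection.
COVALENT_RADIUS = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76,
    "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41,
    "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Sc": 1.70, "Ti": 1.60, "V": 1.53, "Cr": 1.39,
    "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Ga": 1.22, "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95, "Y": 1.90, "Zr": 1.75, "Nb": 1.64, "Mo": 1.54,
    "Tc": 1.47, "Ru": 1.46, "Rh": 1.42, "Pd": 1.39, "Ag": 1.45, "Cd": 1.44,
    "In": 1.42, "Sn": 1.39, "Sb": 1.39, "Te": 1.38, "I": 1.39, "Xe": 1.40,
    "Cs": 2.44, "Ba": 2.15,
}

# Madelung filling order of (n, l) subshells.
_MADELUNG = [
    (1, 0), (2, 0), (2, 1), (3, 0), (3, 1), (4, 0), (3, 2), (4, 1),
    (5, 0), (4, 2), (5, 1), (6, 0), (4, 3), (5, 2), (6, 1), (7, 0),
]

# d-block exceptions: Z -> full configuration overrides as {(n,l): occ}.
_EXCEPTIONS = {
    24: {(4, 0): 1, (3, 2): 5},   # Cr
    29: {(4, 0): 1, (3, 2): 10},  # Cu
    41: {(5, 0): 1, (4, 2): 4},   # Nb
    42: {(5, 0): 1, (4, 2): 5},   # Mo
    44: {(5, 0): 1, (4, 2): 7},   # Ru
    45: {(5, 0): 1, (4, 2): 8},   # Rh
    46: {(5, 0): 0, (4, 2): 10},  # Pd
    47: {(5, 0): 1, (4, 2): 10},  # Ag
}


def ground_configuration(Z: int) -> list[tuple[int, int, float]]:
    """Neutral ground-state (n, l, occupation) list for atomic number Z."""
    if not 1 <= Z <= 56:
        raise ValueError(f"no configuration data for Z={Z}")
    occ: dict[tuple[int, int], float] = {}
    remaining = Z
    for (n, l) in _MADELUNG:
        cap = 2 * (2 * l + 1)
        f = min(cap, remaining)
        if f > 0:
            occ[(n, l)] = float(f)
        remaining -= f
        if remaining <= 0:
            break
    for shell, f in _EXCEPTIONS.get(Z, {}).items():
        occ[shell] = float(f)
        if f == 0:
            occ.pop(shell)
    return [(n, l, f) for (n, l), f in sorted(occ.items())]


def default_valence(Z: int) -> list[tuple[int, int]]:
    """Minimal-basis valence shells: outermost s (+p) and any open d shell.

    For main-group elements an unoccupied outer p shell is included (e.g. H 2p
    is *not*: only shells of the occupied principal quantum number).  For the
    4d metals the valence is (5s, 5p, 4d), matching the lmax=2 convention.
    """
    conf = ground_configuration(Z)
    nmax = max(n for n, l, f in conf)
    val = [(n, l) for n, l, f in conf if n == nmax]
    # open/recent d shell one principal lower
    for n, l, f in conf:
        if l == 2 and n == nmax - 1:
            val.append((n, l))
    # p shell of the outermost period, even if empty (needed for sp bases)
    if Z > 4 and (nmax, 1) not in val:
        val.append((nmax, 1))
    return sorted(val)
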