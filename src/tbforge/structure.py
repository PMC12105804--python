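"""Molecular/crystal structures and (extended) XYZ input/output.

Coordinates are Angstrom at the file boundary and bohr internally, following
the convention that all quantum-mechanical quantities are atomic units.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM
from .elements import ATOMIC_NUMBER

_MIN_DIST_BOHR = 0.1 * ANGSTROM_TO_BOHR


@dataclass
class Structure:
    """Element symbols + Cartesian coordinates (bohr) + optional lattice.

    ``lattice`` is a 3x3 array of row vectors in bohr; ``charge`` is the net
    charge in units of e (electron-deficit positive).
    """

    symbols: list
    positions: np.ndarray
    lattice: np.ndarray | None = None
    charge: int = 0
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.symbols), 3):
            raise ValueError("positions must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        for s in self.symbols:
            if s not in ATOMIC_NUMBER:
                raise ValueError(f"unknown element {s!r}")
        if self.lattice is not None:
            self.lattice = np.asarray(self.lattice, dtype=float)
            if self.lattice.shape != (3, 3):
                raise ValueError("lattice must be 3x3")
        if len(self.symbols) > 1:
            d = self.distance_matrix()
            np.fill_diagonal(d, np.inf)
            if d.min() < _MIN_DIST_BOHR:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                raise ValueError(
                    f"atoms {i} and {j} closer than 0.1 Angstrom "
                    f"({d.min() * BOHR_TO_ANGSTROM:.3f} A)"
                )

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def periodic(self) -> bool:
        return self.lattice is not None

    def distance_matrix(self) -> np.ndarray:
        """Pairwise distances (bohr), minimum-image for periodic systems."""
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        if self.periodic:
            frac = diff @ np.linalg.inv(self.lattice)
            frac -= np.round(frac)
            diff = frac @ self.lattice
        return np.linalg.norm(diff, axis=-1)

    def copy(self) -> "Structure":
        return Structure(
            list(self.symbols),
            self.positions.copy(),
            None if self.lattice is None else self.lattice.copy(),
            self.charge,
            dict(self.info),
        )


def from_angstrom(
    symbols, positions_ang, lattice_ang=None, charge: int = 0
) -> Structure:
    lat = None if lattice_ang is None else np.asarray(lattice_ang) * ANGSTROM_TO_BOHR
    return Structure(
        list(symbols), np.asarray(positions_ang) * ANGSTROM_TO_BOHR, lat, charge
    )


def read_xyz(path) -> Structure:
    """Read an (extended) XYZ file; supports Lattice= and charge= tags."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"empty XYZ file: {path}")
    n = int(lines[0].split()[0])
    comment = lines[1] if len(lines) > 1 else ""
    lattice = None
    charge = 0
    m = re.search(r'Lattice="([^"]+)"', comment)
    if m:
        vals = [float(x) for x in m.group(1).split()]
        if len(vals) != 9:
            raise ValueError("Lattice tag must contain 9 numbers")
        lattice = np.array(vals).reshape(3, 3)
    m = re.search(r"charge=(-?\d+)", comment)
    if m:
        charge = int(m.group(1))
    symbols, pos = [], []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        symbols.append(parts[0])
        pos.append([float(x) for x in parts[1:4]])
    if len(symbols) != n:
        raise ValueError(f"XYZ header promises {n} atoms, found {len(symbols)}")
    return from_angstrom(symbols, np.array(pos), lattice, charge)


def write_xyz(structure: Structure, path, comment: str = "") -> None:
    tags = []
    if structure.periodic:
        lat = (structure.lattice * BOHR_TO_ANGSTROM).ravel()
        tags.append('Lattice="' + " ".join(f"{x:.10f}" for x in lat) + '"')
    if structure.charge:
        tags.append(f"charge={structure.charge}")
    if comment:
        tags.append(comment)
    with open(path, "w") as fh:
        fh.write(f"{len(structure)}\n")
        fh.write(" ".join(tags) + "\n")
        for s, p in zip(structure.symbols, structure.positions * BOHR_TO_ANGSTROM):
            fh.write(f"{s:2s} {p[0]:18.10f} {p[1]:18.10f} {p[2]:18.10f}\n")
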