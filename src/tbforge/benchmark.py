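"""Benchmark harness for metal-ligand association/exchange energies.

Starting geometries for M L_x complexes are built from idealized
coordination polyhedra (square antiprism for 8-fold, capped trigonal prism
for 7-fold coordination) and then relaxed, since published benchmarks print
energies at optimized minima rather than geometries.  The registry is a
YAML file, one entry per reaction, carrying the printed high-level
reference value so the harness can report deviations, MAD and MAX.
"""

from __future__ import annotations

import logging

import numpy as np
import yaml

from .constants import ANGSTROM_TO_BOHR
from .engine import ParameterSet
from .structure import Structure, read_xyz
from .validation import AssociationReaction, BenchmarkRow, reaction_energy, run_benchmark

logger = logging.getLogger(__name__)

# idealized unit vertex sets for n-fold coordination
_VERTS = {
    1: [(0, 0, 1)],
    2: [(0, 0, 1), (0, 0, -1)],
    3: [(1, 0, 0), (-0.5, np.sqrt(3) / 2, 0), (-0.5, -np.sqrt(3) / 2, 0)],
    4: [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)],
    5: [(0, 0, 1), (0, 0, -1), (1, 0, 0),
        (-0.5, np.sqrt(3) / 2, 0), (-0.5, -np.sqrt(3) / 2, 0)],
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
}


def _capped_trigonal_prism():
    """7-fold: trigonal prism plus one rectangular-face cap."""
    top = [(np.cos(a), np.sin(a), 0.8) for a in (0, 2 * np.pi / 3, 4 * np.pi / 3)]
    bot = [(np.cos(a), np.sin(a), -0.8) for a in (0, 2 * np.pi / 3, 4 * np.pi / 3)]
    cap = [(-1.3, 0.0, 0.0)]
    return top + bot + cap


def _square_antiprism():
    """8-fold: two squares rotated by 45 degrees."""
    top = [(np.cos(a), np.sin(a), 0.85) for a in np.arange(4) * np.pi / 2]
    bot = [(np.cos(a + np.pi / 4), np.sin(a + np.pi / 4), -0.85)
           for a in np.arange(4) * np.pi / 2]
    return top + bot


def coordination_vertices(n: int) -> np.ndarray:
    if n == 7:
        v = _capped_trigonal_prism()
    elif n == 8:
        v = _square_antiprism()
    elif n in _VERTS:
        v = _VERTS[n]
    else:
        raise ValueError(f"no idealized polyhedron for coordination {n}")
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v, axis=1)[:, None]


# minimal internal ligand geometries (Angstrom, donor atom at origin,
# attachment axis along -z so the donor points at the metal)
_LIGANDS = {
    "H2O": (["O", "H", "H"],
            [[0, 0, 0], [0.76, 0, 0.59], [-0.76, 0, 0.59]]),
    "NH3": (["N", "H", "H", "H"],
            [[0, 0, 0], [0.94, 0, 0.38], [-0.47, 0.81, 0.38],
             [-0.47, -0.81, 0.38]]),
    "SH2": (["S", "H", "H"],
            [[0, 0, 0], [1.2, 0, 0.75], [-1.2, 0, 0.75]]),
    "PH3": (["P", "H", "H", "H"],
            [[0, 0, 0], [1.19, 0, 0.77], [-0.6, 1.03, 0.77],
             [-0.6, -1.03, 0.77]]),
    "CH3": (["C", "H", "H", "H"],
            [[0, 0, 0], [1.03, 0, 0.36], [-0.51, 0.89, 0.36],
             [-0.51, -0.89, 0.36]]),
    "OH": (["O", "H"], [[0, 0, 0], [0.68, 0, 0.68]]),
    "SH": (["S", "H"], [[0, 0, 0], [1.15, 0, 0.75]]),
    "H": (["H"], [[0, 0, 0]]),
    "Na": (["Na"], [[0, 0, 0]]),
    "K": (["K"], [[0, 0, 0]]),
    "Mg": (["Mg"], [[0, 0, 0]]),
    "Ca": (["Ca"], [[0, 0, 0]]),
    "Zn": (["Zn"], [[0, 0, 0]]),
    "F": (["F"], [[0, 0, 0]]),
    "Cl": (["Cl"], [[0, 0, 0]]),
    "Br": (["Br"], [[0, 0, 0]]),
    "I": (["I"], [[0, 0, 0]]),
    "CN": (["C", "N"], [[0, 0, 0], [0, 0, 1.16]]),
}


def build_complex(
    metal: str,
    ligand: str,
    n_ligands: int,
    charge: int,
    *,
    bond_length_ang: float = 2.3,
) -> Structure:
    """Idealized-polyhedron starting structure for [M(L)_n]^charge."""
    if ligand not in _LIGANDS:
        raise KeyError(f"no internal geometry for ligand {ligand!r}")
    syms = [metal]
    pos = [np.zeros(3)]
    verts = coordination_vertices(n_ligands)
    lsyms, lpos = _LIGANDS[ligand]
    lpos = np.asarray(lpos, dtype=float)
    for v in verts:
        # rotate ligand's +z (lone-pair back side) to point away from metal
        R = _rotate_z_to(v)
        for s, p in zip(lsyms, lpos):
            syms.append(s)
            pos.append(v * bond_length_ang + R @ p)
    return Structure(
        syms, np.asarray(pos) * ANGSTROM_TO_BOHR, charge=charge
    )


def build_mixed_complex(
    metal: str,
    ligands,
    charge: int,
    *,
    bond_length_ang: float = 2.3,
) -> Structure:
    """[M(L1)_a(L2)_b ...] on one idealized polyhedron.

    ``ligands`` is a list of (ligand_name, count); vertices are filled in
    order.
    """
    total = sum(n for _l, n in ligands)
    verts = coordination_vertices(total)
    syms = [metal]
    pos = [np.zeros(3)]
    i = 0
    for name, count in ligands:
        lsyms, lpos = _LIGANDS[name]
        lpos = np.asarray(lpos, dtype=float)
        for _ in range(count):
            v = verts[i]
            i += 1
            R = _rotate_z_to(v)
            for s, p in zip(lsyms, lpos):
                syms.append(s)
                pos.append(v * bond_length_ang + R @ p)
    return Structure(syms, np.asarray(pos) * ANGSTROM_TO_BOHR, charge=charge)


def free_ligand(ligand: str, charge: int = 0) -> Structure:
    lsyms, lpos = _LIGANDS[ligand]
    return Structure(
        list(lsyms), np.asarray(lpos, float) * ANGSTROM_TO_BOHR, charge=charge
    )


def _rotate_z_to(v: np.ndarray) -> np.ndarray:
    from .rotations import rotation_to_z

    return rotation_to_z(v)


def load_registry(path) -> list:
    """Parse the YAML benchmark registry into reaction rows.

    Each entry:
      label, reference (kcal/mol), optimize (bool), and species lists
      ``reactants``/``products`` with either xyz paths or complex builders
      ({metal, ligand, n, charge} / {ligand, charge}).
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    entries = []
    for item in data.get("reactions", []):
        entries.append(item)
    return entries


def _species(spec: dict) -> Structure:
    if "xyz" in spec:
        s = read_xyz(spec["xyz"])
        if "charge" in spec:
            s.charge = spec["charge"]
        return s
    if "metal" in spec:
        if "ligands" in spec:
            return build_mixed_complex(
                spec["metal"],
                [(d["ligand"], d["n"]) for d in spec["ligands"]],
                spec.get("charge", 0),
                bond_length_ang=spec.get("bond_length", 2.3),
            )
        return build_complex(
            spec["metal"], spec["ligand"], spec["n"], spec.get("charge", 0),
            bond_length_ang=spec.get("bond_length", 2.3),
        )
    return free_ligand(spec["ligand"], spec.get("charge", 0))


def run_association_registry(registry_path, params_dir) -> dict:
    """Compute every registry reaction with the given parameter directory."""
    params = ParameterSet.from_directory(params_dir)
    from .cli import _fill_default_hubbards

    _fill_default_hubbards(params)
    entries = load_registry(registry_path)
    rows = [
        BenchmarkRow(label=e.get("label", f"rxn{i}"),
                     reference_value=float(e["reference"]))
        for i, e in enumerate(entries)
    ]

    def evaluate(row):
        e = next(x for x in entries if x.get("label", "") == row.label)
        rxn = AssociationReaction(
            reactants=[(s.get("coef", 1.0), _species(s)) for s in e["reactants"]],
            products=[(s.get("coef", 1.0), _species(s)) for s in e["products"]],
            label=row.label,
        )
        return reaction_energy(rxn, params, optimize=e.get("optimize", True))

    return run_benchmark(rows, evaluate)
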