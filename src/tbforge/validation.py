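"""Validation computations: association/exchange energies, Kabsch RMSD,
displacement filtering, and benchmark bookkeeping.

Energies are hartree internally; kcal/mol appears only at the reporting
boundary (1 hartree = 627.509474 kcal/mol).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import HARTREE_TO_KCALMOL
from .engine import ParameterSet, optimize_geometry, scc_solve
from .structure import Structure

logger = logging.getLogger(__name__)


@dataclass
class AssociationReaction:
    """reactants -> products with stoichiometric coefficients.

    ``reactants``/``products`` are lists of (coefficient, Structure).
    Element and charge balance are enforced.
    """

    reactants: list
    products: list
    label: str = ""

    def __post_init__(self) -> None:
        def totals(side):
            elems: dict = {}
            charge = 0.0
            for coef, s in side:
                charge += coef * s.charge
                for sym in s.symbols:
                    elems[sym] = elems.get(sym, 0.0) + coef
            return elems, charge

        re, rq = totals(self.reactants)
        pe, pq = totals(self.products)
        if re != pe:
            raise ValueError(f"element balance violated: {re} vs {pe}")
        if abs(rq - pq) > 1e-9:
            raise ValueError(f"charge balance violated: {rq} vs {pq}")

    def reversed(self) -> "AssociationReaction":
        return AssociationReaction(
            reactants=self.products, products=self.reactants,
            label=f"reverse({self.label})",
        )


def reaction_energy(
    reaction: AssociationReaction,
    params: ParameterSet,
    *,
    optimize: bool = False,
    **scc_kw,
) -> float:
    """Delta E = sum(products) - sum(reactants) in kcal/mol (0 K, no ZPE).

    With ``optimize=True`` every distinct species is relaxed at its own
    minimum before the energies are taken.
    """
    cache: dict = {}

    def energy(s: Structure) -> float:
        key = id(s)
        if key not in cache:
            try:
                if optimize and len(s) > 1:
                    _, res, _log = optimize_geometry(s, params, **scc_kw)
                else:
                    res = scc_solve(s, params, **scc_kw)
            except Exception as err:
                raise RuntimeError(
                    f"energy evaluation failed for species "
                    f"{''.join(s.symbols)} (charge {s.charge}): {err}"
                ) from err
            cache[key] = res.e_total
        return cache[key]

    de = sum(c * energy(s) for c, s in reaction.products) - sum(
        c * energy(s) for c, s in reaction.reactants
    )
    return float(de * HARTREE_TO_KCALMOL)


def association_energy(
    complex_before: Structure,
    ligand: Structure,
    complex_after: Structure,
    params: ParameterSet,
    *,
    optimize: bool = True,
    **scc_kw,
) -> float:
    """Ligand association  ML_x + L -> ML_{x+1}  in kcal/mol."""
    rxn = AssociationReaction(
        reactants=[(1.0, complex_before), (1.0, ligand)],
        products=[(1.0, complex_after)],
        label="association",
    )
    return reaction_energy(rxn, params, optimize=optimize, **scc_kw)


@dataclass
class RmsdReport:
    rmsd: float                   # Angstrom if inputs are Angstrom; here bohr
    rotation: np.ndarray
    translation: np.ndarray
    n_atoms: int
    excluded: tuple


def kabsch_rmsd(
    A: Structure | np.ndarray,
    B: Structure | np.ndarray,
    exclude: tuple = (),
    symbols=None,
) -> RmsdReport:
    """Minimal RMSD after optimal superposition (proper rotations only).

    Accepts Structures (atom order must match) or raw coordinate arrays with
    ``symbols``.  Elements in ``exclude`` (e.g. ("H",)) are dropped before
    the fit — the standard way to ignore freely rotating hydrogens.
    """
    if isinstance(A, Structure):
        symbols = A.symbols
        if not isinstance(B, Structure) or B.symbols != A.symbols:
            raise ValueError("structures must share the same atom list/order")
        P, Q = A.positions, B.positions
    else:
        P, Q = np.asarray(A, float), np.asarray(B, float)
        symbols = list(symbols or ["X"] * len(P))
    if P.shape != Q.shape:
        raise ValueError("coordinate shapes differ")
    keep = np.array([s not in exclude for s in symbols], dtype=bool)
    if not np.any(keep):
        raise ValueError("all atoms excluded from RMSD")
    P, Q = P[keep], Q[keep]
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = P0.T @ Q0
    U, _sv, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, sign])
    R = U @ D @ Vt            # proper rotation: P0 @ R ~ Q0
    diff = P0 @ R - Q0
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return RmsdReport(
        rmsd=rmsd, rotation=R, translation=cq - cp @ R,
        n_atoms=int(keep.sum()), excluded=tuple(exclude),
    )


def displacement_filter(
    A: Structure, B: Structure, threshold: float
) -> bool:
    """True (pass) iff no atom moved farther than ``threshold`` (same units
    as the coordinates) between the raw, unsuperposed geometries."""
    if A.symbols != B.symbols:
        raise ValueError("structures must share the same atom list/order")
    disp = np.linalg.norm(A.positions - B.positions, axis=1)
    return bool(np.max(disp) <= threshold)


def mad(deviations) -> float:
    """Mean absolute deviation."""
    d = np.asarray(list(deviations), dtype=float)
    return float(np.mean(np.abs(d)))


def max_abs(deviations) -> float:
    """Maximum absolute deviation."""
    d = np.asarray(list(deviations), dtype=float)
    return float(np.max(np.abs(d)))


@dataclass
class BenchmarkRow:
    label: str
    reference_value: float         # printed high-level value, kcal/mol
    computed: float | None = None

    @property
    def deviation(self) -> float | None:
        if self.computed is None:
            return None
        return self.computed - self.reference_value


def run_benchmark(rows, evaluate) -> dict:
    """Evaluate each row, returning per-row deviations plus MAD and MAX.

    ``evaluate(row) -> kcal/mol``; failures are recorded per row and the
    summary is computed over the successful rows.
    """
    report = {"rows": [], "mad": None, "max": None}
    devs = []
    for row in rows:
        entry = {"label": row.label, "reference": row.reference_value}
        try:
            row.computed = evaluate(row)
            entry["computed"] = row.computed
            entry["deviation"] = row.deviation
            devs.append(row.deviation)
        except Exception as err:  # noqa: BLE001 - collected per row
            entry["error"] = str(err)
            logger.warning("benchmark row %s failed: %s", row.label, err)
        report["rows"].append(entry)
    if devs:
        report["mad"] = mad(devs)
        report["max"] = max_abs(devs)
    return report
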