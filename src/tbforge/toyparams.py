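"""End-to-end generation of small self-consistent parameter sets.

These run the *full* pipeline (confined atomic DFT -> two-center tables ->
synthetic spline repulsive -> .skf) for light elements, giving every engine
test a parameter set whose provenance is the code under test rather than an
external download.  Deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
import os

import numpy as np

from .atom import (
    AtomicSpecies,
    ConfinementSpec,
    ShellConfinement,
    hubbard_parameter,
    solve_atom,
)
from .constants import ANGSTROM_TO_BOHR
from .elements import COVALENT_RADIUS
from .engine import ParameterSet
from .grid import RadialGrid
from .repulsive import ReferenceCurve, fit_spline
from .twocenter import two_center_tables

logger = logging.getLogger(__name__)

# confinement radii ~ 1.85 x covalent radius (bohr), the common rule of thumb
_WF_SCALE = 1.85
_DENS_SCALE = 3.6


def _toy_grid() -> RadialGrid:
    return RadialGrid(rmin=1e-9, rmax=40.0, n=600)


def default_confinement(symbol: str, species: AtomicSpecies) -> ConfinementSpec:
    r_cov = COVALENT_RADIUS[symbol] * ANGSTROM_TO_BOHR
    wf = {}
    for (n, l) in species.valence_shells:
        wf["spd"[l]] = ShellConfinement(_WF_SCALE * r_cov, 2.0)
    return ConfinementSpec(wf=wf, dens=ShellConfinement(_DENS_SCALE * r_cov, 2.0))


def generate_toy_parameter_set(
    elements=("H", "O"),
    seed: int = 0,
    *,
    directory=None,
    step: float = 0.05,
    with_repulsive: bool = True,
    quad_order: tuple = (40, 30),
) -> ParameterSet:
    """Full-pipeline parameter set for light elements.

    When ``directory`` is given, all .skf files are written there as well.
    The repulsive splines are synthetic short-range exponentials fitted
    through the spline machinery (their ground truth is recorded in
    table.meta['rep_truth'] as (amplitude, decay length, cutoff)).
    """
    rng = np.random.default_rng(seed)
    grid = _toy_grid()
    basis, dens, free, hubbards, hubbard_derivs = {}, {}, {}, {}, {}
    for sym in elements:
        sp = AtomicSpecies.from_symbol(sym)
        conf = default_confinement(sym, sp)
        basis[sym] = solve_atom(sp, conf, grid=grid)
        dens[sym] = solve_atom(sp, conf.density_only(), grid=grid)
        free[sym] = solve_atom(sp, grid=grid)
        # chemical hardness from the eigenvalue derivative of the HOMO shell
        # (fast and bound for every light element); its charge derivative by
        # central differences
        hubbards[sym] = _janak_hubbard(sp, grid, 0.0)
        up = _janak_hubbard(sp, grid, +0.1)
        um = _janak_hubbard(sp, grid, -0.1)
        hubbard_derivs[sym] = (up - um) / 0.2

    tables = {}
    for i, sa in enumerate(elements):
        for sb in elements[i:]:
            tabs = two_center_tables(
                basis[sa], basis[sb], dens[sa], dens[sb],
                step=step, start=step,
                free_solutions=free, quad_order=quad_order,
                hubbards={s: {l: hubbards[s] for l in (0, 1, 2)} for s in elements},
            )
            tables.update(tabs)

    if with_repulsive:
        for (sa, sb), t in tables.items():
            if (sb, sa) in tables and (sb, sa) < (sa, sb):
                continue
            # exponential-repulsion ground truth scaled so the pair curve has
            # its minimum near the covalent bond length (the electronic
            # attraction slope there is a few tenths of a hartree per bohr)
            rc = (COVALENT_RADIUS[sa] + COVALENT_RADIUS[sb]) * ANGSTROM_TO_BOHR
            amp = float(rng.uniform(6.0, 10.0))
            rho = float(rng.uniform(0.22, 0.28)) * rc
            cut = 2.2 * rc
            d = np.linspace(0.55 * rc, cut - 0.05, 40)
            truth = amp * (np.exp(-d / rho) - np.exp(-cut / rho))
            rep = fit_spline(
                list(zip(d, truth)), knots=8, cutoff=cut
            )
            t.repulsive = rep
            t.meta["rep_truth"] = (amp, rho, cut)
            if (sb, sa) in tables:
                tables[(sb, sa)].repulsive = rep
                tables[(sb, sa)].meta["rep_truth"] = (amp, rho, cut)

    params = ParameterSet(
        tables=tables,
        hubbards=hubbards,
        hubbard_derivs=hubbard_derivs,
    )
    if directory is not None:
        from .skf import write_skf

        os.makedirs(directory, exist_ok=True)
        for (sa, sb), t in tables.items():
            write_skf(t, os.path.join(str(directory), f"{sa}-{sb}.skf"))
    return params


def _janak_hubbard(sp: AtomicSpecies, grid: RadialGrid, dq: float) -> float:
    """d eps_HOMO / d n at electron count N0 + dq (aufbau filling)."""
    n0 = sp.n_electrons + dq
    step = 0.05
    sols = [
        solve_atom(sp, grid=grid, n_electrons=n0 + s, aufbau=True)
        for s in (-step, +step)
    ]
    homos = []
    for sol in sols:
        occ_shells = [s for s, f in sol.occupations.items() if f > 1e-6]
        homo = max(occ_shells, key=lambda s: sol.eigenvalues[s])
        homos.append(sol.eigenvalues[homo])
    return (homos[1] - homos[0]) / (2 * step)


def synthetic_reference_curves(
    pair: tuple,
    params: ParameterSet,
    structures: list,
    distances: np.ndarray,
    *,
    truth,
    noise: float = 0.0,
    seed: int = 0,
) -> ReferenceCurve:
    """Reference curve with a known repulsive ground truth.

    E_ref(d) = E_elec(d) + V_truth(d) + noise, where E_elec is the engine's
    electronic (non-repulsive) energy at each scan geometry.  ``truth`` is
    any callable V(d).
    """
    from .engine import scc_solve

    rng = np.random.default_rng(seed)
    e_elec = np.array(
        [scc_solve(s, params).e_elec for s in structures]
    )
    v = np.array([truth(d) for d in distances], dtype=float)
    e_ref = e_elec + v + (rng.normal(0.0, noise, len(v)) if noise > 0 else 0.0)
    return ReferenceCurve(
        pair=pair, distances=np.asarray(distances, float),
        e_ref=e_ref, e_elec=e_elec, structures=list(structures),
    )
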