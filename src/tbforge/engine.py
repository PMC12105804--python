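"""Self-consistent-charge DFTB3 total energies for molecular systems.

The total energy is the third-order tight-binding expansion

    E = E_H0 + 1/2 sum_ab dq_a dq_b gamma_ab
             + 1/3 sum_ab dq_a^2 dq_b Gamma_ab + E_rep (+ E_disp)

with Mulliken charge fluctuations dq solved self-consistently through the
charge-dependent Hamiltonian

    H_uv = H0_uv + S_uv sum_c dq_c [ (gamma_ac + gamma_bc)/2
           + (dq_a Gamma_ac + dq_b Gamma_bc)/3
           + dq_c (Gamma_ca + Gamma_cb)/6 ],   u in a, v in b.

Parameter sets are closed maps species-pair -> Slater-Koster table plus
per-species Hubbard U and its charge derivative.  Periodic SCC (Ewald
summation of gamma) is deliberately unsupported; periodic inputs are
rejected rather than approximated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh

from .gamma import gamma, gamma_derivative
from .rotations import sk_rotate
from .structure import Structure
from .twocenter import SlaterKosterTable

logger = logging.getLogger(__name__)


class SCCError(RuntimeError):
    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history or []


@dataclass
class ParameterSet:
    """Closed set of Slater-Koster tables + per-species SCC parameters."""

    tables: dict                      # (symA, symB) -> SlaterKosterTable
    hubbards: dict                    # sym -> U (hartree)
    hubbard_derivs: dict              # sym -> Ud (hartree / e)
    zeta: float = 4.0
    dispersion: dict = field(default_factory=dict)

    def table(self, sa: str, sb: str) -> SlaterKosterTable:
        try:
            return self.tables[(sa, sb)]
        except KeyError:
            raise KeyError(f"no Slater-Koster table for pair {(sa, sb)}")

    def lvals(self, sym: str) -> list:
        t = self.table(sym, sym)
        ls = {c[0] for c in t.h} | {c[1] for c in t.h}
        return sorted(ls)

    def neutral_electrons(self, sym: str) -> float:
        t = self.table(sym, sym)
        return float(sum(t.occupations.values()))

    def onsite(self, sym: str) -> dict:
        return self.table(sym, sym).onsite

    def check_closed(self, symbols) -> None:
        for sa in set(symbols):
            for sb in set(symbols):
                self.table(sa, sb)
            if sa not in self.hubbards or sa not in self.hubbard_derivs:
                raise KeyError(f"missing Hubbard data for {sa}")

    @classmethod
    def from_directory(cls, path, hubbards=None, hubbard_derivs=None, **kw):
        """Load every <A>-<B>.skf file in a directory."""
        import glob, os
        from .skf import read_skf

        tables = {}
        for fn in sorted(glob.glob(os.path.join(str(path), "*.skf"))):
            t = read_skf(fn)
            tables[t.pair] = t
        hub = dict(hubbards or {})
        hubd = dict(hubbard_derivs or {})
        for (sa, sb), t in tables.items():
            if sa == sb and sa not in hub and t.hubbard:
                # atom-resolved convention: use the s-shell slot
                hub[sa] = t.hubbard.get(0, max(t.hubbard.values()))
        return cls(tables=tables, hubbards=hub, hubbard_derivs=hubd, **kw)


@dataclass
class SCCResult:
    charges: np.ndarray               # Mulliken dq per atom (excess electrons)
    coefficients: np.ndarray          # MO coefficients, column per orbital
    occupations: np.ndarray
    orbital_energies: np.ndarray
    e_h0: float
    e_gamma: float
    e_gamma3: float
    e_rep: float
    e_disp: float
    history: list = field(default_factory=list)

    @property
    def e_elec(self) -> float:
        """Electronic energy (everything except the repulsive term)."""
        return self.e_h0 + self.e_gamma + self.e_gamma3 + self.e_disp

    @property
    def e_total(self) -> float:
        return self.e_h0 + self.e_gamma + self.e_gamma3 + self.e_rep + self.e_disp


def _basis_layout(structure: Structure, params: ParameterSet):
    offsets, sizes = [], []
    off = 0
    for sym in structure.symbols:
        n = sum(2 * l + 1 for l in params.lvals(sym))
        offsets.append(off)
        sizes.append(n)
        off += n
    return offsets, sizes, off


def build_h0_s(structure: Structure, params: ParameterSet):
    """Assemble the non-SCC Hamiltonian and overlap matrices."""
    offsets, sizes, ntot = _basis_layout(structure, params)
    H0 = np.zeros((ntot, ntot))
    S = np.eye(ntot)
    for a, sym in enumerate(structure.symbols):
        ons = params.onsite(sym)
        i = offsets[a]
        for l in params.lvals(sym):
            for _m in range(2 * l + 1):
                H0[i, i] = ons.get(l, 0.0)
                i += 1
    pos = structure.positions
    n_at = len(structure)
    for a in range(n_at):
        for b in range(a + 1, n_at):
            sa, sb = structure.symbols[a], structure.symbols[b]
            disp = pos[b] - pos[a]
            h, s = sk_rotate(
                params.table(sa, sb), params.table(sb, sa), disp,
                params.lvals(sa), params.lvals(sb),
            )
            ia, ib = offsets[a], offsets[b]
            H0[ia : ia + sizes[a], ib : ib + sizes[b]] = h
            S[ia : ia + sizes[a], ib : ib + sizes[b]] = s
            H0[ib : ib + sizes[b], ia : ia + sizes[a]] = h.T
            S[ib : ib + sizes[b], ia : ia + sizes[a]] = s.T
    return H0, S, offsets, sizes


def _gamma_matrices(structure: Structure, params: ParameterSet):
    n = len(structure)
    G = np.zeros((n, n))
    G3 = np.zeros((n, n))  # Gamma_ab, row index carries Ud_a
    d = structure.distance_matrix()
    for a in range(n):
        sa = structure.symbols[a]
        Ua, Uda = params.hubbards[sa], params.hubbard_derivs[sa]
        for b in range(n):
            sb = structure.symbols[b]
            Ub = params.hubbards[sb]
            xh = "H" in (sa, sb)
            G[a, b] = gamma(Ua, Ub, d[a, b], xh_pair=xh, zeta=params.zeta)
            G3[a, b] = gamma_derivative(
                Ua, Ub, d[a, b], Uda, xh_pair=xh, zeta=params.zeta
            )
    return G, G3


def _fill_aufbau(eps: np.ndarray, n_electrons: float, degeneracy_tol=1e-8):
    occ = np.zeros_like(eps)
    remaining = n_electrons
    i = 0
    n = len(eps)
    while i < n and remaining > 1e-12:
        j = i + 1
        while j < n and eps[j] - eps[i] < degeneracy_tol:
            j += 1
        cap = 2.0 * (j - i)
        take = min(cap, remaining)
        occ[i:j] = take / (j - i)
        remaining -= take
        i = j
    if remaining > 1e-9:
        raise SCCError("more electrons than basis states")
    return occ


def scc_solve(
    structure: Structure,
    params: ParameterSet,
    *,
    charges0: np.ndarray | None = None,
    tol: float = 1e-8,
    mix: float = 0.2,
    maxiter: int = 200,
    dispersion: bool | None = None,
    third_order: bool = True,
) -> SCCResult:
    """Converge the SCC-DFTB3 equations for a molecular structure."""
    if structure.periodic:
        raise ValueError(
            "periodic SCC (Ewald gamma summation) is unsupported; "
            "use band_structure for non-SCC crystals"
        )
    params.check_closed(structure.symbols)
    H0, S, offsets, sizes = build_h0_s(structure, params)
    cond = np.linalg.cond(S)
    if cond > 1e10:
        d = structure.distance_matrix()
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise SCCError(
            f"overlap matrix ill-conditioned (cond={cond:.2e}); "
            f"closest pair {i}-{j} at {d[i, j]:.3f} bohr"
        )
    G, G3 = _gamma_matrices(structure, params)
    n_at = len(structure)
    q0 = np.array([params.neutral_electrons(s) for s in structure.symbols])
    n_elec = q0.sum() - structure.charge
    dq = np.zeros(n_at) if charges0 is None else np.asarray(charges0, float).copy()

    history = []
    diis_q, diis_r = [], []
    eps = occ = C = None
    for it in range(1, maxiter + 1):
        H = H0.copy()
        if np.any(dq != 0.0):
            g_vec = G @ dq                       # sum_c dq_c gamma_ac
            t1 = G3 @ dq                         # sum_c dq_c Gamma_ac
            t2 = G3.T @ (dq * dq)                # sum_c dq_c^2 Gamma_ca
            omega_at = np.zeros((n_at, n_at))
            for a in range(n_at):
                for b in range(n_at):
                    omega_at[a, b] = 0.5 * (g_vec[a] + g_vec[b])
                    if third_order:
                        omega_at[a, b] += (
                            (dq[a] * t1[a] + dq[b] * t1[b]) / 3.0
                            + (t2[a] + t2[b]) / 6.0
                        )
            omega = np.zeros_like(H0)
            for a in range(n_at):
                ia = offsets[a]
                for b in range(n_at):
                    ib = offsets[b]
                    omega[ia : ia + sizes[a], ib : ib + sizes[b]] = omega_at[a, b]
            H = H0 + S * omega
        eps, C = eigh(H, S)
        occ = _fill_aufbau(eps, n_elec)
        P = (C * occ) @ C.T
        PS = P @ S
        pops = np.array(
            [np.trace(PS[offsets[a] : offsets[a] + sizes[a],
                         offsets[a] : offsets[a] + sizes[a]])
             for a in range(n_at)]
        )
        dq_out = pops - q0
        res = dq_out - dq
        rms = float(np.max(np.abs(res)))
        history.append(rms)
        if rms < tol:
            dq = dq_out
            break
        # Anderson/DIIS mixing on the charge vector
        diis_q.append(dq_out.copy())
        diis_r.append(res.copy())
        if len(diis_q) > 6:
            diis_q.pop(0)
            diis_r.pop(0)
        dq_new = None
        if len(diis_q) >= 2:
            m = len(diis_r)
            B = np.empty((m + 1, m + 1))
            B[:m, :m] = np.array(
                [[ri @ rj for rj in diis_r] for ri in diis_r]
            )
            B[m, :m] = B[:m, m] = 1.0
            B[m, m] = 0.0
            rhs = np.zeros(m + 1)
            rhs[m] = 1.0
            try:
                coef = np.linalg.solve(
                    B + 1e-14 * np.eye(m + 1), rhs
                )[:m]
                if np.all(np.isfinite(coef)) and np.abs(coef).sum() < 30:
                    dq_new = sum(
                        c * (qq + mix * rr)
                        for c, qq, rr in zip(coef, diis_q, diis_r)
                    )
            except np.linalg.LinAlgError:
                pass
        if dq_new is None:
            dq_new = dq + mix * res
        dq = dq_new
    else:
        raise SCCError(
            f"SCC did not converge in {maxiter} cycles (residual {history[-1]:.2e})",
            history,
        )

    e_h0 = float(np.sum(P * H0))
    e_gamma = 0.5 * float(dq @ G @ dq)
    e_gamma3 = float(np.sum((dq**2)[:, None] * dq[None, :] * G3)) / 3.0 \
        if third_order else 0.0
    e_rep = repulsive_energy(structure, params)
    do_disp = params.dispersion.get("enabled", False) if dispersion is None \
        else dispersion
    e_disp = dispersion_energy(structure, params.dispersion) if do_disp else 0.0
    return SCCResult(
        charges=dq, coefficients=C, occupations=occ, orbital_energies=eps,
        e_h0=e_h0, e_gamma=e_gamma, e_gamma3=e_gamma3,
        e_rep=e_rep, e_disp=e_disp, history=history,
    )


def repulsive_energy(structure: Structure, params: ParameterSet) -> float:
    """Pairwise repulsive energy from the tables' spline blocks."""
    d = structure.distance_matrix()
    e = 0.0
    n = len(structure)
    for a in range(n):
        for b in range(a + 1, n):
            sa, sb = structure.symbols[a], structure.symbols[b]
            rep = params.table(sa, sb).repulsive
            if rep is None:
                rep = params.table(sb, sa).repulsive
            if rep is None:
                # no spline: treated as zero only beyond every table cutoff
                t = params.table(sa, sb)
                if d[a, b] < t.cutoff:
                    raise SCCError(
                        f"no repulsive spline for pair {(sa, sb)} at "
                        f"{d[a, b]:.2f} bohr"
                    )
                continue
            e += rep(d[a, b])
    return float(e)


def dispersion_energy(structure: Structure, settings: dict) -> float:
    """Pairwise C6/C8 dispersion with Becke-Johnson damping.

    ``settings`` carries s6, s8, a1, a2 and per-element c6/c8 coefficients
    (atomic units); pair coefficients combine geometrically.  This is the
    fixed-coefficient two-body form of the usual D3(BJ) expression.
    """
    if not settings or not settings.get("c6"):
        raise ValueError("dispersion requested but no C6 coefficients given")
    s6 = settings.get("s6", 1.0)
    s8 = settings.get("s8", 0.0)
    a1 = settings.get("a1", 0.4)
    a2 = settings.get("a2", 4.8)
    c6map = settings["c6"]
    c8map = settings.get("c8", {})
    d = structure.distance_matrix()
    e = 0.0
    n = len(structure)
    for a in range(n):
        for b in range(a + 1, n):
            sa, sb = structure.symbols[a], structure.symbols[b]
            c6 = np.sqrt(c6map[sa] * c6map[sb])
            c8 = np.sqrt(c8map.get(sa, 0.0) * c8map.get(sb, 0.0))
            r = d[a, b]
            f = a1 * np.sqrt(c8 / c6 if c6 > 0 else 0.0) + a2
            e -= s6 * c6 / (r**6 + f**6)
            if c8 > 0:
                e -= s8 * c8 / (r**8 + f**8)
    return float(e)


def numerical_forces(
    structure: Structure,
    params: ParameterSet,
    step: float = 1e-3,
    **scc_kw,
) -> np.ndarray:
    """Central-difference forces -dE/dR (hartree/bohr)."""
    n = len(structure)
    forces = np.zeros((n, 3))
    for a in range(n):
        for ax in range(3):
            try:
                ep = _displaced_energy(structure, params, a, ax, +step, **scc_kw)
                em = _displaced_energy(structure, params, a, ax, -step, **scc_kw)
            except SCCError as err:
                raise SCCError(
                    f"SCC failed while displacing atom {a} axis {ax}: {err}"
                )
            forces[a, ax] = -(ep - em) / (2.0 * step)
    return forces


def _displaced_energy(structure, params, a, ax, delta, **scc_kw):
    new = structure.copy()
    new.positions[a, ax] += delta
    return scc_solve(new, params, **scc_kw).e_total


def optimize_geometry(
    structure: Structure,
    params: ParameterSet,
    *,
    fmax: float = 1e-4,
    maxsteps: int = 200,
    step: float = 1e-3,
    **scc_kw,
):
    """Quasi-Newton (L-BFGS-B) energy minimization with numerical forces.

    Returns (optimized Structure, SCCResult, trajectory-log).  If the
    iteration cap is hit the best-so-far geometry is returned with
    ``converged=False`` in the log.
    """
    from scipy.optimize import minimize

    x0 = structure.positions.ravel().copy()
    log = {"energies": [], "max_forces": [], "converged": False}

    def fun(x):
        s = structure.copy()
        s.positions = x.reshape(-1, 3)
        res = scc_solve(s, params, **scc_kw)
        f = numerical_forces(s, params, step=step, **scc_kw)
        log["energies"].append(res.e_total)
        log["max_forces"].append(float(np.abs(f).max()))
        return res.e_total, -f.ravel()

    res = minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": maxsteps, "ftol": 1e-13, "gtol": fmax},
    )
    out = structure.copy()
    out.positions = res.x.reshape(-1, 3)
    final = scc_solve(out, params, **scc_kw)
    f = numerical_forces(out, params, step=step, **scc_kw)
    log["converged"] = bool(np.abs(f).max() < fmax * 1.5)
    return out, final, log
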