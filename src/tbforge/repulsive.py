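"""Pairwise repulsive potentials: spline representation and fitting.

The repulsive term absorbs everything the electronic tight-binding part does
not capture.  It is represented exactly the way .skf files store it: an
exponential head exp(-a1 r + a2) + a3 below the first knot, C2-continuous
cubic segments, a 5th-order terminal segment, and value & slope pinned to
zero at the cutoff.

Fitting follows the usual protocol: reference-minus-electronic energy
differences along bond scans become targets V_rep(d); a constrained
weighted least-squares B-spline fit (equality constraints at the cutoff)
produces the segment coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline, PPoly

from .elements import COVALENT_RADIUS
from .constants import ANGSTROM_TO_BOHR
from .structure import Structure

logger = logging.getLogger(__name__)


@dataclass
class RepulsivePotential:
    """Knotted spline V_rep(r) with exponential head and quintic tail."""

    knots: np.ndarray                 # segment boundaries, increasing (bohr)
    coefficients: list                # per segment: 4 (cubic) or 6 (quintic)
    exp_coeffs: tuple                 # (a1, a2, a3)

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        if len(self.knots) < 2 or np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing, >= 2")
        if len(self.coefficients) != len(self.knots) - 1:
            raise ValueError("need one coefficient set per segment")

    @property
    def cutoff(self) -> float:
        return float(self.knots[-1])

    def __call__(self, r):
        r = np.asarray(r, dtype=float)
        scalar = r.ndim == 0
        r = np.atleast_1d(r)
        out = np.zeros_like(r)
        a1, a2, a3 = self.exp_coeffs
        head = r < self.knots[0]
        out[head] = np.exp(-a1 * r[head] + a2) + a3
        for i in range(len(self.knots) - 1)[::-1]:
            seg = (r >= self.knots[i]) & (r < self.knots[i + 1])
            if not np.any(seg):
                continue
            x = r[seg] - self.knots[i]
            c = self.coefficients[i]
            out[seg] = sum(cj * x**j for j, cj in enumerate(c))
        # r >= cutoff stays 0
        return float(out[0]) if scalar else out

    def derivative(self, r, order: int = 1):
        r = np.asarray(r, dtype=float)
        scalar = r.ndim == 0
        r = np.atleast_1d(r)
        out = np.zeros_like(r)
        a1, a2, a3 = self.exp_coeffs
        head = r < self.knots[0]
        out[head] = (-a1) ** order * np.exp(-a1 * r[head] + a2)
        from math import factorial

        for i in range(len(self.knots) - 1)[::-1]:
            seg = (r >= self.knots[i]) & (r < self.knots[i + 1])
            if not np.any(seg):
                continue
            x = r[seg] - self.knots[i]
            c = self.coefficients[i]
            out[seg] = sum(
                cj * factorial(j) / factorial(j - order) * x ** (j - order)
                for j, cj in enumerate(c) if j >= order
            )
        return float(out[0]) if scalar else out


@dataclass
class ReferenceCurve:
    """A bond scan with high-level reference and electronic DFTB energies."""

    pair: tuple
    distances: np.ndarray          # bohr, strictly monotone
    e_ref: np.ndarray              # hartree
    e_elec: np.ndarray             # hartree (E_total - E_rep at same geometries)
    weights: np.ndarray | None = None
    structures: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.e_ref = np.asarray(self.e_ref, dtype=float)
        self.e_elec = np.asarray(self.e_elec, dtype=float)
        n = len(self.distances)
        if not (len(self.e_ref) == len(self.e_elec) == n):
            raise ValueError("mismatched curve array lengths")
        d = np.diff(self.distances)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("scan distances must be strictly monotone")


def make_scan(
    structure: Structure,
    bond: tuple,
    scales,
    ) -> list:
    """Geometries scanning one bond (molecular) or the lattice (crystal).

    Molecular scans displace the substituent group bonded through ``bond[1]``
    rigidly along the bond axis so that the bond length is scaled by each
    factor in ``scales``; crystal scans rescale lattice and coordinates
    isotropically.  Atom clashes below 0.3 Angstrom raise.
    """
    scales = np.atleast_1d(np.asarray(scales, dtype=float))
    if np.any(scales <= 0):
        raise ValueError("scale factors must be positive")
    out = []
    if structure.periodic:
        for s in scales:
            new = structure.copy()
            new.lattice = structure.lattice * s
            new.positions = structure.positions * s
            out.append(new)
        return out

    i, j = bond
    pos = structure.positions
    axis = pos[j] - pos[i]
    d0 = np.linalg.norm(axis)
    if d0 < 1e-8:
        raise ValueError("degenerate bond")
    axis = axis / d0
    group = _bonded_group(structure, i, j)
    for s in scales:
        new = structure.copy()
        shift = (s - 1.0) * d0 * axis
        for a in group:
            new.positions[a] = pos[a] + shift
        dmat = new.distance_matrix()
        np.fill_diagonal(dmat, np.inf)
        if dmat.min() < 0.3 * ANGSTROM_TO_BOHR:
            raise ValueError(f"atom clash at scale {s:.3f}")
        out.append(new)
    return out


def _bonded_group(structure: Structure, i: int, j: int) -> set:
    """Atoms on the j-side of bond (i, j), via covalent-radius connectivity."""
    n = len(structure)
    d = structure.distance_matrix()
    adj = {a: set() for a in range(n)}
    for a in range(n):
        for b in range(a + 1, n):
            rc = (
                COVALENT_RADIUS.get(structure.symbols[a], 1.5)
                + COVALENT_RADIUS.get(structure.symbols[b], 1.5)
            ) * ANGSTROM_TO_BOHR
            if d[a, b] < 1.3 * rc:
                adj[a].add(b)
                adj[b].add(a)
    group, stack = {j}, [j]
    while stack:
        cur = stack.pop()
        for nb in adj[cur]:
            if nb == i and cur == j:
                continue
            if nb not in group and nb != i:
                group.add(nb)
                stack.append(nb)
    return group


def residual_curve(ref: ReferenceCurve) -> tuple:
    """Target repulsive values: (distance, V_rep_target) pairs.

    The additive gauge is anchored at the largest scanned distance, where the
    repulsive is conventionally zero (the spline cutoff lies beyond the last
    data point): target(d) = [E_ref(d) - E_elec(d)] - [E_ref - E_elec](anchor).
    """
    d = ref.distances
    diff = ref.e_ref - ref.e_elec
    anchor = np.argmax(d)
    target = diff - diff[anchor]
    order = np.argsort(d)
    return d[order], target[order]


def fit_spline(
    targets,
    knots,
    cutoff: float,
    ) -> RepulsivePotential:
    """Weighted constrained least-squares spline fit of repulsive targets.

    ``targets`` is a sequence of (distance, value[, weight]) rows.  ``knots``
    is either an explicit increasing array (first knot = fit-range start) or
    an integer count for uniform placement over the data range.  The fitted
    spline is C2, has V = V' = 0 at ``cutoff``, a 5th-order terminal
    segment, and an exponential extrapolation below the first knot.
    """
    rows = [tuple(t) for t in targets]
    d = np.array([r[0] for r in rows], dtype=float)
    y = np.array([r[1] for r in rows], dtype=float)
    w = np.array([r[2] if len(r) > 2 else 1.0 for r in rows], dtype=float)
    if len(d) < 4:
        raise ValueError("need at least 4 data points")
    if cutoff <= d.max():
        raise ValueError("cutoff must lie beyond the last data point")
    if np.isscalar(knots) or np.ndim(knots) == 0:
        # uniform knots over the data range, plus a single tail segment out
        # to the cutoff where only the boundary constraints act
        kn = np.concatenate([np.linspace(d.min(), d.max(), int(knots)),
                             [cutoff]])
    else:
        kn = np.asarray(knots, dtype=float)
        if kn[0] > d.min() + 1e-9 or kn[-1] < cutoff - 1e-9:
            kn = np.unique(np.concatenate([[min(kn[0], d.min())], kn, [cutoff]]))
    if len(kn) < 3:
        raise ValueError("need at least 3 knots")
    # coverage check: every inter-knot interval inside the data range must
    # contain data (the tail segment is pinned by the cutoff constraints)
    for a, b in zip(kn[:-2], kn[1:-1]):
        if not np.any((d >= a - 1e-9) & (d <= b + 1e-9)):
            raise ValueError(f"no data in knot interval [{a:.3f}, {b:.3f}]")

    k = 3
    t = np.concatenate([[kn[0]] * (k + 1), kn[1:-1], [kn[-1]] * (k + 1)])
    nc = len(t) - k - 1
    A = BSpline.design_matrix(np.clip(d, kn[0], kn[-1]), t, k).toarray()
    if np.linalg.matrix_rank(A) < nc - 2:
        raise ValueError(
            f"under-determined spline fit: {len(d)} points for {nc} "
            f"coefficients with knots {kn}"
        )
    # equality constraints: value and slope zero at the cutoff
    C = np.vstack(
        [
            BSpline.design_matrix(np.array([kn[-1] - 1e-12]), t, k).toarray(),
            _deriv_row(t, k, nc, kn[-1] - 1e-12),
        ]
    )
    coef = _constrained_lstsq(A * w[:, None], y * w, C)
    pp = PPoly.from_spline((t, coef, k))
    # PPoly.from_spline repeats boundary knots; extract unique segments
    segments = []
    for i, (a, b) in enumerate(zip(kn[:-1], kn[1:])):
        idx = np.searchsorted(pp.x, a, side="right") - 1
        idx = min(max(idx, 0), pp.c.shape[1] - 1)
        c_desc = pp.c[:, idx]          # descending powers in (r - a)
        segments.append(c_desc[::-1].copy())
    # quintic tail replacing the last cubic: match value/slope/curvature at
    # the segment start and V = V' = V'' = 0 at the cutoff
    a, b = kn[-2], kn[-1]
    h = b - a
    clast = segments[-1]
    v0 = clast[0]
    s0 = clast[1]
    c0 = 2.0 * clast[2]
    segments[-1] = _quintic(h, v0, s0, c0)
    exp_coeffs = _exp_head(kn[0], segments[0])
    return RepulsivePotential(knots=kn, coefficients=segments, exp_coeffs=exp_coeffs)


def _deriv_row(t, k, nc, x):
    row = np.zeros((1, nc))
    for j in range(nc):
        c = np.zeros(nc)
        c[j] = 1.0
        row[0, j] = BSpline(t, c, k)(x, 1)
    return row


def _constrained_lstsq(A, y, C):
    """min ||A x - y|| subject to C x = 0 via nullspace projection."""
    from scipy.linalg import null_space, lstsq

    N = null_space(C)
    z, *_ = lstsq(A @ N, y)
    return N @ z


def _quintic(h, v0, s0, c0):
    """Quintic on [0, h] with given value/slope/curvature at 0 and
    value = slope = curvature = 0 at h."""
    # p(x) = v0 + s0 x + c0/2 x^2 + a x^3 + b x^4 + c x^5
    rhs = np.array(
        [
            -(v0 + s0 * h + 0.5 * c0 * h * h),
            -(s0 + c0 * h),
            -c0,
        ]
    )
    M = np.array(
        [
            [h**3, h**4, h**5],
            [3 * h**2, 4 * h**3, 5 * h**4],
            [6 * h, 12 * h**2, 20 * h**3],
        ]
    )
    abc = np.linalg.solve(M, rhs)
    return np.array([v0, s0, 0.5 * c0, *abc])


def _exp_head(r0, seg0):
    """Exponential continuation matching value, slope and curvature at r0."""
    v = seg0[0]
    s = seg0[1]
    c = 2.0 * seg0[2]
    if s < 0 and c > 0:
        a1 = c / (-s)
        a2 = np.log(c / a1**2) + a1 * r0
        a3 = v - c / a1**2
    else:
        # non-repulsive head shape: fall back to slope matching only
        a1 = 1.0
        mag = max(abs(s), 1e-12)
        a2 = np.log(mag) + a1 * r0
        a3 = v - (mag if s < 0 else -mag)
        if s > 0:
            logger.warning("repulsive head has positive slope at first knot")
    return (float(a1), float(a2), float(a3))


def multi_curve_fit(
    curves,
    knots,
    cutoff: float | None = None,
    curve_weights=None,
    near_equilibrium_upweight: bool = False,
    ) -> RepulsivePotential:
    """Joint spline fit to several reference curves of the same pair."""
    pairs = {tuple(sorted(c.pair)) for c in curves}
    if len(pairs) != 1:
        raise ValueError(f"curves concern different pairs: {pairs}")
    if curve_weights is None:
        curve_weights = [1.0] * len(curves)
    targets = []
    dmax = 0.0
    for cw, curve in zip(curve_weights, curves):
        d, v = residual_curve(curve)
        wts = np.ones_like(d) if curve.weights is None else np.asarray(curve.weights)
        if near_equilibrium_upweight:
            dmin = d[np.argmin(v + 0)]  # near the target minimum
            sel = np.abs(d - dmin) < 0.05 * dmin
            wts = np.where(sel, wts * 5.0, wts)
            logger.info("upweighted %d near-equilibrium points", int(sel.sum()))
        targets.extend(zip(d, v, cw * wts))
        dmax = max(dmax, d.max())
    if cutoff is None:
        cutoff = dmax + 0.3
    return fit_spline(targets, knots, cutoff)
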