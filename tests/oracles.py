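"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written against textbook formulas and plain
loops, avoiding the package's own rotation/assembly/SCC code paths, so that
agreement is a genuine two-route check.
"""

from __future__ import annotations

import numpy as np

# basis ordering used by the package: s | p(y,z,x) | d(xy,yz,z2,xz,x2-y2)
_P_ORDER = ["y", "z", "x"]
_D_ORDER = ["xy", "yz", "z2", "xz", "x2y2"]


def _sk_entry(alpha: str, beta: str, dc, V) -> float:
    """Classic Slater-Koster two-center matrix element.

    ``alpha`` on the first atom, ``beta`` on the second, ``dc`` = (l, m, n)
    direction cosines pointing from the first to the second atom, ``V`` a
    dict with keys sss, sps, pps, ppp, sds, pds, pdp, dds, ddp, ddd.
    """
    l, m, n = dc
    d = {"x": l, "y": m, "z": n}

    def p_label(lab):
        return lab in ("x", "y", "z")

    def d_label(lab):
        return lab in ("xy", "yz", "zx", "x2y2", "z2")

    # normalize d labels: internal 'xz' == 'zx'
    if alpha == "xz":
        alpha = "zx"
    if beta == "xz":
        beta = "zx"

    if alpha == "s" and beta == "s":
        return V["sss"]
    if alpha == "s" and p_label(beta):
        return d[beta] * V["sps"]
    if p_label(alpha) and beta == "s":
        # <p_A|s_B>(n) = <s|p>(-n) with the reversed-pair sp channel
        return -d[alpha] * V.get("pss", V["sps"])
    if p_label(alpha) and p_label(beta):
        di, dj = d[alpha], d[beta]
        if alpha == beta:
            return di * di * V["pps"] + (1 - di * di) * V["ppp"]
        return di * dj * (V["pps"] - V["ppp"])
    if alpha == "s" and d_label(beta):
        return _sd(beta, d, V["sds"])
    if d_label(alpha) and beta == "s":
        # even parity: <d_A|s_B>(n) = <s|d>(-n) = <s|d>(n)
        return _sd(alpha, d, V.get("dss", V["sds"]))
    if p_label(alpha) and d_label(beta):
        return _pd(alpha, beta, d, V["pds"], V["pdp"])
    if d_label(alpha) and p_label(beta):
        # reversal rule: <d_A|p_B>(n) = <p|d>(-n) with the reversed-pair
        # pd channels
        dneg = {k: -v for k, v in d.items()}
        return _pd(beta, alpha, dneg, V.get("dps", V["pds"]),
                   V.get("dpp", V["pdp"]))
    if d_label(alpha) and d_label(beta):
        return _dd(alpha, beta, d, V["dds"], V["ddp"], V["ddd"])
    raise ValueError((alpha, beta))


def _sd(lab, d, Vs):
    l, m, n = d["x"], d["y"], d["z"]
    r3 = np.sqrt(3.0)
    if lab in ("xy", "yz", "zx"):
        i, j = lab[0], lab[1]
        return r3 * d[i] * d[j] * Vs
    if lab == "x2y2":
        return 0.5 * r3 * (l * l - m * m) * Vs
    return (n * n - 0.5 * (l * l + m * m)) * Vs  # z2


def _pd(p, dd, d, Vs, Vp):
    l, m, n = d["x"], d["y"], d["z"]
    r3 = np.sqrt(3.0)
    di = d[p]
    if dd in ("xy", "yz", "zx"):
        j, k = dd[0], dd[1]
        if p == j:
            return r3 * di * di * d[k] * Vs + d[k] * (1 - 2 * di * di) * Vp
        if p == k:
            return r3 * di * di * d[j] * Vs + d[j] * (1 - 2 * di * di) * Vp
        return r3 * d["x"] * d["y"] * d["z"] * Vs - 2 * d["x"] * d["y"] * d["z"] * Vp
    if dd == "x2y2":
        lm2 = l * l - m * m
        if p == "x":
            return 0.5 * r3 * l * lm2 * Vs + l * (1 - lm2) * Vp
        if p == "y":
            return 0.5 * r3 * m * lm2 * Vs - m * (1 + lm2) * Vp
        return 0.5 * r3 * n * lm2 * Vs - n * lm2 * Vp
    # z2
    z2 = n * n - 0.5 * (l * l + m * m)
    if p == "x":
        return l * z2 * Vs - r3 * l * n * n * Vp
    if p == "y":
        return m * z2 * Vs - r3 * m * n * n * Vp
    return n * z2 * Vs + r3 * n * (l * l + m * m) * Vp


def _dd(a, b, d, Vs, Vp, Vd):
    l, m, n = d["x"], d["y"], d["z"]
    r3 = np.sqrt(3.0)
    t2g = ("xy", "yz", "zx")
    if a in t2g and b in t2g:
        if a == b:
            i, j = a[0], a[1]
            k = ({"x", "y", "z"} - {i, j}).pop()
            di, dj, dk = d[i], d[j], d[k]
            return (
                3 * di * di * dj * dj * Vs
                + (di * di + dj * dj - 4 * di * di * dj * dj) * Vp
                + (dk * dk + di * di * dj * dj) * Vd
            )
        shared = (set(a) & set(b)).pop()
        i = (set(a) - {shared}).pop()
        k = (set(b) - {shared}).pop()
        di, dj, dk = d[i], d[shared], d[k]
        return (
            3 * di * dj * dj * dk * Vs
            + di * dk * (1 - 4 * dj * dj) * Vp
            + di * dk * (dj * dj - 1) * Vd
        )
    if a in t2g and b in ("x2y2", "z2"):
        return _t2g_eg(a, b, d, Vs, Vp, Vd)
    if b in t2g and a in ("x2y2", "z2"):
        return _t2g_eg(b, a, d, Vs, Vp, Vd)  # even total parity
    # eg x eg
    lm2 = l * l - m * m
    z2 = n * n - 0.5 * (l * l + m * m)
    if a == "x2y2" and b == "x2y2":
        return (
            0.75 * lm2 * lm2 * Vs
            + (l * l + m * m - lm2 * lm2) * Vp
            + (n * n + 0.25 * lm2 * lm2) * Vd
        )
    if a == "z2" and b == "z2":
        return (
            z2 * z2 * Vs + 3 * n * n * (l * l + m * m) * Vp
            + 0.75 * (l * l + m * m) ** 2 * Vd
        )
    # x2y2 with z2 (symmetric)
    return r3 * (
        0.5 * lm2 * z2 * Vs + n * n * (m * m - l * l) * Vp
        + 0.25 * (1 + n * n) * lm2 * Vd
    )


def _t2g_eg(t, e, d, Vs, Vp, Vd):
    l, m, n = d["x"], d["y"], d["z"]
    r3 = np.sqrt(3.0)
    lm2 = l * l - m * m
    z2 = n * n - 0.5 * (l * l + m * m)
    if e == "x2y2":
        if t == "xy":
            return 1.5 * l * m * lm2 * Vs + 2 * l * m * (m * m - l * l) * Vp \
                + 0.5 * l * m * lm2 * Vd
        if t == "yz":
            return 1.5 * m * n * lm2 * Vs - m * n * (1 + 2 * lm2) * Vp \
                + m * n * (1 + 0.5 * lm2) * Vd
        return 1.5 * n * l * lm2 * Vs + n * l * (1 - 2 * lm2) * Vp \
            - n * l * (1 - 0.5 * lm2) * Vd
    # z2
    if t == "xy":
        return r3 * (l * m * z2 * Vs - 2 * l * m * n * n * Vp
                     + 0.5 * l * m * (1 + n * n) * Vd)
    if t == "yz":
        return r3 * (m * n * z2 * Vs + m * n * (l * l + m * m - n * n) * Vp
                     - 0.5 * m * n * (l * l + m * m) * Vd)
    return r3 * (l * n * z2 * Vs + l * n * (l * l + m * m - n * n) * Vp
                 - 0.5 * l * n * (l * l + m * m) * Vd)


def sk_block_oracle(direction, channels: dict, lvals_a, lvals_b) -> np.ndarray:
    """Full block via the classic direction-cosine table.

    ``channels`` maps channel name -> value, with reversed-order channels
    (pss, dss, dps, dpp) included when l_a > l_b combinations occur (for a
    homonuclear table they follow from parity of the canonical ones).
    """
    labels_a = _labels(lvals_a)
    labels_b = _labels(lvals_b)
    out = np.zeros((len(labels_a), len(labels_b)))
    for i, la in enumerate(labels_a):
        for j, lb in enumerate(labels_b):
            out[i, j] = _sk_entry(la, lb, direction, channels)
    return out


def _labels(lvals):
    out = []
    for l in sorted(lvals):
        if l == 0:
            out.append("s")
        elif l == 1:
            out.extend(_P_ORDER)
        else:
            out.extend(_D_ORDER)
    return out


def gamma_numeric(Ua: float, Ub: float, R: float, n_r=400, n_c=200) -> float:
    """Coulomb integral of two exponential charge distributions.

    n_tau(r) = tau^3/(8 pi) exp(-tau r) with tau = 16 U / 5; the potential of
    one distribution is known in closed form, the remaining two-center
    integral is done numerically in spherical coordinates.
    """
    ta, tb = 3.2 * Ua, 3.2 * Ub
    from numpy.polynomial.legendre import leggauss

    xr, wr = leggauss(n_r)
    rmax = 40.0 / min(ta, tb)
    r = 0.5 * rmax * (xr + 1.0)
    wr = 0.5 * rmax * wr
    xc, wc = leggauss(n_c)
    na = ta**3 / (8.0 * np.pi) * np.exp(-ta * r)

    def vb(s):
        s = np.maximum(s, 1e-12)
        return 1.0 / s - np.exp(-tb * s) * (1.0 / s + tb / 2.0)

    acc = 0.0
    for ci, wi in zip(xc, wc):
        s = np.sqrt(r * r + R * R - 2.0 * r * R * ci)
        acc += wi * np.sum(wr * r * r * na * vb(s))
    return float(2.0 * np.pi * acc)


def dftb3_scc_oracle(structure, params, third_order=True, maxiter=500,
                     mix=0.2, tol=1e-12):
    """Plain-loop transcription of the third-order SCC equations.

    Independent of the package's assembly and SCC code: blocks come from the
    classic direction-cosine formulas above (reading the same tables), the
    Hamiltonian shift and all energy terms are written as explicit loops.
    Returns (total energy, charges).
    """
    from scipy.linalg import eigh

    from tbforge.gamma import gamma, gamma_derivative

    syms = structure.symbols
    pos = structure.positions
    n_at = len(syms)
    lvals = {s: params.lvals(s) for s in set(syms)}
    sizes = [sum(2 * l + 1 for l in lvals[s]) for s in syms]
    offs = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
    ntot = offs[-1]

    name_of = {(0, 0, 0): "sss", (0, 1, 0): "sps", (0, 2, 0): "sds",
               (1, 1, 0): "pps", (1, 1, 1): "ppp", (1, 2, 0): "pds",
               (1, 2, 1): "pdp", (2, 2, 0): "dds", (2, 2, 1): "ddp",
               (2, 2, 2): "ddd"}
    # raw channels of the reversed-pair table (p/d on the other atom)
    rev_name = {(0, 1, 0): "pss", (0, 2, 0): "dss", (1, 2, 0): "dps",
                (1, 2, 1): "dpp"}

    def channels(sa, sb, dist, kind):
        t_ab = params.table(sa, sb)
        t_ba = params.table(sb, sa)
        ch = {}
        for key, nm in name_of.items():
            ch[nm] = t_ab.interpolate(kind, key, dist)
        for key, nm in rev_name.items():
            ch[nm] = t_ba.interpolate(kind, key, dist)
        return ch

    H0 = np.zeros((ntot, ntot))
    S = np.eye(ntot)
    for a in range(n_at):
        ons = params.onsite(syms[a])
        i = offs[a]
        for l in lvals[syms[a]]:
            for _ in range(2 * l + 1):
                H0[i, i] = ons.get(l, 0.0)
                i += 1
    for a in range(n_at):
        for b in range(n_at):
            if a == b:
                continue
            disp = pos[b] - pos[a]
            dist = np.linalg.norm(disp)
            hb = sk_block_oracle(disp / dist, channels(syms[a], syms[b], dist, "h"),
                                 lvals[syms[a]], lvals[syms[b]])
            sb_ = sk_block_oracle(disp / dist, channels(syms[a], syms[b], dist, "s"),
                                  lvals[syms[a]], lvals[syms[b]])
            H0[offs[a]:offs[a + 1], offs[b]:offs[b + 1]] = hb
            S[offs[a]:offs[a + 1], offs[b]:offs[b + 1]] = sb_

    q0 = np.array([params.neutral_electrons(s) for s in syms])
    n_elec = q0.sum() - structure.charge
    d = structure.distance_matrix()
    G = np.zeros((n_at, n_at))
    G3 = np.zeros((n_at, n_at))
    for a in range(n_at):
        for b in range(n_at):
            xh = "H" in (syms[a], syms[b])
            G[a, b] = gamma(params.hubbards[syms[a]], params.hubbards[syms[b]],
                            d[a, b], xh_pair=xh, zeta=params.zeta)
            G3[a, b] = gamma_derivative(
                params.hubbards[syms[a]], params.hubbards[syms[b]], d[a, b],
                params.hubbard_derivs[syms[a]], xh_pair=xh, zeta=params.zeta)

    atom_of = np.concatenate([[a] * sizes[a] for a in range(n_at)])
    dq = np.zeros(n_at)
    for _ in range(maxiter):
        H = H0.copy()
        for mu in range(ntot):
            for nu in range(ntot):
                a, b = atom_of[mu], atom_of[nu]
                shift = 0.0
                for c in range(n_at):
                    term = 0.5 * (G[a, c] + G[b, c])
                    if third_order:
                        term += (dq[a] * G3[a, c] + dq[b] * G3[b, c]) / 3.0
                        term += dq[c] * (G3[c, a] + G3[c, b]) / 6.0
                    shift += dq[c] * term
                H[mu, nu] += S[mu, nu] * shift
        eps, C = eigh(H, S)
        occ = np.zeros(ntot)
        rem = n_elec
        i = 0
        while rem > 1e-12 and i < ntot:
            j = i + 1
            while j < ntot and eps[j] - eps[i] < 1e-8:
                j += 1
            take = min(2.0 * (j - i), rem)
            occ[i:j] = take / (j - i)
            rem -= take
            i = j
        P = (C * occ) @ C.T
        pops = np.zeros(n_at)
        for mu in range(ntot):
            for nu in range(ntot):
                pops[atom_of[mu]] += P[mu, nu] * S[nu, mu]
        dq_new = pops - q0
        if np.max(np.abs(dq_new - dq)) < tol:
            dq = dq_new
            break
        dq = dq + mix * (dq_new - dq)

    e_h0 = float(np.sum(P * H0))
    e2 = 0.0
    e3 = 0.0
    for a in range(n_at):
        for b in range(n_at):
            e2 += 0.5 * dq[a] * dq[b] * G[a, b]
            if third_order:
                e3 += dq[a] ** 2 * dq[b] * G3[a, b] / 3.0
    e_rep = 0.0
    for a in range(n_at):
        for b in range(a + 1, n_at):
            rep = params.table(syms[a], syms[b]).repulsive
            if rep is not None:
                e_rep += rep(d[a, b])
    return e_h0 + e2 + e3 + e_rep, dq
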