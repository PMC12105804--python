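"""Second- and third-order charge-fluctuation kernels of SCC tight binding.

gamma(U_a, U_b, r) describes the screened Coulomb interaction between the
spherical charge fluctuations of two atoms, interpolating between the on-site
chemical hardness (gamma -> U_a as r -> 0) and the bare 1/r law at long
range.  The short-range part S comes from the exponential-density model with
decay tau = 16 U / 5; pairs involving hydrogen are additionally damped by
h = exp(-((U_a+U_b)/2)^zeta r^2).

Gamma(U_a, U_b, r; Ud_a) is the derivative of gamma with respect to the
charge of atom a, i.e. (d gamma / d U_a) * Ud_a, which drives the
third-order energy term.  All quantities in atomic units.
"""

from __future__ import annotations

import numpy as np

__all__ = ["gamma", "gamma_derivative"]

_TAU_FACTOR = 16.0 / 5.0


def _short_range(tau_a: float, tau_b: float, r: float) -> float:
    """S(tau_a, tau_b, r) such that gamma = 1/r - S (no damping)."""
    if r < 1e-8:
        # on-site limit of 1/r - gamma
        if abs(tau_a - tau_b) < 1e-9 * (tau_a + tau_b):
            raise ValueError("on-site S is singular; use gamma() directly")
        raise ValueError("short-range S undefined at r=0")
    rel = abs(tau_a - tau_b) / (tau_a + tau_b)
    if rel < 1e-10:
        tau = 0.5 * (tau_a + tau_b)
        return np.exp(-tau * r) * (
            1.0 / r + 11.0 * tau / 16.0 + 3.0 * tau**2 * r / 16.0
            + tau**3 * r * r / 48.0
        )

    def term(ta, tb, exp=np.exp):
        f = tb**4 * ta / (2.0 * (ta**2 - tb**2) ** 2)
        g = (tb**6 - 3.0 * tb**4 * ta**2) / ((ta**2 - tb**2) ** 3 * r)
        return exp(-ta * r) * (f - g)

    if rel < 0.05:
        # the delta^-3 denominators cancel catastrophically near the
        # diagonal; evaluate that window in extended precision
        import mpmath as mp

        with mp.workdps(40):
            ta, tb, rr = mp.mpf(tau_a), mp.mpf(tau_b), mp.mpf(r)
            f1 = tb**4 * ta / (2 * (ta**2 - tb**2) ** 2)
            g1 = (tb**6 - 3 * tb**4 * ta**2) / ((ta**2 - tb**2) ** 3 * rr)
            f2 = ta**4 * tb / (2 * (tb**2 - ta**2) ** 2)
            g2 = (ta**6 - 3 * ta**4 * tb**2) / ((tb**2 - ta**2) ** 3 * rr)
            val = mp.e**(-ta * rr) * (f1 - g1) + mp.e**(-tb * rr) * (f2 - g2)
            return float(val)
    return term(tau_a, tau_b) + term(tau_b, tau_a)


def _gamma_onsite(tau_a: float, tau_b: float) -> float:
    """r -> 0 limit of gamma (equals U_a when tau_a == tau_b)."""
    ta, tb = tau_a, tau_b
    s = ta + tb
    return 0.5 * (ta * tb / s + ta**2 * tb**2 / s**3)


def _damping(Ua: float, Ub: float, r: float, zeta: float) -> float:
    return float(np.exp(-((0.5 * (Ua + Ub)) ** zeta) * r * r))


def gamma(
    Ua: float,
    Ub: float,
    r: float,
    *,
    xh_pair: bool = False,
    zeta: float = 4.0,
) -> float:
    """Second-order kernel gamma_ab(r) in hartree.

    ``xh_pair`` switches on the hydrogen short-range damping h with exponent
    ``zeta`` (4.0 for the 3OB-style parametrization).  gamma(U, U, 0) = U and
    gamma -> 1/r for large r.
    """
    if Ua <= 0 or Ub <= 0:
        raise ValueError("Hubbard parameters must be positive")
    if r < 0:
        raise ValueError("negative distance")
    ta, tb = _TAU_FACTOR * Ua, _TAU_FACTOR * Ub
    if r < 1e-8:
        # h(r=0) = 1, so damping does not alter the on-site limit
        return _gamma_onsite(ta, tb)
    S = _short_range(ta, tb, r)
    h = _damping(Ua, Ub, r, zeta) if xh_pair else 1.0
    return 1.0 / r - S * h


def _dS_dtau_a(tau_a: float, tau_b: float, r: float) -> float:
    """Analytic partial dS/d tau_a at fixed tau_b."""
    if abs(tau_a - tau_b) < 1e-10 * (tau_a + tau_b):
        # S is symmetric in (tau_a, tau_b); at the diagonal the partial
        # derivative equals half the total derivative along tau_a = tau_b
        tau = 0.5 * (tau_a + tau_b)
        e = np.exp(-tau * r)
        s_val = 1.0 / r + 11.0 * tau / 16.0 + 3.0 * tau**2 * r / 16.0 \
            + tau**3 * r * r / 48.0
        ds = e * (-r * s_val + 11.0 / 16.0 + 3.0 * tau * r / 8.0
                  + tau**2 * r * r / 16.0)
        return 0.5 * ds
    if abs(tau_a - tau_b) < 0.05 * (tau_a + tau_b):
        import mpmath as mp

        with mp.workdps(40):
            ta, tb, rr = mp.mpf(tau_a), mp.mpf(tau_b), mp.mpf(r)
            delta = ta**2 - tb**2
            A = tb**4 * ta / (2 * delta**2)
            B = (tb**6 - 3 * tb**4 * ta**2) / delta**3
            dA = tb**4 / (2 * delta**2) - 2 * tb**4 * ta**2 / delta**3
            dB = -6 * tb**4 * ta / delta**3 \
                - 6 * ta * (tb**6 - 3 * tb**4 * ta**2) / delta**4
            dC = 2 * ta**3 * tb / delta**2 - 2 * ta**5 * tb / delta**3
            dD = -(6 * ta**5 - 12 * ta**3 * tb**2) / delta**3 \
                + 6 * ta * (ta**6 - 3 * ta**4 * tb**2) / delta**4
            ea, eb = mp.e**(-ta * rr), mp.e**(-tb * rr)
            val = ea * (-rr * (A - B / rr) + dA - dB / rr) + eb * (dC - dD / rr)
            return float(val)
    ta, tb = tau_a, tau_b
    delta = ta**2 - tb**2
    A = tb**4 * ta / (2.0 * delta**2)
    B = (tb**6 - 3.0 * tb**4 * ta**2) / delta**3
    dA = tb**4 / (2.0 * delta**2) - 2.0 * tb**4 * ta**2 / delta**3
    dB = -6.0 * tb**4 * ta / delta**3 \
        - 6.0 * ta * (tb**6 - 3.0 * tb**4 * ta**2) / delta**4
    C = ta**4 * tb / (2.0 * delta**2)
    dC = 2.0 * ta**3 * tb / delta**2 - 2.0 * ta**5 * tb / delta**3
    dD = -(6.0 * ta**5 - 12.0 * ta**3 * tb**2) / delta**3 \
        + 6.0 * ta * (ta**6 - 3.0 * ta**4 * tb**2) / delta**4
    ea, eb = np.exp(-ta * r), np.exp(-tb * r)
    return ea * (-r * (A - B / r) + dA - dB / r) + eb * (dC - dD / r)


def gamma_derivative(
    Ua: float,
    Ub: float,
    r: float,
    Ud_a: float,
    *,
    xh_pair: bool = False,
    zeta: float = 4.0,
) -> float:
    """Third-order kernel Gamma_ab = (d gamma_ab / d U_a) * Ud_a.

    The closed-form U_a-derivative includes the hydrogen damping factor's own
    U_a dependence.  Gamma vanishes identically for Ud_a = 0 (the
    second-order-only limit), and Gamma(U, U, 0) = Ud_a on site.
    """
    if Ud_a == 0.0:
        return 0.0
    if Ua <= 0 or Ub <= 0:
        raise ValueError("Hubbard parameters must be positive")
    if r < 1e-8:
        # on-site: gamma(0) = U_a, so d gamma/d U_a = 1
        return Ud_a
    ta, tb = _TAU_FACTOR * Ua, _TAU_FACTOR * Ub
    S = _short_range(ta, tb, r)
    dS_dUa = _dS_dtau_a(ta, tb, r) * _TAU_FACTOR
    if xh_pair:
        h = _damping(Ua, Ub, r, zeta)
        um = 0.5 * (Ua + Ub)
        dh_dUa = -h * zeta * um ** (zeta - 1.0) * 0.5 * r * r
        dgamma_dUa = -(dS_dUa * h + S * dh_dUa)
    else:
        dgamma_dUa = -dS_dUa
    return dgamma_dUa * Ud_a
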