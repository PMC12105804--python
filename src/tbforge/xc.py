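"""Spin-unpolarized LDA (PW92) and GGA (PBE) exchange-correlation.

Conventions follow the common density-functional library interface:
``eval_xc`` returns the energy density per volume f = rho * eps_xc together
with its partial derivatives vrho = df/drho and vsigma = df/dsigma, where
sigma = |grad rho|^2.  The radial Kohn-Sham potential is then

    v_xc(r) = vrho - (1/r^2) d/dr [ r^2 * 2 vsigma * rho'(r) ]

which is the closed-shell GGA potential for a spherical density.
"""

from __future__ import annotations

import numpy as np

from .grid import RadialGrid

# PBE / PW92 constants
_KAPPA = 0.804
_MU = 0.2195149727645171
_BETA = 0.06672455060314922
_GAMMA = (1.0 - np.log(2.0)) / np.pi**2
_CX = (3.0 / 4.0) * (3.0 / np.pi) ** (1.0 / 3.0)

# PW92 unpolarized correlation parameters
_A_PW = 0.0310907
_ALPHA1 = 0.21370
_BETA1 = 7.5957
_BETA2 = 3.5876
_BETA3 = 1.6382
_BETA4 = 0.49294

_RHO_FLOOR = 1e-20


def _pw92_ec(rs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PW92 correlation energy per electron and its d/d rs."""
    srs = np.sqrt(rs)
    q0 = -2.0 * _A_PW * (1.0 + _ALPHA1 * rs)
    q1 = 2.0 * _A_PW * (_BETA1 * srs + _BETA2 * rs + _BETA3 * rs * srs + _BETA4 * rs * rs)
    dq1 = _A_PW * (_BETA1 / srs + 2 * _BETA2 + 3 * _BETA3 * srs + 4 * _BETA4 * rs)
    log = np.log1p(1.0 / q1)
    ec = q0 * log
    dec = -2.0 * _A_PW * _ALPHA1 * log - q0 * dq1 / (q1 * q1 + q1)
    return ec, dec


def eval_lda(rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """LDA (Slater x + PW92 c): returns (f, vrho) with f = rho*eps_xc."""
    rho = np.maximum(rho, _RHO_FLOOR)
    ex = -_CX * rho ** (1.0 / 3.0)
    fx = rho * ex
    vx = (4.0 / 3.0) * ex
    rs = (3.0 / (4.0 * np.pi * rho)) ** (1.0 / 3.0)
    ec, dec = _pw92_ec(rs)
    fc = rho * ec
    vc = ec - (rs / 3.0) * dec
    return fx + fc, vx + vc


def eval_pbe(rho: np.ndarray, sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PBE exchange-correlation: returns (f, vrho, vsigma)."""
    rho = np.maximum(rho, _RHO_FLOOR)
    sigma = np.maximum(sigma, 0.0)

    # --- exchange ---
    kf2 = (3.0 * np.pi**2) ** (2.0 / 3.0) * rho ** (2.0 / 3.0)
    s2 = sigma / (4.0 * kf2 * rho * rho)
    denom = 1.0 + _MU * s2 / _KAPPA
    fx_enh = 1.0 + _KAPPA - _KAPPA / denom
    dfx_ds2 = _MU / (denom * denom)
    ex_d = -_CX * rho ** (4.0 / 3.0)  # rho * eps_x^unif
    f_x = ex_d * fx_enh
    vrho_x = -(4.0 / 3.0) * _CX * rho ** (1.0 / 3.0) * fx_enh \
        + ex_d * dfx_ds2 * (-(8.0 / 3.0) * s2 / rho)
    vsigma_x = ex_d * dfx_ds2 / (4.0 * kf2 * rho * rho)

    # --- correlation ---
    rs = (3.0 / (4.0 * np.pi * rho)) ** (1.0 / 3.0)
    ec, dec_drs = _pw92_ec(rs)
    dec_drho = -(rs / (3.0 * rho)) * dec_drs
    kf = np.sqrt(kf2)
    u = np.pi * sigma / (16.0 * kf * rho ** 2)  # t^2
    expo = np.exp(-ec / _GAMMA)
    A = (_BETA / _GAMMA) / np.maximum(expo - 1.0, 1e-300)
    n_ = 1.0 + A * u
    d_ = 1.0 + A * u + A * A * u * u
    arg = 1.0 + (_BETA / _GAMMA) * u * n_ / d_
    H = _GAMMA * np.log(arg)
    dH_du = (_BETA / arg) * (1.0 + 2.0 * A * u) / (d_ * d_)
    dH_dA = -(_BETA / arg) * A * u**3 * (2.0 + A * u) / (d_ * d_)
    dA_dec = (A * A / _BETA) * expo
    du_drho = -(7.0 / 3.0) * u / rho
    du_dsigma = np.pi / (16.0 * kf * rho ** 2)
    f_c = rho * (ec + H)
    vrho_c = ec + H + rho * (
        dec_drho + dH_du * du_drho + dH_dA * dA_dec * dec_drho
    )
    vsigma_c = rho * dH_du * du_dsigma

    return f_x + f_c, vrho_x + vrho_c, vsigma_x + vsigma_c


def radial_vxc(
    grid: RadialGrid, rho: np.ndarray, functional: str = "PBE"
) -> tuple[np.ndarray, float]:
    """XC potential and energy for a spherical density rho(r).

    Returns (v_xc on the grid, E_xc).  ``functional`` is "PBE" or "LDA".
    """
    functional = functional.upper()
    if functional == "LDA":
        f, vrho = eval_lda(rho)
        exc = 4.0 * np.pi * grid.integrate(f * grid.r**2)
        return vrho, exc
    if functional != "PBE":
        raise ValueError(f"unknown functional {functional!r}")
    drho = grid.derivative(rho)
    sigma = drho * drho
    f, vrho, vsigma = eval_pbe(rho, sigma)
    exc = 4.0 * np.pi * grid.integrate(f * grid.r**2)
    # divergence term: (1/r^2) d/dr (r^2 * 2 vsigma rho')
    g = 2.0 * vsigma * drho
    div = grid.derivative(grid.r**2 * g) / grid.r**2
    vxc = vrho - div
    # where the density has decayed to the floor the gradient expansion is
    # numerically meaningless; fall back to the (tiny) LDA value there
    dead = rho < 1e-14
    if np.any(dead):
        _, v_lda = eval_lda(rho)
        vxc = np.where(dead, v_lda, vxc)
    return vxc, exc
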