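"""Closed-shell exchange-correlation functionals: Slater/PW92 LDA and PBE.

Energy densities are written once in sympy in terms of the total density
``rho`` and the squared gradient ``gamma = |grad rho|^2``; the potentials
``de/drho`` and ``de/dgamma`` are generated symbolically and lambdified.
This removes an entire class of hand-derivative bugs at the price of a few
hundred milliseconds at first use (cached afterwards).
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["xc_eval", "XC_SPECS"]

# exact-exchange admixture and whether a gradient is needed
XC_SPECS = {
    "HF": {"hyb": 1.0, "gga": False, "grid": False},
    "LDA": {"hyb": 0.0, "gga": False, "grid": True},
    "PBE": {"hyb": 0.0, "gga": True, "grid": True},
    "PBEH40": {"hyb": 0.4, "gga": True, "grid": True},
}


@lru_cache(maxsize=None)
def _functional(tag):
    import sympy as sp

    rho, gam = sp.symbols("rho gamma", positive=True)

    ex_lda = -sp.Rational(3, 4) * (3 / sp.pi) ** sp.Rational(1, 3) * rho ** sp.Rational(4, 3)

    # PW92 uniform-gas correlation, zeta = 0
    rs = (3 / (4 * sp.pi * rho)) ** sp.Rational(1, 3)
    A, a1 = sp.Float("0.0310907"), sp.Float("0.21370")
    b1, b2, b3, b4 = (sp.Float(x) for x in ("7.5957", "3.5876", "1.6382", "0.49294"))
    den = 2 * A * (b1 * sp.sqrt(rs) + b2 * rs + b3 * rs ** sp.Rational(3, 2) + b4 * rs**2)
    eps_c = -2 * A * (1 + a1 * rs) * sp.log(1 + 1 / den)
    ec_lda = rho * eps_c

    # PBE exchange enhancement
    kf = (3 * sp.pi**2 * rho) ** sp.Rational(1, 3)
    s2 = gam / (4 * kf**2 * rho**2)
    kappa, mu = sp.Float("0.8040"), sp.Float("0.2195149727645171")
    fx = 1 + kappa - kappa / (1 + mu * s2 / kappa)
    ex_pbe = ex_lda * fx

    # PBE correlation
    beta, gamc = sp.Float("0.06672455060314922"), (1 - sp.log(2)) / sp.pi**2
    ks = sp.sqrt(4 * kf / sp.pi)
    t2 = gam / (4 * ks**2 * rho**2)
    Ab = beta / gamc / (sp.exp(-eps_c / gamc) - 1)
    num = 1 + Ab * t2
    H = gamc * sp.log(1 + beta / gamc * t2 * num / (num + Ab**2 * t2**2))
    ec_pbe = rho * (eps_c + H)

    if tag == "LDA":
        e = ex_lda + ec_lda
    elif tag == "PBE":
        e = ex_pbe + ec_pbe
    elif tag == "PBEH40":
        e = sp.Float("0.6") * ex_pbe + ec_pbe
    else:
        raise ValueError(tag)

    args = (rho, gam)
    fe = sp.lambdify(args, e, modules="numpy")
    fvr = sp.lambdify(args, sp.diff(e, rho), modules="numpy")
    fvg = sp.lambdify(args, sp.diff(e, gam), modules="numpy")
    return fe, fvr, fvg


def xc_eval(tag, rho, gamma=None):
    """Energy density and potentials on the grid.

    Returns ``(e, v_rho, v_gamma)``; ``v_gamma`` is None for LDA.  Densities
    below 1e-12 are masked out (their contribution is below grid accuracy).
    """
    spec = XC_SPECS[tag]
    if not spec["grid"]:
        z = np.zeros_like(rho)
        return z, z, None
    fe, fvr, fvg = _functional(tag)
    mask = rho > 1e-12
    rr = np.where(mask, rho, 1.0)
    gg = np.where(mask, np.maximum(gamma, 1e-24), 1.0) if gamma is not None else np.full_like(rr, 1e-24)
    e = np.where(mask, fe(rr, gg), 0.0)
    vr = np.where(mask, fvr(rr, gg), 0.0)
    vg = np.where(mask, fvg(rr, gg), 0.0) if spec["gga"] else None
    return e, vr, vg
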