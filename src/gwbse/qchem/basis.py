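"""Gaussian basis sets generated from Slater-type shells.

Rather than shipping literature Gaussian tables, the package constructs its
own bases deterministically: each Slater-type shell (exponents from Slater's
screening rules) is expanded in ``k`` primitive Gaussians by least squares,
in the spirit of the classic STO-kG construction.  Two qualities are
registered:

``min``
    minimal: one 3-Gaussian contraction per occupied Slater shell.
``sv``
    split-valence: 6-Gaussian core contractions; valence shells are fit
    with 3 Gaussians and then split into a tight 2-Gaussian contraction
    plus the free most-diffuse primitive.

Auxiliary (density-fitting) sets are even-tempered expansions derived from
the primary exponent range, name ``etb`` or ``etb@<beta>``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

__all__ = ["Shell", "BasisSet", "build_basis", "build_aux_basis", "ELEMENTS"]

ELEMENTS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5,
    "C": 6, "N": 7, "O": 8, "F": 9, "Ne": 10,
}
SYMBOLS = {v: k for k, v in ELEMENTS.items()}

_DF2 = [1.0, 1.0, 3.0, 15.0, 105.0]  # (2n-1)!! for n = 0..4


def _cart_components(l):
    return [(lx, ly, l - lx - ly) for lx in range(l, -1, -1) for ly in range(l - lx, -1, -1)]


@dataclass
class Shell:
    """One contracted shell of Cartesian Gaussians on a single center."""

    l: int
    center: np.ndarray
    exps: np.ndarray
    coefs: np.ndarray
    raw: bool = False  # raw shells skip primitive normalization (internal use)

    @property
    def ncart(self):
        return (self.l + 1) * (self.l + 2) // 2

    @property
    def cart(self):
        return _cart_components(self.l)

    def prim_weights(self):
        """Contraction weights including primitive norms, (nprim, ncart)."""
        if self.raw:
            return np.repeat(self.coefs[:, None], self.ncart, axis=1)
        a = self.exps
        w = np.empty((len(a), self.ncart))
        for c, (lx, ly, lz) in enumerate(self.cart):
            norm = (
                (2 * a / np.pi) ** 0.75
                * (4 * a) ** (self.l / 2.0)
                / np.sqrt(_DF2[lx] * _DF2[ly] * _DF2[lz])
            )
            w[:, c] = self.coefs * norm
        return w


class BasisSet:
    """A list of shells with bookkeeping and per-function norm scales."""

    def __init__(self, shells, atom_of_shell=None):
        self.shells = list(shells)
        self.atom_of_shell = list(atom_of_shell) if atom_of_shell is not None else [0] * len(self.shells)
        offs = []
        n = 0
        for sh in self.shells:
            offs.append(n)
            n += sh.ncart
        self._offsets = offs
        self.nbf = n
        self.scales = np.ones(n)
        from . import integrals

        s_diag = np.diag(integrals.overlap(self))
        self.scales = 1.0 / np.sqrt(s_diag)

    def slice(self, ish):
        return slice(self._offsets[ish], self._offsets[ish] + self.shells[ish].ncart)

    @property
    def atom_of_bf(self):
        out = []
        for ish, sh in enumerate(self.shells):
            out.extend([self.atom_of_shell[ish]] * sh.ncart)
        return np.asarray(out, dtype=int)

    @property
    def max_l(self):
        return max(sh.l for sh in self.shells)


# ---------------------------------------------------------------------------
# Slater-shell Gaussian expansions
# ---------------------------------------------------------------------------

def _slater_radial(n, zeta, r):
    """Normalized Slater radial function R_n(r) = N r^{n-1} exp(-zeta r)."""
    from scipy.special import factorial

    N = (2 * zeta) ** (n + 0.5) / np.sqrt(factorial(2 * n))
    return N * r ** (n - 1) * np.exp(-zeta * r)


@lru_cache(maxsize=None)
def slater_fit(n: int, l: int, k: int):
    """Least-squares fit of k Gaussians to a unit-zeta Slater shell.

    Returns (exponents, coefficients) for the radial expansion
    ``R_nl(r; zeta=1) ~ sum_i c_i r^l exp(-a_i r^2)`` minimizing the radial
    L2 error.  Exponents for zeta != 1 follow by scaling with zeta**2.
    Deterministic: fixed grid, fixed even-tempered start.
    """
    r = np.geomspace(1e-3, 30.0, 400)
    wr = np.sqrt(np.gradient(r) * r**2)
    target = _slater_radial(n, 1.0, r) * wr

    def design(log_a):
        a = np.exp(log_a)
        cols = r[:, None] ** l * np.exp(-np.outer(r**2, a)) * wr[:, None]
        return cols

    def resid(log_a):
        cols = design(log_a)
        c, *_ = np.linalg.lstsq(cols, target, rcond=None)
        return cols @ c - target

    x0 = np.log(0.08 * 4.0 ** np.arange(k) / max(n, 1))
    sol = least_squares(resid, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000)
    a = np.exp(np.sort(sol.x)[::-1])
    cols = design(np.log(a))
    c, *_ = np.linalg.lstsq(cols, target, rcond=None)
    return a, c


def _slater_zetas(z):
    """Slater's-rules exponents {(n, l): zeta} for elements H..Ne.

    Hydrogen uses the standard molecular-environment scale 1.24.
    """
    if z == 1:
        return {(1, 0): 1.24}
    if z == 2:
        return {(1, 0): z - 0.30}
    zetas = {(1, 0): z - 0.30}
    n_val = z - 2
    s = 2 * 0.85 + 0.35 * (n_val - 1)
    zeta2 = (z - s) / 2.0
    zetas[(2, 0)] = zeta2
    zetas[(2, 1)] = zeta2
    return zetas


def _prim_norm(a, l):
    """Norm of the (l,0,0) Cartesian primitive with exponent a."""
    return (2 * a / np.pi) ** 0.75 * (4 * a) ** (l / 2.0) / np.sqrt(_DF2[l])


def _element_shells(z, quality):
    """List of (l, exps, coefs) for one element.

    Coefficients are re-expressed for unit-normalized primitives, which is
    the convention :meth:`Shell.prim_weights` assumes.
    """
    zetas = _slater_zetas(z)
    shells = []

    def normed(a, c):
        return a, c / _prim_norm(a, l)

    for (n, l), zeta in zetas.items():
        core = z > 2 and (n, l) == (1, 0)
        if quality == "min":
            a, c = slater_fit(n, l, 3)
            shells.append((l, *normed(a * zeta**2, c)))
        elif quality == "sv":
            if core:
                a, c = slater_fit(n, l, 6)
                shells.append((l, *normed(a * zeta**2, c)))
            else:
                a, c = slater_fit(n, l, 3)
                a = a * zeta**2
                shells.append((l, *normed(a[:2], c[:2])))   # tight pair
                shells.append((l, *normed(a[2:], c[2:])))   # free diffuse primitive
        else:
            raise ValueError(f"unknown basis quality {quality!r}")
    return shells


BASIS_ALIASES = {
    "min": "min", "minimal": "min", "sto": "min",
    "sv": "sv", "split-valence": "sv", "svp": "sv",
}


def build_basis(charges, coords, name):
    """Primary basis for a molecule; coords in bohr."""
    key = BASIS_ALIASES.get(str(name).lower())
    if key is None:
        raise ValueError(f"basis {name!r} not resolvable (known: {sorted(set(BASIS_ALIASES))})")
    shells, atoms = [], []
    for ia, (z, xyz) in enumerate(zip(charges, coords)):
        for l, a, c in _element_shells(int(z), key):
            shells.append(Shell(l=l, center=np.asarray(xyz, float), exps=np.asarray(a), coefs=np.asarray(c)))
            atoms.append(ia)
    return BasisSet(shells, atoms)


def build_aux_basis(charges, coords, primary: BasisSet, name="etb"):
    """Even-tempered auxiliary fitting basis.

    Exponents span twice the primary primitive range (Gaussian products),
    geometric progression with ratio ``beta`` (default 2.0); angular momenta
    up to min(2, 2*lmax + 1) per element.
    """
    name = str(name).lower()
    if name.startswith("etb@"):
        beta = float(name.split("@", 1)[1])
    elif name in ("etb", "auto", "even-tempered"):
        beta = 2.0
    else:
        raise ValueError(f"auxiliary basis {name!r} not resolvable (use 'etb' or 'etb@<beta>')")
    if beta <= 1.0:
        raise ValueError("even-tempered ratio must exceed 1")

    # per-atom primitive exponent ranges from the primary set
    ranges = {}
    for ish, sh in enumerate(primary.shells):
        ia = primary.atom_of_shell[ish]
        lo, hi, lmax = ranges.get(ia, (np.inf, 0.0, 0))
        ranges[ia] = (min(lo, sh.exps.min()), max(hi, sh.exps.max()), max(lmax, sh.l))

    shells, atoms = [], []
    for ia, xyz in enumerate(coords):
        lo, hi, lmax = ranges[ia]
        amin, amax = 2.0 * lo, 2.0 * hi
        npts = int(np.ceil(np.log(amax / amin) / np.log(beta))) + 1
        exps = amin * beta ** np.arange(npts)
        l_top = min(2, 2 * lmax + 1)
        for l in range(l_top + 1):
            for a in exps:
                shells.append(Shell(l=l, center=np.asarray(xyz, float), exps=np.array([a]), coefs=np.array([1.0])))
                atoms.append(ia)
    return BasisSet(shells, atoms)
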