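"""Molecular integrals over contracted Cartesian Gaussians.

McMurchie-Davidson scheme: Gaussian products are expanded in Hermite
Gaussians (``E`` coefficients), Coulomb-type integrals are assembled from
Hermite Coulomb integrals (``R`` tensors) built on the Boys function.

Everything is in Hartree atomic units (lengths in bohr).  Basis functions
are individually normalized contracted Cartesian Gaussians
``x^i y^j z^k exp(-a r^2)``; the per-function normalization scales live on
the :class:`~gwbse.qchem.basis.BasisSet` and are applied by the assembly
routines here.
"""
from __future__ import annotations

import numpy as np
from scipy.special import gammainc, gammaln

__all__ = [
    "boys",
    "overlap",
    "kinetic",
    "nuclear_attraction",
    "dipole",
    "eri_2c",
    "eri_3c",
    "eri_4c",
]


# ---------------------------------------------------------------------------
# Boys function
# ---------------------------------------------------------------------------

def boys(nmax: int, t: np.ndarray) -> np.ndarray:
    """Boys functions ``F_n(t)`` for ``n = 0..nmax``.

    Returns an array of shape ``(nmax + 1,) + t.shape``.  Small arguments
    use the Taylor series; otherwise the regularized lower incomplete gamma
    function provides machine-precision values.
    """
    t = np.asarray(t, dtype=float)
    out = np.empty((nmax + 1,) + t.shape)
    small = t < 0.025
    ts = np.where(small, 1.0, t)
    for n in range(nmax + 1):
        a = n + 0.5
        big = 0.5 * np.exp(gammaln(a)) * gammainc(a, ts) / ts**a
        # 8-term Taylor series, relative error < 1e-16 for t < 0.025
        ser = np.zeros_like(t)
        fac = 1.0
        for k in range(8):
            ser = ser + fac / (2 * n + 2 * k + 1)
            fac = fac * (-t) / (k + 1)
        out[n] = np.where(small, ser, big)
    return out


# ---------------------------------------------------------------------------
# Hermite expansion coefficients
# ---------------------------------------------------------------------------

def _e_tables(la, lb, A, B, a, b):
    """Hermite expansion coefficients E[d, i, j, t] for one shell pair.

    ``a``, ``b`` are flattened meshes of primitive exponents (length K).
    The t axis is padded by one slot so the upward recursion never reads
    out of bounds (padding entries stay zero).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    p = a + b
    mu = a * b / p
    oop = 0.5 / p
    K = len(a)
    E = np.zeros((3, la + 1, lb + 1, la + lb + 2, K))
    AB = A - B
    for d in range(3):
        E[d, 0, 0, 0] = np.exp(-mu * AB[d] ** 2)
    PA = np.outer(-b / p, AB)
    PB = np.outer(a / p, AB)
    for d in range(3):
        for i in range(la + 1):
            for j in range(lb + 1):
                if i == 0 and j == 0:
                    continue
                for t in range(i + j + 1):
                    if i > 0:
                        v = PA[:, d] * E[d, i - 1, j, t] + (t + 1) * E[d, i - 1, j, t + 1]
                        if t > 0:
                            v = v + oop * E[d, i - 1, j, t - 1]
                    else:
                        v = PB[:, d] * E[d, i, j - 1, t] + (t + 1) * E[d, i, j - 1, t + 1]
                        if t > 0:
                            v = v + oop * E[d, i, j - 1, t - 1]
                    E[d, i, j, t] = v
    return E, p


def _hermite_R(Lx, Ly, Lz, p, PQ):
    """Hermite Coulomb integrals R[t, u, v] on a flattened point mesh.

    ``p`` is the effective exponent, ``PQ`` the Gaussian-center separation
    (K, 3).  Returns an array of shape (Lx+1, Ly+1, Lz+1, K).
    """
    L = Lx + Ly + Lz
    K = len(p)
    T = p * np.einsum("kd,kd->k", PQ, PQ)
    F = boys(L, T)
    R = np.zeros((L + 1, Lx + 1, Ly + 1, Lz + 1, K))
    pow_m2p = (-2.0 * p)[None, :] ** np.arange(L + 1)[:, None]
    R[:, 0, 0, 0, :] = pow_m2p * F
    for m in range(1, L + 1):
        for t in range(min(m, Lx) + 1):
            for u in range(min(m - t, Ly) + 1):
                v = m - t - u
                if v > Lz:
                    continue
                for n in range(L - m + 1):
                    if t > 0:
                        val = PQ[:, 0] * R[n + 1, t - 1, u, v]
                        if t > 1:
                            val = val + (t - 1) * R[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = PQ[:, 1] * R[n + 1, t, u - 1, v]
                        if u > 1:
                            val = val + (u - 1) * R[n + 1, t, u - 2, v]
                    else:
                        val = PQ[:, 2] * R[n + 1, t, u, v - 1]
                        if v > 1:
                            val = val + (v - 1) * R[n + 1, t, u, v - 2]
                    R[n, t, u, v] = val
    return R[0]


# ---------------------------------------------------------------------------
# one-electron matrices
# ---------------------------------------------------------------------------

def _pair_weights(sha, shb):
    """Contraction weights w[K, ca, cb] including primitive norms."""
    wa = sha.prim_weights()  # (Ka, ncarta)
    wb = shb.prim_weights()
    w = wa[:, None, :, None] * wb[None, :, None, :]
    return w.reshape(-1, wa.shape[1], wb.shape[1])


def _mesh(sha, shb):
    a, b = np.meshgrid(sha.exps, shb.exps, indexing="ij")
    return a.ravel(), b.ravel()


def overlap(basis):
    return _one_electron(basis, kind="overlap")


def kinetic(basis):
    return _one_electron(basis, kind="kinetic")


def dipole(basis, origin=(0.0, 0.0, 0.0)):
    """Length-gauge dipole operator matrices ``<mu| r_d - origin_d |nu>``.

    Returns an array of shape (3, nbf, nbf).
    """
    origin = np.asarray(origin, float)
    n = basis.nbf
    M = np.zeros((3, n, n))
    for isha, sha in enumerate(basis.shells):
        for ishb, shb in enumerate(basis.shells):
            if ishb < isha:
                continue
            a, b = _mesh(sha, shb)
            E, p = _e_tables(sha.l + 1, shb.l, sha.center, shb.center, a, b)
            pref = (np.pi / p) ** 1.5
            w = _pair_weights(sha, shb)
            blk = np.zeros((3, sha.ncart, shb.ncart))
            for ca, (ix, iy, iz) in enumerate(sha.cart):
                for cb, (jx, jy, jz) in enumerate(shb.cart):
                    s0 = [E[0, ix, jx, 0], E[1, iy, jy, 0], E[2, iz, jz, 0]]
                    up = [E[0, ix + 1, jx, 0], E[1, iy + 1, jy, 0], E[2, iz + 1, jz, 0]]
                    for d in range(3):
                        fac = up[d] + (sha.center[d] - origin[d]) * s0[d]
                        val = pref * fac
                        for e in range(3):
                            if e != d:
                                val = val * s0[e]
                        blk[d, ca, cb] = w[:, ca, cb] @ val
            sl_a, sl_b = basis.slice(isha), basis.slice(ishb)
            M[:, sl_a, sl_b] = blk
            if ishb != isha:
                M[:, sl_b, sl_a] = np.transpose(blk, (0, 2, 1))
    sc = basis.scales
    return M * sc[None, :, None] * sc[None, None, :]


def _one_electron(basis, kind):
    n = basis.nbf
    M = np.zeros((n, n))
    for isha, sha in enumerate(basis.shells):
        for ishb, shb in enumerate(basis.shells):
            if ishb < isha:
                continue
            a, b = _mesh(sha, shb)
            E, p = _e_tables(sha.l, shb.l + 2, sha.center, shb.center, a, b)
            pref = (np.pi / p) ** 1.5
            w = _pair_weights(sha, shb)
            blk = np.zeros((sha.ncart, shb.ncart))
            for ca, (ix, iy, iz) in enumerate(sha.cart):
                ia = (ix, iy, iz)
                for cb, (jx, jy, jz) in enumerate(shb.cart):
                    jb = (jx, jy, jz)
                    if kind == "overlap":
                        val = pref * E[0, ix, jx, 0] * E[1, iy, jy, 0] * E[2, iz, jz, 0]
                    else:
                        s0 = [E[0, ix, jx, 0], E[1, iy, jy, 0], E[2, iz, jz, 0]]
                        val = np.zeros_like(p)
                        for d in range(3):
                            j = jb[d]
                            i = ia[d]
                            term = 4.0 * b**2 * E[d, i, j + 2, 0] - 2.0 * b * (2 * j + 1) * E[d, i, j, 0]
                            if j >= 2:
                                term = term + j * (j - 1) * E[d, i, j - 2, 0]
                            for e in range(3):
                                if e != d:
                                    term = term * s0[e]
                            val = val + term
                        val = -0.5 * pref * val
                    blk[ca, cb] = w[:, ca, cb] @ val
            sl_a, sl_b = basis.slice(isha), basis.slice(ishb)
            M[sl_a, sl_b] = blk
            if ishb != isha:
                M[sl_b, sl_a] = blk.T
    sc = basis.scales
    return M * np.outer(sc, sc)


def nuclear_attraction(basis, charges, coords):
    """Nuclear attraction matrix ``-sum_C Z_C <mu| 1/|r-R_C| |nu>``."""
    charges = np.asarray(charges, float)
    coords = np.asarray(coords, float)
    n = basis.nbf
    M = np.zeros((n, n))
    for isha, sha in enumerate(basis.shells):
        for ishb, shb in enumerate(basis.shells):
            if ishb < isha:
                continue
            a, b = _mesh(sha, shb)
            E, p = _e_tables(sha.l, shb.l, sha.center, shb.center, a, b)
            P = (np.outer(a, sha.center) + np.outer(b, shb.center)) / p[:, None]
            w = _pair_weights(sha, shb)
            blk = np.zeros((sha.ncart, shb.ncart))
            L = sha.l + shb.l
            for C, Z in zip(coords, charges):
                R = _hermite_R(L, L, L, p, P - C[None, :])
                pref = -Z * 2.0 * np.pi / p
                for ca, (ix, iy, iz) in enumerate(sha.cart):
                    for cb, (jx, jy, jz) in enumerate(shb.cart):
                        val = np.zeros_like(p)
                        for t in range(ix + jx + 1):
                            for u in range(iy + jy + 1):
                                for v in range(iz + jz + 1):
                                    val = val + (
                                        E[0, ix, jx, t]
                                        * E[1, iy, jy, u]
                                        * E[2, iz, jz, v]
                                        * R[t, u, v]
                                    )
                        blk[ca, cb] += w[:, ca, cb] @ (pref * val)
            sl_a, sl_b = basis.slice(isha), basis.slice(ishb)
            M[sl_a, sl_b] = blk
            if ishb != isha:
                M[sl_b, sl_a] = blk.T
    sc = basis.scales
    return M * np.outer(sc, sc)


# ---------------------------------------------------------------------------
# Coulomb integrals (2-, 3-, 4-center)
# ---------------------------------------------------------------------------

def _hermite_density(sh_pair_E, carts_a, carts_b):
    """List of per-component-pair Hermite coefficient dictionaries."""
    E = sh_pair_E
    out = []
    for (ix, iy, iz) in carts_a:
        row = []
        for (jx, jy, jz) in carts_b:
            terms = []
            for t in range(ix + jx + 1):
                ex = E[0, ix, jx, t]
                for u in range(iy + jy + 1):
                    ey = E[1, iy, jy, u]
                    for v in range(iz + jz + 1):
                        terms.append((t, u, v, ex * ey * E[2, iz, jz, v]))
            row.append(terms)
        out.append(row)
    return out


def _coulomb_block(sha, shb, shc, shd):
    """(ab|cd) block over normalized contracted functions (no scales)."""
    a, b = _mesh(sha, shb)
    c, d = _mesh(shc, shd)
    Eab, p = _e_tables(sha.l, shb.l, sha.center, shb.center, a, b)
    Ecd, q = _e_tables(shc.l, shd.l, shc.center, shd.center, c, d)
    P = (np.outer(a, sha.center) + np.outer(b, shb.center)) / p[:, None]
    Q = (np.outer(c, shc.center) + np.outer(d, shd.center)) / q[:, None]
    K1, K2 = len(p), len(q)
    pm = np.repeat(p, K2)
    qm = np.tile(q, K1)
    alpha = pm * qm / (pm + qm)
    PQ = np.repeat(P, K2, axis=0) - np.tile(Q, (K1, 1))
    Lab = sha.l + shb.l
    Lcd = shc.l + shd.l
    R = _hermite_R(Lab + Lcd, Lab + Lcd, Lab + Lcd, alpha, PQ)
    R = R.reshape(R.shape[0], R.shape[1], R.shape[2], K1, K2)
    pref = (2.0 * np.pi**2.5 / (pm * qm * np.sqrt(pm + qm))).reshape(K1, K2)
    wab = _pair_weights(sha, shb)
    wcd = _pair_weights(shc, shd)
    Dab = _hermite_density(Eab, sha.cart, shb.cart)
    Dcd = _hermite_density(Ecd, shc.cart, shd.cart)
    blk = np.zeros((sha.ncart, shb.ncart, shc.ncart, shd.ncart))
    for ca in range(sha.ncart):
        for cb in range(shb.ncart):
            w1 = wab[:, ca, cb]
            for cc in range(shc.ncart):
                for cd_ in range(shd.ncart):
                    w2 = wcd[:, cc, cd_]
                    acc = np.zeros((K1, K2))
                    for (t, u, v, e1) in Dab[ca][cb]:
                        for (t2, u2, v2, e2) in Dcd[cc][cd_]:
                            sgn = -1.0 if (t2 + u2 + v2) % 2 else 1.0
                            acc += sgn * np.outer(e1, e2) * R[t + t2, u + u2, v + v2]
                    blk[ca, cb, cc, cd_] = w1 @ (pref * acc) @ w2
    return blk


def eri_4c(basis):
    """Full four-center electron-repulsion tensor (pq|rs).

    Intended for small oracle systems; cost grows steeply with basis size.
    """
    n = basis.nbf
    eri = np.zeros((n, n, n, n))
    shells = basis.shells
    npairs = []
    for i in range(len(shells)):
        for j in range(i + 1):
            npairs.append((i, j))
    for ip, (i, j) in enumerate(npairs):
        for (k, l) in npairs[: ip + 1]:
            blk = _coulomb_block(shells[i], shells[j], shells[k], shells[l])
            si, sj, sk, sl = (basis.slice(x) for x in (i, j, k, l))
            eri[si, sj, sk, sl] = blk
            eri[sj, si, sk, sl] = blk.transpose(1, 0, 2, 3)
            eri[si, sj, sl, sk] = blk.transpose(0, 1, 3, 2)
            eri[sj, si, sl, sk] = blk.transpose(1, 0, 3, 2)
            eri[sk, sl, si, sj] = blk.transpose(2, 3, 0, 1)
            eri[sl, sk, si, sj] = blk.transpose(3, 2, 0, 1)
            eri[sk, sl, sj, si] = blk.transpose(2, 3, 1, 0)
            eri[sl, sk, sj, si] = blk.transpose(3, 2, 1, 0)
    sc = basis.scales
    return np.einsum("pqrs,p,q,r,s->pqrs", eri, sc, sc, sc, sc, optimize=True)


def eri_3c(aux, basis):
    """Three-center Coulomb tensor (P|pq), shape (naux, nbf, nbf)."""
    na, n = aux.nbf, basis.nbf
    out = np.zeros((na, n, n))
    for ishp, shp in enumerate(aux.shells):
        slp = aux.slice(ishp)
        for isha, sha in enumerate(basis.shells):
            for ishb, shb in enumerate(basis.shells):
                if ishb < isha:
                    continue
                blk = _coulomb_block(shp, _unit_s(shp.center), sha, shb)[:, 0]
                sl_a, sl_b = basis.slice(isha), basis.slice(ishb)
                out[slp, sl_a, sl_b] = blk
                if ishb != isha:
                    out[slp, sl_b, sl_a] = blk.transpose(0, 2, 1)
    sa, sc = aux.scales, basis.scales
    return out * sa[:, None, None] * sc[None, :, None] * sc[None, None, :]


def eri_2c(aux):
    """Two-center Coulomb metric (P|Q) of the auxiliary set."""
    n = aux.nbf
    out = np.zeros((n, n))
    for i, shp in enumerate(aux.shells):
        for j, shq in enumerate(aux.shells):
            if j < i:
                continue
            blk = _coulomb_block(shp, _unit_s(shp.center), shq, _unit_s(shq.center))[:, 0, :, 0]
            out[aux.slice(i), aux.slice(j)] = blk
            if j != i:
                out[aux.slice(j), aux.slice(i)] = blk.T
    sc = aux.scales
    return out * np.outer(sc, sc)


def _unit_s(center):
    """Dummy zero-exponent s 'shell' used to express single-shell Coulomb
    integrals through the shell-pair machinery."""
    from .basis import Shell

    return Shell(l=0, center=np.asarray(center, float), exps=np.array([0.0]), coefs=np.array([1.0]), raw=True)
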