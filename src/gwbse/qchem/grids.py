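"""Molecular integration grid for the xc potential.

Atom-centered grids: Mura-Knowles log3 radial mapping combined with a
Gauss-Legendre (cos-theta) x uniform (phi) angular product rule, stitched
with Becke's smooth Voronoi partition (three smoothing passes, no atomic
size adjustment).  Accuracy is set for mean-field reference calculations;
the correlated layers never touch this grid.
"""
from __future__ import annotations

import numpy as np

__all__ = ["molecular_grid", "eval_basis"]


def _radial_mura_knowles(n, alpha=5.0):
    x = (np.arange(n) + 0.5) / n
    r = -alpha * np.log1p(-(x**3))
    dr = alpha * 3 * x**2 / (1.0 - x**3) / n
    w = dr * r**2
    return r, w


def _angular_product(n_theta):
    mu, wmu = np.polynomial.legendre.leggauss(n_theta)
    n_phi = 2 * n_theta
    phi = 2 * np.pi * np.arange(n_phi) / n_phi
    st = np.sqrt(1.0 - mu**2)
    pts = np.empty((n_theta * n_phi, 3))
    w = np.empty(n_theta * n_phi)
    k = 0
    for i in range(n_theta):
        for j in range(n_phi):
            pts[k] = (st[i] * np.cos(phi[j]), st[i] * np.sin(phi[j]), mu[i])
            w[k] = wmu[i] * 2 * np.pi / n_phi
            k += 1
    return pts, w


def _becke_weights(points, coords, k=3):
    natm = len(coords)
    if natm == 1:
        return np.ones(len(points))
    d = np.linalg.norm(points[:, None, :] - coords[None, :, :], axis=2)  # (np, natm)
    rij = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    P = np.ones((len(points), natm))
    for i in range(natm):
        for j in range(natm):
            if i == j:
                continue
            mu = (d[:, i] - d[:, j]) / rij[i, j]
            f = mu
            for _ in range(k):
                f = 1.5 * f - 0.5 * f**3
            P[:, i] *= 0.5 * (1.0 - f)
    return P / P.sum(axis=1, keepdims=True)


def molecular_grid(charges, coords, n_rad=60, n_theta=14):
    """Becke-partitioned grid; returns (points (N,3), weights (N,))."""
    coords = np.asarray(coords, float)
    ang_pts, ang_w = _angular_product(n_theta)
    all_pts, all_w = [], []
    for ia, xyz in enumerate(coords):
        alpha = 3.0 if charges[ia] <= 2 else 5.0
        r, wr = _radial_mura_knowles(n_rad, alpha=alpha)
        pts = xyz[None, None, :] + r[:, None, None] * ang_pts[None, :, :]
        w = wr[:, None] * ang_w[None, :]
        pts = pts.reshape(-1, 3)
        w = w.ravel()
        becke = _becke_weights(pts, coords)[:, ia]
        all_pts.append(pts)
        all_w.append(w * becke)
    return np.concatenate(all_pts), np.concatenate(all_w)


def eval_basis(basis, points, deriv=False):
    """Basis values (and Cartesian gradients) on grid points.

    Returns ``vals (N, nbf)`` or ``(vals, grads (3, N, nbf))``.
    """
    N = len(points)
    vals = np.zeros((N, basis.nbf))
    grads = np.zeros((3, N, basis.nbf)) if deriv else None
    for ish, sh in enumerate(basis.shells):
        sl = basis.slice(ish)
        rel = points - sh.center[None, :]
        r2 = np.einsum("nd,nd->n", rel, rel)
        w = sh.prim_weights()  # (nprim, ncart)
        expv = np.exp(-np.outer(r2, sh.exps))  # (N, nprim)
        for c, (lx, ly, lz) in enumerate(sh.cart):
            poly = rel[:, 0] ** lx * rel[:, 1] ** ly * rel[:, 2] ** lz
            radial = expv @ w[:, c]
            vals[:, sl][:, c] = poly * radial
            if deriv:
                dradial = -2.0 * (expv * sh.exps[None, :]) @ w[:, c]
                for d, ld in enumerate((lx, ly, lz)):
                    dpoly = np.zeros(N)
                    if ld > 0:
                        e = [lx, ly, lz]
                        e[d] -= 1
                        dpoly = ld * rel[:, 0] ** e[0] * rel[:, 1] ** e[1] * rel[:, 2] ** e[2]
                    grads[d][:, sl][:, c] = dpoly * radial + poly * rel[:, d] * dradial
    vals *= basis.scales[None, :]
    if deriv:
        grads *= basis.scales[None, None, :]
        return vals, grads
    return vals
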