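"""Restricted closed-shell SCF (HF and Kohn-Sham) with RI-JK and DIIS.

This is the mean-field reference engine behind
:func:`gwbse.system_core.run_mean_field`.  Coulomb and exact exchange are
assembled from the same three-center RI tensor that the correlated layers
use, which makes mean-field and many-body quantities exactly consistent at
the fitted-integral level.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dft, grids, integrals

__all__ = ["SCFResult", "run_scf", "SCFConvergenceError"]


class SCFConvergenceError(RuntimeError):
    pass


@dataclass
class SCFResult:
    e_tot: float
    mo_coeff: np.ndarray
    mo_energy: np.ndarray
    mo_occ: np.ndarray
    fock: np.ndarray          # AO basis
    hcore: np.ndarray
    overlap: np.ndarray
    vxc: np.ndarray           # DFT xc potential matrix (zero for HF)
    k_matrix: np.ndarray      # full exchange matrix K[D] at convergence
    density: np.ndarray
    hyb: float                # exact-exchange fraction in the reference
    reference_tag: str
    e_nuc: float
    converged: bool
    n_iter: int

    @property
    def nocc(self):
        return int(round(self.mo_occ.sum() / 2))

    @property
    def homo_lumo_gap(self):
        n = self.nocc
        return self.mo_energy[n] - self.mo_energy[n - 1]


def _nuclear_repulsion(charges, coords):
    e = 0.0
    for i in range(len(charges)):
        for j in range(i):
            e += charges[i] * charges[j] / np.linalg.norm(coords[i] - coords[j])
    return e


def _vxc_matrix(tag, D, vals, grads, w):
    rho = np.einsum("np,nq,pq->n", vals, vals, D, optimize=True)
    rho = np.maximum(rho, 0.0)
    if grads is not None:
        drho = np.stack([2.0 * np.einsum("np,nq,pq->n", grads[d], vals, D, optimize=True) for d in range(3)])
        gamma = np.einsum("dn,dn->n", drho, drho)
    else:
        drho = gamma = None
    e, vr, vg = dft.xc_eval(tag, rho, gamma)
    exc = float(w @ e)
    V = vals.T @ (vals * (w * vr)[:, None])
    if vg is not None:
        for d in range(3):
            half = grads[d].T @ (vals * (2.0 * w * vg * drho[d])[:, None])
            V += half + half.T
    # double-counting correction pieces
    e_dc = float(np.sum((w * vr) * rho))
    if vg is not None:
        e_dc += float(np.sum(2.0 * w * vg * gamma))
    return exc, V, e_dc


def run_scf(charges, coords, basis, b_tensor, reference_tag,
            conv_tol=1e-11, conv_tol_grad=1e-8, max_cycle=200,
            n_rad=60, n_theta=14):
    """Converge a restricted SCF; ``coords`` in bohr.

    ``b_tensor`` is the orthonormalized RI tensor B[L,p,q] used for both the
    Coulomb and the exact-exchange builds.
    """
    tag = str(reference_tag).upper()
    if tag not in dft.XC_SPECS:
        raise ValueError(f"unknown reference {reference_tag!r}; choose from {sorted(dft.XC_SPECS)}")
    spec = dft.XC_SPECS[tag]
    charges = np.asarray(charges, float)
    coords = np.asarray(coords, float)
    nelec = int(round(charges.sum()))
    S = integrals.overlap(basis)
    T = integrals.kinetic(basis)
    V = integrals.nuclear_attraction(basis, charges, coords)
    h = T + V
    e_nuc = _nuclear_repulsion(charges, coords)

    # canonical orthogonalization
    sval, svec = np.linalg.eigh(S)
    if sval.min() < 1e-10 * sval.max():
        keep = sval > 1e-10 * sval.max()
        X = svec[:, keep] / np.sqrt(sval[keep])
    else:
        X = svec / np.sqrt(sval)

    if spec["grid"]:
        pts, w = grids.molecular_grid(charges, coords, n_rad=n_rad, n_theta=n_theta)
        if spec["gga"]:
            vals, gvals = grids.eval_basis(basis, pts, deriv=True)
        else:
            vals, gvals = grids.eval_basis(basis, pts, deriv=False), None
    else:
        vals = gvals = w = None

    nocc = nelec // 2
    if nelec % 2:
        raise ValueError("open-shell systems are not supported by the restricted engine")

    def make_fock(D):
        gamma_P = np.einsum("Prs,rs->P", b_tensor, D, optimize=True)
        J = np.einsum("Ppq,P->pq", b_tensor, gamma_P, optimize=True)
        K = np.einsum("Ppr,rs,Psq->pq", b_tensor, D, b_tensor, optimize=True)
        if spec["grid"]:
            exc, Vxc, e_dc = _vxc_matrix(tag, D, vals, gvals, w)
        else:
            exc, Vxc, e_dc = 0.0, np.zeros_like(D), 0.0
        F = h + J - 0.5 * spec["hyb"] * K + Vxc
        e_elec = float(np.sum(D * h) + 0.5 * np.sum(D * J)
                       - 0.25 * spec["hyb"] * np.sum(D * K) + exc)
        return F, J, K, Vxc, e_elec

    # deterministic core-Hamiltonian guess
    Ft = X.T @ h @ X
    eps, Ct = np.linalg.eigh(Ft)
    C = X @ Ct
    D = 2.0 * C[:, :nocc] @ C[:, :nocc].T

    diis_F, diis_e = [], []
    e_old = 0.0
    converged = False
    for it in range(1, max_cycle + 1):
        F, J, K, Vxc, e_elec = make_fock(D)
        err = X.T @ (F @ D @ S - S @ D @ F) @ X
        diis_F.append(F.copy())
        diis_e.append(err.ravel())
        if len(diis_F) > 8:
            diis_F.pop(0)
            diis_e.pop(0)
        if len(diis_F) > 1:
            m = len(diis_F)
            Bm = -np.ones((m + 1, m + 1))
            Bm[-1, -1] = 0.0
            for i in range(m):
                for j in range(m):
                    Bm[i, j] = diis_e[i] @ diis_e[j]
            rhs = np.zeros(m + 1)
            rhs[-1] = -1.0
            try:
                c = np.linalg.solve(Bm, rhs)[:m]
                F = sum(ci * Fi for ci, Fi in zip(c, diis_F))
            except np.linalg.LinAlgError:
                pass
        Ft = X.T @ F @ X
        eps, Ct = np.linalg.eigh(Ft)
        C = X @ Ct
        D_new = 2.0 * C[:, :nocc] @ C[:, :nocc].T
        if it <= 2 and len(diis_F) < 3:
            D_new = 0.7 * D_new + 0.3 * D
        de = e_elec + e_nuc - e_old
        gnorm = np.abs(diis_e[-1]).max()
        e_old = e_elec + e_nuc
        D = D_new
        if abs(de) < conv_tol and gnorm < conv_tol_grad and it > 2:
            converged = True
            break
    if not converged:
        raise SCFConvergenceError(
            f"SCF did not converge in {max_cycle} cycles (dE={de:.2e}, grad={gnorm:.2e})")

    # final consistent quantities at the converged density
    F, J, K, Vxc, e_elec = make_fock(D)
    Ft = X.T @ F @ X
    eps, Ct = np.linalg.eigh(Ft)
    C = X @ Ct
    D = 2.0 * C[:, :nocc] @ C[:, :nocc].T
    occ = np.zeros(len(eps))
    occ[:nocc] = 2.0
    return SCFResult(
        e_tot=e_elec + e_nuc, mo_coeff=C, mo_energy=eps, mo_occ=occ,
        fock=F, hcore=h, overlap=S, vxc=Vxc,
        k_matrix=np.einsum("Ppr,rs,Psq->pq", b_tensor, D, b_tensor, optimize=True),
        density=D, hyb=spec["hyb"], reference_tag=tag, e_nuc=e_nuc,
        converged=True, n_iter=it,
    )
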