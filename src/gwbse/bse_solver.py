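"""Singlet Bethe-Salpeter eigenproblem and its iterative (Davidson) solver.

Closed-shell particle-hole BSE with a statically screened kernel:

    A[ia,jb] = (e_a - e_i) delta_ij delta_ab + 2 (ia|jb) - W_{ij,ab}(0)
    B[ia,jb] = 2 (ia|jb) - W_{ib,ja}(0)

where (pq|rs) are fitted Coulomb integrals over quasiparticle orbitals and
W(0) is the statically screened interaction.  Replacing W by the bare
interaction on a Hartree-Fock reference yields TD-HF; dropping B is the
Tamm-Dancoff approximation.  The generalized problem

    [[A, B], [-B, -A]] (X, Y)^T = Omega (X, Y)^T

is solved in the symmetric (A-B)^{1/2} (A+B) (A-B)^{1/2} reduction
projected on a growing orthonormal subspace of particle-hole vectors, with
matrix-free (A +/- B) contractions, diagonal preconditioning, deterministic
initialization from the lowest-gap pairs, and thick restarts.  Dense
materialization is available below a size guard for oracle checks.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

log = logging.getLogger("gwbse")

__all__ = [
    "BSEOperator", "ExcitonSolution", "build_bse_operator",
    "apply_kernel_columns", "davidson_solve", "solve_tda",
]

DENSE_GUARD = 800  # largest particle-hole space materialized densely


@dataclass
class BSEOperator:
    """Matrix-free singlet BSE Hamiltonian in the active pair space."""

    qp_energies: np.ndarray       # active-window QP energies
    nocc: int
    active_pairs: np.ndarray      # (n_act, 2) of (i, a) indices
    gaps: np.ndarray              # (n_act,)
    b_ov: np.ndarray
    b_oo: np.ndarray
    b_vv: np.ndarray
    w_static: np.ndarray
    mode: str = "BSE"
    include_v: bool = True        # diagnostic switches used by tests
    include_w: bool = True
    # precontracted W*B blocks
    _wboo: np.ndarray = field(default=None, repr=False)
    _wbov: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.active_pairs) == 0:
            raise ValueError("empty particle-hole space (cutoff too low?)")
        if self.include_w:
            self._wboo = np.einsum("LM,Lij->Mij", self.w_static, self.b_oo, optimize=True)
            self._wbov = np.einsum("LM,Lia->Mia", self.w_static, self.b_ov, optimize=True)

    @property
    def n_pairs(self):
        return len(self.active_pairs)

    @property
    def nvir(self):
        return self.b_ov.shape[2]

    def diag_a(self):
        """Diagonal of A (used by the preconditioner)."""
        ii, aa = self.active_pairs[:, 0], self.active_pairs[:, 1]
        d = self.gaps.copy()
        if self.include_v:
            d += 2.0 * np.einsum("Lk,Lk->k", self.b_ov[:, ii, aa], self.b_ov[:, ii, aa])
        if self.include_w:
            wii = np.einsum("Mk,Mk->k",
                            np.einsum("LM,Lk->Mk", self.w_static, self.b_oo[:, ii, ii]),
                            self.b_vv[:, aa, aa])
            d -= wii
        return d

    # -- elementary contractions (columns stacked in the second axis) ------

    def _embed(self, t):
        T = np.zeros((t.shape[1], self.nocc, self.nvir))
        T[:, self.active_pairs[:, 0], self.active_pairs[:, 1]] = t.T
        return T

    def _extract(self, T):
        return T[:, self.active_pairs[:, 0], self.active_pairs[:, 1]].T

    def _v_term(self, T):
        VL = np.einsum("Lia,nia->Ln", self.b_ov, T, optimize=True)
        return np.einsum("Lia,Ln->nia", self.b_ov, VL, optimize=True)

    def _w_term_a(self, T):
        # sum_jb W_{ij,ab} T_jb
        t1 = np.einsum("Mab,njb->Mnja", self.b_vv, T, optimize=True)
        return np.einsum("Mij,Mnja->nia", self._wboo, t1, optimize=True)

    def _w_term_b(self, T):
        # sum_jb W_{ib,ja} T_jb
        u = np.einsum("Mja,njb->Mnab", self._wbov, T, optimize=True)
        return np.einsum("Lib,Lnab->nia", self.b_ov, u, optimize=True)

    def apply_a(self, t):
        t = np.atleast_2d(t.T).T if t.ndim == 1 else t
        T = self._embed(t)
        out = self.gaps[:, None] * t
        if self.include_v:
            out = out + 2.0 * self._extract(self._v_term(T))
        if self.include_w:
            out = out - self._extract(self._w_term_a(T))
        return out

    def apply_b(self, t):
        t = np.atleast_2d(t.T).T if t.ndim == 1 else t
        T = self._embed(t)
        out = np.zeros_like(t)
        if self.include_v:
            out = out + 2.0 * self._extract(self._v_term(T))
        if self.include_w:
            out = out - self._extract(self._w_term_b(T))
        return out

    def apply_a_plus_b(self, t):
        return self.apply_a(t) + self.apply_b(t)

    def apply_a_minus_b(self, t):
        return self.apply_a(t) - self.apply_b(t)

    # -- dense materialization (oracle path) -------------------------------

    def dense_ab(self):
        """Dense (A, B) matrices in the active pair space; guarded."""
        n = self.n_pairs
        if n > DENSE_GUARD:
            raise ValueError(
                f"dense materialization refused for {n} > {DENSE_GUARD} pairs")
        ii, aa = self.active_pairs[:, 0], self.active_pairs[:, 1]
        A = np.diag(self.gaps.astype(float))
        B = np.zeros((n, n))
        if self.include_v:
            vov = np.einsum("Lk,Lm->km", self.b_ov[:, ii, aa], self.b_ov[:, ii, aa])
            A = A + 2.0 * vov
            B = B + 2.0 * vov
        if self.include_w:
            woo = self.b_oo[:, ii[:, None], ii[None, :]]     # [L,k,m] = (i_k i_m|
            wvv = self.b_vv[:, aa[:, None], aa[None, :]]
            A = A - np.einsum("Lkm,LM,Mkm->km", woo, self.w_static, wvv, optimize=True)
            wib = self.b_ov[:, ii[:, None], aa[None, :]]     # [L,k,m] = (i_k b_m|
            wja = self.b_ov[:, ii[None, :], aa[:, None]]     # [M,k,m] = (j_m a_k|
            B = B - np.einsum("Lkm,LM,Mkm->km", wib, self.w_static, wja, optimize=True)
        return A, B


def build_bse_operator(qp, screening=None, blocks=None, ph_cutoff=None,
                       mode="BSE") -> BSEOperator:
    """Assemble the BSE operator from a quasiparticle solution.

    ``qp`` is a QPSolution (its stored blocks/screening are used unless
    overridden).  ``ph_cutoff`` (Hartree) restricts the pair space to
    transitions below the cutoff; None keeps all pairs.  ``mode='TDHF'``
    replaces W(0) by the bare (identity) interaction.
    """
    blocks = blocks if blocks is not None else qp._blocks
    screening = screening if screening is not None else qp._screening
    e = np.asarray(qp.qp_energies)
    no = blocks.nocc
    nv = blocks.b_ov.shape[2]
    gaps = e[no:][None, :] - e[:no][:, None]
    mode = str(mode).upper()
    if mode not in ("BSE", "TDHF", "TDA"):
        raise ValueError(f"unknown BSE mode {mode!r}")
    if mode == "TDHF":
        w = np.eye(blocks.b_ov.shape[0])
    else:
        w = screening.w_static
    cut = np.inf if ph_cutoff is None else float(ph_cutoff)
    pairs = [(i, a) for i in range(no) for a in range(nv) if gaps[i, a] <= cut]
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if len(pairs) == 0:
        raise ValueError("particle-hole cutoff removed every transition")
    return BSEOperator(
        qp_energies=e, nocc=no, active_pairs=pairs,
        gaps=gaps[pairs[:, 0], pairs[:, 1]],
        b_ov=blocks.b_ov, b_oo=blocks.b_oo, b_vv=blocks.b_vv,
        w_static=w, mode=mode,
    )


def apply_kernel_columns(operator: BSEOperator, trial, plus=True):
    """(A + B) or (A - B) acting on trial columns (n_pairs, n_cols).

    The plus branch carries the exchange-type antisymmetrized combination;
    cost is linear in the number of trial columns.  NaNs in the contraction
    abort with the offending block named.
    """
    trial = np.asarray(trial, float)
    t = trial[:, None] if trial.ndim == 1 else trial
    out = operator.apply_a_plus_b(t) if plus else operator.apply_a_minus_b(t)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(
            f"non-finite kernel contraction (mode={operator.mode}, plus={plus})")
    return out[:, 0] if trial.ndim == 1 else out


@dataclass
class ExcitonSolution:
    """Converged excitation energies and (X, Y) amplitudes."""

    omegas: np.ndarray            # ascending, Hartree
    x_coeff: np.ndarray           # (n_pairs, n_roots)
    y_coeff: np.ndarray
    residual_norms: np.ndarray
    mode: str
    active_pairs: np.ndarray
    nocc: int
    nvir: int
    converged: bool
    n_iter: int
    subspace_history: list = field(default_factory=list)

    def normalization_defect(self):
        """Max |X^T X - Y^T Y - I| over the converged roots."""
        g = self.x_coeff.T @ self.x_coeff - self.y_coeff.T @ self.y_coeff
        return float(np.abs(g - np.eye(g.shape[0])).max())


def _orthonormalize(V, new, thresh=1e-10):
    for _ in range(2):
        new = new - V @ (V.T @ new)
    keep = []
    for k in range(new.shape[1]):
        col = new[:, k]
        if keep:
            q = np.stack(keep, axis=1)
            col = col - q @ (q.T @ col)
        nrm = np.linalg.norm(col)
        if nrm > thresh:
            keep.append(col / nrm)
    if not keep:
        return np.zeros((V.shape[0], 0))
    return np.stack(keep, axis=1)


def davidson_solve(operator: BSEOperator, n_roots=6, tol=1e-5, max_iter=60,
                   residual_tol=None) -> ExcitonSolution:
    """Lowest eigenpairs of the paired BSE problem, matrix-free.

    Converges when every root changes by less than ``tol`` (Hartree) per
    iteration and residual norms are below ``residual_tol`` (default
    50*tol).  Deterministic: the initial subspace consists of unit vectors
    on the n_roots + 4 lowest-gap pairs.
    """
    n = operator.n_pairs
    if n_roots > n:
        raise ValueError(f"{n_roots} roots requested in a {n}-pair space")
    residual_tol = 50.0 * tol if residual_tol is None else residual_tol
    diag = operator.diag_a()
    nstart = min(n, n_roots + 4)
    order = np.argsort(operator.gaps)
    V = np.zeros((n, nstart))
    V[order[:nstart], np.arange(nstart)] = 1.0
    ApBV = operator.apply_a_plus_b(V)
    AmBV = operator.apply_a_minus_b(V)
    omega_old = None
    history = []
    converged = False
    for it in range(1, max_iter + 1):
        M1 = V.T @ ApBV
        M2 = V.T @ AmBV
        M1 = 0.5 * (M1 + M1.T)
        M2 = 0.5 * (M2 + M2.T)
        try:
            L = np.linalg.cholesky(M2)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "A - B is not positive definite in the subspace; the paired "
                "reduction does not apply") from exc
        K = L.T @ M1 @ L
        K = 0.5 * (K + K.T)
        w2, xi = np.linalg.eigh(K)
        if w2[0] <= 0:
            raise np.linalg.LinAlgError("non-positive BSE eigenvalue; unstable reference")
        nr = min(n_roots, len(w2))
        omega = np.sqrt(w2[:nr])
        xpy_s = L @ xi[:, :nr] / np.sqrt(omega)[None, :]
        xmy_s = (M1 @ xpy_s) / omega[None, :]
        # full-space Ritz vectors and residuals
        XpY = V @ xpy_s
        XmY = V @ xmy_s
        R1 = ApBV @ xpy_s - XmY * omega[None, :]
        R2 = AmBV @ xmy_s - XpY * omega[None, :]
        rnorm = np.sqrt((R1**2).sum(0) + (R2**2).sum(0))
        history.append({"iter": it, "size": V.shape[1], "max_resid": float(rnorm.max())})
        dmax = np.inf if omega_old is None or len(omega_old) != nr else np.abs(omega - omega_old).max()
        omega_old = omega
        if dmax < tol and rnorm.max() < residual_tol:
            converged = True
            break
        # preconditioned expansion
        denom1 = diag[:, None] - omega[None, :]
        denom1 = np.where(np.abs(denom1) < 1e-6, 1e-6 * np.sign(denom1 + 1e-30), denom1)
        cand = np.hstack([R1 / denom1, R2 / denom1])
        mask = np.tile(rnorm > 0.1 * residual_tol, 2)
        if mask.any():
            cand = cand[:, mask]
        new = _orthonormalize(V, cand)
        if new.shape[1] == 0:
            # stagnation: thick restart on the current Ritz space
            new = _orthonormalize(np.zeros((n, 0)), np.hstack([XpY, XmY]))
            V = new
            ApBV = operator.apply_a_plus_b(V)
            AmBV = operator.apply_a_minus_b(V)
            continue
        if V.shape[1] + new.shape[1] > max(20 * n_roots, 3 * nstart):
            V = _orthonormalize(np.zeros((n, 0)), np.hstack([XpY, XmY, new]))
            ApBV = operator.apply_a_plus_b(V)
            AmBV = operator.apply_a_minus_b(V)
        else:
            V = np.hstack([V, new])
            ApBV = np.hstack([ApBV, operator.apply_a_plus_b(new)])
            AmBV = np.hstack([AmBV, operator.apply_a_minus_b(new)])
    X = 0.5 * (XpY + XmY)
    Y = 0.5 * (XpY - XmY)
    return ExcitonSolution(
        omegas=omega, x_coeff=X, y_coeff=Y, residual_norms=rnorm,
        mode=operator.mode, active_pairs=operator.active_pairs,
        nocc=operator.nocc, nvir=operator.nvir,
        converged=converged, n_iter=it, subspace_history=history,
    )


def solve_tda(operator: BSEOperator, n_roots=6, tol=1e-5, max_iter=60,
              residual_tol=None) -> ExcitonSolution:
    """Tamm-Dancoff diagonalization (Hermitian Davidson on A alone)."""
    n = operator.n_pairs
    if n_roots > n:
        raise ValueError(f"{n_roots} roots requested in a {n}-pair space")
    residual_tol = 50.0 * tol if residual_tol is None else residual_tol
    diag = operator.diag_a()
    nstart = min(n, n_roots + 4)
    order = np.argsort(operator.gaps)
    V = np.zeros((n, nstart))
    V[order[:nstart], np.arange(nstart)] = 1.0
    AV = operator.apply_a(V)
    omega_old = None
    history = []
    converged = False
    for it in range(1, max_iter + 1):
        H = V.T @ AV
        H = 0.5 * (H + H.T)
        w, u = np.linalg.eigh(H)
        nr = min(n_roots, len(w))
        omega = w[:nr]
        X = V @ u[:, :nr]
        R = AV @ u[:, :nr] - X * omega[None, :]
        rnorm = np.linalg.norm(R, axis=0)
        history.append({"iter": it, "size": V.shape[1], "max_resid": float(rnorm.max())})
        dmax = np.inf if omega_old is None or len(omega_old) != nr else np.abs(omega - omega_old).max()
        omega_old = omega
        if dmax < tol and rnorm.max() < residual_tol:
            converged = True
            break
        denom = diag[:, None] - omega[None, :]
        denom = np.where(np.abs(denom) < 1e-6, 1e-6, denom)
        new = _orthonormalize(V, R / denom)
        if new.shape[1] == 0:
            converged = rnorm.max() < residual_tol
            break
        if V.shape[1] + new.shape[1] > max(20 * n_roots, 3 * nstart):
            V = _orthonormalize(np.zeros((n, 0)), np.hstack([X, new]))
            AV = operator.apply_a(V)
        else:
            V = np.hstack([V, new])
            AV = np.hstack([AV, operator.apply_a(new)])
    return ExcitonSolution(
        omegas=omega, x_coeff=X, y_coeff=np.zeros_like(X),
        residual_norms=rnorm, mode="TDA", active_pairs=operator.active_pairs,
        nocc=operator.nocc, nvir=operator.nvir,
        converged=converged, n_iter=it, subspace_history=history,
    )
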