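"""GW self-energy and quasiparticle self-consistency.

The correlation self-energy is assembled in imaginary time from the
screened interaction, Sigma_c(i tau) ~ -G(i tau) (W - v)(i tau), split into
its even/odd parts and carried to the imaginary frequency axis by the
grid's certified cosine/sine transforms.  Diagonal quasiparticle solutions
(G0W0 and eigenvalue-only self-consistency, evGW) use Pade analytic
continuation of the diagonal elements to the real axis; quasiparticle
self-consistent GW (qsGW) instead uses the static (omega = 0) limit of the
full self-energy matrix, Hermitized, to build an effective single-particle
Hamiltonian that is re-diagonalized until the density matrix is stationary.

Conventions (closed shell, orthonormalized auxiliary metric, chemical
potential mu at mid-gap, energies in Hartree):

    Sigma_x[p,q]          = - sum_i (pi|iq)
    Sigma_c(i tau > 0)    = + sum_a e^{-(e_a-mu) tau} B_pa (W-v)(i tau) B_qa
    Sigma_c(i tau < 0)    = - sum_i e^{-(mu-e_i)|tau|} B_pi (W-v)(i tau) B_qi
    H_eff = F - v_xc(DFT) - alpha K_ref + Sigma_x + (Sigma_c(0) + Sigma_c(0)^T)/2
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .ri_integrals import transform_to_mo
from .screening import build_screened_interaction, grid_for_gaps
from .system_core import HARTREE_EV

log = logging.getLogger("gwbse")

__all__ = [
    "SelfEnergy", "QPSolution", "PadeModel",
    "exchange_part", "self_energy_tau", "sigma_omega_from_tau",
    "analytic_continuation", "solve_qp_diagonal", "qs_hamiltonian",
    "evgw_loop", "qsgw_loop", "g0w0",
]


# ---------------------------------------------------------------------------
# self-energy construction
# ---------------------------------------------------------------------------

def exchange_part(blocks):
    """Static exchange self-energy in the MO basis: -sum_i (pi|iq)."""
    b_po = blocks.b_full[:, :, : blocks.nocc]
    return -np.einsum("Lpi,Lqi->pq", b_po, b_po, optimize=True)


def self_energy_tau(mo_energy, nocc, wt_tau, blocks, tau_points, mu=None):
    """Correlation self-energy on the positive/negative imaginary-time axis.

    ``wt_tau`` holds (W - v)(i tau_k); returns (sigma_plus, sigma_minus)
    with shape (n_tau, nmo, nmo).  With W = v both vanish identically.
    """
    wt_tau = np.asarray(wt_tau)
    if wt_tau.shape[0] != len(tau_points):
        raise ValueError("grid mismatch between G and W imaginary-time representations")
    e = np.asarray(mo_energy)
    if mu is None:
        mu = 0.5 * (e[nocc - 1] + e[nocc])
    nmo = blocks.b_full.shape[1]
    b_pv = blocks.b_full[:, :, nocc:]
    b_po = blocks.b_full[:, :, :nocc]
    sig_p = np.zeros((len(tau_points), nmo, nmo))
    sig_m = np.zeros_like(sig_p)
    ga = e[nocc:] - mu
    gi = mu - e[:nocc]
    for k, tau in enumerate(tau_points):
        if b_pv.shape[2]:
            bw = np.einsum("LM,Mqa->Lqa", wt_tau[k], b_pv * np.exp(-ga * tau)[None, None, :],
                           optimize=True)
            sp = np.einsum("Lpa,Lqa->pq", b_pv, bw, optimize=True)
            sig_p[k] = 0.5 * (sp + sp.T)
        if b_po.shape[2]:
            bw = np.einsum("LM,Mqi->Lqi", wt_tau[k], b_po * np.exp(-gi * tau)[None, None, :],
                           optimize=True)
            sm = -np.einsum("Lpi,Lqi->pq", b_po, bw, optimize=True)
            sig_m[k] = 0.5 * (sm + sm.T)
    return sig_p, sig_m


def sigma_omega_from_tau(sig_plus, sig_minus, grid):
    """Transform to the imaginary-frequency axis and the static limit.

    Returns (sigma_c_omega complex (n_omega, n, n), sigma_static (n, n)).
    The even part transforms with the cosine matrix, the odd part with the
    sine matrix; the omega = 0 value is the even-function time quadrature.
    """
    even = 0.5 * (sig_plus + sig_minus)
    odd = 0.5 * (sig_plus - sig_minus)
    sig_w = (np.einsum("jk,kpq->jpq", grid.cos_transform, even)
             + 1j * np.einsum("jk,kpq->jpq", grid.sin_transform, odd))
    sig_static = 2.0 * np.einsum("k,kpq->pq", grid.tau_weights, even)
    return sig_w, sig_static


def sigma_ac_from_tau(sig_plus, sig_minus, grid):
    """Self-energy sampled on the dense analytic-continuation mesh."""
    even = 0.5 * (sig_plus + sig_minus)
    odd = 0.5 * (sig_plus - sig_minus)
    return (np.einsum("jk,kpq->jpq", grid.ac_cos_transform, even)
            + 1j * np.einsum("jk,kpq->jpq", grid.ac_sin_transform, odd))


class _ShiftedModel:
    """Continuation model re-centered on absolute orbital energies: the
    imaginary-frequency axis of the transform is anchored at the chemical
    potential mu."""

    def __init__(self, pade, mu):
        self._pade = pade
        self.mu = mu

    def __call__(self, z):
        return self._pade(np.asarray(z, complex) - self.mu)


@dataclass
class SelfEnergy:
    """GW self-energy of one orbital set on one grid."""

    sigma_x: np.ndarray
    sigma_c_tau: tuple            # (sigma_plus, sigma_minus)
    sigma_c_omega: np.ndarray     # complex, (n_omega, nmo, nmo)
    sigma_static: np.ndarray      # Hermitian static limit
    omega_points: np.ndarray
    mu: float = 0.0               # chemical potential (mid-gap)
    ac_omega: np.ndarray = None   # dense continuation mesh
    sigma_c_ac: np.ndarray = None
    ac_models: dict = field(default_factory=dict, repr=False)

    def element_model(self, p, q):
        """Pade model of Sigma_c[p,q](z), z in absolute energy."""
        if (p, q) not in self.ac_models:
            if self.sigma_c_ac is not None:
                pade = analytic_continuation(self.ac_omega, self.sigma_c_ac[:, p, q])
            else:
                pade = analytic_continuation(self.omega_points, self.sigma_c_omega[:, p, q])
            self.ac_models[(p, q)] = _ShiftedModel(pade, self.mu)
        return self.ac_models[(p, q)]

    def diagonal_model(self, p):
        return self.element_model(p, p)


def build_self_energy(mo_energy, blocks, screening, grid, with_ac=True) -> SelfEnergy:
    e = np.asarray(mo_energy)
    mu = 0.5 * (e[blocks.nocc - 1] + e[blocks.nocc])
    sx = exchange_part(blocks)
    sp, sm = self_energy_tau(mo_energy, blocks.nocc, screening.wt_tau, blocks,
                             grid.tau_points, mu=mu)
    sw, sstat = sigma_omega_from_tau(sp, sm, grid)
    sac = sigma_ac_from_tau(sp, sm, grid) if (with_ac and grid.ac_omega is not None) else None
    return SelfEnergy(sigma_x=sx, sigma_c_tau=(sp, sm), sigma_c_omega=sw,
                      sigma_static=0.5 * (sstat + sstat.T),
                      omega_points=grid.omega_points, mu=mu,
                      ac_omega=grid.ac_omega, sigma_c_ac=sac)


# ---------------------------------------------------------------------------
# analytic continuation (Thiele/Pade)
# ---------------------------------------------------------------------------

class PadeModel:
    """Thiele continued-fraction interpolant through (z_j, f_j).

    Built on the positive imaginary axis, evaluated anywhere below the
    model's first real-axis pole.  The divided-difference recursion is
    numerically treacherous in double precision (the standard failure mode
    of Pade continuation for self-energies with dense pole structure), so
    both construction and evaluation run in 60-digit arithmetic via mpmath.
    Degenerate continued-fraction steps trigger automatic node thinning.
    """

    _DPS = 60

    def __init__(self, z, f):
        import mpmath

        z = np.asarray(z, complex)
        f = np.asarray(f, complex)
        with mpmath.workdps(self._DPS):
            zs = [mpmath.mpc(v) for v in z]
            fs = [mpmath.mpc(v) for v in f]
            for attempt in range(3):
                coeff, ok = self._thiele(zs, fs, mpmath)
                if ok:
                    break
                zs, fs = zs[::2], fs[::2]  # thin the nodes and retry
            else:
                raise np.linalg.LinAlgError("degenerate Pade continued fraction")
        self._zs = zs
        self.coeff = coeff
        self.z = np.array([complex(v) for v in zs])

    @staticmethod
    def _thiele(z, f, mpmath):
        n = len(z)
        g = [list(f)]
        coeff = [f[0]]
        for r in range(1, n):
            prev_row = g[-1]
            prev = prev_row[r - 1]
            row = [mpmath.mpc(0)] * n
            degenerate_const = True
            for i in range(r, n):
                diff = prev - prev_row[i]
                den = (z[i] - z[r - 1]) * prev_row[i]
                if den == 0:
                    if abs(diff) < mpmath.mpf("1e-30"):
                        return coeff, True  # constant tail: truncate the model
                    return None, False
                row[i] = diff / den
                if abs(diff) > mpmath.mpf("1e-30"):
                    degenerate_const = False
            if degenerate_const:
                return coeff, True
            g.append(row)
            coeff.append(row[r])
        return coeff, True

    def __call__(self, zeval):
        import mpmath

        scalar = np.isscalar(zeval) or np.asarray(zeval).ndim == 0
        zarr = np.atleast_1d(np.asarray(zeval, complex))
        out = np.empty(zarr.shape, complex)
        a = self.coeff
        n = len(a)
        with mpmath.workdps(self._DPS):
            for idx, zv in enumerate(zarr):
                zz = mpmath.mpc(zv)
                if n == 1:
                    out[idx] = complex(a[0])
                    continue
                acc = mpmath.mpc(1)
                for r in range(n - 1, 0, -1):
                    acc = 1 + a[r] * (zz - self._zs[r - 1]) / acc
                    if acc == 0:
                        acc = mpmath.mpf("1e-30")
                out[idx] = complex(a[0] / acc)
        return out[0] if scalar else out.reshape(np.shape(zeval))


def analytic_continuation(omega_points, values) -> PadeModel:
    """Rational (Thiele/Pade) model of a self-energy element sampled on the
    imaginary axis; at least 8 nodes are required."""
    omega_points = np.asarray(omega_points, float)
    values = np.asarray(values, complex)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite self-energy series")
    if len(omega_points) < 8 and len(omega_points) > 1:
        raise ValueError("analytic continuation needs at least 8 frequency nodes")
    return PadeModel(1j * omega_points, values)


# ---------------------------------------------------------------------------
# quasiparticle equations
# ---------------------------------------------------------------------------

def solve_qp_diagonal(e_ref, sigma_x_pp, vxc_pp, model, tol=1e-9, max_steps=100):
    """Fixed point of  e = e_ref + Re[Sigma_x + Sigma_c(e) - v_xc]  (Newton).

    Returns (e_qp, e_linearized, converged).  On non-convergence the
    linearized (Z-factor) solution is returned with a warning flag.
    """
    h = 1e-5

    def sig(e):
        return float(np.real(model(complex(e))))

    def dsig(e):
        return (sig(e + h) - sig(e - h)) / (2 * h)

    shift0 = sigma_x_pp + sig(e_ref) - vxc_pp
    zden = 1.0 - dsig(e_ref)
    z = 1.0 / zden if 0.2 < zden < 5.0 else 1.0
    e_lin = e_ref + z * shift0

    e = e_ref
    for _ in range(max_steps):
        f = e_ref + sigma_x_pp + sig(e) - vxc_pp - e
        df = dsig(e) - 1.0
        step = -f / df if abs(df) > 1e-8 else f
        if abs(step) > 0.5:
            step = np.sign(step) * 0.5
        e = e + step
        if abs(step) < tol:
            return float(e), float(e_lin), True
    log.warning("QP fixed point not converged; returning linearized solution")
    return float(e_lin), float(e_lin), False


def qs_hamiltonian(fock, vxc, sigma_x, sigma_static, hyb_exchange=None):
    """Static Hermitian qsGW effective Hamiltonian.

    H_eff = F - v_xc - (hybrid exact-exchange part of the reference)
            + Sigma_x + (Sigma_c(0) + Sigma_c(0)^T)/2.

    All inputs must live in one common basis; asymmetry beyond 1e-8 in the
    symmetric inputs is rejected.
    """
    for name, m in (("fock", fock), ("vxc", vxc), ("sigma_x", sigma_x)):
        if np.abs(m - m.T).max() > 1e-8:
            raise ValueError(f"{name} matrix is not symmetric")
    h = fock - vxc + sigma_x + 0.5 * (sigma_static + sigma_static.T)
    if hyb_exchange is not None:
        h = h - hyb_exchange
    return 0.5 * (h + h.T)


# ---------------------------------------------------------------------------
# QP solution container
# ---------------------------------------------------------------------------

@dataclass
class QPSolution:
    """Quasiparticle energies/orbitals from a GW scheme."""

    method_tag: str
    qp_energies: np.ndarray       # active window, Hartree
    eff_hamiltonian: np.ndarray   # in the final orbital basis
    qp_coeff: np.ndarray          # rotation reference MOs -> QP orbitals
    density_matrix: np.ndarray    # AO basis
    history: list
    converged: bool
    mean_field: object
    mo_coeff_ao: np.ndarray
    nocc: int
    n_frozen: int = 0
    warnings: list = field(default_factory=list)
    _blocks: object = field(default=None, repr=False)
    _screening: object = field(default=None, repr=False)
    _grid: object = field(default=None, repr=False)

    @property
    def homo_lumo_gap(self):
        n = self.nocc - self.n_frozen
        return float(self.qp_energies[n] - self.qp_energies[n - 1])

    def to_json(self, path=None):
        doc = {
            "method": self.method_tag,
            "reference": self.mean_field.reference_tag,
            "converged": bool(self.converged),
            "qp_energies_ha": self.qp_energies.tolist(),
            "qp_energies_ev": (self.qp_energies * HARTREE_EV).tolist(),
            "homo_lumo_gap_ev": self.homo_lumo_gap * HARTREE_EV,
            "n_frozen": self.n_frozen,
            "history": self.history,
            "warnings": self.warnings,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(doc, fh, indent=1)
        return doc


def _active(mf):
    nf = mf.n_frozen
    return mf.mo_energy[nf:], mf.nocc - nf


def _vxc_total_mo(mf, mo_coeff=None):
    """Reference non-Hartree potential (DFT xc + scaled exact exchange) in
    the MO basis."""
    c = mf.mo_coeff if mo_coeff is None else mo_coeff
    v = mf.vxc - 0.5 * mf.hyb * mf.k_matrix
    return c.T @ v @ c


# ---------------------------------------------------------------------------
# G0W0 / evGW
# ---------------------------------------------------------------------------

def evgw_loop(mf, n_points=16, conv_ev=3e-3, max_cycles=30, single_shot=False,
              fitted=None, disable_screening=False) -> QPSolution:
    """Eigenvalue-only self-consistent GW (first cycle = G0W0).

    All quasiparticle energies (occupied and virtual) are updated each
    cycle and the screening is rebuilt from them; orbitals stay at the
    mean-field reference.  Convergence: HOMO change below ``conv_ev`` (eV).
    Oscillation of the gap over four cycles engages 0.5 damping.
    """
    from .system_core import get_fitted_arrays

    if fitted is None:
        fitted, *_ = get_fitted_arrays(mf.molecule, mf.basis_spec)
    nf = mf.n_frozen
    blocks = transform_to_mo(fitted, mf.mo_coeff, mf.nocc, n_frozen=nf)
    e_act, no = _active(mf)
    sx = np.diag(exchange_part(blocks))
    vxc = np.diag(_vxc_total_mo(mf))[nf:]
    e_ref = e_act.copy()
    e_cur = e_act.copy()
    history, warnings, gaps = [], [], []
    damping = 0.0
    converged = single_shot
    n_max = 1 if single_shot else max_cycles
    scr = grid = None
    for it in range(1, n_max + 1):
        gap_arr = e_cur[no:][None, :] - e_cur[:no][:, None]
        grid = grid_for_gaps(n_points, gap_arr.min(), gap_arr.max())
        if disable_screening:
            # exchange-only limit: no frequency dependence at all
            e_new = e_ref + sx - vxc
        else:
            scr = build_screened_interaction(e_cur, blocks, grid)
            se = build_self_energy(e_cur, blocks, scr, grid)
            e_new = np.empty_like(e_cur)
            for p in range(len(e_cur)):
                model = se.diagonal_model(p)
                e_new[p], _, ok = solve_qp_diagonal(e_ref[p], sx[p], vxc[p], model)
                if not ok:
                    warnings.append(f"cycle {it}: orbital {p} QP equation linearized")
        if damping > 0:
            e_new = (1 - damping) * e_new + damping * e_cur
        dhomo = abs(e_new[no - 1] - e_cur[no - 1])
        gap = e_new[no] - e_new[no - 1]
        gaps.append(gap)
        history.append({"iter": it, "gap_ev": gap * HARTREE_EV,
                        "homo_change_ev": dhomo * HARTREE_EV})
        log.info("evGW cycle %d: gap %.4f eV, |dHOMO| %.2f meV",
                 it, gap * HARTREE_EV, dhomo * HARTREE_EV * 1e3)
        e_cur = e_new
        if not single_shot and dhomo * HARTREE_EV < conv_ev:
            converged = True
            break
        if len(gaps) >= 4:
            d = np.diff(gaps[-4:])
            if d[0] * d[1] < 0 and d[1] * d[2] < 0 and damping == 0.0:
                damping = 0.5
                warnings.append(f"cycle {it}: oscillating gap, damping engaged")
    if not converged and not single_shot:
        raise RuntimeError(f"evGW did not converge in {max_cycles} cycles")
    tag = "G0W0" if single_shot else "evGW"
    last_scr = scr
    return QPSolution(
        method_tag=tag, qp_energies=e_cur,
        eff_hamiltonian=np.diag(e_cur), qp_coeff=np.eye(len(e_cur)),
        density_matrix=mf.density, history=history, converged=converged,
        mean_field=mf, mo_coeff_ao=mf.mo_coeff, nocc=mf.nocc, n_frozen=nf,
        warnings=warnings, _blocks=blocks, _screening=last_scr, _grid=grid,
    )


def g0w0(mf, n_points=16, fitted=None) -> QPSolution:
    """One-shot perturbative GW on the mean-field reference."""
    return evgw_loop(mf, n_points=n_points, single_shot=True, fitted=fitted)


# ---------------------------------------------------------------------------
# qsGW
# ---------------------------------------------------------------------------

def qsgw_loop(mf, n_points=16, conv=5e-9, mixing=0.3, max_cycles=50,
              scheme="static", fitted=None, disable_screening=False) -> QPSolution:
    """Quasiparticle self-consistent GW.

    Each cycle rebuilds the MO blocks, the screening and the full static
    self-energy from the current orbitals/energies, assembles the Hermitian
    effective Hamiltonian (with the Hartree potential updated to the
    current density), mixes it linearly with the previous one and
    re-diagonalizes.  Convergence: Frobenius norm of the density-matrix
    change below ``conv``.

    ``scheme='kotani'`` evaluates the Hermitized self-energy at the
    quasiparticle energies via per-element analytic continuation instead of
    the omega = 0 static limit (comparison mode).
    ``disable_screening`` replaces W by the bare interaction; the loop then
    converges to the Hartree-Fock solution from any reference.
    """
    from .system_core import get_fitted_arrays

    if fitted is None:
        fitted, *_ = get_fitted_arrays(mf.molecule, mf.basis_spec)
    b_ao = fitted.b_tensor if hasattr(fitted, "b_tensor") else np.asarray(fitted)
    nf = mf.n_frozen
    S = mf.overlap
    nocc = mf.nocc
    c_cur = mf.mo_coeff.copy()
    e_cur = mf.mo_energy.copy()
    d_ref = mf.density
    d_cur = d_ref.copy()
    j_ref = np.einsum("Lpq,L->pq", b_ao, np.einsum("Lrs,rs->L", b_ao, d_ref))
    # the reference Fock operator carries -hyb/2 K; Sigma_x replaces it fully
    hyb_x_ref = -0.5 * mf.hyb * mf.k_matrix
    h_prev = None
    history, warnings = [], []
    converged = False
    blocks = scr = grid = None
    for it in range(1, max_cycles + 1):
        blocks = transform_to_mo(b_ao, c_cur, nocc, n_frozen=nf)
        e_act = e_cur[nf:]
        no = nocc - nf
        gap_arr = e_act[no:][None, :] - e_act[:no][:, None]
        grid = grid_for_gaps(n_points, gap_arr.min(), gap_arr.max())
        # exchange from the current density (all occupied, incl. frozen core)
        k_cur = np.einsum("Lpr,rs,Lsq->pq", b_ao, d_cur, b_ao, optimize=True)
        sigma_x_ao = -0.5 * k_cur
        if disable_screening:
            sig_stat_ao = np.zeros_like(S)
        else:
            scr = build_screened_interaction(e_act, blocks, grid)
            se = build_self_energy(e_act, blocks, scr, grid,
                                   with_ac=(scheme == "kotani"))
            if scheme == "kotani":
                sig_mo = _kotani_sigma(se, e_act, no)
            else:
                sig_mo = se.sigma_static
            c_act = c_cur[:, nf:]
            sig_stat_ao = S @ c_act @ sig_mo @ c_act.T @ S
        j_cur = np.einsum("Lpq,L->pq", b_ao, np.einsum("Lrs,rs->L", b_ao, d_cur))
        h_eff = qs_hamiltonian(mf.fock + (j_cur - j_ref), mf.vxc,
                               sigma_x_ao, sig_stat_ao, hyb_exchange=hyb_x_ref)
        if h_prev is not None:
            h_eff = (1.0 - mixing) * h_eff + mixing * h_prev
        h_prev = h_eff
        e_new, c_new = scipy.linalg.eigh(h_eff, S)
        # root homing: sign-fix and check aufbau continuity
        ov = np.abs(c_cur.T @ S @ c_new)
        if not np.allclose(np.argmax(ov[:, :nocc], axis=0) < nocc, True):
            warnings.append(f"cycle {it}: level crossing through the Fermi level; re-sorted")
        c_cur, e_cur = c_new, e_new
        d_new = 2.0 * c_cur[:, :nocc] @ c_cur[:, :nocc].T
        dnorm = np.linalg.norm(d_new - d_cur)
        d_cur = d_new
        gap = e_cur[nocc] - e_cur[nocc - 1]
        history.append({"iter": it, "gap_ev": gap * HARTREE_EV, "d_norm": float(dnorm)})
        log.info("qsGW cycle %d: gap %.4f eV, |dD| %.3e", it, gap * HARTREE_EV, dnorm)
        if dnorm < conv:
            converged = True
            break
    if not converged:
        raise RuntimeError(f"qsGW did not converge in {max_cycles} cycles "
                           f"(last |dD| = {dnorm:.2e})")
    # rebuild screening on the converged orbitals for downstream (BSE) use
    blocks = transform_to_mo(b_ao, c_cur, nocc, n_frozen=nf)
    e_act = e_cur[nf:]
    if not disable_screening:
        scr = build_screened_interaction(e_act, blocks, grid)
    u = mf.mo_coeff.T @ S @ c_cur
    return QPSolution(
        method_tag="qsGW", qp_energies=e_act,
        eff_hamiltonian=np.diag(e_cur), qp_coeff=u,
        density_matrix=d_cur, history=history, converged=converged,
        mean_field=mf, mo_coeff_ao=c_cur, nocc=nocc, n_frozen=nf,
        warnings=warnings, _blocks=blocks, _screening=scr, _grid=grid,
    )


def _kotani_sigma(se, e_act, no):
    """Hermitized Sigma_c evaluated at the quasiparticle energies
    (per-element analytic continuation); comparison mode for the static
    omega = 0 scheme."""
    n = len(e_act)
    out = np.zeros((n, n))
    for p in range(n):
        for q in range(p, n):
            model = se.element_model(p, q)
            val = 0.5 * (np.real(model(complex(e_act[p]))) + np.real(model(complex(e_act[q]))))
            out[p, q] = out[q, p] = val
    return out
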