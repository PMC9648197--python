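"""Imaginary-time/frequency grids, RPA polarizability and screened Coulomb W.

The low-scaling route works in imaginary time: the polarizability is a sum
of decaying exponentials exp(-Delta*tau) over particle-hole gaps Delta, so
quadrature nodes and transformation matrices only need to be exact on that
kernel family over the system's gap range.  Nodes and weights are obtained
by least-squares optimization (minimax-style) of

    sum_k w_k exp(-Delta tau_k) ~ 1/Delta                (time quadrature)
    sum_j v_j 2 Delta^2/(Delta^2+omega_j^2)^2 ~ pi/(2 Delta)  (frequency quadrature)

and the cosine/sine transforms between the two axes are per-row
least-squares fits on the same kernel family (the scheme standard in
space-time GW implementations).  Every matrix comes with a certified
maximum relative error measured on a denser validation grid.

In the orthonormalized auxiliary metric the bare interaction is the
identity, so the Dyson equation for the screened interaction reduces to
W(i omega) = (1 - P(i omega))^{-1}.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ImaginaryGrid", "ScreenedInteraction", "build_grids",
    "polarizability_tau", "screened_interaction_omega",
    "static_screened_interaction", "build_screened_interaction",
]

log = logging.getLogger("gwbse")


@dataclass
class ImaginaryGrid:
    """Imaginary-time/frequency quadrature with certified transforms."""

    tau_points: np.ndarray
    tau_weights: np.ndarray
    omega_points: np.ndarray
    omega_weights: np.ndarray
    cos_transform: np.ndarray      # (n_omega, n_tau): f(tau_k) -> f(i omega_j)
    sin_transform: np.ndarray      # (n_omega, n_tau), odd-part counterpart
    inv_cos_transform: np.ndarray  # (n_tau, n_omega): f(i omega_j) -> f(tau_k)
    energy_range: tuple
    # denser frequency mesh used only to sample the self-energy for analytic
    # continuation (interpolatory Pade is unstable on sparse node sets)
    ac_omega: np.ndarray = None
    ac_cos_transform: np.ndarray = None
    ac_sin_transform: np.ndarray = None
    errors: dict = field(default_factory=dict)

    @property
    def n_points(self):
        return len(self.tau_points)

    def report(self):
        """JSON-serializable grid report (nodes, weights, certified errors)."""
        return {
            "n_points": self.n_points,
            "energy_range_ha": list(self.energy_range),
            "tau_points": self.tau_points.tolist(),
            "tau_weights": self.tau_weights.tolist(),
            "omega_points": self.omega_points.tolist(),
            "omega_weights": self.omega_weights.tolist(),
            "certified_errors": {k: float(v) for k, v in self.errors.items()},
        }


def _kernel_exp(delta, tau):
    return np.exp(-np.outer(delta, tau))


def _kernel_lor(delta, omega):
    return 2.0 * delta[:, None] / (delta[:, None] ** 2 + omega[None, :] ** 2)


def _opt_quadrature(n, d_fit, d_val, kern, dkern_dlognode, target, init):
    """Near-minimax positive-weight quadrature for one kernel family.

    Joint least-squares over log-nodes/log-weights with an analytic
    Jacobian, polished by Lawson-style iterative reweighting so the
    relative error approaches equioscillation.  Deterministic.
    """
    t_fit, t_val = target(d_fit), target(d_val)
    x = np.concatenate([np.log(init), np.log(init * 0.5)])
    lw = np.ones(len(d_fit))
    best = (np.inf, x.copy())
    stall = 0
    for _ in range(30):
        def resid(x):
            nodes, w = np.exp(x[:n]), np.exp(x[n:])
            return (kern(d_fit, nodes) @ w / t_fit - 1.0) * lw

        def jac(x):
            nodes, w = np.exp(x[:n]), np.exp(x[n:])
            K = kern(d_fit, nodes)
            Jn = dkern_dlognode(d_fit, nodes) * w[None, :] / t_fit[:, None]
            Jw = K * w[None, :] / t_fit[:, None]
            return np.hstack([Jn, Jw]) * lw[:, None]

        sol = least_squares(resid, x, jac=jac, xtol=3e-16, ftol=3e-16,
                            gtol=3e-16, max_nfev=400)
        x = sol.x
        nodes, w = np.exp(x[:n]), np.exp(x[n:])
        r = np.abs(kern(d_fit, nodes) @ w / t_fit - 1.0)
        if r.max() < best[0] * 0.995:
            best, stall = (r.max(), x.copy()), 0
        else:
            stall += 1
        if stall >= 6:
            break
        lw = lw * np.sqrt(np.maximum(r / r.max(), 1e-5))
        lw /= lw.max()
    x = best[1]
    order = np.argsort(x[:n])
    nodes, w = np.exp(x[:n][order]), np.exp(x[n:][order])
    err = np.abs(kern(d_val, nodes) @ w / t_val - 1.0).max()
    return nodes, w, float(err)


def _fit_rows_lawson(design, targets, floors=None, iters=40):
    """Row-wise near-minimax linear fits: C @ design.T ~ targets.

    ``floors`` (per row) switches the error measure from relative to
    absolute once the target drops below the floor.
    """
    nrow = targets.shape[0]
    C = np.empty((nrow, design.shape[1]))
    errs = np.empty(nrow)
    for r in range(nrow):
        t = targets[r]
        scale = np.abs(t) if floors is None else np.abs(t) + floors[r]
        lw = np.ones(len(t))
        best = (np.inf, None)
        for _ in range(iters):
            wgt = lw / scale
            sol, *_ = np.linalg.lstsq(design * wgt[:, None], t * wgt, rcond=None)
            res = np.abs((design @ sol - t) / scale)
            if res.max() < best[0]:
                best = (res.max(), sol)
            lw = lw * np.sqrt(np.maximum(res / res.max(), 1e-5))
            lw /= lw.max()
        errs[r], C[r] = best[0], best[1]
    return C, errs


@lru_cache(maxsize=32)
def _build_grids_cached(n_points, d_min, d_max):
    if n_points < 4:
        raise ValueError("need at least 4 grid points")
    if not (0 < d_min < d_max):
        raise ValueError(f"degenerate energy range [{d_min}, {d_max}]")
    ratio = d_max / d_min
    n_fit = max(240, 16 * n_points)
    d_fit = np.geomspace(d_min, d_max, n_fit)
    d_val = np.geomspace(d_min, d_max, 4 * n_fit)

    # --- time nodes/weights: sum_k w_k exp(-Delta tau_k) ~ 1/Delta --------
    tau, tau_w, tau_err = _opt_quadrature(
        n_points, d_fit, d_val,
        kern=_kernel_exp,
        dkern_dlognode=lambda d, nd: -_kernel_exp(d, nd) * np.outer(d, nd),
        target=lambda d: 1.0 / d,
        init=np.geomspace(0.1 / d_max, 20.0 / d_min, n_points),
    )

    # --- frequency nodes/weights: Lorentzian-squared quadrature -----------
    def kern_l2(d, om):
        return 2.0 * d[:, None] ** 2 / (d[:, None] ** 2 + om[None, :] ** 2) ** 2

    def dkern_l2(d, om):
        return -8.0 * d[:, None] ** 2 * om[None, :] ** 2 / (d[:, None] ** 2 + om[None, :] ** 2) ** 3

    omega, omega_w, omega_err = _opt_quadrature(
        n_points, d_fit, d_val,
        kern=kern_l2, dkern_dlognode=dkern_l2,
        target=lambda d: np.pi / (2.0 * d),
        init=np.geomspace(0.4 * d_min, 4.0 * d_max, n_points),
    )

    # --- transforms (row-wise near-minimax fits on the kernel family) -----
    exp_fit, exp_val = _kernel_exp(d_fit, tau), _kernel_exp(d_val, tau)
    lor_fit, lor_val = _kernel_lor(d_fit, omega), _kernel_lor(d_val, omega)

    # cosine: exp(-Delta tau_k) -> 2 Delta/(Delta^2+omega_j^2)
    ct, _ = _fit_rows_lawson(exp_fit, lor_fit.T)
    ct_err = np.abs((ct @ exp_val.T - lor_val.T) / lor_val.T).max()

    # sine: exp(-Delta tau_k) -> 2 omega_j/(Delta^2+omega_j^2)
    tgt_s = 2.0 * omega[:, None] / (d_fit[None, :] ** 2 + omega[:, None] ** 2)
    st, _ = _fit_rows_lawson(exp_fit, tgt_s)
    tgt_s_val = 2.0 * omega[:, None] / (d_val[None, :] ** 2 + omega[:, None] ** 2)
    st_err = np.abs((st @ exp_val.T - tgt_s_val) / tgt_s_val).max()

    # inverse cosine: 2 Delta/(Delta^2+omega_j^2) -> exp(-Delta tau_k);
    # absolute floor: exponential tails cannot be matched in relative terms
    tgt_i = exp_fit.T
    ict, _ = _fit_rows_lawson(lor_fit, tgt_i, floors=np.ones(n_points))
    ict_err = np.abs(ict @ lor_val.T - exp_val.T).max()

    # dense analytic-continuation mesh with its own cosine/sine rows
    ac_omega = np.geomspace(0.1 * d_min, 1.5 * d_max, max(32, 2 * n_points))
    lor_ac = _kernel_lor(d_fit, ac_omega)
    ct_ac, _ = _fit_rows_lawson(exp_fit, lor_ac.T)
    lor_ac_val = _kernel_lor(d_val, ac_omega)
    ct_ac_err = np.abs((ct_ac @ exp_val.T - lor_ac_val.T) / lor_ac_val.T).max()
    tgt_ac_s = 2.0 * ac_omega[:, None] / (d_fit[None, :] ** 2 + ac_omega[:, None] ** 2)
    st_ac, _ = _fit_rows_lawson(exp_fit, tgt_ac_s)

    errors = {"tau_quadrature_rel": tau_err, "omega_quadrature_rel": omega_err,
              "cos_transform_rel": ct_err, "sin_transform_rel": st_err,
              "inv_cos_transform_abs": ict_err, "ac_cos_transform_rel": ct_ac_err,
              "range_ratio": ratio}
    log.debug("grid n=%d range=[%g, %g] certified: %s", n_points, d_min, d_max, errors)
    return ImaginaryGrid(
        tau_points=tau, tau_weights=tau_w, omega_points=omega, omega_weights=omega_w,
        cos_transform=ct, sin_transform=st, inv_cos_transform=ict,
        energy_range=(d_min, d_max), ac_omega=ac_omega,
        ac_cos_transform=ct_ac, ac_sin_transform=st_ac, errors=errors,
    )


def build_grids(n_points: int, energy_range) -> ImaginaryGrid:
    """Optimize an imaginary-time/frequency grid for transition energies in
    ``energy_range = (d_min, d_max)`` (Hartree).  Deterministic."""
    d_min, d_max = (float(x) for x in energy_range)
    return _build_grids_cached(int(n_points), d_min, d_max)


def grid_for_gaps(n_points, gap_min, gap_max, pad_low=0.9, pad_high=2.2):
    """Grid covering the particle-hole gaps plus padding for the shifted
    self-energy decay rates; the range is snapped to a coarse logarithmic
    lattice so that consecutive self-consistency cycles reuse one grid."""
    lo = 10.0 ** (0.25 * np.floor(np.log10(pad_low * gap_min) / 0.25))
    hi = 10.0 ** (0.25 * np.ceil(np.log10(pad_high * gap_max) / 0.25))
    return build_grids(n_points, (lo, hi))


# ---------------------------------------------------------------------------
# polarizability and screened interaction
# ---------------------------------------------------------------------------

@dataclass
class ScreenedInteraction:
    """P and W sampled on the imaginary grids (retained auxiliary basis)."""

    p_tau: np.ndarray      # (n_tau, L, L)
    p_omega: np.ndarray    # (n_omega, L, L)
    w_omega: np.ndarray    # (n_omega, L, L)
    w_static: np.ndarray   # (L, L), omega = 0
    wt_tau: np.ndarray     # (n_tau, L, L): W(i tau) - v back-transform
    v_matrix: np.ndarray   # identity in the orthonormalized metric
    grid: ImaginaryGrid


def _ph_gaps(mo_energy, nocc):
    eo = np.asarray(mo_energy[:nocc])
    ev = np.asarray(mo_energy[nocc:])
    gaps = ev[None, :] - eo[:, None]
    if gaps.min() <= 0:
        raise ValueError(
            f"non-positive HOMO-LUMO gap ({gaps.min():.3e} Ha): metallic or "
            "inverted occupations are unsupported")
    return gaps


def polarizability_tau(mo_energy, blocks, grid) -> np.ndarray:
    """RPA polarizability P(i tau) in the retained auxiliary basis.

    Closed-shell, spin-summed convention:
    P_LM(i tau) = -2 sum_ia B[L,i,a] B[M,i,a] exp(-(e_a - e_i)|tau|).
    Symmetric and negative semidefinite at every node.
    """
    gaps = _ph_gaps(mo_energy, blocks.nocc).ravel()
    if gaps.max() > grid.energy_range[1] * (1 + 1e-9) or \
       gaps.min() < grid.energy_range[0] * (1 - 1e-9):
        raise ValueError("grid energy range does not cover the particle-hole gaps")
    bov = blocks.b_ov.reshape(blocks.b_ov.shape[0], -1)  # (L, n_ph)
    p = np.empty((grid.n_points, bov.shape[0], bov.shape[0]))
    for k, tau in enumerate(grid.tau_points):
        weighted = bov * np.exp(-gaps * tau)[None, :]
        pk = -2.0 * weighted @ bov.T
        p[k] = 0.5 * (pk + pk.T)
    return p


def polarizability_omega_sos(mo_energy, blocks, omega):
    """Direct sum-over-states P(i omega) (oracle route, no grids):
    P_LM = -4 sum_ia B B Delta/(Delta^2 + omega^2)."""
    gaps = _ph_gaps(mo_energy, blocks.nocc).ravel()
    bov = blocks.b_ov.reshape(blocks.b_ov.shape[0], -1)
    fac = -4.0 * gaps / (gaps**2 + float(omega) ** 2)
    p = (bov * fac[None, :]) @ bov.T
    return 0.5 * (p + p.T)


def screened_interaction_omega(p_omega, v=None):
    """Dyson equation W = (1 - vP)^{-1} v per frequency; v defaults to the
    identity of the orthonormalized metric."""
    p_omega = np.asarray(p_omega)
    single = p_omega.ndim == 2
    ps = p_omega[None] if single else p_omega
    L = ps.shape[-1]
    v = np.eye(L) if v is None else v
    out = np.empty_like(ps)
    for k, p in enumerate(ps):
        a = np.eye(L) - v @ p
        smin = np.linalg.svd(a, compute_uv=False)[-1]
        if smin < 1e-12:
            raise np.linalg.LinAlgError(
                f"(1 - vP) is singular (smallest singular value {smin:.3e})")
        w = np.linalg.solve(a, v)
        out[k] = 0.5 * (w + w.T)
    return out[0] if single else out


def static_screened_interaction(p_tau, grid, v=None):
    """W(omega = 0) from the imaginary-time polarizability.

    The even-function quadrature P(0) = 2 sum_k w_k P(i tau_k) feeds the
    Dyson equation; the quadrature's certified relative error is attached
    to the grid report.
    """
    p0 = 2.0 * np.einsum("k,kLM->LM", grid.tau_weights, np.asarray(p_tau))
    return screened_interaction_omega(p0, v=v)


def build_screened_interaction(mo_energy, blocks, grid) -> ScreenedInteraction:
    """Full screening stack: P(i tau) -> P(i omega) -> W(i omega), the
    static W(0), and the back-transformed W(i tau) - v needed by the
    self-energy contraction."""
    p_tau = polarizability_tau(mo_energy, blocks, grid)
    p_omega = np.einsum("jk,kLM->jLM", grid.cos_transform, p_tau)
    w_omega = screened_interaction_omega(p_omega)
    L = p_tau.shape[-1]
    v = np.eye(L)
    wt_omega = w_omega - v[None]
    wt_tau = np.einsum("kj,jLM->kLM", grid.inv_cos_transform, wt_omega)
    w_static = static_screened_interaction(p_tau, grid)
    return ScreenedInteraction(p_tau=p_tau, p_omega=p_omega, w_omega=w_omega,
                               w_static=w_static, wt_tau=wt_tau, v_matrix=v, grid=grid)
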