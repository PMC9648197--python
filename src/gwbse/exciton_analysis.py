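"""Exciton characterization: oscillator strengths, dominant particle-hole
transitions, and fragment-resolved local/charge-transfer decomposition.

Also hosts the fixture registry (small closed-shell molecules with
hardcoded geometries and recommended settings) and the dense oracle
routines used to cross-check the matrix-free solvers: full RPA
diagonalization, sum-over-states self-energies and polarizabilities, and
dense TD-HF/BSE constructions along an independent code path.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .system_core import HARTREE_EV, FragmentPartition, Molecule

log = logging.getLogger("gwbse")

__all__ = [
    "ExcitonReport", "oscillator_strengths", "dominant_transitions",
    "fragment_character", "make_fixture", "FIXTURES",
    "rpa_spectral", "sos_sigma_c", "sos_g0w0_energy",
    "dense_tdhf", "dense_bse_from_qp", "sos_polarizability", "sos_w_static",
]

ORACLE_PAIR_GUARD = 800


# ---------------------------------------------------------------------------
# per-state analysis
# ---------------------------------------------------------------------------

def _check_normalized(excitons, tol=1e-6):
    if excitons.normalization_defect() > tol:
        raise ValueError("eigenvectors are not X^T X - Y^T Y normalized")


def oscillator_strengths(excitons, dipole_ao, mo_coeff, n_frozen=0):
    """Length-gauge oscillator strengths per state.

    f_S = (2/3) Omega_S sum_u |sqrt(2) sum_ia (X+Y)_ia,S d^u_ia|^2 for the
    closed-shell singlet normalization.  ``dipole_ao`` has shape (3, n, n).
    """
    _check_normalized(excitons)
    c = mo_coeff[:, n_frozen:]
    no, nv = excitons.nocc, excitons.nvir
    d_mo = np.einsum("pi,upq,qj->uij", c, np.asarray(dipole_ao), c, optimize=True)
    d_ov = d_mo[:, :no, no:][:, excitons.active_pairs[:, 0], excitons.active_pairs[:, 1]]
    xpy = excitons.x_coeff + excitons.y_coeff
    t = np.sqrt(2.0) * (d_ov @ xpy)      # (3, n_roots)
    f = (2.0 / 3.0) * excitons.omegas * (t**2).sum(axis=0)
    return np.maximum(f, 0.0)


def dominant_transitions(excitons, threshold=0.05, n_frozen=0):
    """Per state: list of (occupied index, virtual index, weight), sorted by
    descending weight, truncated at ``threshold``.

    Weights are X^2 under the X^T X - Y^T Y = 1 normalization; orbital
    indices are absolute (frozen-core offset applied), virtuals counted
    from the full occupied block.
    """
    out = []
    no = excitons.nocc
    for s in range(len(excitons.omegas)):
        w = excitons.x_coeff[:, s] ** 2
        order = np.argsort(w)[::-1]
        rows = []
        for k in order:
            if w[k] < threshold:
                break
            i, a = excitons.active_pairs[k]
            rows.append((int(i + n_frozen), int(a + no + n_frozen), float(w[k])))
        out.append(rows)
    return out


def _lowdin_fragment_populations(mo_coeff, overlap, atom_of_bf, partition):
    """q[p, F]: Loewdin population of orbital p on fragment F."""
    sval, svec = np.linalg.eigh(overlap)
    s_half = (svec * np.sqrt(np.maximum(sval, 0))) @ svec.T
    ortho = s_half @ mo_coeff           # (nbf, nmo)
    labels = partition.fragment_labels
    q = np.zeros((mo_coeff.shape[1], len(labels)))
    for fidx, lab in enumerate(labels):
        atoms = set(partition.indices(lab))
        mask = np.array([a in atoms for a in atom_of_bf])
        q[:, fidx] = (ortho[mask] ** 2).sum(axis=0)
    return q / q.sum(axis=1, keepdims=True)


def fragment_character(excitons, partition: FragmentPartition, mo_coeff, overlap,
                       atom_of_bf, n_frozen=0, ct_threshold=0.5, amplitude="x2"):
    """Fragment-pair weights and local/CT classification per state.

    The hole (occupied) and electron (virtual) orbitals of every
    particle-hole amplitude are assigned Loewdin populations on the
    fragments; the amplitude weight is distributed over (hole-fragment,
    electron-fragment) cells.  Cell weights sum to one per state; diagonal
    cells are local, off-diagonal cells are charge transfer (CT).

    ``amplitude='x2'`` uses X^2 - Y^2 weights (normalized exactly);
    ``'xpy2'`` uses |X+Y|^2 renormalized (alternative definition).
    Returns (weights (n_states, n_frag, n_frag), classifications).
    """
    _check_normalized(excitons)
    c = mo_coeff[:, n_frozen:]
    q = _lowdin_fragment_populations(c, overlap, atom_of_bf, partition)
    no = excitons.nocc
    qh = q[:no]
    qe = q[no:]
    ii, aa = excitons.active_pairs[:, 0], excitons.active_pairs[:, 1]
    if amplitude == "x2":
        w = excitons.x_coeff**2 - excitons.y_coeff**2
    elif amplitude == "xpy2":
        w = (excitons.x_coeff + excitons.y_coeff) ** 2
        w = w / w.sum(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown amplitude definition {amplitude!r}")
    nstates = w.shape[1]
    nf = partition.n_fragments
    cells = np.einsum("ks,kF,kG->sFG", w, qh[ii], qe[aa], optimize=True)
    classifications = []
    for s in range(nstates):
        offdiag = cells[s].sum() - np.trace(cells[s])
        if offdiag > ct_threshold:
            kind = "CT"
        elif offdiag < 1.0 - ct_threshold:
            kind = "local"
        else:
            kind = "mixed"
        hf, ef = np.unravel_index(np.argmax(cells[s]), cells[s].shape)
        dom = (partition.fragment_labels[hf], partition.fragment_labels[ef])
        classifications.append({"kind": kind, "dominant_pair": dom,
                                "ct_weight": float(offdiag)})
    return cells, classifications


@dataclass
class ExcitonReport:
    """Analysis-layer view of a converged exciton solution.

    Energies are copied bitwise from the solver; the report never modifies
    them.
    """

    omegas_ha: np.ndarray
    omegas_ev: np.ndarray
    f: np.ndarray
    transitions: list
    fragment_weights: np.ndarray = None
    classifications: list = None
    fragment_labels: tuple = None
    mode: str = "BSE"

    @classmethod
    def build(cls, excitons, dipole_ao, mo_coeff, overlap=None, atom_of_bf=None,
              partition=None, n_frozen=0, weight_threshold=0.05, ct_threshold=0.5):
        f = oscillator_strengths(excitons, dipole_ao, mo_coeff, n_frozen=n_frozen)
        trans = dominant_transitions(excitons, threshold=weight_threshold,
                                     n_frozen=n_frozen)
        cells = cls_list = labels = None
        if partition is not None:
            cells, cls_list = fragment_character(
                excitons, partition, mo_coeff, overlap, atom_of_bf,
                n_frozen=n_frozen, ct_threshold=ct_threshold)
            labels = partition.fragment_labels
        return cls(omegas_ha=excitons.omegas.copy(),
                   omegas_ev=excitons.omegas * HARTREE_EV,
                   f=f, transitions=trans, fragment_weights=cells,
                   classifications=cls_list, fragment_labels=labels,
                   mode=excitons.mode)

    def to_json(self, path=None):
        doc = {"mode": self.mode, "states": []}
        for s in range(len(self.omegas_ha)):
            st = {"omega_ha": float(self.omegas_ha[s]),
                  "omega_ev": float(self.omegas_ev[s]),
                  "f": float(self.f[s]),
                  "transitions": [{"occ": i, "virt": a, "weight": w}
                                  for (i, a, w) in self.transitions[s]]}
            if self.classifications is not None:
                st["character"] = self.classifications[s]["kind"]
                st["dominant_fragments"] = list(self.classifications[s]["dominant_pair"])
                st["ct_weight"] = self.classifications[s]["ct_weight"]
            doc["states"].append(st)
        if path is not None:
            with open(path, "w") as fh:
                json.dump(doc, fh, indent=1)
        return doc

    def spectrum_csv(self, path):
        """Flat (omega_eV, f) table for plotting."""
        import pandas as pd

        df = pd.DataFrame({"omega_ev": self.omegas_ev, "f": self.f})
        df.to_csv(path, index=False)
        return df

    def character_table(self):
        """Text table in the style of excited-state characterization tables."""
        lines = [f"{'state':>6s} {'E (eV)':>8s} {'f':>7s}  character"]
        for s in range(len(self.omegas_ha)):
            desc = ", ".join(f"{i}->{a} ({w:.2f})" for i, a, w in self.transitions[s][:3])
            tag = ""
            if self.classifications is not None:
                c = self.classifications[s]
                if c["kind"] == "CT":
                    tag = f"[CT {c['dominant_pair'][0]}+ -> {c['dominant_pair'][1]}-] "
                elif c["kind"] == "local":
                    tag = f"[{c['dominant_pair'][0]}*] "
                else:
                    tag = "[mixed] "
            lines.append(f"{s + 1:>6d} {self.omegas_ev[s]:8.3f} {self.f[s]:7.4f}  {tag}{desc}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# fixture registry
# ---------------------------------------------------------------------------

FIXTURES = {
    "h2": {
        "symbols": ("H", "H"),
        "coords": [[0.0, 0.0, 0.0], [0.0, 0.0, 0.74]],
        "settings": {"basis": "min", "aux_basis": "etb", "n_points": 16},
    },
    "h2_dimer_far": {
        "symbols": ("H", "H", "H", "H"),
        "coords": [[0.0, 0.0, 0.0], [0.0, 0.0, 0.74],
                   [100.0, 0.0, 0.0], [100.0, 0.0, 0.74]],
        "settings": {"basis": "min", "aux_basis": "etb", "n_points": 16},
    },
    "h2o": {
        "symbols": ("O", "H", "H"),
        "coords": [[0.0, 0.0, 0.1173], [0.0, 0.7572, -0.4692], [0.0, -0.7572, -0.4692]],
        "settings": {"basis": "sv", "aux_basis": "etb", "n_points": 20},
    },
    "n2": {
        "symbols": ("N", "N"),
        "coords": [[0.0, 0.0, 0.0], [0.0, 0.0, 1.0977]],
        "settings": {"basis": "sv", "aux_basis": "etb", "n_points": 20},
    },
    "ethylene": {
        "symbols": ("C", "C", "H", "H", "H", "H"),
        "coords": [[0.0, 0.0, 0.6695], [0.0, 0.0, -0.6695],
                   [0.0, 0.9289, 1.2321], [0.0, -0.9289, 1.2321],
                   [0.0, 0.9289, -1.2321], [0.0, -0.9289, -1.2321]],
        "settings": {"basis": "sv", "aux_basis": "etb", "n_points": 20},
    },
    "formaldehyde": {
        "symbols": ("O", "C", "H", "H"),
        "coords": [[0.0, 0.0, 1.205], [0.0, 0.0, 0.0],
                   [0.0, 0.9429, -0.5876], [0.0, -0.9429, -0.5876]],
        "settings": {"basis": "sv", "aux_basis": "etb", "n_points": 20},
    },
}


def make_fixture(name):
    """Deterministic fixture molecule plus recommended settings."""
    key = str(name).lower()
    if key not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    fx = FIXTURES[key]
    mol = Molecule(symbols=fx["symbols"], coords=np.asarray(fx["coords"]))
    return mol, dict(fx["settings"])


# ---------------------------------------------------------------------------
# dense oracles (independent cross-check routes)
# ---------------------------------------------------------------------------

def _guard(n_pairs):
    if n_pairs > ORACLE_PAIR_GUARD:
        raise ValueError(
            f"dense oracle refused for {n_pairs} > {ORACLE_PAIR_GUARD} particle-hole pairs")


def rpa_spectral(mo_energy, blocks):
    """Full (direct) RPA diagonalization: excitation energies Omega_s and
    the spectral amplitudes R[L, s] of the screened interaction,
    W(i omega) - v = -sum_s R R^T 2 Omega_s / (Omega_s^2 + omega^2)."""
    e = np.asarray(mo_energy)
    no = blocks.nocc
    gaps = (e[no:][None, :] - e[:no][:, None]).ravel()
    _guard(len(gaps))
    bov = blocks.b_ov.reshape(blocks.b_ov.shape[0], -1)
    v_ph = bov.T @ bov
    c = np.sqrt(gaps)[:, None] * (np.diag(gaps) + 4.0 * v_ph) * np.sqrt(gaps)[None, :]
    w2, z = np.linalg.eigh(0.5 * (c + c.T))
    omegas = np.sqrt(w2)
    xpy = np.sqrt(gaps)[:, None] * z / np.sqrt(omegas)[None, :]
    r = np.sqrt(2.0) * (bov @ xpy)
    return omegas, r


def sos_polarizability(mo_energy, blocks, omega):
    """Direct sum-over-states P(i omega)."""
    from .screening import polarizability_omega_sos

    return polarizability_omega_sos(mo_energy, blocks, omega)


def sos_w_static(mo_energy, blocks):
    """W(0) by full RPA spectral summation (independent of grids)."""
    omegas, r = rpa_spectral(mo_energy, blocks)
    L = blocks.b_ov.shape[0]
    return np.eye(L) - (r * (2.0 / omegas)[None, :]) @ r.T


def sos_sigma_c(mo_energy, blocks, z, p=None, q=None):
    """Exact correlation self-energy from the RPA spectral representation:

    Sigma_c[p,q](z) = sum_{i,s} M_pi M_qi / (z - e_i + Omega_s)
                    + sum_{a,s} M_pa M_qa / (z - e_a - Omega_s)

    with M[p, m, s] = sum_L B[L, p, m] R[L, s].  ``z`` in absolute energy.
    """
    e = np.asarray(mo_energy)
    no = blocks.nocc
    omegas, r = rpa_spectral(mo_energy, blocks)
    m = np.einsum("Lpm,Ls->pms", blocks.b_full, r, optimize=True)
    if p is not None:
        mq = m[q if q is not None else p]
        mp = m[p]
        occ = (mp[:no] * mq[:no] / (z - e[:no, None] + omegas[None, :])).sum()
        vir = (mp[no:] * mq[no:] / (z - e[no:, None] - omegas[None, :])).sum()
        return occ + vir
    occ = np.einsum("pis,qis,is->pq", m[:, :no], m[:, :no],
                    1.0 / (z - e[:no, None] + omegas[None, :]), optimize=True)
    vir = np.einsum("pas,qas,as->pq", m[:, no:], m[:, no:],
                    1.0 / (z - e[no:, None] - omegas[None, :]), optimize=True)
    return occ + vir


def sos_g0w0_energy(mf, blocks, orbital, tol=1e-12):
    """Brute-force one-shot GW quasiparticle energy for one orbital:
    Newton solution of the QP equation with the exact spectral self-energy."""
    from .gw_selfenergy import _vxc_total_mo, exchange_part

    nf = mf.n_frozen
    e = mf.mo_energy[nf:]
    sx = np.diag(exchange_part(blocks))
    vxc = np.diag(_vxc_total_mo(mf))[nf:]
    p = orbital

    def sig(z):
        return np.real(sos_sigma_c(e, blocks, z, p=p))

    eqp = e[p]
    for _ in range(200):
        fval = e[p] + sx[p] + sig(eqp) - vxc[p] - eqp
        h = 1e-6
        dfd = (sig(eqp + h) - sig(eqp - h)) / (2 * h) - 1.0
        step = fval / dfd
        eqp -= step
        if abs(step) < tol:
            break
    return float(eqp)


def _dense_paired_solve(a, b, n_roots):
    amb = a - b
    lc = np.linalg.cholesky(amb)
    k = lc.T @ (a + b) @ lc
    w2, xi = np.linalg.eigh(0.5 * (k + k.T))
    om = np.sqrt(w2)
    xpy = lc @ xi / np.sqrt(om)[None, :]
    xmy = (a + b) @ xpy / om[None, :]
    x = 0.5 * (xpy + xmy)
    y = 0.5 * (xpy - xmy)
    return om[:n_roots], x[:, :n_roots], y[:, :n_roots]


def dense_tdhf(mo_energy, blocks, n_roots=6):
    """Independent TD-HF construction: dense singlet A/B from the fitted MO
    integrals (direct four-index assembly, separate from the BSE operator
    code path) and a dense generalized solve."""
    e = np.asarray(mo_energy)
    no = blocks.nocc
    nv = blocks.b_ov.shape[2]
    _guard(no * nv)
    eri_ovov = np.einsum("Lia,Ljb->iajb", blocks.b_ov, blocks.b_ov, optimize=True)
    eri_oovv = np.einsum("Lij,Lab->iajb", blocks.b_oo, blocks.b_vv, optimize=True)
    eri_ovvo = np.einsum("Lib,Lja->iajb", blocks.b_ov, blocks.b_ov, optimize=True)
    gaps = (e[no:][None, :] - e[:no][:, None])
    n = no * nv
    a = np.diag(gaps.ravel()) + (2.0 * eri_ovov - eri_oovv).reshape(n, n)
    b = (2.0 * eri_ovov - eri_ovvo).reshape(n, n)
    return _dense_paired_solve(a, b, n_roots)


def dense_bse_from_qp(qp, n_roots=6, ph_cutoff=None):
    """Dense BSE solve (screened kernel) for oracle comparisons."""
    blocks, scr = qp._blocks, qp._screening
    e = np.asarray(qp.qp_energies)
    no = blocks.nocc
    nv = blocks.b_ov.shape[2]
    _guard(no * nv)
    w0 = scr.w_static
    eri_ovov = np.einsum("Lia,Ljb->iajb", blocks.b_ov, blocks.b_ov, optimize=True)
    w_oovv = np.einsum("Lij,LM,Mab->iajb", blocks.b_oo, w0, blocks.b_vv, optimize=True)
    w_ovvo = np.einsum("Lib,LM,Mja->iajb", blocks.b_ov, w0, blocks.b_ov, optimize=True)
    gaps = (e[no:][None, :] - e[:no][:, None])
    n = no * nv
    a = np.diag(gaps.ravel()) + (2.0 * eri_ovov - w_oovv).reshape(n, n)
    b = (2.0 * eri_ovov - w_ovvo).reshape(n, n)
    if ph_cutoff is not None:
        keep = gaps.ravel() <= ph_cutoff
        a = a[np.ix_(keep, keep)]
        b = b[np.ix_(keep, keep)]
    return _dense_paired_solve(a, b, n_roots)
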