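"""High-level driver: configuration dictionary -> GW-BSE excited states."""
from __future__ import annotations

import logging

import numpy as np

from . import system_core as sc
from .bse_solver import build_bse_operator, davidson_solve, solve_tda
from .exciton_analysis import ExcitonReport, make_fixture
from .gw_selfenergy import QPSolution, evgw_loop, g0w0, qsgw_loop
from .qchem import integrals as _ints
from .ri_integrals import build_fitted_integrals, transform_to_mo

log = logging.getLogger("gwbse")

__all__ = ["run_gwbse", "mean_field_qp"]


def mean_field_qp(mf, fitted) -> QPSolution:
    """Wrap a mean-field solution as a trivial 'quasiparticle' solution so
    the BSE layer can run directly on it (TD-HF limit and diagnostics)."""
    nf = mf.n_frozen
    blocks = transform_to_mo(fitted, mf.mo_coeff, mf.nocc, n_frozen=nf)
    return QPSolution(
        method_tag="MF", qp_energies=mf.mo_energy[nf:],
        eff_hamiltonian=np.diag(mf.mo_energy), qp_coeff=np.eye(len(mf.mo_energy) - nf),
        density_matrix=mf.density, history=[], converged=True,
        mean_field=mf, mo_coeff_ao=mf.mo_coeff, nocc=mf.nocc, n_frozen=nf,
        _blocks=blocks, _screening=None, _grid=None,
    )


def run_gwbse(cfg, molecule=None):
    """Execute the full pipeline described by a configuration dictionary
    (see :data:`gwbse.system_core.CONFIG_DEFAULTS`).

    ``molecule`` overrides [system] xyz (useful for fixtures).  Returns a
    dict with the mean field, QP solution, excitons and the analysis report.
    """
    sys_cfg, gw_cfg, bse_cfg, an_cfg = (cfg[k] for k in
                                        ("system", "gw", "bse", "analysis"))
    if molecule is None:
        from .exciton_analysis import FIXTURES

        name = sys_cfg.get("xyz")
        if name and str(name).lower() in FIXTURES:
            molecule, _ = make_fixture(name)
        else:
            molecule = sc.load_molecule(name, charge=sys_cfg.get("charge", 0))
    basis = sc.BasisSpec(primary_name=sys_cfg["basis"],
                         auxiliary_name=sys_cfg["aux_basis"],
                         frozen_core=sys_cfg.get("frozen_core", False))
    eps_s = gw_cfg["eps_s"]
    mf = sc.run_mean_field(molecule, basis, gw_cfg["reference"], eps_s=eps_s)
    fitted = build_fitted_integrals(molecule, basis, eps_s=eps_s)

    method = gw_cfg["method"]
    n_pts = gw_cfg["n_points"]
    if method == "qsgw":
        qp = qsgw_loop(mf, n_points=n_pts, conv=gw_cfg["qsgw_conv"],
                       mixing=gw_cfg["mixing"], max_cycles=gw_cfg["max_cycles"],
                       fitted=fitted)
    elif method == "evgw":
        qp = evgw_loop(mf, n_points=n_pts, conv_ev=gw_cfg["evgw_conv_ev"],
                       max_cycles=gw_cfg["max_cycles"], fitted=fitted)
    else:
        qp = g0w0(mf, n_points=n_pts, fitted=fitted)

    mode = bse_cfg.get("mode", "BSE").upper()
    if mode == "TDHF":
        base = mean_field_qp(mf, fitted)
        op = build_bse_operator(base, screening=None, ph_cutoff=bse_cfg["ph_cutoff"],
                                mode="TDHF")
    else:
        op = build_bse_operator(qp, ph_cutoff=bse_cfg["ph_cutoff"], mode=mode)
    if mode == "TDA":
        excitons = solve_tda(op, n_roots=bse_cfg["n_roots"], tol=bse_cfg["tol"])
    else:
        excitons = davidson_solve(op, n_roots=bse_cfg["n_roots"], tol=bse_cfg["tol"])

    basis_obj = mf._primary_basis
    dip = _ints.dipole(basis_obj)
    frag_map = sys_cfg.get("fragments") or None
    if frag_map:
        frag_map = {int(k): v for k, v in dict(frag_map).items()}
    partition = sc.define_fragments(molecule, frag_map)
    report = ExcitonReport.build(
        excitons, dip, qp.mo_coeff_ao, overlap=mf.overlap,
        atom_of_bf=basis_obj.atom_of_bf, partition=partition,
        n_frozen=mf.n_frozen,
        weight_threshold=an_cfg["weight_threshold"],
        ct_threshold=an_cfg["ct_threshold"])
    return {"molecule": molecule, "mean_field": mf, "qp": qp,
            "operator": op, "excitons": excitons, "report": report}
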