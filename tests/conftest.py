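"""Shared fixtures: mean-field references, fitted integrals and GW runs on
the small fixture molecules.  Expensive objects are session-scoped so the
starting-point-independence experiments are computed once."""
import numpy as np
import pytest

from gwbse import system_core as sc
from gwbse.exciton_analysis import make_fixture
from gwbse.gw_selfenergy import evgw_loop, g0w0, qsgw_loop
from gwbse.ri_integrals import build_fitted_integrals, transform_to_mo
from gwbse.workflow import mean_field_qp

REFERENCES = ("LDA", "PBE", "PBEH40", "HF")


@pytest.fixture(scope="session")
def water():
    mol, settings = make_fixture("h2o")
    spec = sc.BasisSpec(settings["basis"], settings["aux_basis"])
    return mol, spec, settings


@pytest.fixture(scope="session")
def water_fitted(water):
    mol, spec, _ = water
    return build_fitted_integrals(mol, spec)


@pytest.fixture(scope="session")
def water_mfs(water):
    mol, spec, _ = water
    return {tag: sc.run_mean_field(mol, spec, tag) for tag in REFERENCES}


@pytest.fixture(scope="session")
def water_qsgw(water_mfs, water_fitted):
    """qsGW from all four references (the starting-point experiment)."""
    return {tag: qsgw_loop(mf, n_points=16, fitted=water_fitted)
            for tag, mf in water_mfs.items()}


@pytest.fixture(scope="session")
def water_evgw(water_mfs, water_fitted):
    return {tag: evgw_loop(mf, n_points=16, fitted=water_fitted)
            for tag, mf in water_mfs.items()}


@pytest.fixture(scope="session")
def water_g0w0_pbe(water_mfs, water_fitted):
    """One-shot GW on the PBE reference at the water-recommended grid size."""
    return g0w0(water_mfs["PBE"], n_points=20, fitted=water_fitted)


@pytest.fixture(scope="session")
def h2():
    mol, settings = make_fixture("h2")
    spec = sc.BasisSpec(settings["basis"], settings["aux_basis"])
    mf = sc.run_mean_field(mol, spec, "HF")
    fitted = build_fitted_integrals(mol, spec)
    return {"mol": mol, "spec": spec, "mf": mf, "fitted": fitted,
            "blocks": transform_to_mo(fitted, mf.mo_coeff, mf.nocc),
            "settings": settings}


@pytest.fixture(scope="session")
def h2_dimer_far():
    mol, settings = make_fixture("h2_dimer_far")
    spec = sc.BasisSpec(settings["basis"], settings["aux_basis"])
    mf = sc.run_mean_field(mol, spec, "HF")
    fitted = build_fitted_integrals(mol, spec)
    return {"mol": mol, "spec": spec, "mf": mf, "fitted": fitted,
            "qp0": mean_field_qp(mf, fitted)}


@pytest.fixture(scope="session")
def n2_hf():
    mol, settings = make_fixture("n2")
    spec = sc.BasisSpec(settings["basis"], settings["aux_basis"])
    mf = sc.run_mean_field(mol, spec, "HF")
    fitted = build_fitted_integrals(mol, spec)
    return {"mol": mol, "spec": spec, "mf": mf, "fitted": fitted,
            "qp0": mean_field_qp(mf, fitted)}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
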