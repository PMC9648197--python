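"""Oscillator strengths, transition weights, fragment decomposition,
fixtures and report writers."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwbse import system_core as sc
from gwbse.bse_solver import ExcitonSolution, build_bse_operator, davidson_solve
from gwbse.exciton_analysis import (
    ExcitonReport, dense_bse_from_qp, dominant_transitions, fragment_character,
    make_fixture, oscillator_strengths, rpa_spectral,
)
from gwbse.qchem import integrals as qints
from gwbse.system_core import define_fragments


def _single_pair_solution(x=1.0, y=0.0, omega=0.5):
    return ExcitonSolution(
        omegas=np.array([omega]), x_coeff=np.array([[x]]), y_coeff=np.array([[y]]),
        residual_norms=np.zeros(1), mode="BSE",
        active_pairs=np.array([[0, 0]]), nocc=1, nvir=1, converged=True, n_iter=1)


def test_single_pair_oscillator_strength_formula():
    """One pair, Omega = 0.5 Ha, transition dipole 1 a.u. -> f = 2/3."""
    sol = _single_pair_solution()
    dip = np.zeros((3, 2, 2))
    dip[0] = np.array([[0.0, 1.0], [1.0, 0.0]])
    f = oscillator_strengths(sol, dip, np.eye(2))
    assert np.isclose(f[0], 2.0 / 3.0, atol=1e-14)


def test_unnormalized_eigenvectors_rejected():
    sol = _single_pair_solution(x=2.0)
    with pytest.raises(ValueError):
        oscillator_strengths(sol, np.zeros((3, 2, 2)), np.eye(2))


def test_gerade_states_are_dark(h2_dimer_far):
    """Two identical far-apart molecules: the symmetric/antisymmetric
    exciton combinations split into one dark and one bright state."""
    qp0 = h2_dimer_far["qp0"]
    mf = h2_dimer_far["mf"]
    op = build_bse_operator(qp0, screening=None, mode="TDHF")
    sol = davidson_solve(op, n_roots=4, tol=1e-10)
    dip = qints.dipole(mf._primary_basis)
    f = oscillator_strengths(sol, dip, qp0.mo_coeff_ao)
    assert f.min() < 1e-8          # dark (gerade) combination
    assert f.max() > 0.1           # bright (ungerade) partner


def test_f_from_davidson_equals_dense_oracle(water_qsgw, water_mfs):
    qp = water_qsgw["PBE"]
    op = build_bse_operator(qp)
    sol = davidson_solve(op, n_roots=4, tol=1e-10)
    om, x, y = dense_bse_from_qp(qp, n_roots=4)
    dense_sol = ExcitonSolution(
        omegas=om, x_coeff=x, y_coeff=y, residual_norms=np.zeros(4), mode="BSE",
        active_pairs=op.active_pairs, nocc=op.nocc, nvir=op.nvir,
        converged=True, n_iter=0)
    dip = qints.dipole(water_mfs["PBE"]._primary_basis)
    f1 = oscillator_strengths(sol, dip, qp.mo_coeff_ao)
    f2 = oscillator_strengths(dense_sol, dip, qp.mo_coeff_ao)
    assert np.abs(f1 - f2).max() < 1e-8
    assert np.all(f1 >= 0.0)


def test_dominant_transitions_single_and_degenerate():
    sol = _single_pair_solution()
    rows = dominant_transitions(sol)[0]
    assert rows == [(0, 1, 1.0)]
    two = ExcitonSolution(
        omegas=np.array([0.5]), x_coeff=np.array([[np.sqrt(0.5)], [np.sqrt(0.5)]]),
        y_coeff=np.zeros((2, 1)), residual_norms=np.zeros(1), mode="BSE",
        active_pairs=np.array([[0, 0], [1, 1]]), nocc=2, nvir=2,
        converged=True, n_iter=1)
    rows = dominant_transitions(two)[0]
    assert len(rows) == 2
    assert all(np.isclose(w, 0.5) for *_, w in rows)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 1), st.integers(0, 1))
def test_transition_weights_sign_invariant(s1, s2):
    sgn = (-1.0) ** s1, (-1.0) ** s2
    base = np.array([[0.8], [0.6]])
    sol = ExcitonSolution(
        omegas=np.array([0.5]), x_coeff=base * np.array([sgn]).T,
        y_coeff=np.zeros((2, 1)), residual_norms=np.zeros(1), mode="TDA",
        active_pairs=np.array([[0, 0], [1, 1]]), nocc=2, nvir=2,
        converged=True, n_iter=1)
    rows = dominant_transitions(sol)[0]
    assert np.isclose(rows[0][2], 0.64) and np.isclose(rows[1][2], 0.36)


# ---------------------------------------------------------------------------
# fragment decomposition
# ---------------------------------------------------------------------------

def test_single_fragment_is_all_local(water_qsgw, water_mfs):
    mf = water_mfs["PBE"]
    qp = water_qsgw["PBE"]
    op = build_bse_operator(qp)
    sol = davidson_solve(op, n_roots=3, tol=1e-8)
    part = define_fragments(mf.molecule)
    cells, cls = fragment_character(sol, part, qp.mo_coeff_ao, mf.overlap,
                                    mf._primary_basis.atom_of_bf)
    assert np.allclose(cells[:, 0, 0], 1.0, atol=1e-6)
    assert all(c["kind"] == "local" for c in cls)


def test_far_dimer_block_structure_and_normalization(h2_dimer_far):
    """At 100 A separation every low state is (nearly) pure local or pure
    charge transfer; cell weights always sum to one."""
    qp0 = h2_dimer_far["qp0"]
    mf = h2_dimer_far["mf"]
    op = build_bse_operator(qp0, screening=None, mode="TDHF")
    sol = davidson_solve(op, n_roots=4, tol=1e-10)
    part = define_fragments(mf.molecule, {0: "A", 1: "A", 2: "B", 3: "B"})
    cells, cls = fragment_character(sol, part, qp0.mo_coeff_ao, mf.overlap,
                                    mf._primary_basis.atom_of_bf)
    for s in range(cells.shape[0]):
        assert np.isclose(cells[s].sum(), 1.0, atol=1e-6)
        assert cells[s].max() > 0.49   # concentrated in few cells
    # label reordering leaves the physics invariant
    part2 = define_fragments(mf.molecule, {0: "B", 1: "B", 2: "A", 3: "A"})
    cells2, _ = fragment_character(sol, part2, qp0.mo_coeff_ao, mf.overlap,
                                   mf._primary_basis.atom_of_bf)
    assert np.allclose(np.sort(cells.ravel()), np.sort(cells2.ravel()), atol=1e-10)


# ---------------------------------------------------------------------------
# fixtures, oracles, report
# ---------------------------------------------------------------------------

def test_fixture_registry():
    mol, settings = make_fixture("h2")
    assert mol.natm == 2
    assert np.isclose(np.linalg.norm(mol.coords[1] - mol.coords[0]), 0.74)
    with pytest.raises(KeyError):
        make_fixture("benzene")


def test_h2_single_pair_space(h2):
    from gwbse.workflow import mean_field_qp

    qp0 = mean_field_qp(h2["mf"], h2["fitted"])
    op = build_bse_operator(qp0, screening=None, mode="TDHF")
    assert op.n_pairs == 1


def test_oracle_refuses_large_systems(rng):
    class FakeBlocks:
        nocc = 40
        b_ov = np.zeros((2, 40, 30))
        b_full = np.zeros((2, 70, 70))
    with pytest.raises(ValueError):
        rpa_spectral(np.linspace(-1, 1, 70), FakeBlocks())


def test_report_energies_bitwise_and_writers(tmp_path, water_qsgw, water_mfs):
    mf = water_mfs["PBE"]
    qp = water_qsgw["PBE"]
    sol = davidson_solve(build_bse_operator(qp), n_roots=3, tol=1e-8)
    dip = qints.dipole(mf._primary_basis)
    part = define_fragments(mf.molecule)
    rep = ExcitonReport.build(sol, dip, qp.mo_coeff_ao, overlap=mf.overlap,
                              atom_of_bf=mf._primary_basis.atom_of_bf,
                              partition=part)
    assert np.all(rep.omegas_ha == sol.omegas)  # analysis never changes energies
    doc = rep.to_json(tmp_path / "r.json")
    assert len(doc["states"]) == 3
    df = rep.spectrum_csv(tmp_path / "spec.csv")
    assert (tmp_path / "spec.csv").exists() and len(df) == 3
    table = rep.character_table()
    assert "E (eV)" in table and len(table.splitlines()) == 4
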