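"""BSE operator contractions and the paired Davidson solver."""
import numpy as np
import pytest

from gwbse.bse_solver import (
    BSEOperator, build_bse_operator, apply_kernel_columns, davidson_solve,
    solve_tda,
)
from gwbse.exciton_analysis import dense_bse_from_qp, dense_tdhf


def _random_operator(rng, no=10, nv=20, naux=30):
    e = np.concatenate([np.sort(rng.uniform(-2, -0.5, no)),
                        np.sort(rng.uniform(0.3, 2.0, nv))])
    b = rng.normal(0, 0.08, (naux, no + nv, no + nv))
    b = 0.5 * (b + b.transpose(0, 2, 1))
    w = np.eye(naux) - 0.1 * np.ones((naux, naux)) / naux
    pairs = np.array([(i, a) for i in range(no) for a in range(nv)])
    return BSEOperator(
        qp_energies=e, nocc=no, active_pairs=pairs,
        gaps=(e[no:][None, :] - e[:no][:, None]).ravel(),
        b_ov=b[:, :no, no:], b_oo=b[:, :no, :no], b_vv=b[:, no:, no:],
        w_static=w)


@pytest.fixture(scope="module")
def random_op():
    return _random_operator(np.random.default_rng(7))


def test_matrix_free_apply_matches_dense(random_op, rng):
    a, b = random_op.dense_ab()
    t = rng.normal(size=(random_op.n_pairs, 3))
    assert np.abs(random_op.apply_a(t) - a @ t).max() < 1e-12
    assert np.abs(apply_kernel_columns(random_op, t, plus=True) - (a + b) @ t).max() < 1e-12
    assert np.abs(apply_kernel_columns(random_op, t, plus=False) - (a - b) @ t).max() < 1e-12
    assert np.abs(np.diag(a) - random_op.diag_a()).max() < 1e-12


def test_apply_linearity(random_op, rng):
    t1 = rng.normal(size=(random_op.n_pairs, 1))
    t2 = rng.normal(size=(random_op.n_pairs, 1))
    lhs = random_op.apply_a_plus_b(0.3 * t1 + 1.7 * t2)
    rhs = 0.3 * random_op.apply_a_plus_b(t1) + 1.7 * random_op.apply_a_plus_b(t2)
    assert np.abs(lhs - rhs).max() < 1e-12


def test_unit_vector_with_kernel_zeroed_returns_gap(random_op):
    bare = BSEOperator(
        qp_energies=random_op.qp_energies, nocc=random_op.nocc,
        active_pairs=random_op.active_pairs, gaps=random_op.gaps,
        b_ov=random_op.b_ov, b_oo=random_op.b_oo, b_vv=random_op.b_vv,
        w_static=random_op.w_static, include_v=False, include_w=False)
    t = np.zeros((bare.n_pairs, 1))
    t[5, 0] = 1.0
    out = bare.apply_a(t)
    assert np.abs(out - bare.gaps[5] * t).max() == 0.0
    a, b = bare.dense_ab()
    assert np.abs(a - np.diag(bare.gaps)).max() == 0.0 and np.abs(b).max() == 0.0


def test_one_by_one_closed_form():
    """A = 1.0, B = 0.2 -> Omega = sqrt(0.96)."""
    x2, w, gap = 0.15, 2.0 / 3.0, 0.7
    op = BSEOperator(
        qp_energies=np.array([-gap / 2, gap / 2]), nocc=1,
        active_pairs=np.array([[0, 0]]), gaps=np.array([gap]),
        b_ov=np.array([[[np.sqrt(x2)]]]), b_oo=np.zeros((1, 1, 1)),
        b_vv=np.zeros((1, 1, 1)), w_static=np.array([[w]]))
    a, b = op.dense_ab()
    assert np.isclose(a[0, 0], 1.0) and np.isclose(b[0, 0], 0.2)
    sol = davidson_solve(op, n_roots=1, tol=1e-12)
    assert abs(sol.omegas[0] - np.sqrt(0.96)) < 1e-12


def test_diagonal_case_b_zero():
    gaps = np.array([0.3, 0.5, 0.9])
    op = BSEOperator(
        qp_energies=np.array([-0.1, 0.2, 0.4, 0.8]), nocc=1,
        active_pairs=np.array([[0, 0], [0, 1], [0, 2]]), gaps=gaps,
        b_ov=np.zeros((1, 1, 3)), b_oo=np.zeros((1, 1, 1)),
        b_vv=np.zeros((1, 3, 3)), w_static=np.eye(1),
        include_v=False, include_w=False)
    sol = davidson_solve(op, n_roots=3, tol=1e-12)
    assert np.abs(sol.omegas - gaps).max() < 1e-12
    assert np.abs(np.abs(sol.x_coeff) - np.eye(3)).max() < 1e-10


def test_davidson_matches_dense_on_random_model(random_op):
    a, b = random_op.dense_ab()
    lc = np.linalg.cholesky(a - b)
    w2 = np.linalg.eigvalsh(lc.T @ (a + b) @ lc)
    ref = np.sqrt(w2[:6])
    sol = davidson_solve(random_op, n_roots=6, tol=1e-11)
    assert sol.converged
    assert np.abs(sol.omegas - ref).max() < 1e-8
    assert sol.normalization_defect() < 1e-8


def test_tda_bounds_and_dense_limit(random_op):
    a, _ = random_op.dense_ab()
    tda = solve_tda(random_op, n_roots=6, tol=1e-11)
    full = davidson_solve(random_op, n_roots=6, tol=1e-11)
    assert np.all(tda.omegas >= full.omegas - 1e-9)
    assert np.abs(tda.omegas - np.linalg.eigvalsh(a)[:6]).max() < 1e-8


def test_tda_equals_full_when_b_vanishes():
    gaps = np.array([0.4, 0.6])
    op = BSEOperator(
        qp_energies=np.array([-0.2, 0.2, 0.4]), nocc=1,
        active_pairs=np.array([[0, 0], [0, 1]]), gaps=gaps,
        b_ov=np.zeros((1, 1, 2)), b_oo=np.zeros((1, 1, 1)),
        b_vv=np.zeros((1, 2, 2)), w_static=np.eye(1),
        include_v=False, include_w=False)
    t1 = solve_tda(op, n_roots=2, tol=1e-12)
    t2 = davidson_solve(op, n_roots=2, tol=1e-12)
    assert np.abs(t1.omegas - t2.omegas).max() < 1e-12


def test_tdhf_mode_matches_independent_construction(n2_hf):
    """Pins the singlet spin factors: matrix-free TD-HF equals a dense,
    independently assembled TD-HF to tight tolerance."""
    qp0 = n2_hf["qp0"]
    op = build_bse_operator(qp0, screening=None, mode="TDHF")
    sol = davidson_solve(op, n_roots=6, tol=1e-10)
    ref, _, _ = dense_tdhf(n2_hf["mf"].mo_energy, qp0._blocks, n_roots=6)
    assert np.abs(sol.omegas - ref).max() < 1e-6


def test_bse_on_water_qsgw_matches_dense(water_qsgw):
    qp = water_qsgw["PBEH40"]
    op = build_bse_operator(qp)
    sol = davidson_solve(op, n_roots=6, tol=1e-10)
    ref, _, _ = dense_bse_from_qp(qp, n_roots=6)
    assert np.abs(sol.omegas - ref).max() < 1e-8


def test_ph_cutoff_semantics(water_qsgw):
    qp = water_qsgw["PBEH40"]
    full = build_bse_operator(qp)
    cut = build_bse_operator(qp, ph_cutoff=1.5)
    assert cut.n_pairs < full.n_pairs
    assert np.all(cut.gaps <= 1.5)
    with pytest.raises(ValueError):
        build_bse_operator(qp, ph_cutoff=1e-6)


def test_ph_cutoff_mild_effect_on_lowest_root(water_qsgw):
    """A cutoff well above the lowest transitions barely moves the lowest
    excitation (the screened analogue of basis truncation)."""
    qp = water_qsgw["PBEH40"]
    full = davidson_solve(build_bse_operator(qp), n_roots=1, tol=1e-9)
    cut = davidson_solve(build_bse_operator(qp, ph_cutoff=3.0), n_roots=1, tol=1e-9)
    assert abs(full.omegas[0] - cut.omegas[0]) * 27.2114 < 0.02


def test_dense_guard(rng):
    op = _random_operator(rng, no=2, nv=3, naux=4)
    op.active_pairs = np.zeros((801, 2), dtype=int)  # simulate a big space
    with pytest.raises(ValueError):
        op.dense_ab()


def test_too_many_roots_rejected(random_op):
    with pytest.raises(ValueError):
        davidson_solve(random_op, n_roots=random_op.n_pairs + 1)


def test_nan_contraction_aborts(random_op):
    t = np.full((random_op.n_pairs, 1), np.nan)
    with pytest.raises(FloatingPointError):
        apply_kernel_columns(random_op, t)
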