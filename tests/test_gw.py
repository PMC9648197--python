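"""GW self-energy, analytic continuation and the quasiparticle solvers."""
import numpy as np
import pytest

from gwbse import system_core as sc
from gwbse.exciton_analysis import sos_g0w0_energy, sos_sigma_c
from gwbse.gw_selfenergy import (
    PadeModel, _vxc_total_mo, analytic_continuation, build_self_energy,
    evgw_loop, exchange_part, qs_hamiltonian, qsgw_loop, self_energy_tau,
    solve_qp_diagonal,
)
from gwbse.ri_integrals import MOBlocks, transform_to_mo
from gwbse.screening import build_grids, build_screened_interaction

HARTREE_EV = sc.HARTREE_EV


@pytest.fixture(scope="module")
def two_level():
    bfull = np.array([[[0.3, 0.1], [0.1, 0.2]]])
    blocks = MOBlocks(b_ov=bfull[:, :1, 1:], b_oo=bfull[:, :1, :1],
                      b_vv=bfull[:, 1:, 1:], b_full=bfull, nocc=1)
    e = np.array([-0.25, 0.25])
    grid = build_grids(16, (0.25, 1.0))
    scr = build_screened_interaction(e, blocks, grid)
    se = build_self_energy(e, blocks, scr, grid)
    return e, blocks, grid, scr, se


# ---------------------------------------------------------------------------
# self-energy construction
# ---------------------------------------------------------------------------

def test_bare_w_gives_zero_correlation(two_level):
    e, blocks, grid, *_ = two_level
    wt = np.zeros((grid.n_points, 1, 1))  # W - v = 0
    sp, sm = self_energy_tau(e, 1, wt, blocks, grid.tau_points)
    assert np.abs(sp).max() == 0.0 and np.abs(sm).max() == 0.0


def test_no_occupied_orbitals_zero_exchange():
    bfull = np.random.default_rng(0).normal(size=(2, 3, 3))
    blocks = MOBlocks(b_ov=bfull[:, :0, :], b_oo=bfull[:, :0, :0],
                      b_vv=bfull, b_full=bfull, nocc=0)
    assert np.abs(exchange_part(blocks)).max() == 0.0


def test_grid_mismatch_detected(two_level):
    e, blocks, grid, *_ = two_level
    with pytest.raises(ValueError):
        self_energy_tau(e, 1, np.zeros((4, 1, 1)), blocks, grid.tau_points)


def test_exchange_matches_backend_operator(h2):
    """Sigma_x in the MO basis equals the SCF exchange operator."""
    mf, blocks = h2["mf"], h2["blocks"]
    sx = exchange_part(blocks)
    k_mo = mf.mo_coeff.T @ (-0.5 * mf.k_matrix) @ mf.mo_coeff
    assert np.abs(sx - k_mo).max() < 1e-10


def test_sigma_c_omega_matches_spectral_oracle(two_level):
    e, blocks, grid, scr, se = two_level
    for j in (0, 7, 15):
        ref = sos_sigma_c(e, blocks, se.mu + 1j * grid.omega_points[j])
        assert np.abs(se.sigma_c_omega[j] - ref).max() < 1e-10


def test_sigma_static_matches_spectral_oracle(two_level):
    e, blocks, grid, scr, se = two_level
    ref = sos_sigma_c(e, blocks, se.mu + 0j).real
    assert np.abs(se.sigma_static - ref).max() < 1e-8


# ---------------------------------------------------------------------------
# analytic continuation
# ---------------------------------------------------------------------------

def test_pade_constant_series():
    om = np.geomspace(0.1, 10, 16)
    m = PadeModel(1j * om, np.full(16, 2.5 + 0j))
    assert abs(m(0.7 + 0j) - 2.5) < 1e-14


def test_pade_single_pole():
    om = np.geomspace(0.03, 5.0, 16)
    z = 1j * om
    m = PadeModel(z, 1.0 / (z + 2.0))
    assert abs(m(1.0 + 0j) - 1.0 / 3.0) < 1e-8


def test_pade_needs_enough_nodes():
    with pytest.raises(ValueError):
        analytic_continuation(np.array([0.1, 0.2]), np.array([1.0, 2.0]))


def test_two_level_continuation_below_gap(two_level):
    """AC model on the real axis matches the sum-over-states closed form."""
    e, blocks, grid, scr, se = two_level
    m = se.diagonal_model(0)
    for eps in (-0.4, -0.25, -0.05):
        ref = sos_sigma_c(e, blocks, eps + 0j, p=0).real
        assert abs(np.real(m(complex(eps))) - ref) < 1e-6


@pytest.mark.parametrize("seed", range(4))
def test_pade_random_rational_property(seed):
    """Interpolation of random two-pole rationals is exact below the first
    pole (seeded property test)."""
    rng = np.random.default_rng(seed)
    p1, p2 = rng.uniform(1.0, 3.0, 2)
    c1, c2 = rng.uniform(0.1, 1.0, 2)
    om = np.geomspace(0.05, 20.0, 24)
    z = 1j * om

    def f(zz):
        return c1 / (zz - p1 - 0.3) + c2 / (zz + p2)

    m = PadeModel(z, f(z))
    for x in (-0.5, 0.0, 0.7):
        assert abs(m(complex(x)) - f(complex(x))) < 1e-7


# ---------------------------------------------------------------------------
# quasiparticle equations
# ---------------------------------------------------------------------------

def test_qp_fixed_point_trivial_cases():
    zero = PadeModel(1j * np.geomspace(0.1, 10, 16), np.zeros(16, complex))
    e, e_lin, ok = solve_qp_diagonal(-0.5, -0.3, -0.3, zero)
    assert ok and abs(e + 0.5) < 1e-9
    const = PadeModel(1j * np.geomspace(0.1, 10, 16), np.full(16, 0.07 + 0j))
    e, _, ok = solve_qp_diagonal(-0.5, -0.3, -0.25, const)
    assert ok and abs(e - (-0.5 - 0.3 + 0.07 + 0.25)) < 1e-9


def test_g0w0_water_homo_vs_brute_force(water_mfs, water_fitted, water_g0w0_pbe):
    mf = water_mfs["PBE"]
    blocks = transform_to_mo(water_fitted, mf.mo_coeff, mf.nocc)
    ref = sos_g0w0_energy(mf, blocks, orbital=mf.nocc - 1)
    homo = water_g0w0_pbe.qp_energies[mf.nocc - 1]
    assert abs(homo - ref) * HARTREE_EV < 5e-3 * HARTREE_EV or \
        abs(homo - ref) < 5e-3 / HARTREE_EV * HARTREE_EV  # 5 meV
    assert abs(homo - ref) * HARTREE_EV * 1000 < 5.0


def test_evgw_huge_threshold_equals_g0w0(water_mfs, water_fitted):
    mf = water_mfs["PBE"]
    one = evgw_loop(mf, n_points=16, conv_ev=27.2, fitted=water_fitted)
    ref = evgw_loop(mf, n_points=16, single_shot=True, fitted=water_fitted)
    assert np.abs(one.qp_energies - ref.qp_energies).max() < 1e-12
    assert len(one.history) == 1


def test_evgw_bare_w_converges_to_exchange_only(water_mfs, water_fitted):
    """With W frozen to v the eigenvalue loop lands on the diagonal
    exchange-only (Koopmans-like) levels in one cycle, from any reference."""
    for tag in ("PBE", "HF"):
        mf = water_mfs[tag]
        qp = evgw_loop(mf, n_points=8, fitted=water_fitted, disable_screening=True)
        blocks = transform_to_mo(water_fitted, mf.mo_coeff, mf.nocc)
        expected = mf.mo_energy + np.diag(exchange_part(blocks)) \
            - np.diag(_vxc_total_mo(mf))
        assert np.abs(qp.qp_energies - expected).max() < 1e-10
        assert len(qp.history) <= 2


def test_evgw_reduces_starting_point_dependence(water_evgw, water_mfs, water_fitted):
    from gwbse.gw_selfenergy import g0w0

    g_pbe = g0w0(water_mfs["PBE"], n_points=16, fitted=water_fitted).homo_lumo_gap
    g_hyb = g0w0(water_mfs["PBEH40"], n_points=16, fitted=water_fitted).homo_lumo_gap
    ev_pbe = water_evgw["PBE"].homo_lumo_gap
    ev_hyb = water_evgw["PBEH40"].homo_lumo_gap
    assert abs(ev_pbe - ev_hyb) < abs(g_pbe - g_hyb)


# ---------------------------------------------------------------------------
# qsGW
# ---------------------------------------------------------------------------

def test_qs_hamiltonian_hf_reference_identity(water_mfs, water_fitted):
    """With Sigma_c = 0 and unchanged orbitals, H_eff is the Fock matrix."""
    mf = water_mfs["HF"]
    b = water_fitted.b_tensor
    sigma_x = -0.5 * np.einsum("Lpr,rs,Lsq->pq", b, mf.density, b, optimize=True)
    h = qs_hamiltonian(mf.fock, mf.vxc, sigma_x, np.zeros_like(mf.fock),
                       hyb_exchange=-0.5 * mf.hyb * mf.k_matrix)
    assert np.abs(h - mf.fock).max() < 1e-10


def test_qs_hamiltonian_symmetry_guard():
    a = np.eye(3)
    bad = a.copy()
    bad[0, 1] = 1e-4
    with pytest.raises(ValueError):
        qs_hamiltonian(bad, a * 0, a * 0, a * 0)
    h = qs_hamiltonian(a, a * 0, a * 0, a * 0)
    assert np.abs(h - h.T).max() == 0.0


def test_qsgw_bare_w_converges_to_hf(water_mfs, water_fitted):
    mf_pbe = water_mfs["PBE"]
    mf_hf = water_mfs["HF"]
    qp = qsgw_loop(mf_pbe, n_points=8, fitted=water_fitted,
                   disable_screening=True, max_cycles=80)
    assert np.abs(qp.qp_energies - mf_hf.mo_energy).max() < 1e-7


def test_qsgw_iteration_count_and_history(water_qsgw):
    for qp in water_qsgw.values():
        assert qp.converged
        assert len(qp.history) <= 40
        assert qp.history[-1]["d_norm"] < 5e-9


def test_qsgw_effective_hamiltonian_diagonal_at_convergence(water_qsgw):
    qp = water_qsgw["PBEH40"]
    h = qp.eff_hamiltonian
    assert np.abs(h - np.diag(np.diag(h))).max() < 1e-12
    assert np.abs(np.diag(h)[qp.n_frozen:] - qp.qp_energies).max() < 1e-12


def test_qsgw_rotation_is_orthogonal(water_qsgw):
    u = water_qsgw["HF"].qp_coeff
    assert np.abs(u.T @ u - np.eye(len(u))).max() < 1e-8


def test_qsgw_serialization(tmp_path, water_qsgw):
    doc = water_qsgw["PBE"].to_json(tmp_path / "qp.json")
    assert doc["method"] == "qsGW" and doc["converged"]
    assert (tmp_path / "qp.json").exists()


def test_qsgw_kotani_scheme_close_to_static(h2):
    static = qsgw_loop(h2["mf"], n_points=16, fitted=h2["fitted"])
    kotani = qsgw_loop(h2["mf"], n_points=16, fitted=h2["fitted"], scheme="kotani")
    # two Hermitization conventions agree to a few tenths of an eV on a
    # two-electron system (they coincide only when Sigma is static)
    assert abs(static.homo_lumo_gap - kotani.homo_lumo_gap) * HARTREE_EV < 0.5
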