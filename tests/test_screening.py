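"""Imaginary-axis grids, RPA polarizability and the screened interaction."""
import numpy as np
import pytest

from gwbse.ri_integrals import MOBlocks, transform_to_mo
from gwbse.screening import (
    build_grids, build_screened_interaction, polarizability_omega_sos,
    polarizability_tau, screened_interaction_omega, static_screened_interaction,
)
from gwbse.exciton_analysis import sos_w_static


@pytest.fixture(scope="module")
def grid_wide():
    return build_grids(16, (0.1, 100.0))


@pytest.fixture(scope="module")
def two_level():
    """One occupied, one virtual level with gap 0.5 Ha and a single
    auxiliary channel (closed-form reference case)."""
    bfull = np.array([[[0.3, 0.1], [0.1, 0.2]]])
    blocks = MOBlocks(b_ov=bfull[:, :1, 1:], b_oo=bfull[:, :1, :1],
                      b_vv=bfull[:, 1:, 1:], b_full=bfull, nocc=1)
    e = np.array([-0.25, 0.25])
    grid = build_grids(16, (0.25, 1.0))
    return e, blocks, grid


def test_time_quadrature_certified_error(grid_wide):
    """16 nodes over [0.1, 100] Ha integrate exp(-Delta tau) to 1/Delta to
    better than 1e-6 relative."""
    assert grid_wide.errors["tau_quadrature_rel"] < 1e-6
    d = np.geomspace(0.1, 100.0, 37)
    quad = np.exp(-np.outer(d, grid_wide.tau_points)) @ grid_wide.tau_weights
    assert np.abs(quad * d - 1.0).max() < 1e-6


def test_grid_scale_invariance():
    g1 = build_grids(12, (0.2, 20.0))
    g2 = build_grids(12, (0.6, 60.0))
    e1 = g1.errors["tau_quadrature_rel"]
    e2 = g2.errors["tau_quadrature_rel"]
    assert e1 == pytest.approx(e2, rel=0.2)
    # nodes scale inversely with energy
    assert np.allclose(g1.tau_points / 3.0, g2.tau_points, rtol=0.05)


def test_small_grid_is_worse(grid_wide):
    g4 = build_grids(4, (0.1, 100.0))
    assert g4.errors["tau_quadrature_rel"] > grid_wide.errors["tau_quadrature_rel"]


def test_grid_invariants(grid_wide):
    g = grid_wide
    assert np.all(g.tau_weights > 0) and np.all(g.omega_weights > 0)
    assert np.all(np.diff(g.tau_points) > 0) and np.all(np.diff(g.omega_points) > 0)


def test_degenerate_range_rejected():
    with pytest.raises(ValueError):
        build_grids(16, (1.0, 1.0))
    with pytest.raises(ValueError):
        build_grids(3, (0.1, 1.0))


# ---------------------------------------------------------------------------
# polarizability
# ---------------------------------------------------------------------------

def test_two_level_p_tau_formula(two_level):
    e, blocks, grid = two_level
    p = polarizability_tau(e, blocks, grid)
    ref = -2.0 * 0.1**2 * np.exp(-0.5 * grid.tau_points)
    assert np.abs(p[:, 0, 0] - ref).max() < 1e-14


def test_no_occupied_orbitals_gives_zero_p():
    bfull = np.zeros((1, 2, 2))
    blocks = MOBlocks(b_ov=np.zeros((1, 0, 2)), b_oo=np.zeros((1, 0, 0)),
                      b_vv=bfull, b_full=bfull, nocc=0)
    grid = build_grids(8, (0.1, 1.0))
    with pytest.raises(ValueError):
        # no particle-hole pairs -> gap undefined
        polarizability_tau(np.array([0.3, 0.5]), blocks, grid)


def test_metallic_gap_rejected(two_level):
    e, blocks, grid = two_level
    with pytest.raises(ValueError):
        polarizability_tau(np.array([0.25, -0.25]), blocks, grid)


def test_p_omega_transform_matches_sum_over_states(water_mfs, water_fitted):
    mf = water_mfs["PBE"]
    blocks = transform_to_mo(water_fitted, mf.mo_coeff, mf.nocc)
    gaps = mf.mo_energy[mf.nocc:][None] - mf.mo_energy[:mf.nocc][:, None]
    grid = build_grids(16, (gaps.min(), gaps.max()))
    scr = build_screened_interaction(mf.mo_energy, blocks, grid)
    tol = 10 * grid.errors["cos_transform_rel"]
    for j in (0, len(grid.omega_points) // 2, -1):
        ref = polarizability_omega_sos(mf.mo_energy, blocks, grid.omega_points[j])
        scale = np.abs(ref).max()
        assert np.abs(scr.p_omega[j] - ref).max() < tol * scale


# ---------------------------------------------------------------------------
# screened interaction
# ---------------------------------------------------------------------------

def test_w_equals_v_without_screening():
    p = np.zeros((3, 4, 4))
    w = screened_interaction_omega(p)
    assert np.abs(w - np.eye(4)[None]).max() == 0.0


def test_two_level_static_w_closed_form(two_level):
    e, blocks, grid = two_level
    p_tau = polarizability_tau(e, blocks, grid)
    w0 = static_screened_interaction(p_tau, grid)
    # P(0) = -4 d^2 Delta / Delta^2 = -0.08, W = 1/(1 - P)
    assert abs(w0[0, 0] - 1.0 / 1.08) < 1e-7


def test_singular_dyson_reports():
    p = np.array([[[1.0]]])  # 1 - P = 0
    with pytest.raises(np.linalg.LinAlgError):
        screened_interaction_omega(p)


def test_screening_matrix_properties(water_mfs, water_fitted):
    """P(i omega) negative semidefinite, v - W(i omega) positive
    semidefinite, everything symmetric."""
    mf = water_mfs["PBE"]
    blocks = transform_to_mo(water_fitted, mf.mo_coeff, mf.nocc)
    gaps = mf.mo_energy[mf.nocc:][None] - mf.mo_energy[:mf.nocc][:, None]
    grid = build_grids(16, (gaps.min(), gaps.max()))
    scr = build_screened_interaction(mf.mo_energy, blocks, grid)
    for mats in (scr.p_tau, scr.p_omega, scr.w_omega):
        assert np.abs(mats - mats.transpose(0, 2, 1)).max() < 1e-12
    for k in range(len(grid.tau_points)):
        assert np.linalg.eigvalsh(scr.p_tau[k]).max() < 1e-10
    for j in range(len(grid.omega_points)):
        assert np.linalg.eigvalsh(scr.p_omega[j]).max() < 1e-10
        assert np.linalg.eigvalsh(scr.v_matrix - scr.w_omega[j]).min() > -1e-10


def test_w_static_route_equivalence(h2, water_mfs, water_fitted):
    """Time-integrated P(0) route vs the spectral (full RPA) route."""
    from gwbse.screening import grid_for_gaps

    for mf, fitted, n in ((h2["mf"], h2["fitted"], 16),
                          (water_mfs["HF"], water_fitted, 20)):
        blocks = transform_to_mo(fitted, mf.mo_coeff, mf.nocc)
        gaps = mf.mo_energy[mf.nocc:][None] - mf.mo_energy[:mf.nocc][:, None]
        grid = grid_for_gaps(n, gaps.min(), gaps.max())
        scr = build_screened_interaction(mf.mo_energy, blocks, grid)
        ref = sos_w_static(mf.mo_energy, blocks)
        assert np.abs(scr.w_static - ref).max() < 1e-6


def test_grid_doubling_stability(h2):
    mf, fitted = h2["mf"], h2["fitted"]
    blocks = transform_to_mo(fitted, mf.mo_coeff, mf.nocc)
    gaps = mf.mo_energy[mf.nocc:][None] - mf.mo_energy[:mf.nocc][:, None]
    from gwbse.screening import grid_for_gaps

    g1 = grid_for_gaps(8, gaps.min(), gaps.max())
    g2 = grid_for_gaps(16, gaps.min(), gaps.max())
    w1 = static_screened_interaction(polarizability_tau(mf.mo_energy, blocks, g1), g1)
    w2 = static_screened_interaction(polarizability_tau(mf.mo_energy, blocks, g2), g2)
    assert np.abs(w1 - w2).max() <= max(g1.errors["tau_quadrature_rel"], 1e-12) * 10
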