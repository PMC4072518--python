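"""Tests for nondimensionalization, the method-of-lines discretization and
the stiff integration of the coupled system."""

from __future__ import annotations

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st

import callusim as cs
from callusim.solver import (
    _cyl_laplacian,
    default_initial_state,
    mechanics_from_theta,
    pack_state,
    unpack_state,
)

rate = st.floats(min_value=1e-4, max_value=10.0)


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

def test_baseline_scaling_conventions(dp):
    """Scaled baseline: kinetic parameters 1 except the documented
    exceptions (literature OP proliferation, halved osteoblast rates,
    calculated motilities, mechanotransduction coefficient)."""
    ones = ["V_dc", "K_dc", "V_db", "K_db", "V_c", "K_c", "K_b", "K_op",
            "k_cons", "Q_cart_max", "k_apop_c", "k_apop_b", "k_prod"]
    for name in ones:
        assert getattr(dp, name) == pytest.approx(1.0), name
    assert dp.V_op == pytest.approx(168.0)  # 1.5/day * 112 days
    assert dp.V_b == pytest.approx(0.5)
    assert dp.k_min0 == pytest.approx(0.5)
    assert dp.k_mech == pytest.approx(1.2)
    # motility one order of magnitude below the BMP diffusivity
    assert dp.mu_c / dp.D_bmp == pytest.approx(0.1)
    assert dp.mu_b / dp.D_bmp == pytest.approx(0.1)
    assert dp.rho_op_crit == pytest.approx(1.0)


@settings(derandomize=True, max_examples=50)
@given(
    v_op=rate, v_dc=rate, v_c=rate, k_cons=rate, q=rate,
    d=st.floats(min_value=1e-3, max_value=1.0),
    r_in=st.floats(min_value=0.2, max_value=1.0),
    gap=st.floats(min_value=0.1, max_value=1.0),
)
def test_nondimensionalize_round_trip(v_op, v_dc, v_c, k_cons, q, d, r_in, gap):
    p = cs.ModelParameters(
        V_op=v_op, V_dc=v_dc, V_c=v_c, k_cons=k_cons, Q_cart_max=q,
        D_bmp=d, R_in=r_in, R_out=r_in + gap,
    )
    p2 = cs.redimensionalize(cs.nondimensionalize(p))
    for f in ("V_op", "V_dc", "V_c", "k_cons", "Q_cart_max", "D_bmp",
              "R_in", "R_out", "K_op", "k_min0", "rho_op_crit", "k_prod"):
        assert getattr(p2, f) == pytest.approx(getattr(p, f), rel=1e-12), f


# ---------------------------------------------------------------------------
# spatial discretization
# ---------------------------------------------------------------------------

def _manufactured_laplacian_error(n: int) -> float:
    """Discrete vs symbolic cylindrical Laplacian of a smooth field, with the
    exact gradient supplied at both boundaries."""
    r_sym = sympy.Symbol("r", positive=True)
    u_sym = sympy.exp(-r_sym) * sympy.sin(3 * r_sym)
    lap_sym = sympy.diff(r_sym * sympy.diff(u_sym, r_sym), r_sym) / r_sym
    du_sym = sympy.diff(u_sym, r_sym)
    u_f = sympy.lambdify(r_sym, u_sym, "numpy")
    du_f = sympy.lambdify(r_sym, du_sym, "numpy")
    lap_f = sympy.lambdify(r_sym, lap_sym, "numpy")

    grid = cs.RadialGrid(1.8, 2.8, n)
    r = grid.r
    disc = _cyl_laplacian(u_f(r), r, grid.h, float(du_f(r[0])), float(du_f(r[-1])))
    err = np.abs(disc - lap_f(r))
    return float(err[1:-1].max()), float(max(err[0], err[-1]))


def test_discrete_laplacian_second_order():
    """Interior stencil converges at order ~2; the ghost-node closures at the
    boundary nodes converge at least linearly in their pointwise truncation
    (the solution itself remains second-order, see the self-convergence
    test)."""
    int_coarse, bnd_coarse = _manufactured_laplacian_error(51)
    int_fine, bnd_fine = _manufactured_laplacian_error(101)
    order = np.log2(int_coarse / int_fine)
    assert 1.8 < order < 2.3
    assert int_fine < 1e-3
    assert bnd_fine < 0.6 * bnd_coarse


def test_sealed_sourceless_annulus_is_static(dp):
    """Uniform BMP, no cells, no progenitors: every derivative vanishes."""
    grid = dp.grid(31)
    n = grid.n_nodes
    y = pack_state(0.0, np.full(n, 0.7), np.zeros(n), np.zeros(n),
                   np.zeros(n), np.zeros(n))
    ydot = cs.assemble_rhs(y, grid, dp)
    assert np.abs(ydot).max() < 1e-12


def test_empty_defect_production_only_at_periosteum(dp):
    """Empty defect with progenitors present: the only nonzero derivative is
    BMP production at the periosteal boundary node, at the clamped maximum
    strain."""
    grid = dp.grid(31)
    y = default_initial_state(grid, dp)
    ydot = cs.assemble_rhs(y, grid, dp)
    _, db, dc, dbb, dtc, dtb = unpack_state(ydot, grid.n_nodes)
    assert db[-1] > 0.0
    assert np.abs(db[:-1]).max() == 0.0
    for d in (dc, dbb, dtc, dtb):
        assert np.abs(d).max() == 0.0
    assert ydot[0] == 0.0  # no BMP yet, so no OP proliferation
    # the boundary closure carries the production at eps_max
    expected = dp.k_prod * dp.rho_op_init * (1.0 + dp.k_mech * dp.eps_max)
    h, r = grid.h, grid.r
    assert db[-1] == pytest.approx(
        dp.D_bmp * (2.0 * expected / dp.D_bmp / h) + expected / r[-1]
    )


def test_state_vector_length_checked(dp):
    grid = dp.grid(31)
    with pytest.raises(ValueError):
        cs.assemble_rhs(np.zeros(10), grid, dp)
    bad = default_initial_state(grid, dp)
    bad[3] = np.nan
    with pytest.raises(FloatingPointError):
        cs.assemble_rhs(bad, grid, dp)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def test_zero_stimulus_stays_empty(dp):
    """With BMP production forced off the system has no source: the defect
    never fills."""
    res = cs.integrate(None, (0.0, 1.0), dp, dp.grid(41),
                       cs.SolverOptions(production_override=0.0, n_out=9))
    assert np.abs(res.b).max() == 0.0
    assert np.abs(res.theta_c).max() == 0.0
    assert np.abs(res.theta_b).max() == 0.0
    assert res.rho_op == pytest.approx(dp.rho_op_init * np.ones(9))


def test_baseline_matches_described_course(baseline_result, baseline_summary):
    """OP cells saturate at the critical density, BMP rises then gradually
    decays, cartilage precedes bone, the defect fills to the void fraction."""
    res = baseline_result
    assert res.diagnostics["success"]
    assert res.rho_op[-1] == pytest.approx(1.0, rel=1e-3)
    b_max = res.b.max(axis=1)
    i_peak = int(np.argmax(b_max))
    assert 0 < i_peak < res.n_times - 1
    assert b_max[-1] < 0.1 * b_max[i_peak]
    mean_tc = res.theta_c.mean(axis=1)
    mean_tb = res.theta_b.mean(axis=1)
    assert np.argmax(mean_tc >= 0.1) < np.argmax(mean_tb >= 0.1)
    assert baseline_summary.infilling_pct == pytest.approx(90.0, abs=1.0)


def test_theta_invariants_along_trajectory(baseline_result):
    res = baseline_result
    theta_m = res.theta_c + res.theta_b
    assert theta_m.max() <= 1.0 + 1e-6
    assert (np.diff(res.theta_b, axis=0) >= -1e-8).all()


def test_mechanics_monotone_along_trajectory(baseline_result):
    res = baseline_result
    assert (np.diff(res.E_avg) >= -1e-9).all()
    assert (np.diff(res.eps) <= 1e-9).all()


def test_bmp_small_spatial_gradient(baseline_result):
    """Rapid diffusion keeps the BMP profile nearly flat (max/min ratio below
    1.5) after the initial transient, for as long as BMP remains at
    appreciable levels (terminal exhaustion compares near-zeros)."""
    res = baseline_result
    peak = res.b.max()
    for i in range(res.n_times // 5, res.n_times):
        b = res.b[i]
        if b.max() < 0.05 * peak:
            continue
        assert b.max() / b.min() < 1.5


def test_boundary_fluxes(baseline_result):
    """Inner boundary sealed; outer diffusive flux equals the production term
    within discretization error (checked by grid refinement)."""
    def flux_errors(n):
        dp = cs.nondimensionalize(cs.ModelParameters())
        res = cs.integrate(None, (0.0, 0.4), dp, dp.grid(n),
                           cs.SolverOptions(rtol=1e-8, atol=1e-11, n_out=5))
        b = res.b[-1]
        h = res.grid.h
        # second-order one-sided differences
        flux_in = res.dp.D_bmp * (-3 * b[0] + 4 * b[1] - b[2]) / (2 * h)
        flux_out = res.dp.D_bmp * (3 * b[-1] - 4 * b[-2] + b[-3]) / (2 * h)
        production = res.dp.k_prod * res.rho_op[-1] * res.production_factor[-1]
        return abs(flux_in), abs(flux_out - production)

    in_coarse, out_coarse = flux_errors(51)
    in_fine, out_fine = flux_errors(101)
    assert out_fine < out_coarse / 2.0  # at least ~O(h) decay of the residual
    assert in_fine < in_coarse / 2.0
    assert out_fine < 5e-3
    assert in_fine < 5e-3


def test_grid_self_convergence(convergence_solutions):
    """Successive grid halvings converge at order ~2; halving the spacing
    changes the final bone profile by well under 1%."""
    f26 = convergence_solutions[26].theta_b[-1]
    f51 = convergence_solutions[51].theta_b[-1][::2]
    f101 = convergence_solutions[101].theta_b[-1][::4]
    e1 = np.abs(f26 - f101).max()
    e2 = np.abs(f51 - f101).max()
    assert 1.5 < np.log2(e1 / e2) < 3.0
    rel_change = e2 / np.abs(f101).max()
    assert rel_change < 0.01


# ---------------------------------------------------------------------------
# physical-plausibility diagnostics
# ---------------------------------------------------------------------------

def test_baseline_physically_clean(baseline_result):
    report = cs.check_physical(baseline_result)
    assert not report["any_negative"]
    assert report["max_theta_m"] <= 1.0 + 1e-6


def test_over_consumption_raises_negativity_flag():
    """Ten-fold consumption under the per-cell-constant uptake idealization
    drives BMP genuinely negative — the reportable implausibility."""
    p = cs.ModelParameters(uptake="metabolic")
    p = p.with_(k_cons=10.0 * p.k_cons)
    res = cs.integrate(None, (0.0, 1.0), cs.nondimensionalize(p))
    report = cs.check_physical(res)
    assert report["negativity_flags"]["b"]
    assert report["minima"]["b"] < -0.01


def test_clip_mode_keeps_fields_nonnegative():
    p = cs.ModelParameters(uptake="metabolic")
    p = p.with_(k_cons=10.0 * p.k_cons)
    res = cs.integrate(None, (0.0, 1.0), cs.nondimensionalize(p),
                       opts=cs.SolverOptions(clip=True))
    report = cs.check_physical(res)
    assert not report["any_negative"]
    assert min(report["minima"].values()) >= 0.0


def test_staged_feedback_close_to_continuous(baseline_summary):
    """Ten piecewise-constant mechanics updates reproduce the continuous
    feedback to within a few percentage points of outcome."""
    dp = cs.nondimensionalize(cs.ModelParameters())
    res = cs.integrate(None, (0.0, 1.0), dp,
                       opts=cs.SolverOptions(staged_updates=10))
    s = cs.summarize_outcome(res)
    assert s.infilling_pct == pytest.approx(baseline_summary.infilling_pct, abs=2.0)
    assert s.bone_share_pct == pytest.approx(baseline_summary.bone_share_pct, abs=5.0)
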