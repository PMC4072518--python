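"""Nondimensionalization, method-of-lines discretization and stiff integration.

The governing equations are solved on the annular cross-section between the
intramedullary nail (r = R_in, impermeable) and the periosteum (r = R_out,
where all sources live).  Space is discretized with second-order central
differences in cylindrical coordinates using ghost-node boundary closures, and
the resulting stiff ODE system is integrated with a backward-differentiation
(BDF) scheme.

Scaling conventions
-------------------
* time: t = 1 corresponds to the 16-week healing horizon (112 days);
* length: the annulus gap L = R_out - R_in;
* BMP concentration: B0 = k_prod * rho_op_crit * T / L, the concentration a
  saturated periosteum produces per gap width in one healing time;
* cell density: N0 = 1 / (Q_cart_max * T), the density at which matrix
  production fills the section in one healing time;
* OP surface density: the critical density rho_op_crit.

With the default dimensional parameters every scaled kinetic parameter is 1
except the OP proliferation maximum (literature value 1.5/day), the cell
motilities (one order of magnitude below the scaled BMP diffusivity) and the
mechanotransduction coefficient.  The ratio beta = rho_op_crit / (N0 * L)
appears in the scaled differentiated-cell boundary flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from . import kinetics as kin
from . import mechanics as mech
from .kinetics import ModelParameters, TissueState
from .mechanics import StrainFit

__all__ = [
    "RadialGrid",
    "DimensionlessParameters",
    "SolverOptions",
    "SimulationResult",
    "nondimensionalize",
    "redimensionalize",
    "assemble_rhs",
    "integrate",
    "check_physical",
]

# reference scales shared by nondimensionalize/redimensionalize; fixed by the
# published baseline magnitudes so that parameter sweeps remain visible after
# scaling (the scales never follow the instance being scaled)
T_REF_DAYS = kin.T_HEAL_DAYS
Q_REF = kin.Q_CART_DEFAULT
K_PROD_REF = kin.K_PROD_DEFAULT
RHO_OP_CRIT_REF = 1.0e4


@dataclass(frozen=True)
class RadialGrid:
    """Uniform 1-D grid on the annulus [R_in, R_out] (any consistent units)."""

    R_in: float
    R_out: float
    n_nodes: int = 101

    def __post_init__(self) -> None:
        if not self.R_in < self.R_out:
            raise ValueError("R_in must be smaller than R_out")
        if self.n_nodes < 3:
            raise ValueError("need at least three nodes")

    @property
    def r(self) -> np.ndarray:
        return np.linspace(self.R_in, self.R_out, self.n_nodes)

    @property
    def h(self) -> float:
        return (self.R_out - self.R_in) / (self.n_nodes - 1)


@dataclass
class DimensionlessParameters:
    """The scaled parameter set actually integrated.

    Kinetic fields share names with :class:`ModelParameters` so the rate laws
    in :mod:`callusim.kinetics` apply unchanged.  ``cell_influx`` is the scale
    ratio beta multiplying the differentiated-cell boundary flux; the scale
    attributes allow an exact round-trip to dimensional form.
    """

    V_op: float
    K_op: float
    V_dc: float
    K_dc: float
    V_db: float
    K_db: float
    V_c: float
    K_c: float
    V_b: float
    K_b: float
    D_bmp: float
    mu_c: float
    mu_b: float
    k_prod: float
    k_cons: float
    k_uptake: float
    uptake: str
    k_apop_c: float
    k_apop_b: float
    theta_apop_c: float
    theta_apop_b: float
    Q_cart_max: float
    theta_crit: float
    theta_max: float
    k_min0: float
    k_mech: float
    eps_max: float
    E_cart: float
    E_bone: float
    E_floor: float
    rho_op_crit: float
    rho_op_init: float
    switch_width: float
    cell_influx: float
    r_in: float
    r_out: float
    strain_fit: StrainFit
    # scales (dimensional units per one dimensionless unit)
    time_scale: float
    length_scale: float
    bmp_scale: float
    cell_scale: float
    surf_scale: float

    def with_(self, **overrides) -> "DimensionlessParameters":
        return replace(self, **overrides)

    def grid(self, n_nodes: int = 101) -> RadialGrid:
        return RadialGrid(self.r_in, self.r_out, n_nodes)


def nondimensionalize(
    p: ModelParameters, strain_fit: StrainFit | None = None
) -> DimensionlessParameters:
    """Scale a dimensional parameter set for integration."""
    T = T_REF_DAYS
    L = p.R_out - p.R_in
    B0 = K_PROD_REF * RHO_OP_CRIT_REF * T / L
    N0 = 1.0 / (Q_REF * T)
    S0 = RHO_OP_CRIT_REF
    beta = S0 / (N0 * L)
    return DimensionlessParameters(
        V_op=p.V_op * T, K_op=p.K_op / B0,
        V_dc=p.V_dc * T, K_dc=p.K_dc / B0,
        V_db=p.V_db * T, K_db=p.K_db / B0,
        V_c=p.V_c * T, K_c=p.K_c / B0,
        V_b=p.V_b * T, K_b=p.K_b / B0,
        D_bmp=p.D_bmp * T / L**2,
        mu_c=p.mu_c * T / L**2,
        mu_b=p.mu_b * T / L**2,
        k_prod=p.k_prod * S0 * T / (B0 * L),
        k_cons=p.k_cons * N0 * T,
        k_uptake=p.k_uptake / B0,
        uptake=getattr(p, "uptake", "saturable"),
        k_apop_c=p.k_apop_c * T,
        k_apop_b=p.k_apop_b * T,
        theta_apop_c=p.theta_apop_c,
        theta_apop_b=p.theta_apop_b,
        Q_cart_max=p.Q_cart_max * N0 * T,
        theta_crit=p.theta_crit,
        theta_max=p.theta_max,
        k_min0=p.k_min0 * N0 * T,
        k_mech=p.k_mech,
        eps_max=p.eps_max,
        E_cart=p.E_cart,
        E_bone=p.E_bone,
        E_floor=p.E_floor,
        rho_op_crit=p.rho_op_crit / S0,
        rho_op_init=p.rho_op_init / S0,
        switch_width=p.switch_width,
        cell_influx=beta,
        r_in=p.R_in / L,
        r_out=p.R_out / L,
        strain_fit=strain_fit or getattr(p, "strain_fit", None) or StrainFit(),
        time_scale=T,
        length_scale=L,
        bmp_scale=B0,
        cell_scale=N0,
        surf_scale=S0,
    )


def redimensionalize(dp: DimensionlessParameters) -> ModelParameters:
    """Invert :func:`nondimensionalize`; round-trips to round-off."""
    T, L = dp.time_scale, dp.length_scale
    B0, S0 = dp.bmp_scale, dp.surf_scale
    N0 = dp.cell_scale
    R_in = dp.r_in * L
    return ModelParameters(
        R_in=R_in, R_out=R_in + L,
        rho_op_crit=dp.rho_op_crit * S0,
        rho_op_init=dp.rho_op_init * S0,
        V_op=dp.V_op / T, K_op=dp.K_op * B0,
        V_dc=dp.V_dc / T, K_dc=dp.K_dc * B0,
        V_db=dp.V_db / T, K_db=dp.K_db * B0,
        V_c=dp.V_c / T, K_c=dp.K_c * B0,
        V_b=dp.V_b / T, K_b=dp.K_b * B0,
        D_bmp=dp.D_bmp * L**2 / T,
        mu_c=dp.mu_c * L**2 / T,
        mu_b=dp.mu_b * L**2 / T,
        k_prod=dp.k_prod * B0 * L / (S0 * T),
        k_cons=dp.k_cons / (N0 * T),
        k_uptake_frac=dp.k_uptake / dp.K_op,
        k_apop_c=dp.k_apop_c / T,
        k_apop_b=dp.k_apop_b / T,
        theta_apop_c=dp.theta_apop_c,
        theta_apop_b=dp.theta_apop_b,
        Q_cart_max=dp.Q_cart_max / (N0 * T),
        theta_crit=dp.theta_crit,
        theta_max=dp.theta_max,
        k_min0=dp.k_min0 / (N0 * T),
        k_mech=dp.k_mech,
        eps_max=dp.eps_max,
        E_cart=dp.E_cart,
        E_bone=dp.E_bone,
        E_floor=dp.E_floor,
        switch_width=dp.switch_width,
        uptake=dp.uptake,
    )


# ---------------------------------------------------------------------------
# method of lines
# ---------------------------------------------------------------------------

@dataclass
class SolverOptions:
    rtol: float = 1e-6
    atol: float = 1e-9
    method: str = "BDF"
    n_out: int = 41
    t_eval: np.ndarray | None = None
    clip: bool = False
    #: force the BMP production factor to a constant (e.g. 0 for a
    #: zero-stimulus run); None means the mechanical feedback is live
    production_override: float | None = None
    #: emulate the staged finite-element protocol: recompute the production
    #: factor only at N evenly spaced times instead of continuously
    staged_updates: int | None = None
    max_step: float = np.inf


def _cyl_laplacian(u, r, h, inner_flux_over_nu, outer_flux_over_nu):
    """(1/r) d/dr (r du/dr) with ghost-node flux closures at both ends.

    ``*_flux_over_nu`` are the prescribed du/dr values at R_in and R_out.
    """
    lap = np.empty_like(u)
    lap[1:-1] = (u[2:] - 2.0 * u[1:-1] + u[:-2]) / h**2 + (
        u[2:] - u[:-2]
    ) / (2.0 * h * r[1:-1])
    ghost_in = u[1] - 2.0 * h * inner_flux_over_nu
    lap[0] = (u[1] - 2.0 * u[0] + ghost_in) / h**2 + inner_flux_over_nu / r[0]
    ghost_out = u[-2] + 2.0 * h * outer_flux_over_nu
    lap[-1] = (ghost_out - 2.0 * u[-1] + u[-2]) / h**2 + outer_flux_over_nu / r[-1]
    return lap


def unpack_state(y: np.ndarray, n: int):
    """Split the flat solver vector into (rho_op, b, rho_c, rho_b, th_c, th_b)."""
    if y.shape[-1] != 1 + 5 * n:
        raise ValueError("state vector length does not match the grid")
    return (
        y[..., 0],
        y[..., 1 : n + 1],
        y[..., n + 1 : 2 * n + 1],
        y[..., 2 * n + 1 : 3 * n + 1],
        y[..., 3 * n + 1 : 4 * n + 1],
        y[..., 4 * n + 1 : 5 * n + 1],
    )


def pack_state(rho_op, b, rho_c, rho_b, theta_c, theta_b) -> np.ndarray:
    return np.concatenate([[rho_op], b, rho_c, rho_b, theta_c, theta_b])


def mechanics_from_theta(theta_c, theta_b, grid: RadialGrid, dp: DimensionlessParameters):
    """E_avg -> eps -> production factor for one snapshot."""
    e_avg = mech.average_modulus(
        np.clip(theta_c, 0.0, None), np.clip(theta_b, 0.0, None), grid, dp
    )
    eps = mech.strain_from_modulus(e_avg, dp, dp.strain_fit)
    factor = mech.bmp_production_factor(eps, dp)
    return mech.MechanicsState(E_avg=e_avg, eps=eps, production_factor=factor)


def assemble_rhs(
    y: np.ndarray,
    grid: RadialGrid,
    dp: DimensionlessParameters,
    production_override: float | None = None,
    clip: bool = False,
) -> np.ndarray:
    """Time derivative of the flattened state.

    Cylindrical diffusion for BMP and both cell fields; zero-flux closures at
    the nail; Robin closures at the periosteum where BMP production and the
    differentiated-cell influx enter; reaction terms from
    :mod:`callusim.kinetics`; the mechanical feedback recomputed from the
    current matrix fractions unless overridden.
    """
    if np.any(~np.isfinite(y)):
        raise FloatingPointError("non-finite value in state vector")
    n = grid.n_nodes
    rho_op, b, rho_c, rho_b, theta_c, theta_b = unpack_state(np.asarray(y, float), n)
    if clip:
        rho_op = max(rho_op, 0.0)
        b = np.clip(b, 0.0, None)
        rho_c = np.clip(rho_c, 0.0, None)
        rho_b = np.clip(rho_b, 0.0, None)
        theta_c = np.clip(theta_c, 0.0, None)
        theta_b = np.clip(theta_b, 0.0, None)
    r, h = grid.r, grid.h

    # non-negative views for rate laws that require physical arguments
    b_pos = np.clip(b, 0.0, None)
    c_pos = np.clip(rho_c, 0.0, None)
    bb_pos = np.clip(rho_b, 0.0, None)
    tc_pos = np.clip(theta_c, 0.0, None)
    tb_pos = np.clip(theta_b, 0.0, None)
    theta_m = np.clip(tc_pos + tb_pos, 0.0, 1.0)

    # mechanical feedback
    if production_override is not None:
        factor = production_override
    else:
        factor = mechanics_from_theta(theta_c, theta_b, grid, dp).production_factor

    # boundary fluxes (values of nu * du/dr at the periosteum)
    b_surf = float(b_pos[-1])
    rho_op_pos = max(float(rho_op), 0.0)
    bmp_influx = dp.k_prod * rho_op_pos * factor
    rate_c, rate_b = kin.differentiation_rates(b_surf, dp)
    c_influx = dp.cell_influx * rate_c * rho_op_pos
    bb_influx = dp.cell_influx * rate_b * rho_op_pos

    # transport
    db = dp.D_bmp * _cyl_laplacian(b, r, h, 0.0, bmp_influx / dp.D_bmp)
    dc = dp.mu_c * _cyl_laplacian(rho_c, r, h, 0.0, c_influx / dp.mu_c)
    dbb = dp.mu_b * _cyl_laplacian(rho_b, r, h, 0.0, bb_influx / dp.mu_b)

    # reactions
    db -= kin.bmp_reaction(b_pos, c_pos, bb_pos, dp)
    dc += kin.chondro_reaction(c_pos, b_pos, theta_m, dp)
    dbb += kin.osteo_reaction(bb_pos, b_pos, np.clip(tb_pos, 0.0, 1.0), dp)
    dtc, dtb = kin.ecm_rhs(tc_pos, tb_pos, c_pos, bb_pos, dp)

    d_op = kin.op_rhs(rho_op_pos, b_surf, dp)
    return pack_state(d_op, db, dc, dbb, dtc, dtb)


def _jacobian_sparsity(n: int) -> lil_matrix:
    """Structural sparsity of the RHS Jacobian for the BDF solver."""
    m = 1 + 5 * n
    pat = lil_matrix((m, m), dtype=np.int8)
    sl_b = slice(1, n + 1)
    sl_c = slice(n + 1, 2 * n + 1)
    sl_bb = slice(2 * n + 1, 3 * n + 1)
    sl_tc = slice(3 * n + 1, 4 * n + 1)
    sl_tb = slice(4 * n + 1, 5 * n + 1)

    pat[0, 0] = 1
    pat[0, n] = 1  # OP sees BMP at the periosteal node

    def tridiag(sl):
        for i in range(n):
            row = sl.start + i
            pat[row, row] = 1
            if i > 0:
                pat[row, row - 1] = 1
            if i < n - 1:
                pat[row, row + 1] = 1
        # ghost closures reach one node further in
        pat[sl.start, sl.start + 1] = 1
        pat[sl.start + n - 1, sl.start + n - 2] = 1

    for sl in (sl_b, sl_c, sl_bb):
        tridiag(sl)
    idx = np.arange(n)
    # local reaction couplings
    pat[sl_b.start + idx, sl_c.start + idx] = 1
    pat[sl_b.start + idx, sl_bb.start + idx] = 1
    pat[sl_c.start + idx, sl_b.start + idx] = 1
    pat[sl_c.start + idx, sl_tc.start + idx] = 1
    pat[sl_c.start + idx, sl_tb.start + idx] = 1
    pat[sl_bb.start + idx, sl_b.start + idx] = 1
    pat[sl_bb.start + idx, sl_tb.start + idx] = 1
    pat[sl_tc.start + idx, sl_tc.start + idx] = 1
    pat[sl_tc.start + idx, sl_tb.start + idx] = 1
    pat[sl_tc.start + idx, sl_c.start + idx] = 1
    pat[sl_tc.start + idx, sl_bb.start + idx] = 1
    pat[sl_tb.start + idx, sl_tc.start + idx] = 1
    pat[sl_tb.start + idx, sl_bb.start + idx] = 1
    pat[sl_tb.start + idx, sl_tb.start + idx] = 1
    # the periosteal BMP node feels the mechanics, i.e. every matrix fraction
    pat[n, 3 * n + 1 : 5 * n + 1] = 1
    pat[n, 0] = 1
    # cell boundary nodes feel OP density and surface BMP
    for row in (sl_c.start + n - 1, sl_bb.start + n - 1):
        pat[row, 0] = 1
        pat[row, n] = 1
    pat[0, 3 * n + 1 : 5 * n + 1] = 0  # OP cap does not involve mechanics
    return pat


@dataclass
class SimulationResult:
    """Time-ordered snapshots plus mechanical summaries and diagnostics."""

    times: np.ndarray
    rho_op: np.ndarray  # (nt,)
    b: np.ndarray  # (nt, n)
    rho_c: np.ndarray
    rho_b: np.ndarray
    theta_c: np.ndarray
    theta_b: np.ndarray
    E_avg: np.ndarray
    eps: np.ndarray
    production_factor: np.ndarray
    grid: RadialGrid
    dp: DimensionlessParameters
    diagnostics: dict

    @property
    def n_times(self) -> int:
        return len(self.times)

    def state_at(self, i: int) -> TissueState:
        return TissueState(
            rho_op=float(self.rho_op[i]),
            b=self.b[i],
            rho_c=self.rho_c[i],
            rho_b=self.rho_b[i],
            theta_c=self.theta_c[i],
            theta_b=self.theta_b[i],
        )

    def interp_fields(self, t: float) -> TissueState:
        """Linear-in-time interpolation of every field at time t."""
        times = self.times
        if not times[0] <= t <= times[-1]:
            raise ValueError("time outside stored range")
        j = int(np.searchsorted(times, t))
        if j == 0 or times[j] == t:
            return self.state_at(j)
        w = (t - times[j - 1]) / (times[j] - times[j - 1])

        def lerp(a):
            return (1.0 - w) * a[j - 1] + w * a[j]

        return TissueState(
            rho_op=float(lerp(self.rho_op)),
            b=lerp(self.b),
            rho_c=lerp(self.rho_c),
            rho_b=lerp(self.rho_b),
            theta_c=lerp(self.theta_c),
            theta_b=lerp(self.theta_b),
        )


def default_initial_state(grid: RadialGrid, dp: DimensionlessParameters) -> np.ndarray:
    """Empty defect: no BMP, no cells, no matrix; OP at its initial density."""
    n = grid.n_nodes
    z = np.zeros(n)
    return pack_state(dp.rho_op_init, z, z, z, z, z)


def integrate(
    state0: np.ndarray | None,
    t_span: tuple[float, float],
    dp: DimensionlessParameters,
    grid: RadialGrid | None = None,
    opts: SolverOptions | None = None,
) -> SimulationResult:
    """Integrate the coupled system with a stiff BDF scheme.

    Snapshots are stored at the requested output times; solver statistics and
    the raw solver message are kept in ``diagnostics``.  On integration
    failure the partial result up to the last accepted time is returned with
    ``diagnostics['success'] = False``.
    """
    opts = opts or SolverOptions()
    grid = grid or dp.grid()
    if state0 is None:
        state0 = default_initial_state(grid, dp)
    state0 = np.asarray(state0, dtype=float)
    t0, t1 = t_span
    t_eval = (
        np.asarray(opts.t_eval, float)
        if opts.t_eval is not None
        else np.linspace(t0, t1, opts.n_out)
    )

    if opts.staged_updates:
        return _integrate_staged(state0, t_span, dp, grid, opts, t_eval)

    def rhs(t, y):
        return assemble_rhs(y, grid, dp, opts.production_override, opts.clip)

    sol = solve_ivp(
        rhs,
        (t0, t1),
        state0,
        method=opts.method,
        t_eval=t_eval,
        rtol=opts.rtol,
        atol=opts.atol,
        max_step=opts.max_step,
        jac_sparsity=_jacobian_sparsity(grid.n_nodes) if opts.method in ("BDF", "Radau") else None,
    )
    diagnostics = {
        "success": bool(sol.success),
        "message": sol.message,
        "nfev": int(sol.nfev),
        "njev": int(getattr(sol, "njev", 0)),
        "nlu": int(getattr(sol, "nlu", 0)),
        "n_steps": int(len(sol.t)),
        "rtol": opts.rtol,
        "atol": opts.atol,
    }
    return _collect(sol.t, sol.y.T, grid, dp, opts, diagnostics)


def _integrate_staged(state0, t_span, dp, grid, opts, t_eval):
    """Piecewise-constant mechanical feedback: the production factor is
    frozen at the start of each of N equal windows (the staged finite-element
    protocol), continuous integration within windows."""
    n_stage = int(opts.staged_updates)
    edges = np.linspace(t_span[0], t_span[1], n_stage + 1)
    inner = replace(opts, staged_updates=None)
    times, states = [], []
    y = state0
    diagnostics = {"success": True, "message": "", "nfev": 0, "n_steps": 0,
                   "rtol": opts.rtol, "atol": opts.atol, "stages": n_stage}
    for k in range(n_stage):
        _, _, _, _, tc, tb = unpack_state(y, grid.n_nodes)
        frozen = mechanics_from_theta(tc, tb, grid, dp).production_factor
        stage_opts = replace(
            inner,
            production_override=frozen if opts.production_override is None
            else opts.production_override,
            t_eval=None,
        )
        mask = (t_eval >= edges[k]) & (
            t_eval < edges[k + 1] if k < n_stage - 1 else t_eval <= edges[k + 1]
        )
        stage_eval = np.unique(np.concatenate([t_eval[mask], [edges[k + 1]]]))
        stage_opts.t_eval = np.concatenate([[edges[k]], stage_eval]) \
            if stage_eval[0] > edges[k] else stage_eval
        res = integrate(y, (edges[k], edges[k + 1]), dp, grid, stage_opts)
        diagnostics["nfev"] += res.diagnostics["nfev"]
        diagnostics["n_steps"] += res.diagnostics["n_steps"]
        diagnostics["success"] &= res.diagnostics["success"]
        keep = np.isin(res.times, t_eval[mask])
        for i in np.where(keep)[0]:
            times.append(res.times[i])
            states.append(
                pack_state(res.rho_op[i], res.b[i], res.rho_c[i],
                           res.rho_b[i], res.theta_c[i], res.theta_b[i])
            )
        y = pack_state(res.rho_op[-1], res.b[-1], res.rho_c[-1],
                       res.rho_b[-1], res.theta_c[-1], res.theta_b[-1])
    return _collect(np.asarray(times), np.asarray(states), grid, dp, opts, diagnostics)


def _collect(times, states, grid, dp, opts, diagnostics) -> SimulationResult:
    nt = len(times)
    n = grid.n_nodes
    rho_op = np.empty(nt)
    b = np.empty((nt, n))
    rho_c = np.empty((nt, n))
    rho_b = np.empty((nt, n))
    theta_c = np.empty((nt, n))
    theta_b = np.empty((nt, n))
    E_avg = np.empty(nt)
    eps = np.empty(nt)
    factor = np.empty(nt)
    for i in range(nt):
        op, bb, cc, ob, tc, tb = unpack_state(states[i], n)
        if opts.clip:
            bb, cc, ob = np.clip(bb, 0, None), np.clip(cc, 0, None), np.clip(ob, 0, None)
            tc, tb = np.clip(tc, 0, None), np.clip(tb, 0, None)
            op = max(float(op), 0.0)
        rho_op[i] = op
        b[i], rho_c[i], rho_b[i] = bb, cc, ob
        theta_c[i], theta_b[i] = tc, tb
        ms = mechanics_from_theta(tc, tb, grid, dp)
        E_avg[i], eps[i] = ms.E_avg, ms.eps
        factor[i] = (
            opts.production_override
            if opts.production_override is not None
            else ms.production_factor
        )
    return SimulationResult(
        times=np.asarray(times, float), rho_op=rho_op, b=b, rho_c=rho_c,
        rho_b=rho_b, theta_c=theta_c, theta_b=theta_b, E_avg=E_avg, eps=eps,
        production_factor=factor, grid=grid, dp=dp, diagnostics=diagnostics,
    )


def check_physical(result: SimulationResult, negativity_factor: float = 100.0) -> dict:
    """Physical-plausibility report for a completed run (never mutates it).

    Reports the space–time minimum of every field, flags negativity below
    ``-negativity_factor * atol`` (the reportable artifact of over-consumption
    closures), and the maximum total matrix fraction.
    """
    atol = result.diagnostics.get("atol", 1e-9)
    tol = -negativity_factor * atol
    minima = {
        "rho_op": float(result.rho_op.min()),
        "b": float(result.b.min()),
        "rho_c": float(result.rho_c.min()),
        "rho_b": float(result.rho_b.min()),
        "theta_c": float(result.theta_c.min()),
        "theta_b": float(result.theta_b.min()),
    }
    flags = {name: bool(v < tol) for name, v in minima.items()}
    return {
        "minima": minima,
        "negativity_flags": flags,
        "any_negative": any(flags.values()),
        "max_theta_m": float((result.theta_c + result.theta_b).max()),
        "threshold": tol,
    }
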