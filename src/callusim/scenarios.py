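"""Reproducible scenario driver: configuration, baseline run, parameter
sweeps, outcome summaries and tabular exports.

A fully defaulted :class:`ScenarioConfig` reproduces the baseline healing
simulation (all scaled kinetic parameters at their published baseline, the
calculated motilities and mechanotransduction coefficient, empty defect at
t = 0) run to dimensionless time 1, i.e. 16 weeks.
"""

from __future__ import annotations

import json
import logging
import math
import time as _time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import ModelParameters
from .mechanics import StrainFit, fit_strain_surrogate
from .solver import (
    RadialGrid,
    SimulationResult,
    SolverOptions,
    check_physical,
    integrate,
    nondimensionalize,
)

__all__ = [
    "ScenarioConfig",
    "OutcomeSummary",
    "SweepResult",
    "run_baseline",
    "parameter_sweep",
    "radial_profile_export",
    "summarize_outcome",
    "search_parameters",
    "SWEEPABLE",
]

log = logging.getLogger("callusim")

#: dimensionless parameters recognized by `parameter_sweep`, mapped to the
#: dimensional field the multiplier is applied to (scaling is linear, so a
#: multiplier on the dimensional value is a multiplier on the scaled one)
SWEEPABLE = {
    "V_op": "V_op",
    "V_dc": "V_dc",
    "V_db": "V_db",
    "V_c": "V_c",
    "V_b": "V_b",
    "k_cons": "k_cons",
    "Q_cart_max": "Q_cart_max",
    "k_min0": "k_min0",
    "k_prod": "k_prod",
    "k_mech": "k_mech",
    "k_apop_c": "k_apop_c",
    "k_apop_b": "k_apop_b",
    "D_bmp": "D_bmp",
}


@dataclass
class ScenarioConfig:
    """Schema-validated scenario description.

    ``parameters`` holds overrides of :class:`ModelParameters` fields
    (dimensional); the remaining blocks configure grid, solver, mechanics and
    outputs.  Unknown keys anywhere are rejected.
    """

    parameters: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)  # n_nodes
    solver: dict = field(default_factory=dict)  # rtol, atol, t_end, n_out, clip,
    # staged_updates, production_override
    mechanics: dict = field(default_factory=dict)  # strain_a, strain_c
    output: dict = field(default_factory=dict)  # directory, times
    sweep: dict = field(default_factory=dict)  # param, multipliers
    seed: int = 0

    _GRID_KEYS = {"n_nodes"}
    _SOLVER_KEYS = {"rtol", "atol", "t_end", "n_out", "clip", "staged_updates",
                    "production_override", "method"}
    _MECH_KEYS = {"strain_a", "strain_c"}
    _OUTPUT_KEYS = {"directory", "times"}
    _SWEEP_KEYS = {"param", "multipliers"}

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        param_keys = {f.name for f in fields(ModelParameters)}
        for key in self.parameters:
            if key not in param_keys:
                raise ValueError(f"unknown parameter key: {key}")
        for block, allowed in (
            (self.grid, self._GRID_KEYS),
            (self.solver, self._SOLVER_KEYS),
            (self.mechanics, self._MECH_KEYS),
            (self.output, self._OUTPUT_KEYS),
            (self.sweep, self._SWEEP_KEYS),
        ):
            for key in block:
                if key not in allowed:
                    raise ValueError(f"unknown config key: {key}")
        if self.sweep.get("param") is not None and self.sweep["param"] not in SWEEPABLE:
            raise ValueError(f"unknown sweep parameter: {self.sweep['param']}")

    # -- construction / serialization ------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        allowed = {f.name for f in fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "parameters": dict(self.parameters),
            "grid": dict(self.grid),
            "solver": dict(self.solver),
            "mechanics": dict(self.mechanics),
            "output": dict(self.output),
            "sweep": dict(self.sweep),
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    # -- realization ------------------------------------------------------
    def model_parameters(self) -> ModelParameters:
        return ModelParameters(**self.parameters)

    def strain_fit(self) -> StrainFit:
        if "strain_a" in self.mechanics or "strain_c" in self.mechanics:
            base = StrainFit()
            return StrainFit(
                a=self.mechanics.get("strain_a", base.a),
                c=self.mechanics.get("strain_c", base.c),
            )
        return StrainFit()

    def radial_grid(self, dp) -> RadialGrid:
        return dp.grid(self.grid.get("n_nodes", 101))

    def solver_options(self) -> SolverOptions:
        s = self.solver
        return SolverOptions(
            rtol=s.get("rtol", 1e-6),
            atol=s.get("atol", 1e-9),
            method=s.get("method", "BDF"),
            n_out=s.get("n_out", 41),
            clip=s.get("clip", False),
            staged_updates=s.get("staged_updates"),
            production_override=s.get("production_override"),
        )

    @property
    def t_end(self) -> float:
        return self.solver.get("t_end", 1.0)


@dataclass
class OutcomeSummary:
    """Healing outcome at the final stored time.

    Infilling is the area-weighted mean total matrix fraction over the
    annulus (percent of the cross-section filled); bone and cartilage shares
    partition the regenerate and sum to 100 whenever any matrix formed.
    """

    infilling_pct: float
    bone_share_pct: float
    cartilage_share_pct: float
    final_E_avg: float
    final_eps: float
    peak_series: dict

    def to_dict(self) -> dict:
        d = asdict(self)
        d["peak_series"] = {k: list(np.asarray(v, float)) for k, v in self.peak_series.items()}
        return d


def _area_mean(values: np.ndarray, grid: RadialGrid) -> float:
    """Area-weighted radial mean over the annulus (2 pi r dr weighting)."""
    r = grid.r
    return float(np.trapezoid(values * r, r) / np.trapezoid(r, r))


def summarize_outcome(result: SimulationResult, area_weighted: bool = True) -> OutcomeSummary:
    """Area-weighted outcome shares and the peak time series of each field."""
    if result.n_times == 0:
        raise ValueError("empty result")
    tc = np.clip(result.theta_c[-1], 0.0, None)
    tb = np.clip(result.theta_b[-1], 0.0, None)
    if area_weighted:
        mean_tc = _area_mean(tc, result.grid)
        mean_tb = _area_mean(tb, result.grid)
    else:
        mean_tc, mean_tb = float(tc.mean()), float(tb.mean())
    mean_tm = mean_tc + mean_tb
    if mean_tm > 0.0:
        bone_share = 100.0 * mean_tb / mean_tm
        cart_share = 100.0 * mean_tc / mean_tm
    else:
        bone_share = cart_share = 0.0
    return OutcomeSummary(
        infilling_pct=100.0 * mean_tm,
        bone_share_pct=bone_share,
        cartilage_share_pct=cart_share,
        final_E_avg=float(result.E_avg[-1]),
        final_eps=float(result.eps[-1]),
        peak_series={
            "times": result.times,
            "rho_op": result.rho_op,
            "b_max": result.b.max(axis=1),
            "rho_c_max": result.rho_c.max(axis=1),
            "rho_b_max": result.rho_b.max(axis=1),
            "theta_c_max": result.theta_c.max(axis=1),
            "theta_b_max": result.theta_b.max(axis=1),
        },
    )


def run_scenario(config: ScenarioConfig, params: ModelParameters | None = None):
    """Nondimensionalize -> integrate -> summarize for one scenario."""
    p = params if params is not None else config.model_parameters()
    dp = nondimensionalize(p, config.strain_fit())
    grid = config.radial_grid(dp)
    opts = config.solver_options()
    t0 = _time.perf_counter()
    result = integrate(None, (0.0, config.t_end), dp, grid, opts)
    wall = _time.perf_counter() - t0
    if not result.diagnostics["success"]:
        log.warning("integration ended early: %s", result.diagnostics["message"])
    result.diagnostics["wall_time_s"] = wall
    summary = summarize_outcome(result)
    return result, summary


def run_baseline(config: ScenarioConfig | None = None):
    """Run the (possibly customized) baseline scenario and write outputs.

    Returns ``(SimulationResult, OutcomeSummary)``; snapshots, summary JSON
    and a plain-text log are written when an output directory is configured.
    """
    config = config or ScenarioConfig()
    result, summary = run_scenario(config)
    outdir = config.output.get("directory")
    if outdir:
        _write_outputs(Path(outdir), config, result, summary)
    return result, summary


def _write_outputs(outdir: Path, config, result, summary) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    times = config.output.get("times") or list(result.times[:: max(1, result.n_times // 5)])
    for t in times:
        st = result.interp_fields(float(t))
        frame = pd.DataFrame(
            {
                "r": result.grid.r,
                "b": st.b,
                "rho_c": st.rho_c,
                "rho_b": st.rho_b,
                "theta_c": st.theta_c,
                "theta_b": st.theta_b,
            }
        )
        frame.to_csv(outdir / f"snapshot_t{t:.3f}.csv", index=False)
    payload = {
        "summary": {
            k: v for k, v in summary.to_dict().items() if k != "peak_series"
        },
        "diagnostics": result.diagnostics,
        "physical": check_physical(result),
        "config": config.to_dict(),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
    with open(outdir / "run.log", "w") as fh:
        fh.write(
            "callusim run\n"
            f"wall_time_s: {result.diagnostics.get('wall_time_s', float('nan')):.2f}\n"
            f"solver: {result.diagnostics}\n"
            f"summary: {payload['summary']}\n"
        )


# ---------------------------------------------------------------------------
# parameter sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    param: str
    multipliers: list
    summaries: list  # OutcomeSummary per multiplier
    results: list  # SimulationResult per multiplier
    table: pd.DataFrame  # per-multiplier outcome metrics

    def directional_effects(self) -> pd.DataFrame:
        """Sign of the change of each metric relative to multiplier 1."""
        base = self.table.loc[self.table["multiplier"] == 1.0].iloc[0]
        rows = []
        for _, row in self.table.iterrows():
            if row["multiplier"] == 1.0:
                continue
            rows.append(
                {
                    "multiplier": row["multiplier"],
                    **{
                        col: int(np.sign(row[col] - base[col]))
                        for col in self.table.columns
                        if col != "multiplier"
                    },
                }
            )
        return pd.DataFrame(rows)


def _time_to_half_max(times: np.ndarray, series: np.ndarray) -> float:
    """First time the series reaches half of its final maximum (NaN if flat)."""
    peak = series.max()
    if peak <= 0.0:
        return float("nan")
    idx = np.argmax(series >= 0.5 * peak)
    return float(times[idx])


def _sweep_metrics(mult: float, result: SimulationResult, summary: OutcomeSummary) -> dict:
    mean_tc = np.array([_area_mean(v, result.grid) for v in result.theta_c])
    mean_tb = np.array([_area_mean(v, result.grid) for v in result.theta_b])
    return {
        "multiplier": mult,
        "peak_rho_c": float(result.rho_c.max()),
        "peak_rho_b": float(result.rho_b.max()),
        "bmp_min": float(result.b.min()),
        "bmp_peak": float(result.b.max()),
        "bmp_final_mean": float(_area_mean(result.b[-1], result.grid)),
        "t_half_cartilage": _time_to_half_max(result.times, mean_tc),
        "t_half_bone": _time_to_half_max(result.times, mean_tb),
        "peak_theta_c": float(result.theta_c.max()),
        "infilling_pct": summary.infilling_pct,
        "bone_share_pct": summary.bone_share_pct,
    }


def parameter_sweep(
    config: ScenarioConfig, param_name: str, multipliers=(0.5, 1.0, 2.0)
) -> SweepResult:
    """Rerun the scenario with one dimensionless parameter scaled by each
    multiplier (shared grid and solver settings); collects outcome metrics
    and trajectories for directional-effect analysis."""
    if param_name not in SWEEPABLE:
        raise ValueError(f"unknown sweep parameter: {param_name}")
    if np.any(np.asarray(multipliers) <= 0):
        raise ValueError("multipliers must be positive")
    field_name = SWEEPABLE[param_name]
    base = config.model_parameters()
    summaries, results, rows = [], [], []
    for mult in multipliers:
        p = base.with_(**{field_name: getattr(base, field_name) * mult})
        result, summary = run_scenario(config, params=p)
        summaries.append(summary)
        results.append(result)
        rows.append(_sweep_metrics(float(mult), result, summary))
    return SweepResult(
        param=param_name,
        multipliers=list(multipliers),
        summaries=summaries,
        results=results,
        table=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# exports and utilities
# ---------------------------------------------------------------------------

def radial_profile_export(result: SimulationResult, time: float, n_points: int = 51) -> pd.DataFrame:
    """Normalized bone-fraction-vs-radius table at one time.

    The position axis follows the experimental convention: 0 at the
    periosteum, 10 at the nail surface.  Fields are interpolated linearly in
    time between snapshots and linearly (monotone) in radius.
    """
    st = result.interp_fields(time)
    r = result.grid.r
    x = np.linspace(0.0, 10.0, n_points)
    # position x maps to radius R_out - x/10 * (R_out - R_in)
    r_sample = result.grid.R_out - x / 10.0 * (result.grid.R_out - result.grid.R_in)
    theta_b = np.interp(r_sample, r, st.theta_b)
    theta_c = np.interp(r_sample, r, st.theta_c)
    return pd.DataFrame({"position": x, "theta_b": theta_b, "theta_c": theta_c})


def search_parameters(
    target_bone_share: float,
    target_infilling: float,
    config: ScenarioConfig | None = None,
    n_trials: int = 20,
    seed: int = 0,
    sweep_fields=("V_db", "V_c", "V_b", "Q_cart_max", "k_min0"),
):
    """Seeded random search for parameter multipliers matching target outcome
    shares (a labelled exploratory utility, not a fitted reference set).

    Draws log-uniform multipliers in [1/4, 4] for the given fields, scores
    each trial by the distance to the target (bone share, infilling) pair and
    returns the trials sorted best-first.
    """
    config = config or ScenarioConfig()
    rng = np.random.default_rng(seed)
    base = config.model_parameters()
    rows = []
    for _ in range(n_trials):
        mults = {f: float(np.exp(rng.uniform(np.log(0.25), np.log(4.0)))) for f in sweep_fields}
        p = base.with_(**{f: getattr(base, f) * m for f, m in mults.items()})
        try:
            _, summary = run_scenario(config, params=p)
        except Exception as err:  # noqa: BLE001 - searches must survive bad corners
            log.warning("search trial failed: %s", err)
            continue
        score = math.hypot(
            summary.bone_share_pct - target_bone_share,
            summary.infilling_pct - target_infilling,
        )
        rows.append({**mults, "bone_share_pct": summary.bone_share_pct,
                     "infilling_pct": summary.infilling_pct, "score": score})
    return pd.DataFrame(rows).sort_values("score").reset_index(drop=True)

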