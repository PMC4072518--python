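"""Shared fixtures: the baseline run and the heavier simulation studies are
session-scoped so every test module (and the acceptance suite) reuses them."""

from __future__ import annotations

import numpy as np
import pytest

import callusim as cs


@pytest.fixture()
def params() -> cs.ModelParameters:
    return cs.ModelParameters()


@pytest.fixture()
def dp(params) -> cs.DimensionlessParameters:
    return cs.nondimensionalize(params)


@pytest.fixture(scope="session")
def baseline_result() -> cs.SimulationResult:
    """Defaulted baseline healing run to dimensionless t = 1 (16 weeks)."""
    dp = cs.nondimensionalize(cs.ModelParameters())
    return cs.integrate(None, (0.0, 1.0), dp)


@pytest.fixture(scope="session")
def baseline_summary(baseline_result) -> cs.OutcomeSummary:
    return cs.summarize_outcome(baseline_result)


@pytest.fixture(scope="session")
def sweep_results() -> dict:
    """The six single-parameter sweeps at multipliers (0.5, 1, 2)."""
    cfg = cs.ScenarioConfig(grid={"n_nodes": 61}, solver={"n_out": 33})
    return {
        name: cs.parameter_sweep(cfg, name, (0.5, 1.0, 2.0))
        for name in ("V_dc", "V_db", "V_c", "V_b", "k_cons", "Q_cart_max")
    }


@pytest.fixture(scope="session")
def convergence_solutions() -> dict:
    """Baseline solved on successively halved grids at tight tolerances."""
    dp = cs.nondimensionalize(cs.ModelParameters())
    opts = cs.SolverOptions(rtol=1e-8, atol=1e-11, n_out=3)
    return {
        n: cs.integrate(None, (0.0, 1.0), dp, dp.grid(n), opts)
        for n in (26, 51, 101)
    }
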