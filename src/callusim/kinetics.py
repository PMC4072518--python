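"""Pointwise reaction kinetics of the cellular–tissue healing model.

The defect annulus between an intramedullary nail and the periosteum fills by
endochondral ossification: osteochondroprogenitor (OP) cells in the periosteum
proliferate and differentiate into chondrocytes and osteoblasts under the
control of a single diffusible growth factor (BMP-2 standing in for the class
of osteochondrogenic factors).  Chondrocytes secrete a cartilage template that
osteoblasts subsequently mineralize into bone.  Every cell-level rate law of
the model lives in this module; spatial transport and the mechanical feedback
loop are handled by :mod:`callusim.solver` and :mod:`callusim.mechanics`.

All rate laws are written so that they accept either dimensional parameters
(:class:`ModelParameters`) or their scaled counterparts
(:class:`callusim.solver.DimensionlessParameters`), which share field names.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "ModelParameters",
    "TissueState",
    "monod_rate",
    "op_rhs",
    "differentiation_rates",
    "chondro_reaction",
    "osteo_reaction",
    "cartilage_production_coeff",
    "ecm_rhs",
    "bmp_reaction",
    "smooth_step",
    "cap_factor",
    "apoptosis_switch",
]

#: healing horizon in days; dimensionless time t = 1 corresponds to 16 weeks
T_HEAL_DAYS = 112.0

#: default BMP production per OP cell (one boundary-flux unit per cell per day)
K_PROD_DEFAULT = 1.0

#: literature OP proliferation maximum (1/day)
V_OP_LITERATURE = 1.5

#: printed matrix production maximum, cm^2/(cell day)
Q_CART_DEFAULT = 3.0e-6


def _bmp_scale(rho_op_crit: float, k_prod: float, length: float) -> float:
    """BMP concentration produced per unit length by a saturated periosteum in
    one healing time — the natural concentration scale of the boundary source."""
    return k_prod * rho_op_crit * T_HEAL_DAYS / length


@dataclass
class ModelParameters:
    """Dimensional rate constants, geometry and material properties.

    Defaults are constructed so that nondimensionalization reproduces the
    published baseline convention: every kinetic parameter scales to 1 except
    the OP proliferation maximum (kept at its literature value of 1.5/day),
    the cell motilities (one order of magnitude below the BMP diffusivity) and
    the mechanotransduction coefficient k_mech = 1.2 per millistrain.
    """

    # geometry (cm): 12 mm nail diameter; outer radius from the 4000 mm^3
    # defect space over the 2.54 cm defect length plus the nail cross-section
    R_in: float = 0.6
    R_out: float = 0.93

    # OP cells (surface densities, cells/cm^2 of periosteum)
    rho_op_crit: float = 1.0e4
    rho_op_init: float = 1.0e3  # 0.1 * rho_op_crit, so the early transient is visible
    V_op: float = V_OP_LITERATURE
    K_op: float = 0.0  # filled in __post_init__ with the BMP scale

    # OP -> chondrocyte / osteoblast differentiation (1/day)
    V_dc: float = 1.0 / T_HEAL_DAYS
    K_dc: float = 0.0
    V_db: float = 1.0 / T_HEAL_DAYS
    K_db: float = 0.0

    # chondrocyte / osteoblast proliferation (1/day); the healed baseline
    # requires chondrocytes to proliferate faster than osteoblasts, so the
    # osteoblast rate defaults to half the chondrocyte rate
    V_c: float = 1.0 / T_HEAL_DAYS
    K_c: float = 0.0
    V_b: float = 0.5 / T_HEAL_DAYS
    K_b: float = 0.0

    # transport (cm^2/day): BMP as protein in cytoplasm, motility = D/10
    D_bmp: float = 0.013
    mu_c: float = 0.0013
    mu_b: float = 0.0013

    # BMP turnover
    k_prod: float = K_PROD_DEFAULT  # BMP units/(cell day), boundary production
    k_cons: float = Q_CART_DEFAULT  # cm^3/(cell day), consumption per cell
    k_uptake_frac: float = 0.01  # uptake half-saturation as a fraction of K_op
    #: "saturable": uptake vanishes smoothly as BMP is exhausted (default);
    #: "metabolic": per-cell-constant removal, the idealization that can
    #: over-consume and drive BMP negative (reportable diagnostic)
    uptake: str = "saturable"

    # apoptosis
    k_apop_c: float = 1.0 / T_HEAL_DAYS
    k_apop_b: float = 1.0 / T_HEAL_DAYS
    theta_apop_c: float = 0.8  # total-ECM fraction triggering chondrocyte death
    theta_apop_b: float = 0.5  # bone fraction embedding/retiring osteoblasts

    # extracellular matrix; mineralization proceeds at half the rate of
    # cartilage production in the healed baseline
    Q_cart_max: float = Q_CART_DEFAULT  # cm^2/(cell day)
    theta_crit: float = 0.5  # contact inhibition onset
    theta_max: float = 0.9  # production stop; 1 - phi with void fraction 0.1
    k_min0: float = 0.5 * Q_CART_DEFAULT  # mineralization per osteoblast

    # mechanics
    E_cart: float = 0.01  # GPa
    E_bone: float = 17.0  # GPa
    E_floor: float = 0.0  # modulus below which strain is clamped at eps_max
    eps_max: float = 12.0  # millistrain, FE-model maximum
    k_mech: float = 1.2  # fold BMP upregulation per millistrain

    # numerical smoothing of the critical-density switches (fraction of threshold)
    switch_width: float = 0.01

    def __post_init__(self) -> None:
        b0 = _bmp_scale(self.rho_op_crit, self.k_prod, self.R_out - self.R_in)
        for name in ("K_op", "K_dc", "K_db", "K_c", "K_b"):
            if getattr(self, name) == 0.0:
                object.__setattr__(self, name, b0)
        self.validate()

    def validate(self) -> None:
        positive = [
            "V_op", "K_op", "V_dc", "K_dc", "V_db", "K_db", "V_c", "K_c",
            "V_b", "K_b", "mu_c", "mu_b", "D_bmp", "k_prod", "k_cons",
            "k_apop_c", "k_apop_b", "Q_cart_max", "k_min0", "E_cart",
            "E_bone", "eps_max", "R_in", "R_out", "rho_op_crit", "k_mech",
        ]
        for name in positive:
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.R_in < self.R_out:
            raise ValueError("R_in must be smaller than R_out")
        if not 0.0 < self.theta_crit < self.theta_max <= 1.0:
            raise ValueError("need 0 < theta_crit < theta_max <= 1")
        for name in ("theta_apop_c", "theta_apop_b"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.rho_op_init < 0.0:
            raise ValueError("rho_op_init must be non-negative")
        if not 0.0 < self.switch_width < 1.0:
            raise ValueError("switch_width must lie in (0, 1)")
        if self.uptake not in ("saturable", "metabolic"):
            raise ValueError("uptake must be 'saturable' or 'metabolic'")

    @property
    def k_uptake(self) -> float:
        """Uptake half-saturation in BMP concentration units."""
        return self.k_uptake_frac * self.K_op

    def with_(self, **overrides) -> "ModelParameters":
        """Return a copy with the given fields replaced (revalidated)."""
        return replace(self, **overrides)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class TissueState:
    """One snapshot of the system.

    rho_op is the OP surface density at the periosteum (scalar); the remaining
    fields are radial profiles on the solver grid: BMP concentration ``b``,
    chondrocyte and osteoblast densities ``rho_c``/``rho_b`` and the area
    fractions of cartilage and bone ``theta_c``/``theta_b``.
    """

    rho_op: float
    b: np.ndarray
    rho_c: np.ndarray
    rho_b: np.ndarray
    theta_c: np.ndarray
    theta_b: np.ndarray

    @property
    def theta_m(self) -> np.ndarray:
        """Total extracellular-matrix area fraction (cartilage + bone)."""
        return self.theta_c + self.theta_b


# ---------------------------------------------------------------------------
# switch smoothing
# ---------------------------------------------------------------------------

def smooth_step(x):
    """C^1 ramp: 0 for x <= 0, 1 for x >= 1, cubic smoothstep in between."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def cap_factor(rho_op, rho_op_crit, width):
    """Gate on OP net growth: 1 well below the critical density, exactly 0 at
    and above it, so the OP population saturates smoothly at rho_op_crit."""
    w = width * rho_op_crit
    return smooth_step((rho_op_crit - rho_op) / w)


def apoptosis_switch(theta, threshold, width):
    """Critical-density trigger: exactly 1 at and above the threshold, 0 for
    ECM fractions more than one switch-width below it."""
    w = width * threshold
    return smooth_step((theta - threshold) / w + 1.0)


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def monod_rate(b, V, K):
    """Saturating rate V*b/(K+b) for a rate-limiting factor at concentration b.

    V is the maximum rate and K the concentration at which the rate is V/2.
    """
    if np.any(np.asarray(b) < 0):
        raise ValueError("negative concentration in monod_rate")
    if not V >= 0:
        raise ValueError("V must be non-negative")
    if not K > 0:
        raise ValueError("K must be strictly positive")
    b = np.asarray(b, dtype=float)
    out = V * b / (K + b)
    return out if out.ndim else float(out)


def op_rhs(rho_op, b_surf, p) -> float:
    """Net rate of change of the OP surface density at the periosteum.

    Below the critical density the population grows at the proliferation rate
    minus both differentiation rates, each Monod-limited by the BMP level at
    the periosteal surface; at and above the critical density proliferation
    exactly balances differentiation and the population is constant.
    """
    if rho_op < 0 or b_surf < 0:
        raise ValueError("negative input to op_rhs")
    net = (
        monod_rate(b_surf, p.V_op, p.K_op)
        - monod_rate(b_surf, p.V_dc, p.K_dc)
        - monod_rate(b_surf, p.V_db, p.K_db)
    )
    return float(net * rho_op * cap_factor(rho_op, p.rho_op_crit, p.switch_width))


def differentiation_rates(b, p):
    """Monod-limited rates of OP differentiation to chondrocytes and osteoblasts."""
    return monod_rate(b, p.V_dc, p.K_dc), monod_rate(b, p.V_db, p.K_db)


def chondro_reaction(rho_c, b, theta_m, p):
    """Local net chondrocyte rate: Monod proliferation minus apoptosis.

    Apoptosis switches on as the total ECM fraction reaches the critical
    density theta_apop_c (nutrient exclusion by the maturing matrix).
    """
    _check_nonneg(rho_c=rho_c, b=b, theta_m=theta_m)
    if np.any(np.asarray(theta_m) > 1.0 + 1e-12):
        raise ValueError("theta_m exceeds 1")
    growth = monod_rate(b, p.V_c, p.K_c) * rho_c
    death = p.k_apop_c * rho_c * apoptosis_switch(theta_m, p.theta_apop_c, p.switch_width)
    return growth - death


def osteo_reaction(rho_b, b, theta_b, p):
    """Local net osteoblast rate; apoptosis (or osteocyte embedding) switches
    on once the surrounding bone fraction reaches theta_apop_b."""
    _check_nonneg(rho_b=rho_b, b=b, theta_b=theta_b)
    growth = monod_rate(b, p.V_b, p.K_b) * rho_b
    death = p.k_apop_b * rho_b * apoptosis_switch(theta_b, p.theta_apop_b, p.switch_width)
    return growth - death


def cartilage_production_coeff(theta_m, p):
    """Per-chondrocyte cartilage production rate with contact inhibition.

    Maximal below theta_crit, then a linear ramp to exactly zero at theta_max
    (the printed void fraction phi = 1 - theta_max survives unfilled).
    """
    arr = np.asarray(theta_m, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1.0 + 1e-12):
        raise ValueError("theta_m outside [0, 1]")
    ramp = np.clip((p.theta_max - arr) / (p.theta_max - p.theta_crit), 0.0, 1.0)
    out = p.Q_cart_max * ramp
    return out if out.ndim else float(out)


def ecm_rhs(theta_c, theta_b, rho_c, rho_b, p):
    """Rates of change of the cartilage and bone area fractions.

    Cartilage accumulates in proportion to the chondrocyte density, slowed by
    contact inhibition of the total ECM; osteoblasts mineralize the cartilage
    template at rate k_min0*rho_b, converting it one-to-one into bone so the
    exchange conserves total ECM and bone never resorbs.
    """
    _check_nonneg(theta_c=theta_c, theta_b=theta_b, rho_c=rho_c, rho_b=rho_b)
    theta_m = np.asarray(theta_c) + np.asarray(theta_b)
    if np.any(np.asarray(theta_m) > 1.0 + 1e-12):
        raise ValueError("theta_c + theta_b exceeds 1")
    production = cartilage_production_coeff(theta_m, p) * rho_c
    mineralization = p.k_min0 * np.asarray(rho_b) * np.asarray(theta_c)
    d_theta_c = production - mineralization
    d_theta_b = mineralization
    return d_theta_c, d_theta_b


def bmp_reaction(b, rho_c, rho_b, p):
    """BMP consumption sink (reported non-negative).

    Metabolic removal by cell uptake: proportional to the total density of
    consuming cells.  In the default "saturable" form the uptake saturates in
    BMP with a small half-saturation k_uptake, so it is effectively
    per-cell-constant at physiological levels and vanishes only as BMP is
    exhausted.  The "metabolic" form removes at the per-cell-constant rate
    regardless of the remaining BMP — the idealization under which
    over-consumption drives BMP negative (a reportable diagnostic).
    """
    b = np.asarray(b, dtype=float)
    cells = np.asarray(rho_c, dtype=float) + np.asarray(rho_b, dtype=float)
    if getattr(p, "uptake", "saturable") == "metabolic":
        out = p.k_cons * cells * np.ones_like(b)
    else:
        out = p.k_cons * cells * b / (p.k_uptake + b)
    return out if out.ndim else float(out)


def _check_nonneg(**values) -> None:
    for name, value in values.items():
        if np.any(np.asarray(value) < 0):
            raise ValueError(f"negative {name}")
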