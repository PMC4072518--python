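"""Mechanical feedback: callus stiffness -> periosteal strain -> BMP production.

As cartilage and bone accumulate in the defect the emergent callus stiffens.
The average elastic modulus over the annular cross-section (law of mixtures,
area-weighted) sets the axial tensile strain at the periosteal surface through
a logarithmic surrogate fitted to finite-element output, and that strain sets
the fold-upregulation of BMP production by the mechanosensitive progenitors.
Only the tensile (lateral) branch is modeled.

The default :class:`StrainFit` coefficients are a synthetic reconstruction of
the finite-element strain–modulus relationship: the published anchors are the
strain range (zero to a maximum of 12 millistrain) over the modulus range from
all-cartilage (0.01 GPa) to cortical bone (17 GPa).  Users with their own
(modulus, strain) tables can refit via :func:`fit_strain_surrogate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StrainFit",
    "MechanicsState",
    "local_modulus",
    "average_modulus",
    "strain_from_modulus",
    "bmp_production_factor",
    "fit_strain_surrogate",
]


@dataclass(frozen=True)
class StrainFit:
    """Logarithmic strain surrogate eps = a + c*ln(E), eps in millistrain, E in GPa."""

    a: float = 4.632
    c: float = -1.600
    residual: float = 0.0

    def __call__(self, modulus: float) -> float:
        return self.a + self.c * math.log(modulus)


@dataclass(frozen=True)
class MechanicsState:
    """Mechanical summary of one snapshot: average modulus (GPa), periosteal
    axial strain (millistrain) and the fold-multiplier on BMP production."""

    E_avg: float
    eps: float
    production_factor: float


def local_modulus(theta_c, theta_b, p):
    """Law-of-mixtures modulus E = theta_c*E_cart + theta_b*E_bone (GPa).

    Where the section is essentially empty (total ECM below machine-level
    content) the mixture returns the configured floor modulus ``E_floor``
    (default 0; the strain surrogate clamps at eps_max there).
    """
    theta_c = np.asarray(theta_c, dtype=float)
    theta_b = np.asarray(theta_b, dtype=float)
    e = theta_c * p.E_cart + theta_b * p.E_bone
    e = np.where(theta_c + theta_b > 0.0, e, p.E_floor)
    return e if e.ndim else float(e)


def average_modulus(theta_c, theta_b, grid, p=None) -> float:
    """Average elastic modulus over the defect annulus (GPa).

    Area-weighted radial integral of the local mixture modulus,
    (integral of E(r) 2 pi r dr) / (annulus area).  Constituent moduli come
    from ``p`` when given, otherwise the standard constants (0.01, 17.0 GPa).
    """
    theta_c = np.asarray(theta_c, dtype=float)
    theta_b = np.asarray(theta_b, dtype=float)
    r = np.asarray(grid.r, dtype=float)
    if theta_c.shape != r.shape or theta_b.shape != r.shape:
        raise ValueError("field length does not match grid")
    e_cart = p.E_cart if p is not None else 0.01
    e_bone = p.E_bone if p is not None else 17.0
    e = theta_c * e_cart + theta_b * e_bone
    num = np.trapezoid(e * r, r)
    den = np.trapezoid(r, r)
    return float(num / den)


def strain_from_modulus(E_avg: float, p, fit: StrainFit | None = None) -> float:
    """Mean axial tensile strain at the periosteum (millistrain).

    Evaluates the logarithmic surrogate, clamped to [0, eps_max].  At or below
    the floor modulus (empty defect) the finite-element maximum eps_max
    applies; the result is monotone non-increasing in E_avg.
    """
    if E_avg < 0.0:
        raise ValueError("negative modulus")
    fit = fit if fit is not None else getattr(p, "strain_fit", None) or StrainFit()
    if E_avg <= max(p.E_floor, 0.0) or E_avg == 0.0:
        return p.eps_max
    return float(np.clip(fit(E_avg), 0.0, p.eps_max))


def bmp_production_factor(eps: float, p) -> float:
    """Fold-multiplier on baseline BMP production at periosteal strain eps.

    Linear mechanotransduction 1 + k_mech*eps (eps in millistrain): unloaded
    periosteum produces at baseline (factor 1); 2.5 millistrain with the
    default k_mech = 1.2 gives the experimentally observed four-fold rate.
    """
    if eps < 0.0:
        raise ValueError("compressive strain out of scope")
    return 1.0 + p.k_mech * eps


def fit_strain_surrogate(pairs) -> StrainFit:
    """Least-squares fit of eps = a + c*ln(E) to (modulus GPa, strain mstrain) pairs.

    Requires at least three pairs with positive, distinct moduli; returns the
    coefficients and the residual norm.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least three (modulus, strain) pairs")
    E, eps = arr[:, 0], arr[:, 1]
    if np.any(E <= 0.0):
        raise ValueError("moduli must be positive")
    if len(np.unique(E)) != len(E):
        raise ValueError("degenerate fit: duplicate moduli")
    design = np.column_stack([np.ones_like(E), np.log(E)])
    coef, res, rank, _ = np.linalg.lstsq(design, eps, rcond=None)
    if rank < 2:
        raise ValueError("degenerate fit: collinear design")
    residual = float(np.sqrt(res[0])) if res.size else float(
        np.linalg.norm(design @ coef - eps)
    )
    return StrainFit(a=float(coef[0]), c=float(coef[1]), residual=residual)
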