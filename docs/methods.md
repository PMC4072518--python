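# Methods

## The model

`callusim` simulates tissue genesis in a critical-sized long-bone defect
stabilized by an intramedullary nail and enveloped by periosteum. The defect
cross-section is the annulus between the nail surface (r = R_in) and the
periosteum (r = R_out). Healing proceeds by endochondral ossification and is
driven entirely from the outer boundary, where mechanosensitive
osteochondroprogenitor (OP) cells live.

State variables:

* `rho_op(t)` — OP surface density at the periosteum (cells per unit surface
  area; a single scalar, since OP cells do not migrate into the defect);
* `b(r, t)` — BMP-2 concentration (representative of the class of
  osteochondrogenic factors);
* `rho_c(r, t)`, `rho_b(r, t)` — chondrocyte and osteoblast densities;
* `theta_c(r, t)`, `theta_b(r, t)` — area fractions of cartilage and
  mineralized bone, with `theta_c + theta_b <= 1`.

Rate laws:

* OP cells proliferate and differentiate with Monod (saturating) kinetics in
  the local BMP level, `V b/(K + b)`. Below a critical surface density
  `rho_op_crit` the population evolves at proliferation minus both
  differentiation rates; at the critical density proliferation exactly
  balances differentiation and the population stays constant.
* BMP is produced at the periosteum in proportion to `rho_op` and to the
  mechanotransduction factor `1 + k_mech * eps` (`eps` = periosteal axial
  tensile strain in millistrain, `k_mech = 1.2`/millistrain calibrated from a
  four-fold upregulation at 2.5 millistrain). It diffuses through the annulus
  (`D = 0.013 cm²/day`, protein in cytoplasm) and is removed by cell uptake.
* Differentiated cells enter the defect as a boundary flux at the periosteum
  equal to the differentiation rate times `rho_op`, then spread by random
  motility (`mu = D/10`), proliferate (Monod in BMP) and die by apoptosis
  when a critical matrix density surrounds them (`theta_m >= theta_apop_c`
  for chondrocytes, `theta_b >= theta_apop_b` for osteoblasts).
* Cartilage is produced per chondrocyte at rate `Q` up to a contact-inhibition
  onset `theta_crit`, ramping linearly to zero at `theta_max`. Osteoblasts
  mineralize the cartilage template at `k_min0 * rho_b * theta_c`, converting
  cartilage to bone one-to-one (the exchange conserves total matrix, and bone
  never resorbs). Bone formation therefore requires a pre-existing cartilage
  template.
* Mechanics closes the loop: the local modulus is the law of mixtures
  `E = theta_c * E_cart + theta_b * E_bone` (0.01 and 17.0 GPa); the average
  modulus is the area-weighted annulus integral; the periosteal strain is a
  logarithmic surrogate `eps = a + c ln(E_avg)` clipped to [0, 12]
  millistrain; the strain sets the BMP production factor. Only the tensile
  (lateral) branch is modeled; compressive strains are out of scope.

## Scaling

Dimensionless time maps t = 1 to 16 weeks (T = 112 days); length is scaled by
the gap L = R_out − R_in. The BMP scale `B0 = k_prod * rho_op_crit * T / L`
is the concentration a saturated periosteum produces per gap width per
healing time, so the scaled production coefficient is 1. The cell-density
scale `N0 = 1/(Q * T)` is the density at which matrix production fills the
section in one healing time, so the scaled production and consumption
coefficients are 1. The OP scale is `rho_op_crit` itself. One derived ratio
survives in the scaled cell boundary flux, `beta = rho_op_crit/(N0 * L)`
(≈ 10.2 with `rho_op_crit = 1e4 cells/cm²`, a cambium-layer progenitor
density of plausible magnitude).

Baseline scaled parameters are 1 by convention, with the documented
exceptions:

| parameter | scaled value | reason |
|---|---|---|
| `V_op` | 168 | literature OP proliferation 1.5/day kept dimensional; required for the rapid early saturation of the OP pool |
| `V_b` | 0.5 | healed baseline requires chondrocyte proliferation faster than osteoblast proliferation |
| `k_min0` | 0.5 | mineralization proceeds at half the rate of cartilage production |
| `D_bmp` | 13.37 | calculated, 0.013 cm²/day |
| `mu_c`, `mu_b` | 1.337 | calculated, one order of magnitude below BMP |
| `k_mech` | 1.2 | mechanotransduction calibration |

Threshold defaults: `theta_max = 0.9` (a residual void fraction phi = 0.1,
i.e. 90% maximal infilling), `theta_crit = 0.5`, `theta_apop_c = 0.8`
(chondrocytes die as the matrix closes around them), `theta_apop_b = 0.5`
(osteoblasts retire — biologically, embed as osteocytes — once bone is the
majority phase). These are not printed anywhere; they were fixed once by
requiring the defaulted baseline to reproduce the described ideal healing
state (cartilage template first, ~90% infilling, ~80% bone share at t = 1)
and are not tuned per scenario.

## Strain surrogate

The finite-element strain–modulus relationship is represented by the
logarithmic fit `eps = a + c ln(E)`. The shipped coefficients
(`a = 4.632`, `c = −1.600`) are a synthetic reconstruction anchored to the
published range: the clamp maximum of 12 millistrain at the all-cartilage end
(0.01 GPa) and a near-zero residual strain at cortical bone (17 GPa). They
are not digitized finite-element output; `fit_strain_surrogate` refits the
same form to any user-supplied (modulus, strain) table, and the scenario
configuration can override `a` and `c` directly. At and below the floor
modulus (`E_floor`, default 0 — the empty defect) the strain is clamped at
`eps_max = 12` millistrain rather than extrapolating the diverging logarithm.

## Numerics

* Method of lines: second-order central differences for the cylindrical
  operator `(1/r) d/dr (r d/dr)`; ghost-node closures carry the zero-flux
  condition at the nail and the Robin production/influx conditions at the
  periosteum. The ghost closure is first-order in its pointwise boundary
  truncation but the solution converges at order ≈ 2 (verified by
  manufactured-solution and self-convergence tests).
* Default grid: 101 uniform nodes. The domain is a thin annulus with no
  boundary layers at baseline diffusivities, so uniform spacing suffices.
* Time integration: SciPy `solve_ivp` BDF with `rtol 1e-6`, `atol 1e-9` and
  an explicit Jacobian sparsity pattern (tridiagonal transport blocks, local
  reaction couplings, plus one dense row coupling the periosteal BMP node to
  every matrix fraction through the average modulus).
* Critical-density conditions (OP cap, both apoptosis triggers) are smoothed
  with a C¹ cubic step of width 1% of the threshold so the stiff integrator
  sees a C¹ right-hand side; the step reaches 0 and 1 exactly, so the OP
  derivative is exactly zero at and above the critical density. Width → 0
  recovers the sharp threshold.
* The mechanical feedback is recomputed at every right-hand-side evaluation
  (the surrogate makes this cheap). An optional staged mode freezes the
  production factor over N equal windows, emulating a protocol in which the
  finite-element properties are updated at discrete intervals; with N = 10 it
  reproduces the continuous outcome to within ~1 percentage point.
* BMP uptake: the default "saturable" form `k_cons (rho_c + rho_b) b/(k_u + b)`
  with a small half-saturation (`k_u` = 1% of the Monod constant) is linear
  near zero — so all sources vanish with BMP — and effectively
  per-cell-constant at physiological levels. The "metabolic" option removes
  BMP at a per-cell-constant rate regardless of the remaining level; under
  over-consumption (e.g. ten-fold `k_cons`) it drives the concentration
  genuinely negative. That implausibility is deliberately reproducible:
  `check_physical` reports field minima and raises a negativity flag below
  −100·atol. Negative excursions are detected and flagged by default; a
  clip-at-zero mode is available for exploratory runs. Rate laws inside the
  solver always receive non-negative clipped arguments, which keeps
  `theta_b` non-decreasing and the matrix budget conserved even when a field
  undershoots.

## What the scenario driver computes

`run_baseline` executes nondimensionalize → integrate → summarize and writes
per-time snapshots (CSV), a run summary (JSON) and a plain-text log.
Outcome shares are area-weighted annulus means (2πr dr), consistent with the
cross-sectional area-fraction framing; a plain radial average is available.
`parameter_sweep` varies one dimensionless parameter at multipliers
{0.5, 1, 2} (directions, not magnitudes, are the claim) and tabulates peak
densities, BMP extrema and times-to-half-maximum for directional-effect
analysis. `radial_profile_export` writes the bone profile against the
experimental position convention (0 = periosteum, 10 = nail).
`search_parameters` is a seeded random-multiplier search toward target
outcome shares — an exploratory utility, labelled as such, not a fitted
reference parameter set.

## Problem sizes

The test suite and the acceptance script run the baseline on the default
101-node grid (integration ≈ 2–3 s), the sweep battery on 61 nodes and the
convergence study on 26/51/101 nodes at tightened tolerances. These sizes
put the discretization error far below the tolerances asserted anywhere.

## Known limitations

* One radial dimension: no axial healing gradient, no moving callus boundary,
  fixed annular geometry.
* No OP migration, no cell–cell interactions, no angiogenesis or oxygen
  transport, no intramembranous (direct) bone formation, no bone remodeling
  or resorption.
* The strain surrogate is a static fitted relationship, not a live
  finite-element computation; its default coefficients are synthetic
  (see above).
* Apoptosis and uptake closures are idealized first-order laws gated by
  critical densities; the thresholds are calibrated to the described healed
  baseline, not measured.
* The simulator's agreement with the described healing course shows the
  feedback structure can reproduce those patterns under the stated
  conventions; it does not validate the parameter values against tissue
  data.
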