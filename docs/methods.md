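# Methods

This note documents the model, its numerical treatment, the choices made
where the design was open, and the limits of what the synthetic benchmarks
can show.

## Magnetostatics of the finite cylinder

The external H-field of a uniformly, axially magnetised cylinder of radius
R, length L and magnetisation M_s is evaluated from its closed form in the
complete elliptic integrals (parameter convention m = modulus²):

- H_ρ from the auxiliary function P1(m) = K(m) − (2/m)(K(m) − E(m)),
- H_z from Q(m; γ) = K(m) − γ Π(1 − γ², m) with γ = (ρ − R)/(ρ + R),

with ζ± = z ± L/2, α± = (ζ±² + (R+ρ)²)^(−1/2), β± = ζ± α± and
m± = 4Rρ α±². The sign convention of ζ± is fixed by requiring agreement
with the on-axis closed form
H_z(0, z) = (M_s/2)[ζ₊/√(ζ₊²+R²) − ζ₋/√(ζ₋²+R²)], under which the field
decays to zero far from the magnet and matches the point dipole of moment
M_s πR²L to <1 % beyond 50 R.

Numerical choices:

- All elliptic integrals go through Carlson symmetric forms
  (`scipy.special.elliprf/elliprd/elliprj`). In particular
  K − E = (m/3)·R_D(0, 1−m, 1), which avoids catastrophic cancellation in
  P1 for small m (near the magnet axis).
- On the axis (ρ < 10⁻⁹ R) the closed-form axis limits are substituted:
  H_ρ = 0, the on-axis H_z, ∂H_ρ/∂ρ = −½ ∂H_z/∂z (solenoidality), zero
  off-diagonal Jacobian entries.
- On the cylinder-radius line ρ = R the characteristic of Π reaches 1 and
  the Carlson R_J argument degenerates; points within a relative band of
  10⁻⁷ around ρ = R are clamped onto the band edge. The field varies by
  O(10⁻⁷) relative across the band, far below every tolerance used.
- The spatial Jacobian is assembled in closed form by chain rule using
  dK/dm = (E − (1−m)K)/(2m(1−m)), dE/dm = (E − K)/(2m),
  dΠ/dm = (E/(m−1) + Π)/(2(n−m)) and
  dΠ/dn = (E + (m−n)K/n + (n²−m)Π/n)/(2(m−n)(n−1)). A 4th-order
  finite-difference evaluation of the field exists only in the tests, as an
  independent oracle (agreement ≤ 10⁻⁶ relative at random points).
- The edge ring ρ = R, z = ±L/2 is a true singularity of the field and is
  rejected; points inside the magnet body are rejected.

The magnetisation factor is implemented exactly as the two-branch
linear-with-saturation law: f = 3 below |H| = M_sp/3, f = M_sp/|H| above.
The constant 3 corresponds to the spherical demagnetisation limit of a
high-susceptibility particle; no independent susceptibility parameter
enters below saturation. The particle moment f|H|V is continuous at the
branch point, so the force is continuous along any ray crossing the
saturation surface. Particles are treated as spheres, V = (4/3)πR_NP³.

## One-domain Darcy flow

With the tumour-cell saturation field frozen and the cell phase four
orders of magnitude more viscous than the medium, the cell phase is
immobile and the summed two-phase mass balance reduces to

    ∇·(K_ℓ(x) ∇p_ℓ) = 0,

with K_ℓ = (S^ℓ)^{A_ℓ} k/μ_ℓ inside the spheroid and a calibrated constant
K_free in the free region. Dirichlet pressures are imposed on the inlet and
outlet faces, zero normal flux on the walls.

Key choices:

- **Calibration.** In pure Darcy only the product K_free·∇p is fixed by
  the mean-velocity target, not the pair. The pair is pinned by the second
  observable the study reports: interstitial velocities inside the spheroid
  of the order of nm/s. With Δp = 1 kPa over the 2 mm chamber
  (K_free = 5×10⁻¹⁰ m² Pa⁻¹ s⁻¹) the conjugate-sphere estimate gives
  interior velocities of ≈7 nm/s for the interior conductivity
  1.6×10⁻¹⁵ m² Pa⁻¹ s⁻¹, which the solved fields confirm (7–13 nm/s).
  A smaller Δp would leave the free stream unchanged but push the interior
  into the pm/s range.
- **Interface blending.** The spheroid interface carries a tanh profile of
  half-width 20 µm in all phase fields. Because the conductivity contrast
  spans six decades, K is blended geometrically (log-linearly) in the
  tumour fraction — an arithmetic blend would be dominated by K_free
  through almost the entire band.
- **Interior phase state.** ε = 0.8 and S^ℓ = 0.2 give ε^ℓ = εS^ℓ = 0.16;
  this self-consistent value is the default (a reported alternative of
  0.12 is reachable via the config by lowering S^ℓ).
- **No-slip emulation.** Darcy flow cannot satisfy tangential no-slip at
  the bottom wall. A linear conductivity taper over the lowest 0.3 mm
  (floor 10⁻³) emulates the wall boundary layer; the free-region
  conductivity is boosted by the inverse mean taper factor so the
  cross-section mean velocity stays on target. The taper is on by default
  in the reference scenarios and off for plain solver calls; the empty-
  chamber calibration benchmark runs without it.
- **Discretisation and solver.** Trilinear hexahedral elements on the
  uniform cubic grid. The PDE is homogeneous in K, so the stiffness is
  assembled with K normalised and rescaled to a unit diagonal before the
  Dirichlet rows are added — otherwise the constraint rows (O(1)) drown
  the PDE rows (O(10⁻¹⁴)) and iterative residuals become meaningless.
  Systems up to 40k nodes are solved by sparse LU; larger ones by conjugate
  gradients preconditioned with a geometric multigrid V-cycle (trilinear
  prolongation via Kronecker products, Galerkin coarse operators, damped
  Jacobi smoothing, direct coarsest solve). Relative residuals reach 10⁻¹².
- **Diagnostics.** Boundary fluxes are consistent-residual fluxes (the
  assembled-operator residual summed over a face's nodes), so global
  conservation closes to solver precision by construction; the reported
  mean velocity is measured independently from the nodal −K∇p field at the
  mid-chamber cross-section.

## Nanoparticle transport

The mass-fraction balance combines storage ρεS^ℓ ∂ω/∂t, diffusion
∇·(ρεS^ℓ D ∇ω), non-conservative advection ρ(K∇p)·∇ω and the conservative
magnetophoretic term ∇·(ρ ω 𝓜F). The magnetic term is split into an
advective part (drift 𝓜F, a superficial velocity) and a reaction part
ω ∇·(𝓜F) evaluated per element from the nodal drift — this keeps the
operator linear in ω and SUPG-compatible. The combined advective
coefficient is q + 𝓜F; dividing by εS^ℓ gives the resident velocity used
in the stabilisation parameter

    τ = (c_t/Δt + c_a|a|/h + c_d D/h²)⁻¹,  (c_t, c_a, c_d) = (1, 2, 4).

Boundary conditions: Dirichlet sigmoid at the inlet (zero below one third
of the chamber height, plateau 10⁻⁶ above, logistic width 0.05 mm, midpoint
exactly at H/3), advective do-nothing outflow, natural zero-flux walls.
Wall impenetrability is enforced exactly as in the continuous model: the
wall-normal mobility 𝓜_z ramps to zero at the bottom wall through a C¹
smoothstep over two cell layers, so the wall-normal magnetophoretic flux
vanishes identically. ω starts at zero and is never clipped; undershoot is
a reported diagnostic.

Time stepping is backward Euler with the operator assembled once (flow and
saturations are frozen). The step system is solved by sparse LU up to 60k
nodes; beyond that a Ruiz-equilibrated incomplete-LU/GMRES path exists, and
every step verifies the true relative residual (< 10⁻⁸ enforced, ~10⁻¹⁵
observed on the LU path) so a weak solve cannot pass silently.

The mass ledger is defined on the assembled operator: the stored-mass rate
1ᵀM(ωⁿ⁺¹−ωⁿ)/Δt equals influx (inlet-row residual sum) minus outflux
(total spatial-operator action) up to the linear-solver residual, and the
run metrics report the defect every step. The bottom-wall flux reported per
step is the wall-row residual sum — the discrete statement that the wall
equations contain no boundary-flux term.

## Problem sizes

The production resolution of the study setup is 10 µm (2×10⁶ cells). The
package's working scales are: 20 µm ("desk") for magnetics and flow
benchmarks, and 40 µm ("bench") for transport runs, where the step systems
(34k nodes) factor exactly by sparse LU in seconds and a 20-step capture
run completes in under a minute. All scales share the same assembly code;
only the linear-solver path differs.

## What the benchmarks do and do not show

- The magnetics oracles (on-axis equivalence, dipole far field, ∇·B = 0,
  ∇×H = 0, the force/gradient identity (H·∇)H = ½∇|H|²) validate the
  analytic field implementation to near machine precision. They do not test
  magnet demagnetisation inhomogeneity, which the uniform-magnetisation
  model excludes.
- The conjugate-sphere benchmark (interior velocity 3β/(β+2) of the
  far-field flux) checks the variable-coefficient pressure solve at a
  moderate contrast β = 0.1 within 5 % at 20 µm; the formal second-order
  convergence of the discretisation is verified separately on a smooth-
  coefficient manufactured solution, because the sharp-interface sphere
  limits the observable order.
- The transport manufactured solution measures spatial order ≈1.95 at cell
  Peclet numbers up to ~100 and temporal order ≈1 by Richardson
  comparison. Conservation and wall impermeability are exact-by-
  construction properties and are asserted to 10⁻¹⁰ or tighter.
- The capture-pattern check (scenario d at t = 20 s) is qualitative: the
  near-wall concentration maximum lies inside the magnet footprint at the
  drift stagnation point on the magnet axis, and a concentration ring forms
  around the bottom-seated spheroid.

## Known limitations

- The physical wall-accumulation layer has thickness D/u_mag ≈ 0.4 µm —
  below any practical grid. The discrete solution concentrates the
  captured mass into the lowest cell layer, so the peak value and the
  local undershoot of the non-monotone SUPG scheme both scale with the
  (unresolved) layer: undershoot relative to the inlet plateau is large
  near the wall peak, while on resolved fronts (magnet far away) it stays
  below 1 %. A discontinuity-capturing term or an adsorbed-mass surface
  variable would be the principled fixes; both are out of scope.
- Along the frictionless wall the tangential mobility stays finite, so
  deposited particles slide to the in-plane drift stagnation point at the
  magnet axis and the time-integrated deposit peaks there; the upstream
  bias of the arriving plume is visible in particle characteristics and in
  the transient concentration field, not in the long-time deposit
  location.
- Steady flow, frozen saturations, rigid ECM, no particle aggregation,
  no cellular uptake, no gravity — in line with the modelled test setup.
  Transient saturation dynamics and Navier–Stokes free flow are out of
  scope.
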