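"""SUPG-stabilised transport of the nanoparticle mass fraction.

The mass fraction omega of nanoparticles in the culture medium obeys a
Smoluchowski advection-diffusion balance with three fluxes: Fickian
diffusion, advection with the medium, and magnetophoresis,

    rho eps S_l  d(omega)/dt
      - div( rho eps S_l D grad omega )
      - rho (K_l grad p) . grad omega
      + div( rho omega M F_mag ) = 0.

The magnetophoretic term is split into an advective part (drift velocity
M F_mag) and a reaction part omega * div(M F_mag), which keeps the operator
linear in omega.  The combined advective coefficient is therefore the
superficial flux q = -K grad p plus the superficial drift M F_mag.

M is the diagonal mobility tensor: Stokes mobility 1/(6 pi mu_l R_NP)
scaled by the relative mobility (S_l)^{A_l}, with the wall-normal entry M_z
ramped to zero at the impenetrable bottom wall through a C^1 smoothstep over
a band of a few cells.  The degenerate mobility is what makes the wall
impenetrable to magnetophoresis: no extra boundary condition is imposed.

Discretisation: trilinear hexahedral elements, backward Euler in time, and
streamline-upwind Petrov-Galerkin (SUPG) stabilisation with the inverse-sum
stabilisation parameter

    tau = ( c_t/dt + c_a |a|/h + c_d D/h^2 )^{-1},   (c_t, c_a, c_d) = (1, 2, 4),

where |a| is the resident advective speed (superficial coefficient divided
by eps S_l).  The mass-fraction field is not clipped: any undershoot from
the non-monotone stabilised scheme is reported as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _fem
from .grid import StructuredGrid
from .porous_flow import PhaseFields, PhaseParams

__all__ = [
    "WallSpec",
    "TransportBC",
    "TransportState",
    "TransportSystem",
    "stokes_mobility",
    "mobility_field",
    "supg_tau",
    "assemble_transport_operator",
    "advance",
    "solve_steady",
    "total_np_mass",
    "run_simulation",
]

SUPG_CONSTANTS = (1.0, 2.0, 4.0)  # (c_t, c_a, c_d)


@dataclass(frozen=True)
class WallSpec:
    """Wall-degenerate mobility: which walls are impenetrable and the band.

    ``band_cells`` is the thickness (in cell layers) of the C^1 smoothstep
    ramp from zero wall-normal mobility to the bulk value.
    """

    bottom: bool = True
    band_cells: float = 2.0


@dataclass
class TransportState:
    """Nanoparticle mass-fraction field and simulation clock."""

    omega: np.ndarray
    time: float = 0.0

    @property
    def undershoot(self) -> float:
        return float(min(self.omega.min(), 0.0))


@dataclass(frozen=True)
class TransportBC:
    """Inlet Dirichlet profile; walls zero-flux; outlet advective outflow.

    ``inlet_profile`` maps (y, z) on the inlet face to the prescribed mass
    fraction.
    """

    inlet_profile: Optional[Callable] = None  # None: fully closed domain


def stokes_mobility(viscosity: float, particle_radius: float) -> float:
    """Scalar Stokes-drag mobility 1/(6 pi mu R) [m N^-1 s^-1]."""
    if viscosity <= 0 or particle_radius <= 0:
        raise ValueError("viscosity and particle radius must be positive")
    return 1.0 / (6.0 * np.pi * viscosity * particle_radius)


def _smoothstep(s):
    s = np.clip(s, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def mobility_field(
    grid: StructuredGrid,
    s_l: np.ndarray,
    exponent: float,
    wall: WallSpec = WallSpec(),
    viscosity: float = 1e-3,
    particle_radius: float = 100e-9,
) -> np.ndarray:
    """Diagonal nanoparticle mobility per node, shape (n_nodes, 3).

    Bulk entries are the Stokes mobility times the relative mobility
    (S_l)^{A_l}; the z entry ramps to zero at the bottom wall.
    """
    m0 = stokes_mobility(viscosity, particle_radius)
    m_rel = np.asarray(s_l, dtype=float) ** exponent
    bulk = m0 * m_rel
    M = np.repeat(bulk[:, None], 3, axis=1)
    if wall.bottom:
        z = grid.nodes[:, 2]
        delta = wall.band_cells * grid.spacing
        M[:, 2] = bulk * _smoothstep(z / delta)
    return M


def supg_tau(h, a_mag, diffusion, dt=None, constants=SUPG_CONSTANTS):
    """Inverse-sum SUPG stabilisation parameter [s].

    tau = (c_t/dt + c_a a/h + c_d D/h^2)^{-1}; the transient term is dropped
    when ``dt`` is None (steady problems).
    """
    c_t, c_a, c_d = constants
    if h <= 0 or (dt is not None and dt <= 0):
        raise ValueError("h and dt must be positive")
    a_mag = np.asarray(a_mag, dtype=float)
    inv = c_a * a_mag / h + c_d * np.asarray(diffusion) / h**2
    if dt is not None:
        inv = inv + c_t / dt
    with np.errstate(divide="ignore"):
        tau = np.where(inv > 0, 1.0 / np.where(inv > 0, inv, 1.0), np.inf)
    return float(tau) if tau.ndim == 0 else tau


@dataclass
class TransportSystem:
    """Assembled backward-Euler SUPG system (constant while the flow is frozen)."""

    grid: StructuredGrid
    dt: float
    mass_matrix: sp.csr_matrix  # Galerkin + SUPG mass (rho eps S_l weighted)
    spatial_matrix: sp.csr_matrix  # diffusion + advection + reaction + SUPG
    step_matrix: sp.csr_matrix  # mass/dt + spatial, unconstrained
    dirichlet_nodes: np.ndarray
    dirichlet_values: np.ndarray
    source_weights: np.ndarray  # (E, 8) load weights incl. SUPG test
    scale: float  # equilibration factor applied to the constrained system
    solver: object = None
    constrained_matrix: sp.csr_matrix = None
    mass_vector: np.ndarray = None  # 1^T (Galerkin mass): physical quadrature
    wall_nodes: np.ndarray = None  # bottom-face nodes excluding Dirichlet ones


def _element_divergence(grid: StructuredGrid, vec_nodal: np.ndarray) -> np.ndarray:
    """Cell-centred divergence of a nodal vector field."""
    div = np.zeros(grid.n_cells)
    for d in range(3):
        div += _fem.element_gradient(grid, vec_nodal[:, d])[:, d]
    return div


def assemble_transport_operator(
    grid: StructuredGrid,
    flow: PhaseFields,
    mobility: np.ndarray,
    force: np.ndarray,
    diffusion: float,
    dt: float,
    bc: TransportBC,
    density: float = 1e3,
    supg: bool = True,
    dirichlet=None,
) -> TransportSystem:
    """Build the backward-Euler SUPG system for the mass-fraction update.

    ``flow`` must carry solved pressure/flux fields; ``mobility`` and
    ``force`` are nodal (n_nodes, 3) arrays.  The returned system is reused
    for every step because saturations and flow are frozen.

    ``dt=None`` assembles the steady operator (no transient term, no
    transient contribution to tau); use :func:`solve_steady` on it.
    ``dirichlet=(nodes, values)`` overrides the inlet-face constraint, e.g.
    to pin every boundary node in manufactured-solution studies.
    """
    B = _fem.element_blocks(grid.spacing)
    conn = grid.cell_nodes
    eps_s = grid.cell_mean(flow.porosity * flow.s_l)
    c = density * eps_s  # mass coefficient
    d = density * eps_s * diffusion

    drift = mobility * force  # superficial magnetophoretic drift [m/s]
    q_elem = np.stack(
        [_fem.element_gradient(grid, flow.pressure)[:, i] for i in range(3)], axis=1
    )
    k_elem = grid.cell_mean(flow.conductivity)
    q_elem = -k_elem[:, None] * q_elem
    a = q_elem + drift[conn].mean(axis=1)  # combined superficial advective coeff
    r = density * _element_divergence(grid, drift)  # reaction coefficient

    a_res = a / eps_s[:, None]  # resident advective velocity
    a_mag = np.linalg.norm(a_res, axis=1)
    tau = supg_tau(grid.spacing, a_mag, diffusion, dt) if supg else np.zeros_like(a_mag)

    E = grid.n_cells
    # Galerkin blocks
    elem_mass = c[:, None, None] * B["NN"]
    elem_A = d[:, None, None] * B["GG"]
    elem_A = elem_A + density * np.einsum("ed,dij->eij", a, B["NG"])
    elem_A = elem_A + r[:, None, None] * B["NN"]
    if supg:
        # SUPG perturbation of the test function: tau (a_res . grad v)
        test = np.einsum("ed,dij->eij", a_res, B["GN"])  # (E,8,8): (a.grad Ni) Nj
        adv2 = np.einsum("ed,ef,dfij->eij", a_res, a, B["GdG"])  # (a.grad Ni)(a.grad Nj)
        elem_mass = elem_mass + (tau * c)[:, None, None] * test
        elem_A = elem_A + density * tau[:, None, None] * adv2
        elem_A = elem_A + (tau * r)[:, None, None] * test
        src_w = B["N1"][None, :] + tau[:, None] * np.einsum("ed,di->ei", a_res, B["G1"])
    else:
        src_w = np.broadcast_to(B["N1"], (E, 8)).copy()

    M = _fem.assemble_csr(grid, elem_mass)
    A = _fem.assemble_csr(grid, elem_A)
    S = A.copy() if dt is None else (M / dt + A).tocsr()

    if dirichlet is not None:
        inlet, vals = np.asarray(dirichlet[0]), np.asarray(dirichlet[1], float)
    elif bc.inlet_profile is None:
        inlet = np.empty(0, dtype=int)
        vals = np.empty(0)
    else:
        inlet = grid.boundary_nodes("x-")
        pts = grid.nodes[inlet]
        vals = np.asarray(bc.inlet_profile(pts[:, 1], pts[:, 2]), dtype=float)
        vals = np.broadcast_to(vals, inlet.shape).copy()

    scale = 1.0 / np.abs(S.diagonal()).max()
    mass_vec = _fem.scatter_vector(grid, c[:, None] * np.broadcast_to(B["N1"], (E, 8)))
    wall = np.setdiff1d(grid.boundary_nodes("z-"), inlet)

    return TransportSystem(
        grid=grid,
        dt=dt,
        mass_matrix=M,
        spatial_matrix=A,
        step_matrix=S,
        dirichlet_nodes=inlet,
        dirichlet_values=vals,
        source_weights=src_w,
        scale=scale,
        mass_vector=mass_vec,
        wall_nodes=wall,
    )


def _constrained(system: TransportSystem) -> sp.csr_matrix:
    if system.constrained_matrix is None:
        S = (system.scale * system.step_matrix).tolil()
        mask = np.zeros(S.shape[0], dtype=bool)
        mask[system.dirichlet_nodes] = True
        keep = sp.diags((~mask).astype(float))
        Sc = (keep @ S.tocsr() + sp.diags(mask.astype(float))).tocsr()
        system.constrained_matrix = Sc
    return system.constrained_matrix


class _EquilibratedILU:
    """Ruiz-equilibrated ILU + GMRES for transport systems too large for LU.

    The wall-accumulation reaction makes the operator badly scaled between
    the spheroid interior and the free stream; symmetric (Ruiz) row/column
    equilibration restores usable pivots for the incomplete factorisation.
    The caller verifies the true residual, so a weak factorisation surfaces
    as an error rather than silent inaccuracy.
    """

    def __init__(self, Sc: sp.csr_matrix):
        A = Sc.copy()
        n = A.shape[0]
        r = np.ones(n)
        c = np.ones(n)
        for _ in range(6):
            Aa = abs(A)
            rn = np.sqrt(Aa.max(axis=1).toarray().ravel())
            A = sp.diags(1.0 / rn) @ A
            cn = np.sqrt(Aa.max(axis=0).toarray().ravel())
            A = A @ sp.diags(1.0 / cn)
            r *= rn
            c *= cn
        self.A = A.tocsr()
        self.r, self.c = r, c
        self.ilu = spla.spilu(A.tocsc(), drop_tol=1e-5, fill_factor=10)
        self.M = spla.LinearOperator(A.shape, self.ilu.solve)

    def solve(self, b: np.ndarray) -> np.ndarray:
        y, _ = spla.gmres(
            self.A, b / self.r, rtol=1e-13, restart=200, maxiter=5, M=self.M
        )
        return y / self.c


def _solver(system: TransportSystem):
    if system.solver is None:
        Sc = _constrained(system)
        if Sc.shape[0] <= 60_000:
            system.solver = spla.splu(Sc.tocsc())
        else:
            system.solver = _EquilibratedILU(Sc)
    return system.solver


def advance(
    state: TransportState,
    system: TransportSystem,
    source: Optional[np.ndarray] = None,
) -> tuple:
    """One backward-Euler step; returns (new_state, step_diagnostics).

    ``source`` is an optional nodal volumetric source [1/s, mass-fraction
    rate scaled by rho eps S_l] evaluated at the new time level.

    The step diagnostics carry the consistent-residual boundary fluxes: the
    discrete ledger  d(stored)/dt = influx - outflux  closes to the linear-
    solver tolerance by construction.
    """
    if system.dt is None:
        raise ValueError("system was assembled steady (dt=None); use solve_steady")
    grid = system.grid
    b = system.mass_matrix @ state.omega / system.dt
    if source is not None:
        s_elem = grid.cell_mean(np.asarray(source, float))
        b = b + _fem.scatter_vector(grid, s_elem[:, None] * system.source_weights)
    bs = system.scale * b
    bs[system.dirichlet_nodes] = system.dirichlet_values
    solver = _solver(system)
    omega = solver.solve(bs)
    Sc = _constrained(system)
    res = np.linalg.norm(Sc @ omega - bs) / max(np.linalg.norm(bs), 1e-300)
    if res > 1e-8:
        raise RuntimeError(f"transport step failed to converge (relative residual {res:.2e})")

    # consistent-residual mass ledger on the full (unconstrained) system
    r_full = system.step_matrix @ omega - b
    influx = float(r_full[system.dirichlet_nodes].sum())
    stored_rate = float(np.sum(system.mass_matrix @ (omega - state.omega))) / system.dt
    outflux = float(np.sum(system.spatial_matrix @ omega))
    diag = {
        "residual": res,
        "influx": influx,
        "outflux": outflux,
        "stored_rate": stored_rate,
        "ledger_defect": stored_rate - (influx - outflux),
        # total discrete normal flux through the bottom wall: the wall rows
        # carry no boundary-flux term, so their residual sum is the flux
        "bottom_flux": float(r_full[system.wall_nodes].sum()),
    }
    return TransportState(omega=omega, time=state.time + system.dt), diag


def solve_steady(system: TransportSystem, source: Optional[np.ndarray] = None) -> np.ndarray:
    """Solve the steady transport problem A omega = F for a nodal source."""
    grid = system.grid
    b = np.zeros(grid.n_nodes)
    if source is not None:
        s_elem = grid.cell_mean(np.asarray(source, float))
        b = _fem.scatter_vector(grid, s_elem[:, None] * system.source_weights)
    bs = system.scale * b
    bs[system.dirichlet_nodes] = system.dirichlet_values
    return _solver(system).solve(bs)


def total_np_mass(
    state: TransportState,
    grid: StructuredGrid,
    porosity: np.ndarray,
    s_l: np.ndarray,
    density: float = 1e3,
) -> float:
    """Total nanoparticle mass [kg]: trilinear quadrature of rho eps S_l omega."""
    B = _fem.element_blocks(grid.spacing)
    c = density * grid.cell_mean(np.asarray(porosity) * np.asarray(s_l))
    w_elem = state.omega[grid.cell_nodes] @ B["N1"]
    return float(np.sum(c * w_elem))


def run_simulation(
    config,
    t_end: Optional[float] = None,
    output_every: int = 0,
    snapshot_callback: Optional[Callable] = None,
    supg: bool = True,
):
    """Full pipeline for one scenario: flow solve, then transport stepping.

    Returns ``(metrics, state, fields)`` where ``metrics`` is a DataFrame
    with one row per step (time, total mass, boundary fluxes, ledger defect,
    undershoot, extrema and argmax location) and ``fields`` the solved
    PhaseFields.  ``snapshot_callback(step, state, fields)`` is invoked every
    ``output_every`` steps when set.
    """
    from . import scenarios as _sc
    from .magnetics import sample_force_field
    from .porous_flow import WallTaper, solve_flow

    grid = _sc.build_grid(config)
    if config.spheroid_radius is None:
        fields = PhaseFields.free_chamber(grid)
    else:
        fields = _sc.spheroid_phase_fields(
            grid, config.spheroid_radius, config.spheroid_position
        )
    params = _sc.effective_phase_params(config, grid)
    taper = WallTaper() if config.wall_taper else None
    fields = solve_flow(fields, params, config.flow_bc, wall_taper=taper)

    mob = mobility_field(
        grid,
        fields.s_l,
        params.exponent_medium,
        viscosity=params.viscosity_medium,
        particle_radius=config.particle.radius,
    )
    force = sample_force_field(grid, config.magnet, config.particle)
    bc = TransportBC(inlet_profile=lambda y, z: _sc.inflow_profile(y, z, config))
    system = assemble_transport_operator(
        grid,
        fields,
        mob,
        force,
        config.particle.diffusion,
        config.dt,
        bc,
        density=params.density_medium,
        supg=supg,
    )

    state = TransportState(omega=np.zeros(grid.n_nodes), time=0.0)
    t_final = config.t_end if t_end is None else t_end
    n_steps = int(round(t_final / config.dt))
    rows = []
    for step in range(1, n_steps + 1):
        state, diag = advance(state, system)
        omega3 = grid.reshape_nodal(state.omega)
        kmax = np.unravel_index(np.argmax(omega3), omega3.shape)
        x, y, z = (grid.axes[i][kmax[i]] for i in range(3))
        rows.append(
            {
                "t": state.time,
                "total_mass": total_np_mass(state, grid, fields.porosity, fields.s_l, params.density_medium),
                "influx": diag["influx"],
                "outflux": diag["outflux"],
                "ledger_defect": diag["ledger_defect"],
                "bottom_flux": diag["bottom_flux"],
                "min_omega": float(state.omega.min()),
                "max_omega": float(state.omega.max()),
                "argmax_x": x,
                "argmax_y": y,
                "argmax_z": z,
            }
        )
        if output_every and snapshot_callback and step % output_every == 0:
            snapshot_callback(step, state, fields)
    return pd.DataFrame(rows), state, fields
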