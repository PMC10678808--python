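"""One-domain steady multiphase Darcy flow through the chamber and spheroid.

The chamber and the spheroid are treated as a single porous-media domain.
Inside the spheroid the culture medium flows through the extracellular
matrix with conductivity

    K_l = k_rel^l k / mu_l,     k_rel^l = (S_l)^{A_l},

while in the free region the hydraulic conductivity K_free and the imposed
pressure drop are calibrated jointly so that the mean medium velocity
matches the perfusion target (0.25 mm/s by default).  The tumour-cell phase
is four orders of magnitude more viscous than the medium and its saturation
field is frozen, so it is treated as immobile and the summed two-phase
pressure equation reduces to a single variable-coefficient Poisson problem

    div( K_l(x) grad p_l ) = 0

with Dirichlet pressures at the inlet/outlet faces and zero normal flux on
the walls.  Discretisation is by trilinear hexahedral finite elements on the
structured grid; the SPD system is solved directly at small sizes and by
geometric-multigrid-preconditioned conjugate gradients above.

Because the conductivity contrast between the free region and the spheroid
interior spans many decades, the interface band blends conductivity
geometrically (log-linearly) in the tumour fraction, which keeps the blend
monotone and free of overshoot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _fem
from ._mg import MGSolver
from .grid import StructuredGrid

__all__ = [
    "PhaseParams",
    "PhaseFields",
    "FlowBC",
    "WallTaper",
    "relative_permeability",
    "conductivity_field",
    "solve_flow",
    "calibrate_free_flow",
    "solve_pressure",
    "darcy_velocity",
    "flow_diagnostics",
]


@dataclass(frozen=True)
class PhaseParams:
    """Fluid-phase and ECM parameters (strict SI).

    Defaults: medium density/viscosity of water-like culture medium, tumour
    cells as a highly viscous fluid, ECM intrinsic permeability 1e-9 mm^2
    = 1e-15 m^2, relative-permeability exponents A_l = 4, A_t = 2.
    """

    density_medium: float = 1e3  # rho_l [kg m^-3]
    density_tumour: float = 1e3  # rho_t [kg m^-3]
    viscosity_medium: float = 1e-3  # mu_l [Pa s]
    viscosity_tumour: float = 20.0  # mu_t [Pa s]
    intrinsic_permeability: float = 1e-15  # k [m^2]
    exponent_medium: float = 4.0  # A_l
    exponent_tumour: float = 2.0  # A_t
    free_conductivity: float = 5e-10  # K_free [m^2 Pa^-1 s^-1], see calibrate_free_flow

    def __post_init__(self):
        for name in (
            "density_medium",
            "density_tumour",
            "viscosity_medium",
            "viscosity_tumour",
            "intrinsic_permeability",
            "exponent_medium",
            "exponent_tumour",
            "free_conductivity",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PhaseFields:
    """Nodal phase fields over a grid.

    ``tumour_fraction`` is the smooth indicator (1 inside the spheroid,
    0 in the free region, blended across the interface band) used to place
    the conductivity between its interior and free-region values.
    """

    grid: StructuredGrid
    porosity: np.ndarray  # eps(x)
    s_l: np.ndarray  # medium saturation
    s_t: np.ndarray  # tumour-cell saturation
    tumour_fraction: np.ndarray
    conductivity: Optional[np.ndarray] = None  # K_l(x) [m^2 Pa^-1 s^-1]
    pressure: Optional[np.ndarray] = None  # p_l(x) [Pa]
    flux: Optional[np.ndarray] = None  # superficial q = -K grad p [m s^-1]
    velocity: Optional[np.ndarray] = None  # phase velocity u_l = q/(eps S_l)

    def validate(self):
        if np.any(np.abs(self.s_l + self.s_t - 1.0) > 1e-12):
            raise ValueError("saturations must sum to one")
        if np.any((self.porosity <= 0) | (self.porosity > 1.0 + 1e-12)):
            raise ValueError("porosity must lie in (0, 1]")

    @classmethod
    def free_chamber(cls, grid: StructuredGrid) -> "PhaseFields":
        """Empty chamber: medium is the only phase everywhere."""
        n = grid.n_nodes
        one = np.ones(n)
        return cls(
            grid=grid,
            porosity=one.copy(),
            s_l=one.copy(),
            s_t=np.zeros(n),
            tumour_fraction=np.zeros(n),
        )


@dataclass(frozen=True)
class FlowBC:
    """Dirichlet pressures at the inlet (x-) and outlet (x+) faces [Pa]."""

    inlet_pressure: float = 1000.0
    outlet_pressure: float = 0.0

    def __post_init__(self):
        if self.inlet_pressure < self.outlet_pressure:
            raise ValueError("inlet pressure must be >= outlet pressure for forward flow")

    @property
    def delta_p(self) -> float:
        return self.inlet_pressure - self.outlet_pressure


@dataclass(frozen=True)
class WallTaper:
    """Near-wall conductivity damping emulating the no-slip bottom wall.

    Pure Darcy flow slips along walls; the physical chamber has a no-slip
    bottom, with a boundary layer visible in the measured velocity field.
    Tapering the conductivity linearly from ``floor`` (relative) at z = 0 to
    1 over ``band`` reproduces the vanishing near-wall velocity without
    leaving the one-domain formulation.
    """

    band: float = 0.3e-3  # [m]
    floor: float = 1e-3  # relative conductivity at the wall

    def factor(self, z):
        z = np.asarray(z, dtype=float)
        return np.clip(z / self.band, self.floor, 1.0)


def relative_permeability(saturation, exponent):
    """Power-law relative permeability k_rel = S^A."""
    S = np.asarray(saturation, dtype=float)
    if np.any((S < 0) | (S > 1)):
        raise ValueError("saturation must lie in [0, 1]")
    if exponent <= 0:
        raise ValueError("relative-permeability exponent must be positive")
    out = S**exponent
    return float(out) if out.ndim == 0 else out


def conductivity_field(
    fields: PhaseFields, params: PhaseParams, wall_taper: Optional[WallTaper] = None
) -> np.ndarray:
    """Nodal medium conductivity K_l(x).

    Interior: (S_l)^{A_l} k / mu_l; free region: the calibrated K_free;
    interface band: geometric blend weighted by the tumour fraction, stored
    on ``fields.conductivity`` and returned.  ``wall_taper`` optionally damps
    the conductivity near the bottom wall (no-slip emulation).
    """
    fields.validate()
    k_in = (
        relative_permeability(fields.s_l, params.exponent_medium)
        * params.intrinsic_permeability
        / params.viscosity_medium
    )
    w = np.clip(fields.tumour_fraction, 0.0, 1.0)
    logK = (1.0 - w) * np.log(params.free_conductivity) + w * np.log(
        np.maximum(k_in, 1e-300)
    )
    K = np.exp(logK)
    if wall_taper is not None:
        K = K * wall_taper.factor(fields.grid.nodes[:, 2])
    fields.conductivity = K
    return K


def calibrate_free_flow(target_u: float, domain_length: float, delta_p: float) -> float:
    """Free-region conductivity reproducing a target mean velocity.

    In an empty chamber the pressure is linear, so the Darcy closed form
    u = K dp / L inverts to K_free = u L / dp.  The pressure drop is a free
    scale of the model; it is pinned jointly with K_free (see docs).
    """
    if target_u == 0:
        return 0.0
    if delta_p <= 0:
        raise ValueError("a positive pressure drop is required for a nonzero target velocity")
    return target_u * domain_length / delta_p


def _solve_spd(grid: StructuredGrid, A: sp.csr_matrix, b: np.ndarray) -> np.ndarray:
    """Solve an equilibrated SPD system: direct at small n, multigrid-CG above."""
    if A.shape[0] <= 40_000:
        return spla.spsolve(A.tocsc(), b)
    return MGSolver(A, grid.n_nodes_axis, symmetric=True).solve(b, rtol=1e-12)


def solve_pressure(grid: StructuredGrid, conductivity, bc: FlowBC):
    """Solve div(K grad p) = 0 with Dirichlet inlet/outlet, no-flux walls.

    ``conductivity`` may be nodal (averaged onto cells) or per-cell.
    """
    K = np.asarray(conductivity, dtype=float)
    if K.shape == (grid.n_nodes,):
        k_elem = grid.cell_mean(K)
    elif K.shape == (grid.n_cells,):
        k_elem = K
    else:
        raise ValueError("conductivity must be nodal or per-cell")
    if np.any(k_elem <= 0):
        raise ValueError("conductivity must be positive everywhere")

    # div(K grad p) = 0 is homogeneous in K: normalise and rescale the
    # stiffness to a unit diagonal so Dirichlet identity rows and PDE rows
    # carry comparable weight (keeps iterative residual tolerances honest)
    A = _fem.stiffness(grid, k_elem / k_elem.max())
    A = (1.0 / A.diagonal().max()) * A
    b = np.zeros(grid.n_nodes)
    inlet = grid.boundary_nodes("x-")
    outlet = grid.boundary_nodes("x+")
    nodes = np.concatenate([inlet, outlet])
    values = np.concatenate(
        [np.full(inlet.size, bc.inlet_pressure), np.full(outlet.size, bc.outlet_pressure)]
    )
    Ad, bd = _fem.apply_dirichlet(A, b, nodes, values)
    return _solve_spd(grid, Ad, bd)


def darcy_velocity(
    grid: StructuredGrid,
    pressure: np.ndarray,
    conductivity: np.ndarray,
    porosity: np.ndarray,
    s_l: np.ndarray,
):
    """Superficial flux q = -K grad p and phase velocity u_l = q/(eps S_l).

    Gradients are second-order nodal central differences on the structured
    grid.  Returns ``(q, u_l)``, both (n_nodes, 3) in m/s.
    """
    eps_s = np.asarray(porosity) * np.asarray(s_l)
    if np.any(eps_s <= 0):
        raise ValueError("porosity * saturation must be positive everywhere")
    gradp = grid.nodal_gradient(pressure)
    q = -np.asarray(conductivity)[:, None] * gradp
    return q, q / eps_s[:, None]


def solve_flow(
    fields: PhaseFields,
    params: PhaseParams,
    bc: FlowBC,
    wall_taper: Optional[WallTaper] = None,
) -> PhaseFields:
    """Conductivity + pressure + velocity in one call; fills the field struct."""
    K = conductivity_field(fields, params, wall_taper)
    fields.pressure = solve_pressure(fields.grid, K, bc)
    fields.flux, fields.velocity = darcy_velocity(
        fields.grid, fields.pressure, K, fields.porosity, fields.s_l
    )
    return fields


def flow_diagnostics(
    grid: StructuredGrid, pressure: np.ndarray, conductivity, bc: FlowBC
) -> pd.DataFrame:
    """Boundary-flux report from the consistent FEM residual.

    The residual r = A p of the unconstrained stiffness, summed over a
    Dirichlet face's nodes, is the discrete outward flux through that face
    [m^3/s]; its global sum measures the conservation imbalance.  Also
    reports the cross-section-averaged x-velocity at mid-chamber.
    """
    K = np.asarray(conductivity, dtype=float)
    if K.shape != (grid.n_nodes,):
        raise ValueError("flow_diagnostics expects a nodal conductivity field")
    A = _fem.stiffness(grid, grid.cell_mean(K))
    r = A @ pressure
    inlet = grid.boundary_nodes("x-")
    outlet = grid.boundary_nodes("x+")
    influx = float(r[inlet].sum())  # flux entering through the inlet
    outflux = -float(r[outlet].sum())  # flux leaving through the outlet
    imbalance = influx - outflux
    area = grid.extents[1] * grid.extents[2]
    # mean x-velocity over the mid-chamber cross-section
    gradp = grid.nodal_gradient(pressure)
    qx3 = grid.reshape_nodal(-K * gradp[:, 0])
    mean_u = float(qx3[grid.n_nodes_axis[0] // 2].mean())
    rows = [
        ("influx_m3_s", influx),
        ("outflux_m3_s", outflux),
        ("imbalance_m3_s", imbalance),
        ("relative_imbalance", imbalance / influx if influx != 0 else 0.0),
        ("mean_velocity_mid_m_s", mean_u),
        ("mean_velocity_mid_mm_s", mean_u * 1e3),
        ("inlet_area_m2", area),
    ]
    return pd.DataFrame(rows, columns=["quantity", "value"])
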