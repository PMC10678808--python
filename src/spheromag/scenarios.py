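"""Reference configurations of the spheroid-in-flow-chamber experiment.

The chamber is a 2 mm x 1 mm x 1 mm box perfused along x at a mean medium
velocity of 0.25 mm/s.  Four reference configurations combine two spheroid
sizes (radius ~200 um and ~340 um) with two positions (centred in the
chamber, or lying on the bottom wall).  A cylindrical permanent magnet
(R = 0.5 mm, L = 1 mm, M_s = 1e6 A/m) sits below the chamber, axis vertical,
its top face 0.25 mm beneath the bottom wall and its axis through
(x, y) = (1.0, 0.5) mm.  Nanoparticles enter at the inlet with a sigmoid
mass-fraction profile: zero over the lower third of the inlet face, plateau
1e-6 above.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid import StructuredGrid
from .magnetics import CylMagnet, ParticleSpec
from .porous_flow import FlowBC, PhaseFields, PhaseParams

__all__ = [
    "ScenarioConfig",
    "GRID_PRESETS",
    "build_grid",
    "spheroid_phase_fields",
    "inflow_profile",
    "reference_scenarios",
    "reference_magnet",
    "reference_particle",
]

#: Grid spacings [m] of the named presets.  "paper" reproduces the
#: ~2e6-element production resolution; "desk" is the workstation-scale
#: default used throughout the tests; "coarse" is for smoke tests.
GRID_PRESETS = {"paper": 10e-6, "desk": 20e-6, "bench": 40e-6, "coarse": 50e-6}

DOMAIN_EXTENTS = (2e-3, 1e-3, 1e-3)

#: Interior phase state of the spheroid: porosity 0.8, tumour-cell
#: saturation 0.8, medium saturation 0.2.
INTERIOR_POROSITY = 0.8
INTERIOR_S_T = 0.8

#: Half-width of the tanh blend across the spheroid interface [m].
INTERFACE_HALFWIDTH = 20e-6

#: Inlet sigmoid: breakpoint at one third of the chamber height, width [m],
#: plateau mass fraction.
SIGMOID_WIDTH = 0.05e-3
OMEGA_MAX = 1e-6


def reference_magnet() -> CylMagnet:
    """Cylindrical magnet posed below the chamber.

    The magnet axis is vertical through (1.0, 0.5) mm; the top face sits
    0.25 mm below the bottom wall, so the centre is at z = -(0.25 + L/2) mm.
    """
    return CylMagnet(
        magnetisation=1e6,
        radius=0.5e-3,
        length=1e-3,
        centre=(1.0e-3, 0.5e-3, -0.75e-3),
        axis=(0.0, 0.0, 1.0),
    )


def reference_particle() -> ParticleSpec:
    """100 nm SPIONs: D = 2.5e-10 m^2/s, M_sp = 4.78e5 A/m."""
    return ParticleSpec(
        radius=100e-9, diffusion=2.5e-10, saturation_magnetisation=4.78e5
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """One complete flow-chamber configuration."""

    name: str
    spheroid_radius: float  # [m]
    spheroid_position: str  # "centred" | "bottom"
    grid_preset: str = "desk"
    spacing: float = None  # overrides the preset when set [m]
    magnet: CylMagnet = field(default_factory=reference_magnet)
    particle: ParticleSpec = field(default_factory=reference_particle)
    phase_params: PhaseParams = field(default_factory=PhaseParams)
    target_velocity: float = 0.25e-3  # mean medium velocity [m/s]
    delta_p: float = 1000.0  # inlet-outlet pressure drop [Pa]
    omega_max: float = OMEGA_MAX
    wall_taper: bool = True  # no-slip emulation at the bottom wall
    dt: float = 1.0  # [s]
    t_end: float = 100.0  # [s]

    def __post_init__(self):
        if self.spheroid_position not in ("centred", "bottom"):
            raise ValueError("spheroid position must be 'centred' or 'bottom'")
        if self.spacing is None and self.grid_preset not in GRID_PRESETS:
            raise ValueError(f"unknown grid preset {self.grid_preset!r}")
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("time step and end time must be positive")
        if self.spheroid_radius is not None:
            R = self.spheroid_radius
            cz = self.spheroid_centre[2]
            Lx, Ly, Lz = DOMAIN_EXTENTS
            if R <= 0:
                raise ValueError("spheroid radius must be positive")
            if (
                self.spheroid_centre[0] - R < 0
                or self.spheroid_centre[0] + R > Lx
                or self.spheroid_centre[1] - R < 0
                or self.spheroid_centre[1] + R > Ly
                or cz - R < -1e-12
                or cz + R > Lz
            ):
                raise ValueError("spheroid must lie inside the chamber (tangency allowed)")

    @property
    def grid_spacing(self) -> float:
        return self.spacing if self.spacing is not None else GRID_PRESETS[self.grid_preset]

    @property
    def spheroid_centre(self) -> tuple:
        Lx, Ly, Lz = DOMAIN_EXTENTS
        if self.spheroid_position == "centred":
            return (Lx / 2, Ly / 2, Lz / 2)
        # "bottom": sphere tangent to the wall
        return (Lx / 2, Ly / 2, self.spheroid_radius)

    @property
    def flow_bc(self) -> FlowBC:
        return FlowBC(inlet_pressure=self.delta_p, outlet_pressure=0.0)

    def with_spacing(self, spacing: float) -> "ScenarioConfig":
        return replace(self, spacing=spacing)


def build_grid(config: ScenarioConfig) -> StructuredGrid:
    """Cubic-cell grid over the chamber; z = 0 at the bottom wall."""
    return StructuredGrid(extents=DOMAIN_EXTENTS, spacing=config.grid_spacing)


def spheroid_phase_fields(
    grid: StructuredGrid, radius: float, position: str, centre=None
) -> PhaseFields:
    """Porosity/saturation fields of a spheroid blended into the free chamber.

    Inside: (eps, S_t, S_l) = (0.8, 0.8, 0.2); outside: (1, 0, 1).  The
    interface is a tanh profile of half-width 20 um in the signed distance,
    stored as the smooth ``tumour_fraction`` indicator.
    """
    if centre is None:
        cfg = ScenarioConfig(name="_tmp", spheroid_radius=radius, spheroid_position=position)
        centre = cfg.spheroid_centre
    centre = np.asarray(centre, float)
    Lx, Ly, Lz = grid.extents
    if (
        np.any(centre - radius < -1e-12)
        or centre[0] + radius > Lx
        or centre[1] + radius > Ly
        or centre[2] + radius > Lz
    ):
        raise ValueError("spheroid intersects a chamber boundary beyond tangency")
    d = np.linalg.norm(grid.nodes - centre, axis=1) - radius
    w = 0.5 * (1.0 - np.tanh(d / INTERFACE_HALFWIDTH))
    s_t = INTERIOR_S_T * w
    fields = PhaseFields(
        grid=grid,
        porosity=1.0 - (1.0 - INTERIOR_POROSITY) * w,
        s_l=1.0 - s_t,
        s_t=s_t,
        tumour_fraction=w,
    )
    fields.validate()
    return fields


def inflow_profile(y, z, config: ScenarioConfig):
    """Inlet nanoparticle mass fraction: sigmoid in height.

    Zero plateau below one third of the chamber height, ``omega_max`` above,
    midpoint exactly at z = H/3 with logistic width 0.05 mm.  Uniform in y.
    """
    z = np.asarray(z, dtype=float)
    H = DOMAIN_EXTENTS[2]
    val = config.omega_max / (1.0 + np.exp(-(z - H / 3.0) / SIGMOID_WIDTH))
    out = np.broadcast_arrays(val, np.asarray(y, float))[0]
    return float(out) if out.ndim == 0 else out


def effective_phase_params(config: ScenarioConfig, grid: StructuredGrid) -> PhaseParams:
    """Phase parameters with the calibrated free-region conductivity.

    K_free follows from the Darcy closed form for the configured pressure
    drop and target mean velocity.  When the no-slip wall taper is active it
    reduces the cross-section mean; K_free is boosted by the inverse mean
    taper factor so the calibration target still holds.
    """
    from dataclasses import replace as _replace

    from .porous_flow import WallTaper, calibrate_free_flow

    k_free = calibrate_free_flow(
        config.target_velocity, DOMAIN_EXTENTS[0], config.delta_p
    )
    if config.wall_taper:
        k_free /= WallTaper().factor(grid.axes[2]).mean()
    return _replace(config.phase_params, free_conductivity=k_free)


def reference_scenarios() -> dict:
    """The four reference configurations keyed 'a'..'d'.

    (a) small/centred, (b) large/centred, (c) small/bottom, (d) large/bottom.
    """
    small, large = 200e-6, 340e-6
    return {
        "a": ScenarioConfig(name="a", spheroid_radius=small, spheroid_position="centred"),
        "b": ScenarioConfig(name="b", spheroid_radius=large, spheroid_position="centred"),
        "c": ScenarioConfig(name="c", spheroid_radius=small, spheroid_position="bottom"),
        "d": ScenarioConfig(name="d", spheroid_radius=large, spheroid_position="bottom"),
    }
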