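"""Analytic magnetostatics of a finite, axially magnetised cylindrical magnet.

The external H-field of a uniformly magnetised cylinder of finite length has
a closed form in the complete elliptic integrals K, E and Pi.  In cylindrical
coordinates (rho, z) attached to the magnet (origin at the magnet centre,
z along the magnetisation axis) the field components are

    H_rho(rho, z) = (M_s R / pi) * [alpha_+ P1(k_+) - alpha_- P1(k_-)]
    H_z(rho, z)   = (M_s R / (pi (rho + R))) * [beta_+ P2(k_+) - beta_- P2(k_-)]

with the auxiliary quantities

    rho_±  = R ± rho,           zeta_± = z ± L/2,
    alpha_± = 1 / sqrt(zeta_±^2 + rho_+^2),   beta_± = zeta_± alpha_±,
    gamma  = (rho - R)/(rho + R),
    k_±^2  = (zeta_±^2 + rho_-^2) / (zeta_±^2 + rho_+^2),

    P1(k) = K(1-k^2) - (2/(1-k^2)) [K(1-k^2) - E(1-k^2)],
    P2(k) = (K(1-k^2) - gamma * Pi(1-gamma^2, 1-k^2)) * (rho + R)/(2 R),

where all elliptic integrals use the *parameter* convention m = modulus^2,
i.e. K(m), E(m), Pi(n, m).  The P2 form above is the algebraically
simplified equivalent of the usual two-term expression; substituting it into
H_z gives

    H_z = (M_s / (2 pi)) * [beta_+ Q(k_+) - beta_- Q(k_-)],
    Q(k) = K(1-k^2) - gamma Pi(1-gamma^2, 1-k^2).

The sign convention zeta_± = z ± L/2 is fixed by requiring agreement with the
standard on-axis closed form (`h_on_axis`), under which the field decays to
zero far from the magnet.

All elliptic integrals are evaluated through Carlson symmetric forms
(scipy.special.elliprf/elliprd/elliprj), which stay accurate where the
Legendre forms suffer cancellation; in particular K(m) - E(m) is computed as
(m/3) R_D(0, 1-m, 1) so that P1 does not lose precision for small m.

The spatial Jacobian of (H_rho, H_z) is assembled in closed form by chain
rule through the elliptic-integral derivative identities

    dK/dm  = (E - (1-m) K) / (2 m (1-m))
    dE/dm  = (E - K) / (2 m)
    dPi/dm = (E/(m-1) + Pi) / (2 (n-m))
    dPi/dn = (E + (m-n) K / n + (n^2 - m) Pi / n) / (2 (m-n)(n-1)).

The magnetophoretic force on a superparamagnetic particle of volume V is

    F_mag = mu_0 V f(H) (H . grad) H

with the piecewise-linear magnetisation factor f(H) = 3 below saturation
(|H| < M_sp/3) and f = M_sp/|H| above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ellipe, ellipk, elliprd, elliprf, elliprj

__all__ = [
    "MU_0",
    "CylMagnet",
    "ParticleSpec",
    "LocalField",
    "ForceSample",
    "elliptic_suite",
    "magnet_local_coords",
    "h_on_axis",
    "h_field_local",
    "h_jacobian_local",
    "h_field_global",
    "magnetization_factor",
    "magnetic_force",
    "sample_force_field",
]

#: Vacuum magnetic permeability [N A^-2].
MU_0 = 1.25663706212e-6

# Relative half-width of the band around rho = R_mag inside which the
# characteristic 1 - gamma^2 of Pi reaches 1 and the Carlson R_J argument
# degenerates; points in the band are clamped onto its edge.  The field
# varies by O(1e-7) relative across the band.
_GAMMA_BAND = 1e-7
# Below this fraction of R_mag a point counts as on-axis and the closed-form
# axis limits are used (H_rho = 0, on-axis H_z, symmetric Jacobian limits).
_AXIS_FRAC = 1e-9


@dataclass(frozen=True)
class CylMagnet:
    """Finite cylindrical permanent magnet, uniformly magnetised along its axis.

    Parameters
    ----------
    magnetisation : float
        Remanent magnetisation M_s [A m^-1].
    radius : float
        Cylinder radius R_mag [m].
    length : float
        Cylinder length L_mag [m].
    centre : array-like of 3 floats
        Centre of the cylinder in global coordinates [m].
    axis : array-like of 3 floats
        Magnetisation axis (normalised on construction).
    """

    magnetisation: float
    radius: float
    length: float
    centre: tuple = (0.0, 0.0, 0.0)
    axis: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("magnet radius and length must be positive")
        ax = np.asarray(self.axis, dtype=float)
        nrm = np.linalg.norm(ax)
        if nrm == 0:
            raise ValueError("magnet axis must be a nonzero vector")
        object.__setattr__(self, "axis", tuple(ax / nrm))
        object.__setattr__(self, "centre", tuple(np.asarray(self.centre, float)))

    @property
    def frame(self) -> np.ndarray:
        """Orthonormal basis (e1, e2, e3) with e3 along the magnet axis.

        e1 is built from the global cardinal direction least aligned with the
        axis, so the frame is deterministic.
        """
        e3 = np.asarray(self.axis)
        pick = np.argmin(np.abs(e3))
        seed = np.zeros(3)
        seed[pick] = 1.0
        e1 = seed - np.dot(seed, e3) * e3
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(e3, e1)
        return np.stack([e1, e2, e3])

    @property
    def dipole_moment(self) -> float:
        """Total moment |m| = M_s * pi R^2 L [A m^2] (far-field equivalent)."""
        return self.magnetisation * np.pi * self.radius**2 * self.length


@dataclass(frozen=True)
class ParticleSpec:
    """Superparamagnetic nanoparticle properties.

    Particles are taken as spheres, so ``volume = 4/3 pi radius^3``.
    """

    radius: float  # R_NP [m]
    diffusion: float  # D_NP [m^2 s^-1]
    saturation_magnetisation: float  # M_sp [A m^-1]

    def __post_init__(self):
        if min(self.radius, self.diffusion, self.saturation_magnetisation) <= 0:
            raise ValueError("all particle properties must be positive")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3


@dataclass(frozen=True)
class LocalField:
    """H-field components and Jacobian in the magnet's (rho, z) plane."""

    h_rho: float
    h_z: float
    jacobian: np.ndarray = field(default=None, repr=False)  # d(H_rho,H_z)/d(rho,z)


@dataclass(frozen=True)
class ForceSample:
    """Field, flux density and magnetophoretic force at one global point."""

    h: np.ndarray  # [A m^-1]
    b: np.ndarray  # [T]
    f_mag: np.ndarray  # [N]


# ---------------------------------------------------------------------------
# elliptic integrals


def elliptic_suite(m, n=0.0):
    """Complete elliptic integrals (K, E, Pi) in the parameter convention.

    ``m`` is the parameter (modulus squared); ``n`` the characteristic of the
    third integral, Pi(n, m).  Evaluation goes through Carlson symmetric
    forms R_F, R_D, R_J.

    Raises
    ------
    ValueError
        If ``m`` is outside [0, 1] or ``n >= 1``.
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((m < 0) | (m > 1)):
        raise ValueError("elliptic parameter m must lie in [0, 1]")
    if np.any(n >= 1):
        raise ValueError("elliptic characteristic n must be < 1")
    K = ellipk(m)
    E = ellipe(m)
    Pi = elliprf(0.0, 1.0 - m, 1.0) + (n / 3.0) * elliprj(0.0, 1.0 - m, 1.0, 1.0 - n)
    if m.ndim == 0:
        return float(K), float(E), float(Pi)
    return K, E, Pi


def _ellippi(n, m):
    """Complete Pi(n, m) via Carlson forms, no domain checks (internal)."""
    return elliprf(0.0, 1.0 - m, 1.0) + (n / 3.0) * elliprj(0.0, 1.0 - m, 1.0, 1.0 - n)


# ---------------------------------------------------------------------------
# geometry


def magnet_local_coords(point, magnet: CylMagnet):
    """Map a global point into the magnet's cylindrical frame.

    Returns ``(rho, z, frame)`` where ``frame`` rows are the orthonormal basis
    (e1, e2, e3 = axis).  Round-trips to global coordinates to machine
    precision.
    """
    frame = magnet.frame
    rel = np.asarray(point, float) - np.asarray(magnet.centre)
    local = frame @ rel
    rho = float(np.hypot(local[0], local[1]))
    return rho, float(local[2]), frame


def _local_coords_vec(points, magnet: CylMagnet):
    frame = magnet.frame
    rel = np.atleast_2d(points) - np.asarray(magnet.centre)
    local = rel @ frame.T
    rho = np.hypot(local[:, 0], local[:, 1])
    phi_hat = np.zeros_like(local)
    r = np.where(rho > 0, rho, 1.0)
    # radial unit vector in global coordinates; arbitrary (e1) on the axis
    phi_hat = (local[:, :1] / r[:, None]) * frame[0] + (local[:, 1:2] / r[:, None]) * frame[1]
    phi_hat[rho == 0] = frame[0]
    return rho, local[:, 2], phi_hat


def _inside_body(rho, z, magnet: CylMagnet, tol=0.0):
    return (rho < magnet.radius * (1 + tol)) & (np.abs(z) < magnet.length / 2 * (1 + tol))


# ---------------------------------------------------------------------------
# field evaluation


def h_on_axis(z, magnet: CylMagnet):
    """On-axis H_z of the cylinder: closed form without elliptic integrals.

    ``H_z(0, z) = (M_s/2) [ zeta_+ / sqrt(zeta_+^2 + R^2)
                          - zeta_- / sqrt(zeta_-^2 + R^2) ]``
    with zeta_± = z ± L/2.  Valid outside the magnet (|z| > L/2).
    """
    z = np.asarray(z, dtype=float)
    if np.any(np.abs(z) < magnet.length / 2):
        raise ValueError("on-axis evaluation requires |z| > L/2 (outside the magnet)")
    zp = z + magnet.length / 2
    zm = z - magnet.length / 2
    R2 = magnet.radius**2
    out = magnet.magnetisation / 2 * (zp / np.sqrt(zp**2 + R2) - zm / np.sqrt(zm**2 + R2))
    return float(out) if out.ndim == 0 else out


def _h_on_axis_dz(z, magnet: CylMagnet):
    zp = z + magnet.length / 2
    zm = z - magnet.length / 2
    R2 = magnet.radius**2
    return magnet.magnetisation / 2 * (R2 / (zp**2 + R2) ** 1.5 - R2 / (zm**2 + R2) ** 1.5)


def _field_core(rho, z, magnet: CylMagnet, want_jacobian: bool):
    """Vectorised H components (and optionally the Jacobian) in local coords.

    Points must be outside the magnet body.  ``rho`` is clamped off the axis
    branch cut at rho = R_mag and replaced by exact limits on the axis.
    """
    rho = np.asarray(rho, dtype=float)
    z = np.asarray(z, dtype=float)
    rho, z = np.broadcast_arrays(rho, z)
    rho = rho.astype(float).copy()
    z = z.astype(float)

    M, R, L = magnet.magnetisation, magnet.radius, magnet.length

    inside = _inside_body(rho, z, magnet)
    if np.any(inside):
        idx = np.argwhere(inside)[0]
        raise ValueError(
            f"field evaluation point inside the magnet body (local rho={rho[tuple(idx)]:.3e} m, "
            f"z={z[tuple(idx)]:.3e} m)"
        )
    edge = (np.abs(rho - R) < 1e-12 * R) & (np.abs(np.abs(z) - L / 2) < 1e-12 * L)
    if np.any(edge):
        raise ValueError("field evaluation point on the singular magnet edge ring")

    on_axis = rho < _AXIS_FRAC * R
    # clamp the Pi characteristic away from its n = 1 degeneracy at rho = R
    lo, hi = R * (1 - _GAMMA_BAND), R * (1 + _GAMMA_BAND)
    band = (rho > lo) & (rho < hi)
    rho[band] = np.where(rho[band] >= R, hi, lo)

    rp = R + rho
    zp = z + L / 2
    zm = z - L / 2
    ap = 1.0 / np.sqrt(zp**2 + rp**2)
    am = 1.0 / np.sqrt(zm**2 + rp**2)
    bp = zp * ap
    bm = zm * am
    g = (rho - R) / rp
    n = 1.0 - g**2
    mp = 4.0 * R * rho * ap**2
    mm = 4.0 * R * rho * am**2
    mp = np.clip(mp, 0.0, 1.0)
    mm = np.clip(mm, 0.0, 1.0)

    Kp, Ep = ellipk(mp), ellipe(mp)
    Km, Em = ellipk(mm), ellipe(mm)
    Pip = _ellippi(n, mp)
    Pim = _ellippi(n, mm)
    # P1(m) = K - (2/m)(K - E) with K - E = (m/3) R_D(0, 1-m, 1)
    RDp = elliprd(0.0, 1.0 - mp, 1.0)
    RDm = elliprd(0.0, 1.0 - mm, 1.0)
    P1p = Kp - (2.0 / 3.0) * RDp
    P1m = Km - (2.0 / 3.0) * RDm
    Qp = Kp - g * Pip
    Qm = Km - g * Pim

    h_rho = M * R / np.pi * (ap * P1p - am * P1m)
    h_z = M / (2 * np.pi) * (bp * Qp - bm * Qm)

    if np.any(on_axis):
        h_rho = np.where(on_axis, 0.0, h_rho)
        zp_ax = z + L / 2
        zm_ax = z - L / 2
        hz_ax = M / 2 * (zp_ax / np.sqrt(zp_ax**2 + R**2) - zm_ax / np.sqrt(zm_ax**2 + R**2))
        h_z = np.where(on_axis, hz_ax, h_z)

    if not want_jacobian:
        return h_rho, h_z, None

    # --- closed-form Jacobian by chain rule -------------------------------
    with np.errstate(divide="ignore", invalid="ignore"):
        dKp = (Ep - (1 - mp) * Kp) / (2 * mp * (1 - mp))
        dKm = (Em - (1 - mm) * Km) / (2 * mm * (1 - mm))
        # P1'(m) = dK/dm + (2/m) [ (K-E)/m - E/(2(1-m)) ], (K-E)/m = R_D/3
        dP1p = dKp + (2 / mp) * (RDp / 3 - Ep / (2 * (1 - mp)))
        dP1m = dKm + (2 / mm) * (RDm / 3 - Em / (2 * (1 - mm)))
        # dPi/dm and dPi/dn at characteristic n
        dPim_p = (Ep / (mp - 1) + Pip) / (2 * (n - mp))
        dPim_m = (Em / (mm - 1) + Pim) / (2 * (n - mm))
        dPin_p = (Ep + (mp - n) / n * Kp + (n**2 - mp) / n * Pip) / (2 * (mp - n) * (n - 1))
        dPin_m = (Em + (mm - n) / n * Km + (n**2 - mm) / n * Pim) / (2 * (mm - n) * (n - 1))

    # geometric derivatives
    dap_dr = -rp * ap**3
    dam_dr = -rp * am**3
    dap_dz = -zp * ap**3
    dam_dz = -zm * am**3
    dbp_dr = zp * dap_dr
    dbm_dr = zm * dam_dr
    dbp_dz = ap**3 * rp**2
    dbm_dz = am**3 * rp**2
    dg_dr = 2 * R / rp**2
    dn_dr = -2 * g * dg_dr
    dmp_dr = 4 * R * ap**2 + 4 * R * rho * 2 * ap * dap_dr
    dmm_dr = 4 * R * am**2 + 4 * R * rho * 2 * am * dam_dr
    dmp_dz = 8 * R * rho * ap * dap_dz
    dmm_dz = 8 * R * rho * am * dam_dz

    # dQ/d(rho,z) with Q = K(m) - g * Pi(n, m)
    dQp_dr = dKp * dmp_dr - dg_dr * Pip - g * (dPim_p * dmp_dr + dPin_p * dn_dr)
    dQm_dr = dKm * dmm_dr - dg_dr * Pim - g * (dPim_m * dmm_dr + dPin_m * dn_dr)
    dQp_dz = (dKp - g * dPim_p) * dmp_dz
    dQm_dz = (dKm - g * dPim_m) * dmm_dz

    c1 = M * R / np.pi
    dHr_dr = c1 * (dap_dr * P1p + ap * dP1p * dmp_dr - dam_dr * P1m - am * dP1m * dmm_dr)
    dHr_dz = c1 * (dap_dz * P1p + ap * dP1p * dmp_dz - dam_dz * P1m - am * dP1m * dmm_dz)
    c2 = M / (2 * np.pi)
    dHz_dr = c2 * (dbp_dr * Qp + bp * dQp_dr - dbm_dr * Qm - bm * dQm_dr)
    dHz_dz = c2 * (dbp_dz * Qp + bp * dQp_dz - dbm_dz * Qm - bm * dQm_dz)

    if np.any(on_axis):
        # symmetry limits: dHz/dz from the on-axis closed form,
        # dHr/drho = -dHz/dz / 2 (solenoidality), off-diagonals vanish
        dHz_dz_ax = _h_on_axis_dz(z, magnet)
        dHz_dz = np.where(on_axis, dHz_dz_ax, dHz_dz)
        dHr_dr = np.where(on_axis, -0.5 * dHz_dz_ax, dHr_dr)
        dHr_dz = np.where(on_axis, 0.0, dHr_dz)
        dHz_dr = np.where(on_axis, 0.0, dHz_dr)

    jac = np.stack(
        [np.stack([dHr_dr, dHr_dz], axis=-1), np.stack([dHz_dr, dHz_dz], axis=-1)],
        axis=-2,
    )
    return h_rho, h_z, jac


def h_field_local(rho, z, magnet: CylMagnet) -> LocalField:
    """H components (H_rho, H_z) at one local point outside the magnet."""
    hr, hz, _ = _field_core(float(rho), float(z), magnet, want_jacobian=False)
    return LocalField(h_rho=float(hr), h_z=float(hz))


def h_jacobian_local(rho, z, magnet: CylMagnet) -> np.ndarray:
    """Closed-form Jacobian d(H_rho, H_z)/d(rho, z) at one local point."""
    _, _, jac = _field_core(float(rho), float(z), magnet, want_jacobian=True)
    return np.asarray(jac, dtype=float)


def h_field_global(point, magnet: CylMagnet):
    """H and B = mu_0 H at a global point outside the magnet."""
    h, _ = _h_global_vec(np.asarray(point, float)[None, :], magnet)
    h = h[0]
    return h, MU_0 * h


def _h_global_vec(points, magnet: CylMagnet, want_jacobian=False):
    rho, z, rho_hat = _local_coords_vec(points, magnet)
    hr, hz, jac = _field_core(rho, z, magnet, want_jacobian=want_jacobian)
    e3 = np.asarray(magnet.axis)
    h = hr[:, None] * rho_hat + hz[:, None] * e3
    if not want_jacobian:
        return h, None
    return h, (hr, hz, jac, rho, rho_hat)


def magnetization_factor(h_mag, m_sp):
    """Magnetisation factor f of the linear-with-saturation particle model.

    f = 3 while |H| < M_sp/3 (linear regime at the spherical demagnetisation
    limit), and f = M_sp/|H| once saturated, so the particle moment
    f(|H|) |H| V rises linearly and then stays at M_sp V.
    """
    h_mag = np.asarray(h_mag, dtype=float)
    if np.any(h_mag < 0):
        raise ValueError("field magnitude must be non-negative")
    out = np.where(h_mag < m_sp / 3.0, 3.0, m_sp / np.where(h_mag > 0, h_mag, 1.0))
    return float(out) if out.ndim == 0 else out


def magnetic_force(point, magnet: CylMagnet, particle: ParticleSpec) -> np.ndarray:
    """Magnetophoretic force F = mu_0 V f(H) (H.grad)H at a global point [N]."""
    return _force_vec(np.asarray(point, float)[None, :], magnet, particle)[0]


def _force_vec(points, magnet: CylMagnet, particle: ParticleSpec) -> np.ndarray:
    h, extra = _h_global_vec(points, magnet, want_jacobian=True)
    hr, hz, jac, rho, rho_hat = extra
    # (H.grad)H for an axisymmetric field, in the (rho_hat, axis) plane:
    # the azimuthal component vanishes and the convective derivative is
    #   [H_rho dHr/dr + H_z dHr/dz, H_rho dHz/dr + H_z dHz/dz]
    conv_r = hr * jac[:, 0, 0] + hz * jac[:, 0, 1]
    conv_z = hr * jac[:, 1, 0] + hz * jac[:, 1, 1]
    hmag = np.sqrt(hr**2 + hz**2)
    f = magnetization_factor(hmag, particle.saturation_magnetisation)
    scale = MU_0 * particle.volume * np.asarray(f)
    e3 = np.asarray(magnet.axis)
    return scale[:, None] * (conv_r[:, None] * rho_hat + conv_z[:, None] * e3)


def force_sample(point, magnet: CylMagnet, particle: ParticleSpec) -> ForceSample:
    """H, B and F_mag bundled at one global point."""
    h, b = h_field_global(point, magnet)
    return ForceSample(h=h, b=b, f_mag=magnetic_force(point, magnet, particle))


_force_field_cache: dict = {}


def sample_force_field(grid, magnet: CylMagnet, particle: ParticleSpec) -> np.ndarray:
    """Magnetophoretic force at every grid node, shape (n_nodes, 3) [N].

    Pure function of (grid, magnet, particle); results are cached.  Raises if
    any node lies inside the magnet body.
    """
    key = (id(grid), magnet, particle)
    if key in _force_field_cache:
        return _force_field_cache[key]
    pts = grid.nodes
    rho, z, _ = _local_coords_vec(pts, magnet)
    inside = _inside_body(rho, z, magnet)
    if np.any(inside):
        bad = int(np.argmax(inside))
        raise ValueError(f"grid node {bad} at {pts[bad]} lies inside the magnet body")
    F = _force_vec(pts, magnet, particle)
    if not np.all(np.isfinite(F)):
        bad = int(np.argmax(~np.isfinite(F).all(axis=1)))
        raise FloatingPointError(f"non-finite force at node {bad} ({pts[bad]})")
    F.setflags(write=False)
    _force_field_cache[key] = F
    return F


def sample_b_field(grid, magnet: CylMagnet) -> np.ndarray:
    """B = mu_0 H at every grid node, shape (n_nodes, 3) [T]."""
    h, _ = _h_global_vec(grid.nodes, magnet)
    return MU_0 * h
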