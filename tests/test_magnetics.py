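"""Analytic cylinder-magnet field against independent oracles.

The closed-form field is cross-checked against: the arithmetic-geometric
mean evaluation of the elliptic integrals, the on-axis closed form, the
point-dipole far field, high-order finite differences of the field itself
(for the Jacobian and the convective force term), and Maxwell's constraints
(solenoidal B, curl-free H outside the magnet).
"""

import numpy as np
import pytest

from spheromag.grid import StructuredGrid
from spheromag.magnetics import (
    MU_0,
    CylMagnet,
    ParticleSpec,
    elliptic_suite,
    h_field_global,
    h_field_local,
    h_jacobian_local,
    h_on_axis,
    magnet_local_coords,
    magnetic_force,
    magnetization_factor,
    sample_b_field,
    sample_force_field,
)


def agm_elliptic_k(m, tol=1e-15):
    """Complete K(m) by the arithmetic-geometric mean (independent oracle)."""
    a, b = 1.0, np.sqrt(1.0 - m)
    while abs(a - b) > tol * a:
        a, b = (a + b) / 2.0, np.sqrt(a * b)
    return np.pi / (2.0 * a)


class TestEllipticSuite:
    def test_identity_values_at_zero_parameter(self):
        K, E, Pi = elliptic_suite(0.0, 0.0)
        assert K == pytest.approx(np.pi / 2, abs=1e-15)
        assert E == pytest.approx(np.pi / 2, abs=1e-15)
        assert Pi == pytest.approx(np.pi / 2, abs=1e-15)

    @pytest.mark.parametrize("m", [0.1, 0.5, 0.9, 0.999])
    def test_first_kind_matches_agm(self, m):
        K, _, _ = elliptic_suite(m)
        assert K == pytest.approx(agm_elliptic_k(m), rel=1e-14)

    def test_known_value_half_parameter(self):
        K, _, _ = elliptic_suite(0.5)
        assert K == pytest.approx(1.8540746773013719, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            elliptic_suite(-0.1)
        with pytest.raises(ValueError):
            elliptic_suite(1.5)
        with pytest.raises(ValueError):
            elliptic_suite(0.5, n=1.0)


class TestLocalCoords:
    def test_centre_maps_to_origin(self, table_magnet):
        rho, z, _ = magnet_local_coords(table_magnet.centre, table_magnet)
        assert rho == 0.0 and z == 0.0

    def test_axial_and_radial_offsets(self, posed_magnet):
        c = np.asarray(posed_magnet.centre)
        rho, z, _ = magnet_local_coords(c + [0, 0, 0.75e-3], posed_magnet)
        assert rho == pytest.approx(0.0, abs=1e-15)
        assert z == pytest.approx(0.75e-3, rel=1e-12)
        rho, z, _ = magnet_local_coords(c + [0.3e-3, 0, 0], posed_magnet)
        assert rho == pytest.approx(0.3e-3, rel=1e-12)
        assert z == pytest.approx(0.0, abs=1e-15)

    def test_round_trip(self, rng):
        mag = CylMagnet(
            magnetisation=1e6,
            radius=0.5e-3,
            length=1e-3,
            centre=(0.3e-3, -0.2e-3, 0.1e-3),
            axis=(1.0, 2.0, -0.5),
        )
        for _ in range(20):
            p = rng.uniform(-2e-3, 2e-3, 3)
            rho, z, frame = magnet_local_coords(p, mag)
            local = frame @ (p - np.asarray(mag.centre))
            back = np.asarray(mag.centre) + frame.T @ local
            assert np.allclose(back, p, atol=1e-15)
            assert np.hypot(local[0], local[1]) == pytest.approx(rho, abs=1e-18)


class TestOnAxis:
    def test_top_face_value(self, table_magnet):
        # (M/2) * 1e-3 / sqrt(1.25e-6), direct evaluation of the closed form
        assert h_on_axis(0.5e-3, table_magnet) == pytest.approx(
            5e5 * (1e-3 / np.sqrt(1.25e-6)), rel=1e-12
        )

    def test_decay_and_mirror_symmetry(self, table_magnet):
        assert abs(h_on_axis(1.0, table_magnet)) < 1e-3
        for z in (0.6e-3, 1.1e-3, 5e-3):
            assert h_on_axis(z, table_magnet) == pytest.approx(
                h_on_axis(-z, table_magnet), rel=1e-14
            )

    def test_inside_magnet_rejected(self, table_magnet):
        with pytest.raises(ValueError):
            h_on_axis(0.0, table_magnet)

    def test_paper_pose_distance(self, table_magnet):
        # 0.75 mm above the centre: flux density 302.39 mT
        hz = h_on_axis(0.75e-3, table_magnet)
        assert MU_0 * hz == pytest.approx(0.30239, rel=1e-4)
        assert hz == pytest.approx(2.406e5, rel=1e-3)


class TestFieldLocal:
    def test_zero_radial_component_on_axis(self, table_magnet):
        for z in (0.51e-3, 0.75e-3, 2e-3, -1e-3):
            f = h_field_local(0.0, z, table_magnet)
            assert f.h_rho == 0.0

    def test_on_axis_equivalence(self, table_magnet):
        L = table_magnet.length
        for z in np.geomspace(L / 2 + 10e-6, 100 * L, 40):
            ref = h_on_axis(z, table_magnet)
            assert h_field_local(0.0, z, table_magnet).h_z == pytest.approx(
                ref, rel=1e-10
            )

    def test_far_field_matches_dipole_and_converges(self, table_magnet):
        m = table_magnet.dipole_moment
        R = table_magnet.radius
        prev = np.inf
        for fac in (10, 20, 50, 100):
            z = fac * R
            dip = 2 * m / (4 * np.pi * z**3)
            rel = abs(h_on_axis(z, table_magnet) - dip) / dip
            assert rel < prev  # monotone convergence
            prev = rel
            if fac >= 50:
                assert rel < 0.01

    def test_continuous_across_cylinder_radius_line(self, table_magnet):
        R = table_magnet.radius
        z = 0.75e-3
        left = h_field_local(R * (1 - 1e-6), z, table_magnet)
        right = h_field_local(R * (1 + 1e-6), z, table_magnet)
        assert left.h_z == pytest.approx(right.h_z, rel=1e-4)
        assert left.h_rho == pytest.approx(right.h_rho, rel=1e-4)

    def test_inside_and_edge_rejected(self, table_magnet):
        with pytest.raises(ValueError):
            h_field_local(0.2e-3, 0.0, table_magnet)
        with pytest.raises(ValueError):
            h_field_local(table_magnet.radius, table_magnet.length / 2, table_magnet)


def _fd_jacobian(rho, z, magnet, h=1e-9):
    """4th-order central differences of the local field (test oracle)."""
    cols = []
    for dr, dz in ((1, 0), (0, 1)):
        vals = []
        for s in (2, 1, -1, -2):
            f = h_field_local(rho + s * dr * h, z + s * dz * h, magnet)
            vals.append(np.array([f.h_rho, f.h_z]))
        cols.append((-vals[0] + 8 * vals[1] - 8 * vals[2] + vals[3]) / (12 * h))
    return np.stack(cols, axis=-1)


class TestJacobian:
    def test_matches_finite_differences(self, table_magnet, rng):
        checked = 0
        while checked < 100:
            rho = rng.uniform(0.02e-3, 1.2e-3)
            z = rng.uniform(0.52e-3, 1.5e-3)
            if abs(rho - table_magnet.radius) < 1e-5:
                continue
            Ja = h_jacobian_local(rho, z, table_magnet)
            Jf = _fd_jacobian(rho, z, table_magnet)
            assert np.abs(Ja - Jf).max() <= 1e-6 * np.abs(Jf).max()
            checked += 1

    def test_axis_symmetry(self, table_magnet):
        J = h_jacobian_local(0.0, 0.75e-3, table_magnet)
        assert J[1, 0] == 0.0 and J[0, 1] == 0.0
        # solenoidality on the axis: dHr/drho = -dHz/dz / 2
        assert J[0, 0] == pytest.approx(-J[1, 1] / 2, rel=1e-12)

    def test_curl_free_off_axis(self, table_magnet, rng):
        for _ in range(200):
            rho = rng.uniform(0.05e-3, 1.2e-3)
            z = rng.uniform(0.55e-3, 1.5e-3)
            if abs(rho - table_magnet.radius) < 1e-5:
                continue
            J = h_jacobian_local(rho, z, table_magnet)
            assert abs(J[0, 1] - J[1, 0]) <= 1e-8 * np.abs(J).max()

    def test_solenoidal_in_plane_divergence(self, table_magnet, rng):
        for _ in range(1000):
            rho = rng.uniform(0.05e-3, 1.2e-3)
            z = rng.uniform(0.55e-3, 1.5e-3)
            if abs(rho - table_magnet.radius) < 1e-5:
                continue
            J = h_jacobian_local(rho, z, table_magnet)
            hr = h_field_local(rho, z, table_magnet).h_rho
            div = J[0, 0] + hr / rho + J[1, 1]
            assert abs(div) <= 1e-6 * np.abs(J).max()


class TestGlobalField:
    def test_rotation_invariance_about_axis(self, posed_magnet):
        c = np.asarray(posed_magnet.centre)
        r, zoff = 0.4e-3, 1.0e-3
        mags = []
        for phi in np.linspace(0, 2 * np.pi, 7):
            p = c + [r * np.cos(phi), r * np.sin(phi), zoff]
            h, b = h_field_global(p, posed_magnet)
            mags.append(np.linalg.norm(h))
            assert np.allclose(b, MU_0 * h)
        assert np.ptp(mags) <= 1e-10 * mags[0]

    def test_axis_aligned_z_component_matches_local(self, posed_magnet):
        p = np.asarray(posed_magnet.centre) + [0.3e-3, 0.1e-3, 1.2e-3]
        rho, z, _ = magnet_local_coords(p, posed_magnet)
        h, _ = h_field_global(p, posed_magnet)
        assert h[2] == pytest.approx(h_field_local(rho, z, posed_magnet).h_z, rel=1e-12)

    def test_tilted_magnet_field_is_rigid_rotation(self, table_magnet):
        """Rotating magnet and evaluation point together rotates the field."""
        angle = 0.7
        Rz = np.array(
            [
                [np.cos(angle), -np.sin(angle), 0],
                [np.sin(angle), np.cos(angle), 0],
                [0, 0, 1],
            ]
        )
        Ry = np.array(
            [
                [np.cos(angle), 0, np.sin(angle)],
                [0, 1, 0],
                [-np.sin(angle), 0, np.cos(angle)],
            ]
        )
        Q = Rz @ Ry
        tilted = CylMagnet(
            magnetisation=1e6, radius=0.5e-3, length=1e-3, axis=tuple(Q @ [0, 0, 1])
        )
        p = np.array([0.2e-3, 0.1e-3, 0.9e-3])
        h_ref, _ = h_field_global(p, table_magnet)
        h_rot, _ = h_field_global(Q @ p, tilted)
        assert np.allclose(h_rot, Q @ h_ref, rtol=1e-10)


class TestMagnetisationFactor:
    def test_linear_branch(self, particle):
        m_sp = particle.saturation_magnetisation
        assert magnetization_factor(1e5, m_sp) == 3.0
        assert magnetization_factor(0.0, m_sp) == 3.0

    def test_saturated_branch(self, particle):
        m_sp = particle.saturation_magnetisation
        assert magnetization_factor(4.78e5, m_sp) == pytest.approx(1.0, rel=1e-12)

    def test_moment_continuous_at_threshold(self, particle):
        m_sp = particle.saturation_magnetisation
        h = m_sp / 3
        below = magnetization_factor(h * (1 - 1e-12), m_sp) * h
        above = magnetization_factor(h * (1 + 1e-12), m_sp) * h
        assert below == pytest.approx(above, rel=1e-10)
        assert below == pytest.approx(m_sp, rel=1e-10)


class TestMagneticForce:
    def test_gradient_identity(self, posed_magnet, particle, rng):
        """(H.grad)H = grad|H|^2 / 2 for curl-free H; FD gradient oracle."""

        def h2(p):
            h, _ = h_field_global(p, posed_magnet)
            return h @ h

        for _ in range(50):
            p = np.array(
                [
                    rng.uniform(0.05e-3, 1.95e-3),
                    rng.uniform(0.05e-3, 0.95e-3),
                    rng.uniform(0.0, 1e-3),
                ]
            )
            F = magnetic_force(p, posed_magnet, particle)
            g = np.zeros(3)
            eps = 1e-9
            for i in range(3):
                e = np.zeros(3)
                e[i] = eps
                g[i] = (-h2(p + 2 * e) + 8 * h2(p + e) - 8 * h2(p - e) + h2(p - 2 * e)) / (
                    12 * eps
                )
            h, _ = h_field_global(p, posed_magnet)
            f = magnetization_factor(np.linalg.norm(h), particle.saturation_magnetisation)
            F_ref = MU_0 * particle.volume * f * 0.5 * g
            assert np.abs(F - F_ref).max() <= 1e-6 * np.abs(F_ref).max()

    def test_transverse_force_vanishes_on_axis(self, posed_magnet, particle):
        p = np.asarray(posed_magnet.centre) + [0, 0, 1.0e-3]
        F = magnetic_force(p, posed_magnet, particle)
        assert abs(F[0]) <= 1e-12 * abs(F[2])
        assert abs(F[1]) <= 1e-12 * abs(F[2])
        assert F[2] < 0  # pulled down towards the magnet

    def test_force_continuous_across_saturation_threshold(self, posed_magnet, particle):
        """|H| = M_sp/3 is crossed on the magnet axis inside the chamber."""
        m_sp = particle.saturation_magnetisation
        zs = np.linspace(0.0, 1.0e-3, 400)
        c = np.asarray(posed_magnet.centre)
        hmag = np.array(
            [np.linalg.norm(h_field_global(c + [0, 0, 0.75e-3 + z], posed_magnet)[0]) for z in zs]
        )
        cross = np.where(np.diff(np.sign(hmag - m_sp / 3)))[0]
        assert cross.size > 0, "ray must cross the saturation threshold"
        z0 = zs[cross[0]]
        from scipy.optimize import brentq

        zstar = brentq(
            lambda z: np.linalg.norm(
                h_field_global(c + [0, 0, 0.75e-3 + z], posed_magnet)[0]
            )
            - m_sp / 3,
            z0,
            zs[cross[0] + 1],
        )
        f_below = magnetic_force(c + [0, 0, 0.75e-3 + zstar - 1e-12], posed_magnet, particle)
        f_above = magnetic_force(c + [0, 0, 0.75e-3 + zstar + 1e-12], posed_magnet, particle)
        assert np.linalg.norm(f_below - f_above) <= 1e-8 * np.linalg.norm(f_below)

    def test_domain_maximum_force_in_piconewton_decade(self, coarse_chamber, posed_magnet, particle):
        F = sample_force_field(coarse_chamber, posed_magnet, particle)
        fmax = np.linalg.norm(F, axis=1).max()
        assert 1e-13 < fmax < 1e-11  # pN decade


class TestSampleFields:
    def test_single_point_matches_pointwise(self, posed_magnet, particle):
        g = StructuredGrid(extents=(1e-4, 1e-4, 1e-4), spacing=1e-4)
        F = sample_force_field(g, posed_magnet, particle)
        for k, node in enumerate(g.nodes):
            assert np.allclose(
                F[k], magnetic_force(node, posed_magnet, particle), rtol=1e-12
            )

    def test_pure_function_and_finite(self, coarse_chamber, posed_magnet, particle):
        F1 = sample_force_field(coarse_chamber, posed_magnet, particle)
        F2 = sample_force_field(coarse_chamber, posed_magnet, particle)
        assert F1 is F2  # cached
        assert np.all(np.isfinite(F1))

    def test_node_inside_magnet_rejected(self, particle):
        g = StructuredGrid(extents=(1e-3, 1e-3, 1e-3), spacing=0.5e-3)
        inside = CylMagnet(
            magnetisation=1e6, radius=0.6e-3, length=1e-3, centre=(0.5e-3, 0.5e-3, 0.2e-3)
        )
        with pytest.raises(ValueError, match="node"):
            sample_force_field(g, inside, particle)

    def test_max_flux_density_printed_value(self, posed_magnet):
        g = StructuredGrid(extents=(2e-3, 1e-3, 1e-3), spacing=50e-6)
        B = sample_b_field(g, posed_magnet)
        bmax = np.linalg.norm(B, axis=1).max()
        assert bmax == pytest.approx(0.302, rel=5e-3)


class TestParticleSpec:
    def test_spherical_volume(self, particle):
        assert particle.volume == pytest.approx(4 / 3 * np.pi * (100e-9) ** 3, rel=1e-14)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            ParticleSpec(radius=-1e-9, diffusion=1e-10, saturation_magnetisation=1e5)


class TestCylMagnet:
    def test_axis_normalised(self):
        m = CylMagnet(magnetisation=1e6, radius=1e-3, length=1e-3, axis=(0, 0, 5))
        assert np.linalg.norm(m.axis) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            CylMagnet(magnetisation=1e6, radius=0.0, length=1e-3)
        with pytest.raises(ValueError):
            CylMagnet(magnetisation=1e6, radius=1e-3, length=1e-3, axis=(0, 0, 0))
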