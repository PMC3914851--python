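"""Crimped-collagen scar law: fiber distribution, fiber law, membrane stress."""

import numpy as np
import pytest
from scipy.integrate import quad

from lvscar.errors import InvalidParameterError
from lvscar.geometry import plane_C
from lvscar.scar import (FiberDistribution, ScarMaterial, collagen_energy,
                         fiber_density, fiber_energy, fiber_pk_stress,
                         fiber_stretch, scar_energy, scar_stress,
                         scar_stress_components)

M = ScarMaterial()  # reference parameter set


class TestFiberDensity:
    def test_uniform_at_zero_gamma(self):
        phi = np.linspace(-np.pi / 2, np.pi / 2, 7)
        assert np.allclose(fiber_density(phi, 0.0), 1.0 / np.pi)

    @pytest.mark.parametrize("gamma", [0.0, 0.771, 5.0])
    def test_normalised_on_half_circle(self, gamma):
        val, _ = quad(lambda p: fiber_density(p, gamma), -np.pi / 2, np.pi / 2)
        assert abs(val - 1.0) < 1e-10
        assert FiberDistribution(gamma).normalization_error() < 1e-8

    def test_alignment_ratio(self):
        ratio = fiber_density(0.0, 0.771) / fiber_density(np.pi / 2, 0.771)
        assert np.isclose(ratio, np.exp(2 * 0.771), rtol=1e-12)

    def test_positive_and_symmetric(self):
        phi = np.linspace(-np.pi / 2, np.pi / 2, 21)
        rho = fiber_density(phi, 2.0)
        assert np.all(rho > 0)
        assert np.allclose(rho, rho[::-1])

    def test_negative_gamma_rejected(self):
        with pytest.raises(InvalidParameterError):
            fiber_density(0.0, -0.1)


class TestFiberStretch:
    def test_identity_and_equibiaxial(self):
        I2 = np.eye(2)
        phis = np.linspace(-1.5, 1.5, 9)
        assert np.allclose(fiber_stretch(I2, phis), 1.0)
        assert np.allclose(fiber_stretch(1.44 * I2, phis, mu_deg=30.0), 1.2)

    def test_matches_quadratic_form(self, rng):
        for _ in range(10):
            A = rng.normal(size=(2, 2))
            C = A @ A.T + 0.5 * np.eye(2)
            for phi in rng.uniform(-np.pi / 2, np.pi / 2, 10):
                N = np.array([np.cos(phi), np.sin(phi)])
                assert np.isclose(fiber_stretch(C, phi), np.sqrt(N @ C @ N))


class TestFiberLaw:
    def test_unloaded_and_compressed_fibers_carry_nothing(self):
        assert fiber_pk_stress(1.0, M) == 0.0
        assert fiber_pk_stress(0.95, M) == 0.0
        assert fiber_energy(0.9, M) == 0.0

    def test_monotone_nonnegative(self):
        lam = np.linspace(1.0, 1.2, 50)
        Pf = fiber_pk_stress(lam, M)
        assert np.all(Pf >= 0)
        assert np.all(np.diff(Pf) > 0)

    def test_tangent_stiffness_increases_toward_locking(self):
        lam = np.linspace(1.001, M.lambda_lock - 1e-4, 40)
        h = 1e-7
        k = (fiber_pk_stress(lam + h, M) - fiber_pk_stress(lam - h, M)) / (2 * h)
        assert np.all(np.diff(k) > 0)

    def test_straight_filament_limit_small_crimp(self):
        m0 = ScarMaterial(theta0_deg=0.5, e_col=1e6, dd_ratio=2.39)
        lam = 1.05
        assert np.isclose(fiber_pk_stress(lam, m0), 1e6 * (lam - 1.0), rtol=2e-3)

    def test_locked_stiffness_approaches_filament_modulus(self):
        lam = M.lambda_lock + 0.01
        h = 1e-6
        k = (fiber_pk_stress(lam + h, M) - fiber_pk_stress(lam - h, M)) / (2 * h)
        assert np.isclose(k, M.e_col * np.cos(np.deg2rad(M.theta0_deg)), rtol=1e-6)

    def test_energy_is_integral_of_stress(self):
        for lam in (1.05, M.lambda_lock + 0.02):
            w_ref, _ = quad(lambda u: float(fiber_pk_stress(u, M)), 1.0, lam,
                            points=[M.lambda_lock], limit=200)
            assert np.isclose(fiber_energy(lam, M), w_ref, rtol=1e-8)


class TestCollagenEnergy:
    def test_zero_at_reference(self):
        assert collagen_energy(1.0, 0.0, 1.0, M) == 0.0

    def test_quadrature_refinement(self):
        # state with every fiber family taut and below locking: the
        # orientation integrand is smooth and the fixed rule is converged
        Ctt, Ctz, Czz, _ = plane_C(1.05, 1.03, 0.02)
        coarse = collagen_energy(Ctt, Ctz, Czz, M, FiberDistribution(M.gamma, M.mu_deg))
        fine = collagen_energy(Ctt, Ctz, Czz, M,
                               FiberDistribution(M.gamma, M.mu_deg, n_nodes=128))
        assert abs(coarse - fine) / abs(fine) < 1e-8

    def test_isotropic_equibiaxial_equals_single_fiber(self):
        m_iso = ScarMaterial(gamma=0.0)
        lam = 1.08
        W = collagen_energy(lam ** 2, 0.0, lam ** 2, m_iso)
        assert np.isclose(W, fiber_energy(lam, m_iso), rtol=1e-10)

    def test_reflection_symmetry_at_zero_mean_angle(self):
        Ctt, Ctz, Czz, _ = plane_C(1.1, 1.05, 0.06)
        assert np.isclose(collagen_energy(Ctt, Ctz, Czz, M),
                          collagen_energy(Ctt, -Ctz, Czz, M), rtol=1e-12)


class TestScarStress:
    def test_zero_at_reference(self):
        assert np.allclose(scar_stress(np.eye(3), M), 0.0, atol=1e-12)

    def test_pure_ground_substance_closed_form(self):
        m_g = ScarMaterial(omega_col=0.0)
        for lam in (1.05, 1.15, 1.3):
            s_tt, s_zz, s_tz = scar_stress_components(lam, lam, 0.0, m_g)
            expected = 2.0 * m_g.c_g * (lam ** 2 - lam ** -4)
            assert np.isclose(s_tt, expected, rtol=1e-12)
            assert np.isclose(s_zz, expected, rtol=1e-12)
            assert abs(s_tz) < 1e-12

    def test_circumferential_is_stiff_axis_at_reference_parameters(self):
        # mean angle 0: the aligned direction carries more equibiaxial stress
        for lam in (1.05, 1.1, 1.15):
            s_tt, s_zz, _ = scar_stress_components(lam, lam, 0.0, M)
            assert s_tt > s_zz > 0

    def test_mean_angle_rotation_swaps_responses(self):
        m90 = ScarMaterial(mu_deg=90.0)
        s0 = scar_stress_components(1.10, 1.04, 0.0, M)
        s90 = scar_stress_components(1.04, 1.10, 0.0, m90)
        assert np.isclose(s0[0], s90[1], rtol=1e-9)
        assert np.isclose(s0[1], s90[0], rtol=1e-9)

    def test_stress_energy_consistency(self, rng):
        dist = FiberDistribution(M.gamma, M.mu_deg)
        h = 1e-6
        for _ in range(30):
            lt = rng.uniform(0.95, 1.25)
            lz = rng.uniform(0.95, 1.25)
            kp = rng.uniform(-0.15, 0.15)
            Ctt, Ctz, Czz, Crr = plane_C(lt, lz, kp)
            W = lambda a, b, c, d: scar_energy(a, b, c, d, M, dist)
            S_tt = (W(Ctt + h, Ctz, Czz, Crr) - W(Ctt - h, Ctz, Czz, Crr)) / h
            S_zz = (W(Ctt, Ctz, Czz + h, Crr) - W(Ctt, Ctz, Czz - h, Crr)) / h
            S_rr = (W(Ctt, Ctz, Czz, Crr + h) - W(Ctt, Ctz, Czz, Crr - h)) / h
            S_tz = (W(Ctt, Ctz + h, Czz, Crr) - W(Ctt, Ctz - h, Czz, Crr)) / (2 * h)
            pm = Crr * S_rr
            ref = (lt * lt * S_tt + 2 * lt * kp * S_tz + kp * kp * S_zz - pm,
                   lz * lz * S_zz - pm,
                   lz * (lt * S_tz + kp * S_zz))
            got = scar_stress_components(lt, lz, kp, M, dist)
            scale = max(np.max(np.abs(ref)), 1.0)
            assert np.allclose(got, ref, atol=1e-6 * scale)

    def test_high_alignment_approaches_single_fiber_family(self):
        # gamma = 50: nearly all mass at the mean angle; compare with the
        # analytic single-family membrane response
        m_hi = ScarMaterial(gamma=50.0, omega_col=1.0, c_g=0.0)
        lt, lz = 1.08, 1.02
        s_tt, s_zz, _ = scar_stress_components(lt, lz, 0.0, m_hi)
        P1 = fiber_pk_stress(lt, m_hi)
        assert np.isclose(s_tt, lt ** 2 * P1 / lt, rtol=0.05)
        assert abs(s_zz) < 0.05 * s_tt


class TestParameterValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(theta0_deg=95.0), dict(e_col=-1.0), dict(dd_ratio=0.0),
        dict(c_g=-5.0), dict(gamma=-0.1), dict(omega_col=1.4),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            ScarMaterial(**kwargs)
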