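"""Microstructure-based constitutive model of infarct scar tissue.

The scar is a planar membrane of crimped collagen fibers embedded in an
isotropic neo-Hookean ground substance.  The total strain energy is the
volume-weighted mixture

    W = (1 - omega_col) * Wg + omega_col * Wcol,
    Wg = c_g (I1 - 3),

with ``omega_col`` the collagen volume fraction.  ``Wcol`` averages a
single-fiber energy over the in-plane orientation distribution

    rho(phi) = exp(gamma cos 2 phi) / (pi I0(gamma)),

a von Mises density wrapped on (-90, +90] degrees about the mean fiber
angle ``mu`` (measured from the circumferential axis); ``gamma`` controls
alignment (gamma = 0 is isotropic).  A fiber at offset ``phi`` sees the
stretch ``lambda = sqrt(N . C . N)`` of the unit vector N at angle
``mu + phi``.

Single-fiber law (helical-spring uncrimping).  Each collagen fiber is a
filament of diameter ``d`` and Young's modulus ``E_col`` coiled into a
helix of centreline diameter ``D`` (parameterised by the ratio
``q = D/d``) with initial crimp angle ``theta0`` between filament tangent
and fiber axis.  Under axial tension the wire deforms in torsion, bending
and axial stretch; Castigliano's theorem gives the tangent compliance per
unit reference fiber length.  With the filament inextensible at leading
order, the crimp angle at fiber stretch ``lambda`` follows from
``cos theta = lambda cos theta0`` and the helix radius shrinks as
``R = R0 sin theta / sin theta0``, which makes the tangent stiffness

    dP/dlambda = E_col cos(theta0) / D(lambda),
    D(lambda) = (q^2/4) * (1 - lambda^2 a^2)/(1 - a^2) * (24 - 8 lambda^2 a^2)
                + lambda^2 a^2,          a = cos theta0,

(the constants 24 and 8 combine the torsion/bending shape factors of a
circular wire with an incompressible-filament shear modulus G = E/3).
The fiber first Piola-Kirchhoff stress is the integral of this stiffness
from lambda = 1.  The coil locks at ``lambda_lock = 1/a`` where the
filament is straight; beyond it the response is the straight filament,
``dP/dlambda = E_col cos(theta0)``.  As ``theta0 -> 0`` the compliant coil
regime vanishes and ``P -> E_col (lambda - 1)`` to first order.  Fibers
carry no load in compression (P = 0 for lambda < 1).

Orientation averaging uses fixed Gauss-Legendre quadrature (64 nodes on
(-pi/2, pi/2)), so all results are deterministic; the fiber-stress
integral over stretch uses a nested 24-node rule.  All branching is on
real parts so the functions remain analytic under complex-step
perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0 as bessel_i0

from .errors import InvalidParameterError
from .geometry import plane_C

#: E/G for the collagen filament (Poisson ratio 0.5, incompressible wire).
_E_OVER_G = 3.0
_N_PHI = 64     # orientation quadrature nodes
_N_LAM = 24     # fiber stretch-integral quadrature nodes


@dataclass(frozen=True)
class ScarMaterial:
    """Microstructural parameters of the collagenous scar."""

    theta0_deg: float = 25.5   # initial crimp angle, degrees
    e_col: float = 1.16e6      # filament Young's modulus, Pa
    dd_ratio: float = 2.39     # helix diameter / filament diameter
    c_g: float = 5.72e3        # ground-substance neo-Hookean constant, Pa
    gamma: float = 0.771       # von Mises alignment factor
    omega_col: float = 0.4     # collagen volume fraction
    mu_deg: float = 0.0        # mean fiber angle from circumferential, degrees

    def __post_init__(self):
        if not 0.0 <= self.theta0_deg < 90.0:
            raise InvalidParameterError("crimp angle must lie in [0, 90) degrees")
        if self.e_col <= 0 or self.dd_ratio <= 0:
            raise InvalidParameterError("E_col and D/d must be positive")
        if self.c_g < 0:
            raise InvalidParameterError("ground constant must be >= 0")
        if self.gamma < 0:
            raise InvalidParameterError("alignment factor gamma must be >= 0")
        if not 0.0 <= self.omega_col <= 1.0:
            raise InvalidParameterError("collagen fraction must lie in [0, 1]")

    @property
    def lambda_lock(self) -> float:
        """Fiber stretch at which the coil is fully straightened."""
        return 1.0 / np.cos(np.deg2rad(self.theta0_deg))


def _gauss(n, a, b):
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (b - a) * x + 0.5 * (b + a), 0.5 * (b - a) * w


@dataclass(frozen=True)
class FiberDistribution:
    """Quadrature representation of the wrapped von Mises orientation density."""

    gamma: float
    mu_deg: float = 0.0
    n_nodes: int = _N_PHI
    phi: np.ndarray = field(init=False, repr=False)
    weights: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.gamma < 0:
            raise InvalidParameterError("gamma must be >= 0")
        phi, w = _gauss(self.n_nodes, -np.pi / 2, np.pi / 2)
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "weights", w)

    @property
    def density(self) -> np.ndarray:
        return fiber_density(self.phi, self.gamma)

    def normalization_error(self) -> float:
        """Quadrature error of the unit-mass condition on the half-circle."""
        return abs(float(np.sum(self.weights * self.density)) - 1.0)


def fiber_density(phi, gamma):
    """Wrapped von Mises orientation density (1/rad) on (-pi/2, pi/2]."""
    if gamma < 0:
        raise InvalidParameterError("gamma must be >= 0")
    phi = np.asarray(phi)
    return np.exp(gamma * np.cos(2.0 * phi)) / (np.pi * bessel_i0(gamma))


def fiber_stretch(C_plane, phi, mu_deg=0.0):
    """Stretch of the fiber family at angular offset ``phi`` from the mean angle.

    ``C_plane`` is the planar right Cauchy-Green tensor ``(..., 2, 2)`` in
    wall axes (theta, z); ``lambda = sqrt(N . C . N)`` with N at angle
    ``mu + phi`` from the circumferential axis.
    """
    C = np.asarray(C_plane)
    beta = np.deg2rad(mu_deg) + np.asarray(phi)
    cb, sb = np.cos(beta), np.sin(beta)
    lam2 = (C[..., 0, 0] * cb * cb + 2.0 * C[..., 0, 1] * sb * cb
            + C[..., 1, 1] * sb * sb)
    return np.sqrt(lam2)


# ---------------------------------------------------------------------------
# Single-fiber helix law
# ---------------------------------------------------------------------------

def _tangent_stiffness(lam, m: ScarMaterial):
    """d(P_col)/d(lambda) of the coiled regime (valid for lambda <= lambda_lock)."""
    a = np.cos(np.deg2rad(m.theta0_deg))
    a2 = a * a
    s2 = 1.0 - a2
    la2 = lam * lam * a2
    denom = (m.dd_ratio ** 2 / 4.0) * ((1.0 - la2) / s2) * (24.0 - 8.0 * la2) + la2
    return m.e_col * a / denom


def fiber_pk_stress(lam, m: ScarMaterial):
    """First Piola-Kirchhoff stress of a single fiber at stretch ``lam``.

    Piecewise: zero in compression, the integrated coil stiffness on
    ``[1, lambda_lock]`` and the straight-filament line beyond.  Vectorised
    and complex-step safe (branches on real parts).
    """
    lam = np.asarray(lam)
    if np.any(np.real(lam) <= 0):
        raise InvalidParameterError("fiber stretch must be positive")
    a = np.cos(np.deg2rad(m.theta0_deg))
    if m.theta0_deg < 1e-8:
        # straight filament: no coil regime
        taut = np.real(lam) > 1.0
        return np.where(taut, m.e_col * (lam - 1.0), 0.0)
    lam_lock = 1.0 / a

    taut = np.real(lam) > 1.0
    over = np.real(lam) > lam_lock
    # upper limit of the coil integral, clipped to [1, lam_lock] by branch
    lam_c = np.where(taut, np.where(over, lam_lock, lam), 1.0)

    x, w = np.polynomial.legendre.leggauss(_N_LAM)
    half = (lam_c - 1.0) / 2.0
    mid = (lam_c + 1.0) / 2.0
    nodes = mid[..., None] + half[..., None] * x          # (..., n_lam)
    k = _tangent_stiffness(nodes, m)
    P_coil = half * np.sum(w * k, axis=-1)

    P_straight = m.e_col * a * np.where(over, lam - lam_lock, 0.0)
    return np.where(taut, P_coil + P_straight, 0.0)


def fiber_energy(lam, m: ScarMaterial):
    """Single-fiber strain energy ``w(lam) = int_1^lam P_col``, by quadrature.

    The integral is split at the locking stretch, where the fiber law has a
    slope discontinuity, so each Gauss panel sees a smooth integrand; the
    straight-filament part beyond locking integrates in closed form.
    """
    lam = np.asarray(lam)
    taut = np.real(lam) > 1.0
    if m.theta0_deg < 1e-8:
        ext = np.where(taut, lam - 1.0, 0.0)
        return 0.5 * m.e_col * ext * ext
    a = np.cos(np.deg2rad(m.theta0_deg))
    lam_lock = 1.0 / a
    over = np.real(lam) > lam_lock
    lam_c = np.where(taut, np.where(over, lam_lock, lam), 1.0)

    x, w = np.polynomial.legendre.leggauss(_N_LAM)
    half = (lam_c - 1.0) / 2.0
    mid = (lam_c + 1.0) / 2.0
    nodes = mid[..., None] + half[..., None] * x
    P = fiber_pk_stress(np.where(np.real(nodes) > 1.0, nodes, 1.0), m)
    w_coil = half * np.sum(w * P, axis=-1)

    ext = np.where(over, lam - lam_lock, 0.0)
    P_lock = fiber_pk_stress(np.asarray(lam_lock), m)
    w_straight = P_lock * ext + 0.5 * m.e_col * a * ext * ext
    return np.where(taut, w_coil + w_straight, 0.0)


# ---------------------------------------------------------------------------
# Orientation-averaged energy and stress
# ---------------------------------------------------------------------------

def _lam_squared_nodes(C_tt, C_tz, C_zz, m: ScarMaterial, dist: FiberDistribution):
    beta = np.deg2rad(m.mu_deg) + dist.phi
    cb, sb = np.cos(beta), np.sin(beta)
    return (np.asarray(C_tt)[..., None] * cb * cb
            + 2.0 * np.asarray(C_tz)[..., None] * sb * cb
            + np.asarray(C_zz)[..., None] * sb * sb), cb, sb


def collagen_energy(C_tt, C_tz, C_zz, m: ScarMaterial,
                    dist: FiberDistribution | None = None):
    """Orientation-averaged collagen strain energy W_col (Pa)."""
    if dist is None:
        dist = FiberDistribution(m.gamma, m.mu_deg)
    lam2, _, _ = _lam_squared_nodes(C_tt, C_tz, C_zz, m, dist)
    lam = np.sqrt(lam2)
    wfib = fiber_energy(lam, m)
    return np.sum(dist.weights * dist.density * wfib, axis=-1)


def scar_energy(C_tt, C_tz, C_zz, C_rr, m: ScarMaterial,
                dist: FiberDistribution | None = None):
    """Total scar energy: volume-weighted ground substance + collagen."""
    I1 = np.asarray(C_tt) + np.asarray(C_zz) + np.asarray(C_rr)
    Wg = m.c_g * (I1 - 3.0)
    Wcol = collagen_energy(C_tt, C_tz, C_zz, m, dist)
    return (1.0 - m.omega_col) * Wg + m.omega_col * Wcol


def scar_stress_components(lam_theta, lam_z, kappa, m: ScarMaterial,
                           dist: FiberDistribution | None = None):
    """Planar Cauchy stress (sigma_tt, sigma_zz, sigma_tz) of the scar membrane.

    The collagen second Piola-Kirchhoff stress is the orientation average
    of ``(P_col(lambda)/lambda) N (x) N``; the ground substance contributes
    ``2 c_g I``.  The Lagrange multiplier zeroes the radial normal stress.
    Vectorised over arbitrary leading shapes; complex-step safe.
    """
    if dist is None:
        dist = FiberDistribution(m.gamma, m.mu_deg)
    C_tt, C_tz, C_zz, C_rr = plane_C(lam_theta, lam_z, kappa)
    lam2, cb, sb = _lam_squared_nodes(C_tt, C_tz, C_zz, m, dist)
    lam = np.sqrt(lam2)
    P = fiber_pk_stress(lam, m)
    wrho = dist.weights * dist.density
    coef = wrho * P / lam                                  # (..., n_phi)
    S_tt_col = np.sum(coef * cb * cb, axis=-1)
    S_zz_col = np.sum(coef * sb * sb, axis=-1)
    S_tz_col = np.sum(coef * sb * cb, axis=-1)

    g = 2.0 * m.c_g * (1.0 - m.omega_col)
    S_tt = g + m.omega_col * S_tt_col
    S_zz = g + m.omega_col * S_zz_col
    S_tz = m.omega_col * S_tz_col
    S_rr = g                                               # collagen is in-plane

    lt, lz, kp = lam_theta, lam_z, kappa
    p_mult = C_rr * S_rr
    sig_tt = lt * lt * S_tt + 2.0 * lt * kp * S_tz + kp * kp * S_zz - p_mult
    sig_zz = lz * lz * S_zz - p_mult
    sig_tz = lz * (lt * S_tz + kp * S_zz)
    return sig_tt, sig_zz, sig_tz


def scar_stress(F: np.ndarray, m: ScarMaterial,
                dist: FiberDistribution | None = None):
    """Planar Cauchy stress from the membrane deformation gradient ``F``."""
    F = np.asarray(F)
    return scar_stress_components(F[..., 0, 0], F[..., 1, 1], F[..., 0, 1], m, dist)
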