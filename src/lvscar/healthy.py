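"""Passive and active constitutive behaviour of healthy myocardium.

Passive response: each healthy region is a laminate of ``n_layers`` thin
sheets whose myocyte (fiber) axes fan from -50 to +50 degrees about the
circumferential direction.  Every layer carries the same planar deformation
(transmural shear ignored) and obeys the Fung exponential strain energy

    W = (c/2) (exp(Q) - 1),
    Q = b_ff E_ff^2 + b_xx (E_cc^2 + E_rr^2) + b_fx (E_fc^2 + E_cf^2),

written in the layer's fiber (f) / cross-fiber (c) / radial (r) axes, with
E the Green strain.  The Cauchy stress follows from
``sigma = -p I + 2 F dW/dC F^T`` with the Lagrange multiplier ``p`` chosen
so the radial normal stress vanishes (thin-membrane plane stress).

Active response: an elastance model of myocyte contraction.  The active
stress acts along the myocyte axis of each layer as a second
Piola-Kirchhoff dyad ``sigma_a(ls, t) m0 (x) m0`` pushed forward with F.
Its magnitude is

    sigma_a = sigma0(ls) * (1/2) (1 - cos omega(ls, t)),

where ``ls = lambda_fiber * ls0`` is the sarcomere length.  The 1/2
normalises the twitch so its peak equals the length-dependent peak tension

    sigma0(ls) = Tmax * Ca0^2 / (Ca0^2 + ECa50(ls)^2),
    ECa50(ls) = Ca0max / sqrt(exp(B (ls - l0)) - 1),

which is zero at or below the slack length ``l0`` and saturates toward
``Tmax`` at long sarcomere lengths (Frank-Starling effect).  The twitch
phase is

    omega = pi t / t0                      0 <= t < t0,
    omega = pi (t - t0 + tr) / tr          t0 <= t <= t0 + tr,   tr = m ls + b,
    omega = 0                              otherwise,

so activation is zero at t = 0, peaks at exactly 1 at t = t0 and returns
to zero at t = t0 + tr.

Everything here is analytic in the kinematic arguments so that the
equilibrium solver can differentiate through it with complex-step
perturbations; branches are taken on real parts only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InvalidKinematicsError
from .geometry import plane_C

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FungConstants:
    """Fung-law constants: stress scale ``c`` (Pa) and exponents."""

    c: float = 880.0
    b_ff: float = 18.5
    b_xx: float = 3.58
    b_fx: float = 1.63

    def __post_init__(self):
        if not self.c > 0:
            raise ValueError("c must be > 0")
        if min(self.b_ff, self.b_xx, self.b_fx) < 0:
            raise ValueError("Fung exponents must be >= 0")


@dataclass(frozen=True)
class LaminateSpec:
    """Myocyte fiber angles of the laminate layers (degrees from circumferential)."""

    fiber_angles_deg: tuple

    def __post_init__(self):
        if len(self.fiber_angles_deg) == 0:
            raise ValueError("laminate needs at least one layer")
        for a in self.fiber_angles_deg:
            if not -90.0 < a <= 90.0:
                raise ValueError("fiber angles must lie in (-90, 90] degrees")

    @property
    def n_layers(self) -> int:
        return len(self.fiber_angles_deg)

    @classmethod
    def evenly_spaced(cls, n_layers: int = 9, angle_min: float = -50.0,
                      angle_max: float = 50.0) -> "LaminateSpec":
        return cls(tuple(np.linspace(angle_min, angle_max, n_layers)))


@dataclass(frozen=True)
class ContractionParams:
    """Elastance contraction parameters (SI except sarcomere lengths in um)."""

    t_max: float = 135.7e3     # peak isometric tension at saturating length, Pa
    ca0: float = 4.35          # intracellular calcium, umol/L
    ca0_max: float = 4.35      # calcium scale in ECa50, umol/L
    b_len: float = 4.75        # length sensitivity of ECa50, 1/um
    l0: float = 1.58           # slack sarcomere length, um
    m_relax: float = 1.0489    # relaxation-duration slope, s/um
    b_relax: float = -1.429    # relaxation-duration intercept, s
    t0: float = 0.15           # time to peak tension, s
    cycle: float = 0.8         # twitch window simulated, s
    ls0: float = 1.65          # reference sarcomere length, um
    ls_max: float = 2.4        # clamp limit of the tabulated range, um

    def __post_init__(self):
        if self.t_max < 0 or self.t0 <= 0 or self.cycle <= 0 or self.ls0 <= 0:
            raise ValueError("invalid contraction parameters")


# ---------------------------------------------------------------------------
# Fung passive law
# ---------------------------------------------------------------------------

def _rotation(angle_deg):
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


def rotate_to_fiber_frame(E: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a wall-frame (theta, z, r) tensor into fiber axes at ``angle_deg``."""
    R = _rotation(angle_deg)
    return R @ np.asarray(E) @ R.T


def fung_energy(E_fiber: np.ndarray, k: FungConstants):
    """Strain energy density (Pa) of one layer; ``E_fiber`` in fiber axes."""
    E = np.asarray(E_fiber)
    Q = (k.b_ff * E[..., 0, 0] ** 2
         + k.b_xx * (E[..., 1, 1] ** 2 + E[..., 2, 2] ** 2)
         + k.b_fx * (E[..., 0, 1] ** 2 + E[..., 1, 0] ** 2))
    return 0.5 * k.c * (np.exp(Q) - 1.0)


def _layer_pk2(E_tt, E_tz, E_zz, E_rr, angles_deg, k: FungConstants):
    """Second Piola-Kirchhoff stress of each layer, rotated back to wall axes.

    Strain components have any shape ``S``; ``angles_deg`` has shape ``(n,)``
    appended as a trailing axis.  Returns (S_tt, S_zz, S_tz, S_rr, E_ff),
    each of shape ``S + (n,)``.
    """
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    ca, sa = np.cos(a), np.sin(a)
    c2, s2, sc = ca * ca, sa * sa, sa * ca

    E_tt = np.asarray(E_tt)[..., None]
    E_tz = np.asarray(E_tz)[..., None]
    E_zz = np.asarray(E_zz)[..., None]
    E_rr = np.asarray(E_rr)[..., None]

    E_ff = E_tt * c2 + 2.0 * E_tz * sc + E_zz * s2
    E_cc = E_tt * s2 - 2.0 * E_tz * sc + E_zz * c2
    E_fc = (E_zz - E_tt) * sc + E_tz * (c2 - s2)

    Q = k.b_ff * E_ff ** 2 + k.b_xx * (E_cc ** 2 + E_rr ** 2) + 2.0 * k.b_fx * E_fc ** 2
    ceQ = k.c * np.exp(Q)
    S_ff = ceQ * k.b_ff * E_ff
    S_cc = ceQ * k.b_xx * E_cc
    S_rr = ceQ * k.b_xx * E_rr
    S_fc = ceQ * k.b_fx * E_fc

    S_tt = S_ff * c2 + S_cc * s2 - 2.0 * S_fc * sc
    S_zz = S_ff * s2 + S_cc * c2 + 2.0 * S_fc * sc
    S_tz = (S_ff - S_cc) * sc + S_fc * (c2 - s2)
    return S_tt, S_zz, S_tz, S_rr, E_ff


# ---------------------------------------------------------------------------
# Elastance contraction
# ---------------------------------------------------------------------------

def sarcomere_length(lambda_fiber, ls0):
    """Sarcomere length (um) from the myocyte-direction stretch."""
    if np.any(np.real(lambda_fiber) <= 0):
        raise InvalidKinematicsError("fiber stretch must be strictly positive")
    return lambda_fiber * ls0


def _clamp_ls(ls, p: ContractionParams):
    over = np.real(ls) > p.ls_max
    if np.any(over):
        logger.warning("sarcomere length above %.2f um clamped", p.ls_max)
        ls = np.where(over, p.ls_max, ls)
    return ls


def sigma0(ls, p: ContractionParams):
    """Length-dependent peak contraction stress (Pa)."""
    ls = _clamp_ls(np.asarray(ls), p)
    g = np.exp(p.b_len * (ls - p.l0)) - 1.0
    active = np.real(g) > 0.0
    g = np.where(active, g, 0.0)
    ca2 = p.ca0 ** 2
    return np.where(active, p.t_max * ca2 * g / (ca2 * g + p.ca0_max ** 2), 0.0)


def activation(ls, t, p: ContractionParams):
    """Normalised twitch time course in [0, 1]; zero at t = 0 and at relaxation end."""
    ls = _clamp_ls(np.asarray(ls), p)
    tr = p.m_relax * ls + p.b_relax
    tr = np.where(np.real(tr) > 1e-6, tr, 1e-6)
    rise = (0.0 <= t) & (t < p.t0)
    fall = (p.t0 <= t) & (np.real(t - p.t0) <= np.real(tr))
    omega = np.where(rise, np.pi * t / p.t0, 0.0)
    omega = np.where(fall, np.pi * (t - p.t0 + tr) / tr, omega)
    return 0.5 * (1.0 - np.cos(omega))


def active_stress(ls, t, p: ContractionParams):
    """Active myocyte-direction stress (Pa) at sarcomere length ``ls`` and time ``t``."""
    return sigma0(ls, p) * activation(ls, t, p)


# ---------------------------------------------------------------------------
# Stress assembly
# ---------------------------------------------------------------------------

def laminate_stress_components(lam_theta, lam_z, kappa, laminate: LaminateSpec,
                               k: FungConstants, p: ContractionParams | None = None,
                               t: float = 0.0):
    """Planar Cauchy stress (sigma_tt, sigma_zz, sigma_tz) of the laminate.

    Vectorised over arbitrarily shaped (possibly complex) kinematic arrays.
    Active stress is included when contraction parameters are given; each
    layer uses its own fiber stretch to set the sarcomere length.
    """
    C_tt, C_tz, C_zz, C_rr = plane_C(lam_theta, lam_z, kappa)
    E_tt, E_tz, E_zz, E_rr = ((C_tt - 1) / 2, C_tz / 2, (C_zz - 1) / 2, (C_rr - 1) / 2)

    angles = laminate.fiber_angles_deg
    S_tt, S_zz, S_tz, S_rr, E_ff = _layer_pk2(E_tt, E_tz, E_zz, E_rr, angles, k)

    if p is not None and p.t_max > 0.0:
        lam_f = np.sqrt(2.0 * E_ff + 1.0)
        ls = lam_f * p.ls0
        sa = active_stress(ls, t, p)
        a = np.deg2rad(np.asarray(angles, dtype=float))
        ca, sa_ang = np.cos(a), np.sin(a)
        S_tt = S_tt + sa * ca * ca
        S_zz = S_zz + sa * sa_ang * sa_ang
        S_tz = S_tz + sa * sa_ang * ca

    # equal-thickness layer average, then push forward once (linear in S)
    S_tt_m = np.mean(S_tt, axis=-1)
    S_zz_m = np.mean(S_zz, axis=-1)
    S_tz_m = np.mean(S_tz, axis=-1)
    S_rr_m = np.mean(S_rr, axis=-1)

    lt, lz, kp = lam_theta, lam_z, kappa
    p_mult = C_rr * S_rr_m  # radial Cauchy stress; removed by the multiplier
    sig_tt = lt * lt * S_tt_m + 2.0 * lt * kp * S_tz_m + kp * kp * S_zz_m - p_mult
    sig_zz = lz * lz * S_zz_m - p_mult
    sig_tz = lz * (lt * S_tz_m + kp * S_zz_m)
    return sig_tt, sig_zz, sig_tz


def passive_stress(F: np.ndarray, angle_deg: float, k: FungConstants):
    """Planar Cauchy stress of a single passive layer at one fiber angle.

    ``F`` is the membrane deformation gradient (3x3 or batched).  Returns
    (sigma_tt, sigma_zz, sigma_tz) with the radial normal stress zeroed.
    """
    F = np.asarray(F)
    lt, lz, kp = F[..., 0, 0], F[..., 1, 1], F[..., 0, 1]
    single = LaminateSpec((angle_deg,))
    return laminate_stress_components(lt, lz, kp, single, k, None, 0.0)


def healthy_total_stress(F: np.ndarray, laminate: LaminateSpec, k: FungConstants,
                         p: ContractionParams, t: float):
    """Layer-averaged passive + active planar Cauchy stress of healthy tissue."""
    F = np.asarray(F)
    lt, lz, kp = F[..., 0, 0], F[..., 1, 1], F[..., 0, 1]
    return laminate_stress_components(lt, lz, kp, laminate, k, p, t)


def healthy_energy(C_tt, C_tz, C_zz, C_rr, laminate: LaminateSpec, k: FungConstants):
    """Layer-averaged passive strain energy as a function of planar C.

    Used by stress-energy consistency checks: finite differences of this
    function with respect to the C components must reproduce the passive
    second Piola-Kirchhoff stress.
    """
    E_tt, E_tz, E_zz, E_rr = ((np.asarray(C_tt) - 1) / 2, np.asarray(C_tz) / 2,
                              (np.asarray(C_zz) - 1) / 2, (np.asarray(C_rr) - 1) / 2)
    a = np.deg2rad(np.asarray(laminate.fiber_angles_deg, dtype=float))
    ca, sa = np.cos(a), np.sin(a)
    c2, s2, sc = ca * ca, sa * sa, sa * ca
    E_tt = E_tt[..., None]
    E_tz = E_tz[..., None]
    E_zz = E_zz[..., None]
    E_rr = E_rr[..., None]
    E_ff = E_tt * c2 + 2.0 * E_tz * sc + E_zz * s2
    E_cc = E_tt * s2 - 2.0 * E_tz * sc + E_zz * c2
    E_fc = (E_zz - E_tt) * sc + E_tz * (c2 - s2)
    Q = k.b_ff * E_ff ** 2 + k.b_xx * (E_cc ** 2 + E_rr ** 2) + 2.0 * k.b_fx * E_fc ** 2
    return np.mean(0.5 * k.c * (np.exp(Q) - 1.0), axis=-1)
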