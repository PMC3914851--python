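"""Coupled-region equilibrium: residual assembly and complex-step Newton solver.

The six shared kinematic unknowns are determined by six force balances
derived from the Law of Laplace for a thin-walled, closed-end cylinder
(circumferential load ``q_theta = P r h``, longitudinal load
``q_z = pi P r^2``) and the series/parallel force-sharing arrangement of
the four regions.  With per-region planar Cauchy stresses
(sigma_tt, sigma_zz, sigma_tz) the residuals are, in order,

  a) column-1/row coupling:   sum over rows of
         (sigma_tt - sigma_tz kappa/lam_z) H T / lam_theta_R  = P r h
  b) the same for column 2 (scar column)                       = P r h
  c,d) longitudinal sine components per row:
         sum over columns of sigma_tz L T / lam_z  = pi P r^2 sin(phi)
  e,f) longitudinal cosine components per row:
         sum over columns of sigma_zz L T / lam_z  = pi P r^2 cos(phi)

with the shear angle ``phi = atan(kappa / lam_z)`` of each row, and with
``r`` and ``h`` evaluated from the current state.  Residuals carry units
of newtons; a converged state satisfies the force-sharing identities to
the solver tolerance (default 1e-9 N).

Derivatives are computed by complex-step differentiation: every operation
along the residual path is analytic (branches taken on real parts only),
so ``Im f(x + i h e_j) / h`` yields machine-precision columns of the
Jacobian at h = 1e-20, free of subtractive cancellation.  The residual
function is vectorised over a leading batch axis, so one batched call
evaluates the full Jacobian.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import SolverError
from .geometry import (LVLayout, DeformationState, cavity_volume_batched,
                       _IDX_KAPPA, _IDX_LAM_THETA, _IDX_LAM_Z)
from .healthy import (ContractionParams, FungConstants, LaminateSpec,
                      laminate_stress_components)
from .scar import FiberDistribution, ScarMaterial, scar_stress_components

logger = logging.getLogger(__name__)

REFERENCE_STATE = np.array([1.0, 1.0, 1.0, 1.0, 0.0, 0.0])


def laplace_loads(P, r, h):
    """Thin-wall loads: circumferential ``P r h`` and longitudinal ``pi P r^2``."""
    if np.any(np.real(r) <= 0) or np.any(np.real(h) <= 0):
        raise ValueError("r and h must be positive")
    return P * r * h, np.pi * P * r * r


def shear_angle(kappa, lam_z):
    """Inclination of the longitudinal force vector, phi = atan(kappa/lam_z)."""
    if np.any(np.real(lam_z) <= 0):
        raise ValueError("lam_z must be positive")
    return np.arctan(kappa / lam_z)


@dataclass
class LoadState:
    """Loading point: cavity pressure (Pa) and time in the cycle (s)."""

    P: float
    t: float = 0.0

    def __post_init__(self):
        if self.P < 0:
            raise ValueError("pressure must be >= 0")


@dataclass
class FourRegionModel:
    """The assembled four-region LV: geometry plus per-region materials.

    ``scar`` may be None, in which case all four regions (including the S
    block) are healthy myocardium -- the baseline, pre-infarct ventricle.
    """

    layout: LVLayout
    fung: FungConstants
    laminate: LaminateSpec
    contraction: ContractionParams
    scar: ScarMaterial | None = None
    dist: FiberDistribution | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.scar is not None and self.dist is None:
            self.dist = FiberDistribution(self.scar.gamma, self.scar.mu_deg)

    # -- kinements of the shared state ------------------------------------
    def region_kinematics(self, x: np.ndarray):
        """Per-region (lam_theta, lam_z, kappa), each of shape (..., 4)."""
        lt = x[..., list(_IDX_LAM_THETA)]
        lz = x[..., list(_IDX_LAM_Z)]
        kp = x[..., list(_IDX_KAPPA)]
        return lt, lz, kp

    def region_stresses(self, x: np.ndarray, t: float = 0.0, active: bool = True):
        """Planar Cauchy stresses of the four regions; arrays (..., 4)."""
        lt, lz, kp = self.region_kinematics(x)
        p = self.contraction if active else None
        if self.scar is None:
            return laminate_stress_components(lt, lz, kp, self.laminate,
                                              self.fung, p, t)
        s_tt_h, s_zz_h, s_tz_h = laminate_stress_components(
            lt[..., :3], lz[..., :3], kp[..., :3], self.laminate, self.fung, p, t)
        s_tt_s, s_zz_s, s_tz_s = scar_stress_components(
            lt[..., 3], lz[..., 3], kp[..., 3], self.scar, self.dist)
        s_tt = np.concatenate([s_tt_h, s_tt_s[..., None]], axis=-1)
        s_zz = np.concatenate([s_zz_h, s_zz_s[..., None]], axis=-1)
        s_tz = np.concatenate([s_tz_h, s_tz_s[..., None]], axis=-1)
        return s_tt, s_zz, s_tz

    def radius_height(self, x: np.ndarray):
        L1, L2 = self.layout.column_widths
        H1, H2 = self.layout.row_heights
        r = (x[..., 0] * L1 + x[..., 1] * L2) / (2.0 * np.pi)
        h = x[..., 2] * H1 + x[..., 3] * H2
        return r, h

    def cavity_volume(self, x: np.ndarray):
        return cavity_volume_batched(self.layout, x)

    @property
    def reference_volume(self) -> float:
        return float(self.cavity_volume(REFERENCE_STATE))

    # -- residual assembly -------------------------------------------------
    def residuals(self, x: np.ndarray, P: float, t: float = 0.0,
                  active: bool = True) -> np.ndarray:
        """Six equilibrium residuals (N) for states ``x`` of shape (..., 6)."""
        x = np.asarray(x)
        s_tt, s_zz, s_tz = self.region_stresses(x, t, active)
        geo = self.layout.regions
        T = [g.T for g in geo]
        L1, L2 = self.layout.column_widths
        H1, H2 = self.layout.row_heights

        lt_R, lt_S = x[..., 0], x[..., 1]
        lz_R, lz_S = x[..., 2], x[..., 3]
        kp_R, kp_S = x[..., 4], x[..., 5]

        r, h = self.radius_height(x)
        q_t = P * r * h
        q_z = np.pi * P * r * r
        phi_R = np.arctan(kp_R / lz_R)
        phi_S = np.arctan(kp_S / lz_S)

        # circumferential balances (columns share lam_theta; rows add in series)
        res = np.empty(x.shape[:-1] + (6,), dtype=x.dtype)
        res[..., 0] = ((s_tt[..., 0] - s_tz[..., 0] * kp_R / lz_R) * H1 * T[0] / lt_R
                       + (s_tt[..., 2] - s_tz[..., 2] * kp_S / lz_S) * H2 * T[2] / lt_R
                       - q_t)
        res[..., 1] = ((s_tt[..., 1] - s_tz[..., 1] * kp_R / lz_R) * H1 * T[1] / lt_S
                       + (s_tt[..., 3] - s_tz[..., 3] * kp_S / lz_S) * H2 * T[3] / lt_S
                       - q_t)
        # longitudinal sine components per row
        res[..., 2] = (s_tz[..., 0] * L1 * T[0] / lz_R
                       + s_tz[..., 1] * L2 * T[1] / lz_R
                       - q_z * np.sin(phi_R))
        res[..., 3] = (s_tz[..., 2] * L1 * T[2] / lz_S
                       + s_tz[..., 3] * L2 * T[3] / lz_S
                       - q_z * np.sin(phi_S))
        # longitudinal cosine components per row
        res[..., 4] = (s_zz[..., 0] * L1 * T[0] / lz_R
                       + s_zz[..., 1] * L2 * T[1] / lz_R
                       - q_z * np.cos(phi_R))
        res[..., 5] = (s_zz[..., 2] * L1 * T[2] / lz_S
                       + s_zz[..., 3] * L2 * T[3] / lz_S
                       - q_z * np.cos(phi_S))
        return res

    def shear_consistency(self, x: np.ndarray, t: float = 0.0,
                          active: bool = True) -> np.ndarray:
        """Per-region mismatch sigma_tz - sigma_zz kappa/lam_z (Pa).

        The torque-free condition absorbed into the definition of the shear
        angle is not one of the six solved equations; this diagnostic
        reports how well the constitutive shear satisfies it at a state.
        """
        x = np.asarray(x)
        _, s_zz, s_tz = self.region_stresses(x, t, active)
        _, lz, kp = self.region_kinematics(x)
        return s_tz - s_zz * kp / lz


def residuals(state, P, t, model: FourRegionModel) -> np.ndarray:
    """Functional wrapper: residual vector (N) at a :class:`DeformationState`."""
    x = state.as_array() if isinstance(state, DeformationState) else np.asarray(state)
    return model.residuals(x, P, t)


# ---------------------------------------------------------------------------
# Complex-step differentiation and Newton iteration
# ---------------------------------------------------------------------------

def complex_step_jacobian(residual_fn, x: np.ndarray, step: float = 1e-20):
    """Jacobian of a batched residual function by complex-step differentiation.

    ``residual_fn`` must accept states of shape ``(batch, n)`` (complex) and
    return residuals ``(batch, m)``.  Column j is
    ``Im(residual(x + i*step*e_j)) / step``.  Also returns the residual at
    ``x`` itself (the real part, exact to O(step^2)).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    X = np.tile(x.astype(complex), (n, 1))
    X[np.arange(n), np.arange(n)] += 1j * step
    try:
        R = np.asarray(residual_fn(X))
        if np.iscomplexobj(R):
            return (R.imag / step).T, R.real[0]
        raise TypeError("residual function discarded the imaginary perturbation")
    except (TypeError, ValueError) as exc:
        # non-analytic residual path: fall back to central differences
        logger.warning("complex-step differentiation unavailable (%s); "
                       "falling back to central finite differences", exc)
        res = np.asarray(residual_fn(x[None, :]))[0].real
        h = 1e-7
    J = np.empty((len(res), n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        rp = np.asarray(residual_fn((x + e)[None, :]))[0].real
        rm = np.asarray(residual_fn((x - e)[None, :]))[0].real
        J[:, j] = (rp - rm) / (2 * h)
    return J, res


@dataclass
class SolverResult:
    state: np.ndarray
    residual: np.ndarray
    n_iter: int
    converged: bool


def newton_solve(residual_fn, x0: np.ndarray, tol=1e-9, max_iter: int = 50,
                 step: float = 1e-20, damping: bool = True,
                 max_halvings: int = 10,
                 positive_indices=(0, 1, 2, 3)) -> SolverResult:
    """Damped Newton iteration with complex-step derivatives.

    ``tol`` may be a scalar or a per-component vector; convergence requires
    ``|residual| <= tol`` componentwise.  Stretch-like unknowns listed in
    ``positive_indices`` are kept strictly positive by step halving.
    Raises :class:`SolverError` on a singular Jacobian, non-finite
    residuals, or failure to converge.
    """
    x = np.array(x0, dtype=float)
    n = x.shape[-1]
    tol = np.broadcast_to(np.asarray(tol, dtype=float), (n,))

    with np.errstate(over="ignore", invalid="ignore"):
        res = np.asarray(residual_fn(x[None, :]))[0].real
    if not np.all(np.isfinite(res)):
        raise SolverError("non-finite residual at the initial state",
                          state=x, residual=res, n_iter=0)
    if np.all(np.abs(res) <= tol):
        return SolverResult(x, res, 0, True)

    for it in range(1, max_iter + 1):
        with np.errstate(over="ignore", invalid="ignore"):
            J, res = complex_step_jacobian(residual_fn, x, step)
        if not np.all(np.isfinite(J)):
            raise SolverError("non-finite Jacobian", state=x, residual=res, n_iter=it)
        try:
            delta = np.linalg.solve(J, -res)
        except np.linalg.LinAlgError as exc:
            raise SolverError(f"singular Jacobian: {exc}", state=x,
                              residual=res, n_iter=it) from exc

        norm0 = np.max(np.abs(res / tol))
        alpha = 1.0
        accepted = False
        for _ in range(max_halvings + 1):
            x_try = x + alpha * delta
            if any(x_try[i] <= 0 for i in positive_indices):
                if not damping:
                    raise SolverError("step left the admissible region",
                                      state=x, residual=res, n_iter=it)
                alpha *= 0.5
                continue
            with np.errstate(over="ignore", invalid="ignore"):
                res_try = np.asarray(residual_fn(x_try[None, :]))[0].real
            if np.all(np.isfinite(res_try)) and (
                    np.max(np.abs(res_try / tol)) < norm0 or not damping):
                x, res = x_try, res_try
                accepted = True
                break
            if not damping:
                raise SolverError("non-finite residual during iteration",
                                  state=x_try, residual=res_try, n_iter=it)
            alpha *= 0.5
        if not accepted:
            raise SolverError("Newton step failed to reduce the residual "
                              f"after {max_halvings} halvings",
                              state=x, residual=res, n_iter=it)
        if np.all(np.abs(res) <= tol):
            logger.debug("Newton converged in %d iterations (|res|=%.3e)",
                         it, float(np.max(np.abs(res))))
            return SolverResult(x, res, it, True)

    raise SolverError(f"no convergence in {max_iter} iterations",
                      state=x, residual=res, n_iter=max_iter)
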