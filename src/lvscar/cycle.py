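"""Diastolic filling, ESPVR construction and cardiac-function metrics.

The simulated cycle has two quasi-static branches:

* **Diastole** -- a passive pressure ramp from 0 to the end-diastolic
  pressure (default 1.3 kPa) in equal increments, each solved with the
  previous converged state as the initial guess (natural continuation).
  The end-diastolic volume (EDV) is the cavity volume at the final
  pressure.

* **ESPVR** -- the end-systolic pressure-volume relationship.  For each
  volume on a grid (default 10 equally spaced volumes from the reference
  cavity volume to the EDV) the cavity volume is held fixed (isovolumic
  constraint) while the myocyte twitch runs over the cycle (default 100
  time points); pressure becomes the seventh unknown of the augmented
  equilibrium system and the ESPVR pressure at that volume is the maximum
  over the contraction.  If the grid does not bracket the systolic
  pressure (default 13 kPa) it is extended, with a log message, so the
  end-systolic volume can always be interpolated rather than extrapolated.

Stroke volume and ejection fraction follow as ``SV = EDV - ESV`` and
``EF = SV / EDV``, with the end-systolic volume (ESV) read off the ESPVR
at the systolic pressure by monotone piecewise-cubic interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .equilibrium import FourRegionModel, newton_solve
from .errors import OutOfRangeError, SolverError

logger = logging.getLogger(__name__)

M3_TO_ML = 1e6
MMHG_PER_PA = 1.0 / 133.322

#: pressure scale used to keep the augmented isovolumic unknown O(1)
_P_SCALE = 1e3


@dataclass(frozen=True)
class LoadingProtocol:
    """Loading parameters of one simulated case (SI units)."""

    edp: float = 1.3e3          # end-diastolic pressure, Pa
    p_sys: float = 13.0e3       # systolic pressure defining ESV, Pa
    n_increments: int = 100     # diastolic pressure increments
    n_time_points: int = 100    # time points per isovolumic contraction
    espvr_points: int = 10      # volumes on the ESPVR grid

    def __post_init__(self):
        if self.edp <= 0 or self.p_sys <= 0:
            raise ValueError("pressures must be positive")
        if min(self.n_increments, self.n_time_points) < 1 or self.espvr_points < 2:
            raise ValueError("invalid discretisation")


@dataclass(frozen=True)
class SolverSettings:
    """Newton-solver numerics."""

    tol: float = 1e-9           # residual max-norm tolerance, N
    vol_tol: float = 1e-10      # relative volume-constraint tolerance
    max_iter: int = 50
    complex_step: float = 1e-20
    damping: bool = True


@dataclass
class PVCurve:
    """Ordered pressure-volume samples of one branch."""

    pressures: np.ndarray       # Pa
    volumes: np.ndarray         # m^3
    branch: str                 # "diastolic" | "espvr"

    def __post_init__(self):
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.pressures.shape != self.volumes.shape:
            raise ValueError("pressures and volumes must have equal length")

    def __len__(self):
        return len(self.pressures)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pressure_Pa": self.pressures,
            "pressure_mmHg": self.pressures * MMHG_PER_PA,
            "volume_ml": self.volumes * M3_TO_ML,
            "branch": self.branch,
        })


@dataclass
class CardiacMetrics:
    """Headline pump-function metrics (volumes in mL)."""

    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef: float

    def __post_init__(self):
        if not np.isclose(self.sv_ml, self.edv_ml - self.esv_ml):
            raise ValueError("SV must equal EDV - ESV")
        if not np.isclose(self.ef, self.sv_ml / self.edv_ml):
            raise ValueError("EF must equal SV / EDV")
        if not 0.0 <= self.ef < 1.0:
            raise ValueError("EF must lie in [0, 1)")


@dataclass
class DiastoleResult:
    curve: PVCurve
    states: np.ndarray          # (n+1, 6), including the reference state
    edv: float                  # m^3
    end_state: np.ndarray


@dataclass
class ESPVRResult:
    curve: PVCurve
    n_extended_up: int = 0
    n_extended_down: int = 0


@dataclass
class CaseResult:
    metrics: CardiacMetrics
    diastole: DiastoleResult
    espvr: ESPVRResult


# ---------------------------------------------------------------------------
# Diastole
# ---------------------------------------------------------------------------

def simulate_diastole(model: FourRegionModel, p_end: float, n_increments: int,
                      settings: SolverSettings = SolverSettings()) -> DiastoleResult:
    """Passive filling along an equally spaced pressure ramp.

    Raises :class:`SolverError` with the partial curve attached if any
    increment fails.
    """
    if p_end <= 0 or n_increments < 1:
        raise ValueError("p_end must be > 0 and n_increments >= 1")
    pressures = np.linspace(0.0, p_end, n_increments + 1)
    x = np.array([1.0, 1.0, 1.0, 1.0, 0.0, 0.0])
    states = [x.copy()]
    volumes = [float(model.cavity_volume(x))]
    for P in pressures[1:]:
        fn = lambda X: model.residuals(X, P, 0.0, active=False)
        try:
            sol = newton_solve(fn, x, tol=settings.tol, max_iter=settings.max_iter,
                               step=settings.complex_step, damping=settings.damping)
        except SolverError as exc:
            exc.partial_curve = PVCurve(pressures[:len(volumes)],
                                        np.array(volumes), "diastolic")
            raise
        x = sol.state
        states.append(x.copy())
        volumes.append(float(model.cavity_volume(x)))
    curve = PVCurve(pressures, np.array(volumes), "diastolic")
    return DiastoleResult(curve=curve, states=np.array(states),
                          edv=volumes[-1], end_state=x)


# ---------------------------------------------------------------------------
# Isovolumic systole
# ---------------------------------------------------------------------------

def solve_isovolumic(model: FourRegionModel, v_target: float, t: float,
                     x0: np.ndarray | None = None, p0: float = 0.0,
                     settings: SolverSettings = SolverSettings()):
    """Solve the 7-unknown system: six balances plus a fixed cavity volume.

    Returns ``(state, P)``.  The volume constraint is satisfied to the
    relative tolerance of the solver settings (default 1e-10).
    """
    if v_target <= 0:
        raise ValueError("target volume must be positive")
    y0 = np.empty(7)
    y0[:6] = np.array([1.0, 1.0, 1.0, 1.0, 0.0, 0.0]) if x0 is None else x0
    y0[6] = p0 / _P_SCALE

    def fn(Y):
        X = Y[..., :6]
        P = Y[..., 6] * _P_SCALE
        forces = model.residuals(X, P, t, active=True)
        vres = model.cavity_volume(X) / v_target - 1.0
        return np.concatenate([forces, vres[..., None]], axis=-1)

    tol = np.array([settings.tol] * 6 + [settings.vol_tol])
    sol = newton_solve(fn, y0, tol=tol, max_iter=settings.max_iter,
                       step=settings.complex_step, damping=settings.damping)
    return sol.state[:6], sol.state[6] * _P_SCALE


def _isovolumic_twitch(model, v_target, times, x0, p0, settings):
    """Pressure transient at fixed volume; returns (P(t) array, state at t=0)."""
    P_hist = np.empty(len(times))
    x, p = x0, p0
    state0 = None
    for j, t in enumerate(times):
        x, p = solve_isovolumic(model, v_target, t, x0=x, p0=p, settings=settings)
        if j == 0:
            state0, p_start = x.copy(), p
        P_hist[j] = p
    return P_hist, state0, p_start


def compute_espvr(model: FourRegionModel, loading: LoadingProtocol,
                  diastole: DiastoleResult,
                  settings: SolverSettings = SolverSettings()) -> ESPVRResult:
    """End-systolic PV relationship over the volume grid.

    The base grid spans the reference cavity volume to the EDV; each
    volume's ESPVR pressure is the maximum of the isovolumic pressure
    transient over the contraction.  The grid is extended (up or down)
    when it does not bracket the systolic pressure.
    """
    cyc = model.contraction.cycle
    times = np.linspace(0.0, cyc, loading.n_time_points)
    v_ref = model.reference_volume
    grid = np.linspace(v_ref, diastole.edv, loading.espvr_points)
    dv = grid[1] - grid[0]

    dia_v = diastole.curve.volumes
    dia_states = diastole.states

    def passive_guess(v):
        # interpolate the diastolic trajectory componentwise as initial guess
        x = np.array([np.interp(v, dia_v, dia_states[:, i]) for i in range(6)])
        p = np.interp(v, dia_v, diastole.curve.pressures)
        return x, p

    volumes, peaks = [], []
    t0_states = {}
    for v in grid:
        x0, p0 = passive_guess(v)
        P_hist, state0, p_start = _isovolumic_twitch(model, v, times, x0, p0, settings)
        volumes.append(v)
        peaks.append(P_hist.max())
        t0_states[v] = (state0, p_start)

    n_up = n_down = 0
    while peaks[-1] < loading.p_sys and n_up < 12:
        v = volumes[-1] + dv
        x0, p0 = t0_states[volumes[-1]]
        P_hist, state0, p_start = _isovolumic_twitch(model, v, times, x0, p0, settings)
        volumes.append(v)
        peaks.append(P_hist.max())
        t0_states[v] = (state0, p_start)
        n_up += 1
        logger.info("ESPVR grid extended up to %.2f mL (peak %.2f kPa)",
                    v * M3_TO_ML, peaks[-1] / 1e3)
    while peaks[0] > loading.p_sys and n_down < 12 and volumes[0] - dv > 0.2 * v_ref:
        v = volumes[0] - dv
        x0, p0 = t0_states[volumes[0]]
        P_hist, state0, p_start = _isovolumic_twitch(model, v, times, x0, p0, settings)
        volumes.insert(0, v)
        peaks.insert(0, P_hist.max())
        t0_states[v] = (state0, p_start)
        n_down += 1
        logger.info("ESPVR grid extended down to %.2f mL (peak %.2f kPa)",
                    v * M3_TO_ML, peaks[0] / 1e3)

    curve = PVCurve(np.array(peaks), np.array(volumes), "espvr")
    return ESPVRResult(curve=curve, n_extended_up=n_up, n_extended_down=n_down)


def end_systolic_volume(espvr: PVCurve, p_sys: float) -> float:
    """Volume on the ESPVR at the systolic pressure, by monotone interpolation.

    Raises :class:`OutOfRangeError` if ``p_sys`` is outside the pressure
    span of the curve -- the curve is never extrapolated.
    """
    P = np.asarray(espvr.pressures, dtype=float)
    V = np.asarray(espvr.volumes, dtype=float)
    order = np.argsort(P)
    P, V = P[order], V[order]
    if not (P[0] <= p_sys <= P[-1]):
        raise OutOfRangeError(
            f"systolic pressure {p_sys/1e3:.2f} kPa outside ESPVR span "
            f"[{P[0]/1e3:.2f}, {P[-1]/1e3:.2f}] kPa")
    if np.any(np.diff(P) <= 0):
        # fall back to linear interpolation on a non-strict grid
        return float(np.interp(p_sys, P, V))
    return float(PchipInterpolator(P, V)(p_sys))


# ---------------------------------------------------------------------------
# Whole-case pipeline and sweeps
# ---------------------------------------------------------------------------

def run_model(model: FourRegionModel, loading: LoadingProtocol = LoadingProtocol(),
              settings: SolverSettings = SolverSettings()) -> CaseResult:
    """Diastole, ESPVR and metrics for an assembled model.  Deterministic."""
    dia = simulate_diastole(model, loading.edp, loading.n_increments, settings)
    esp = compute_espvr(model, loading, dia, settings)
    esv = end_systolic_volume(esp.curve, loading.p_sys)
    edv_ml = dia.edv * M3_TO_ML
    esv_ml = esv * M3_TO_ML
    sv_ml = edv_ml - esv_ml
    metrics = CardiacMetrics(edv_ml=edv_ml, esv_ml=esv_ml, sv_ml=sv_ml,
                             ef=sv_ml / edv_ml)
    return CaseResult(metrics=metrics, diastole=dia, espvr=esp)


def run_case(config) -> CaseResult:
    """Run the full pipeline from a :class:`~lvscar.config.ModelConfig`."""
    from .config import build_model, loading_from_config, solver_from_config
    return run_model(build_model(config), loading_from_config(config),
                     solver_from_config(config))


def parametric_sweep(config, parameter: str, values,
                     second_parameter: str | None = None,
                     second_values=None) -> pd.DataFrame:
    """Run one case per grid point of one or two config parameters.

    ``parameter`` is a dotted path into the config (e.g.
    ``"scar.mean_angle_deg"``).  Individual case failures are recorded in
    the ``error`` column and the sweep continues.
    """
    from .config import with_override
    if (second_parameter is None) != (second_values is None):
        raise ValueError("second_parameter and second_values go together")
    grid = ([(v,) for v in values] if second_parameter is None
            else [(v, w) for v in values for w in second_values])
    rows = []
    for point in grid:
        cfg = with_override(config, parameter, point[0])
        row = {parameter: point[0]}
        if second_parameter is not None:
            cfg = with_override(cfg, second_parameter, point[1])
            row[second_parameter] = point[1]
        try:
            result = run_case(cfg)
            m = result.metrics
            row.update(edv_ml=m.edv_ml, esv_ml=m.esv_ml, sv_ml=m.sv_ml,
                       ef=m.ef, error="")
        except Exception as exc:  # keep sweeping; record the failure
            logger.warning("sweep point %s failed: %s", point, exc)
            row.update(edv_ml=np.nan, esv_ml=np.nan, sv_ml=np.nan,
                       ef=np.nan, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)
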