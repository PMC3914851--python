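"""Configuration schema and model assembly.

The config file is YAML with explicit unit suffixes in key names (``_cm``,
``_deg``, ``_kPa``, ``_MPa``, ``_um``, ``_s``) to prevent unit drift; all
values are converted to SI when the model is built.  Unknown keys are
rejected.  A missing block gets the full reference (Table-1-style) default;
within an explicitly provided ``scar`` block every material parameter must
be spelled out, so a scar description can never silently mix defaults with
user values.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .equilibrium import FourRegionModel
from .cycle import LoadingProtocol, SolverSettings
from .geometry import make_layout
from .healthy import ContractionParams, FungConstants, LaminateSpec
from .scar import ScarMaterial

CM = 1e-2
KPA = 1e3
MPA = 1e6


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GeometryBlock(_Block):
    """Undeformed dimensions (cm) and scar placement fractions."""

    total_circumference_cm: float = 10.0
    total_height_cm: float = 5.0
    healthy_thickness_cm: float = 0.8
    scar_thickness_cm: float = 0.4
    scar_circ_fraction: float = 0.5
    scar_height_fraction: float = 0.5


class HealthyBlock(_Block):
    """Fung constants and laminate layout of the healthy regions."""

    c_Pa: float = 880.0
    b_ff: float = 18.5
    b_xx: float = 3.58
    b_fx: float = 1.63
    n_layers: int = 9
    fiber_angle_min_deg: float = -50.0
    fiber_angle_max_deg: float = 50.0


class ContractionBlock(_Block):
    """Elastance contraction parameters."""

    t_max_kPa: float = 135.7
    ca0_uM: float = 4.35
    ca0_max_uM: float = 4.35
    length_sensitivity_per_um: float = 4.75
    slack_length_um: float = 1.58
    relax_slope_s_per_um: float = 1.0489
    relax_intercept_s: float = -1.429
    time_to_peak_s: float = 0.15
    cycle_s: float = 0.8
    ls0_um: float = 1.65
    ls_max_um: float = 2.4


class ScarBlock(_Block):
    """Scar microstructure.  All material fields are required when the
    block is given explicitly; ``present: false`` makes the S region
    healthy myocardium (the pre-infarct baseline)."""

    crimp_angle_deg: float
    e_col_MPa: float
    dd_ratio: float
    c_g_kPa: float
    gamma: float
    collagen_fraction: float
    mean_angle_deg: float
    present: bool = True


def _default_scar() -> ScarBlock:
    return ScarBlock(crimp_angle_deg=25.5, e_col_MPa=1.16, dd_ratio=2.39,
                     c_g_kPa=5.72, gamma=0.771, collagen_fraction=0.4,
                     mean_angle_deg=0.0)


class LoadingBlock(_Block):
    """Loading protocol (pressures in kPa) and discretisation."""

    edp_kPa: float = 1.3
    p_sys_kPa: float = 13.0
    n_increments: int = 100
    n_time_points: int = 100
    espvr_points: int = 10


class SolverBlock(_Block):
    """Newton-solver numerics."""

    tol_N: float = 1e-9
    vol_tol_rel: float = 1e-10
    max_iter: int = 50
    complex_step: float = 1e-20
    damping: bool = True


class ModelConfig(_Block):
    """Complete model configuration; defaults reproduce the reference
    post-infarct example (canine-sized LV, moderately sized scar)."""

    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    healthy: HealthyBlock = Field(default_factory=HealthyBlock)
    contraction: ContractionBlock = Field(default_factory=ContractionBlock)
    scar: ScarBlock = Field(default_factory=_default_scar)
    loading: LoadingBlock = Field(default_factory=LoadingBlock)
    solver: SolverBlock = Field(default_factory=SolverBlock)


def default_config() -> ModelConfig:
    """The reference post-infarct configuration."""
    return ModelConfig()


def baseline_config() -> ModelConfig:
    """Pre-infarct baseline: four healthy regions of uniform thickness."""
    cfg = ModelConfig()
    cfg.scar.present = False
    cfg.geometry.scar_thickness_cm = cfg.geometry.healthy_thickness_cm
    return cfg


def load_config(path) -> ModelConfig:
    """Read and validate a YAML config file; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return ModelConfig(**raw)
    except ValidationError as exc:
        # re-raise with a compact, key-naming message
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors())
        raise ValueError(f"invalid config {path}: {details}") from exc


def save_config(cfg: ModelConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))


def config_hash(cfg: ModelConfig) -> str:
    """Stable sha256 of the canonical JSON form (for run manifests)."""
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def with_override(cfg: ModelConfig, dotted_key: str, value) -> ModelConfig:
    """Copy of ``cfg`` with one dotted-path field replaced."""
    new = cfg.model_copy(deep=True)
    parts = dotted_key.split(".")
    obj = new
    for p in parts[:-1]:
        if not hasattr(obj, p):
            raise KeyError(f"unknown config path {dotted_key!r}")
        obj = getattr(obj, p)
    if not hasattr(obj, parts[-1]):
        raise KeyError(f"unknown config path {dotted_key!r}")
    setattr(obj, parts[-1], value)
    return new


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

def build_model(cfg: ModelConfig) -> FourRegionModel:
    """Assemble the SI-unit four-region model from a validated config."""
    g = cfg.geometry
    layout = make_layout(
        total_circumference=g.total_circumference_cm * CM,
        total_height=g.total_height_cm * CM,
        healthy_thickness=g.healthy_thickness_cm * CM,
        scar_thickness=g.scar_thickness_cm * CM,
        scar_circ_fraction=g.scar_circ_fraction,
        scar_height_fraction=g.scar_height_fraction,
    )
    h = cfg.healthy
    fung = FungConstants(c=h.c_Pa, b_ff=h.b_ff, b_xx=h.b_xx, b_fx=h.b_fx)
    laminate = LaminateSpec.evenly_spaced(h.n_layers, h.fiber_angle_min_deg,
                                          h.fiber_angle_max_deg)
    c = cfg.contraction
    contraction = ContractionParams(
        t_max=c.t_max_kPa * KPA, ca0=c.ca0_uM, ca0_max=c.ca0_max_uM,
        b_len=c.length_sensitivity_per_um, l0=c.slack_length_um,
        m_relax=c.relax_slope_s_per_um, b_relax=c.relax_intercept_s,
        t0=c.time_to_peak_s, cycle=c.cycle_s, ls0=c.ls0_um, ls_max=c.ls_max_um)
    scar = None
    if cfg.scar.present:
        s = cfg.scar
        scar = ScarMaterial(theta0_deg=s.crimp_angle_deg, e_col=s.e_col_MPa * MPA,
                            dd_ratio=s.dd_ratio, c_g=s.c_g_kPa * KPA,
                            gamma=s.gamma, omega_col=s.collagen_fraction,
                            mu_deg=s.mean_angle_deg)
    return FourRegionModel(layout=layout, fung=fung, laminate=laminate,
                           contraction=contraction, scar=scar)


def loading_from_config(cfg: ModelConfig) -> LoadingProtocol:
    ld = cfg.loading
    return LoadingProtocol(edp=ld.edp_kPa * KPA, p_sys=ld.p_sys_kPa * KPA,
                           n_increments=ld.n_increments,
                           n_time_points=ld.n_time_points,
                           espvr_points=ld.espvr_points)


def solver_from_config(cfg: ModelConfig) -> SolverSettings:
    s = cfg.solver
    return SolverSettings(tol=s.tol_N, vol_tol=s.vol_tol_rel, max_iter=s.max_iter,
                          complex_step=s.complex_step, damping=s.damping)
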