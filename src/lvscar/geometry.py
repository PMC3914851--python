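"""Kinematics and geometry of the four-region cylindrical left ventricle.

The LV wall is an initially planar sheet folded into a closed-end cylinder.
The sheet is partitioned into a 2x2 block of rectangular regions: three
healthy (remote) blocks RI, RII, RIII and one scar block S,

    row 1:  RI  (column 1)   RII (column 2)
    row 2:  RIII (column 1)  S   (column 2)

Each block has an undeformed circumferential length ``L``, longitudinal
height ``H`` and wall thickness ``T``.  The cylinder is assumed to remain
cylindrical under load, so the planar membrane deformation of every region
is described by three components: a circumferential stretch ``lam_theta``,
a longitudinal stretch ``lam_z`` and an in-plane shear ``kappa``.  The
radial stretch follows from incompressibility, giving the deformation
gradient

    F = [[lam_theta, kappa,     0                    ],
         [0,         lam_z,     0                    ],
         [0,         0,         1/(lam_theta*lam_z) ]]

with det F = 1 identically.

Coupling between regions is kinematic: regions in the same column share the
circumferential stretch, and regions in the same row share the longitudinal
stretch and the shear.  The whole configuration therefore has six shared
unknowns, collected in :class:`DeformationState`:
``lam_theta_R`` (column 1: RI, RIII), ``lam_theta_S`` (column 2: RII, S),
``lam_z_R``/``kappa_R`` (row 1: RI, RII) and ``lam_z_S``/``kappa_S``
(row 2: RIII, S).

Cavity volume.  Each wall block of deformed arc length ``l``, height ``h``
and thickness ``t`` standing at mid-wall radius ``r`` subtends a lumen
sector of volume

    V = h * (l / (2 r)) * (r - t/2)**2,

the exact volume of a cylindrical sector of inner radius ``r - t/2``.  This
reproduces the zero-thickness sector limit ``V = l r h / 2`` and, summed
over blocks forming a complete uniform cylinder, the closed-form lumen
volume ``pi (r - t/2)^2 h``.

All lengths are SI (metres) internally; the configuration layer converts
from the centimetre units used for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, InvalidKinematicsError

REGION_IDS = ("RI", "RII", "RIII", "S")

#: Index mapping from the six shared unknowns to per-region kinematics.
#: State vector layout: [lam_theta_R, lam_theta_S, lam_z_R, lam_z_S, kappa_R, kappa_S]
_IDX_LAM_THETA = (0, 1, 0, 1)  # RI, RII, RIII, S
_IDX_LAM_Z = (2, 2, 3, 3)
_IDX_KAPPA = (4, 4, 5, 5)


@dataclass(frozen=True)
class RegionGeometry:
    """Undeformed dimensions of one wall block.

    Parameters
    ----------
    region_id : str
        One of ``"RI"``, ``"RII"``, ``"RIII"``, ``"S"``.
    L, H, T : float
        Undeformed circumferential length, longitudinal height and wall
        thickness in metres.  All must be strictly positive.
    """

    region_id: str
    L: float
    H: float
    T: float

    def __post_init__(self):
        if self.region_id not in REGION_IDS:
            raise ValueError(f"unknown region_id {self.region_id!r}")
        for name in ("L", "H", "T"):
            if not getattr(self, name) > 0:
                raise ValueError(f"region {self.region_id}: {name} must be > 0")


@dataclass(frozen=True)
class LVLayout:
    """The 2x2 block arrangement of the four wall regions.

    ``regions`` is ordered (RI, RII, RIII, S).  Regions in the same column
    must have equal ``L`` and regions in the same row equal ``H``; the total
    circumference and height are the sums of the two column widths and the
    two row heights.
    """

    regions: tuple[RegionGeometry, RegionGeometry, RegionGeometry, RegionGeometry]

    def __post_init__(self):
        ids = tuple(g.region_id for g in self.regions)
        if ids != REGION_IDS:
            raise ValueError(f"regions must be ordered {REGION_IDS}, got {ids}")
        ri, rii, riii, s = self.regions
        if not np.isclose(ri.L, riii.L) or not np.isclose(rii.L, s.L):
            raise ValueError("regions in the same column must have equal L")
        if not np.isclose(ri.H, rii.H) or not np.isclose(riii.H, s.H):
            raise ValueError("regions in the same row must have equal H")

    @property
    def column_widths(self) -> tuple[float, float]:
        return (self.regions[0].L, self.regions[1].L)

    @property
    def row_heights(self) -> tuple[float, float]:
        return (self.regions[0].H, self.regions[2].H)

    @property
    def total_circumference(self) -> float:
        return sum(self.column_widths)

    @property
    def total_height(self) -> float:
        return sum(self.row_heights)


@dataclass
class DeformationState:
    """The six shared kinematic unknowns of the coupled four-region model."""

    lam_theta_R: float = 1.0
    lam_theta_S: float = 1.0
    lam_z_R: float = 1.0
    lam_z_S: float = 1.0
    kappa_R: float = 0.0
    kappa_S: float = 0.0

    def __post_init__(self):
        for name in ("lam_theta_R", "lam_theta_S", "lam_z_R", "lam_z_S"):
            if not np.real(getattr(self, name)) > 0:
                raise InvalidKinematicsError(f"{name} must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.lam_theta_R, self.lam_theta_S, self.lam_z_R,
             self.lam_z_S, self.kappa_R, self.kappa_S]
        )

    @classmethod
    def from_array(cls, x) -> "DeformationState":
        x = np.asarray(x)
        return cls(*(x[i] for i in range(6)))


def build_deformation_gradient(lam_theta, lam_z, kappa) -> np.ndarray:
    """Assemble the membrane deformation gradient.

    Accepts scalars or broadcastable arrays; returns an array of shape
    ``(..., 3, 3)``.  The radial component ``1/(lam_theta*lam_z)`` enforces
    incompressibility, so ``det F == 1`` to machine precision.
    """
    lam_theta, lam_z, kappa = np.broadcast_arrays(
        np.asarray(lam_theta), np.asarray(lam_z), np.asarray(kappa)
    )
    if np.any(np.real(lam_theta) <= 0) or np.any(np.real(lam_z) <= 0):
        raise InvalidKinematicsError("stretches must be strictly positive")
    F = np.zeros(lam_theta.shape + (3, 3), dtype=np.result_type(lam_theta, lam_z, kappa, float))
    F[..., 0, 0] = lam_theta
    F[..., 0, 1] = kappa
    F[..., 1, 1] = lam_z
    F[..., 2, 2] = 1.0 / (lam_theta * lam_z)
    return F


def green_strain(F: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain E = (F^T F - I)/2 for ``(..., 3, 3)`` tensors."""
    F = np.asarray(F)
    C = np.swapaxes(F, -1, -2) @ F
    return (C - np.eye(3)) / 2.0


def plane_C(lam_theta, lam_z, kappa):
    """Planar right Cauchy-Green components for the membrane kinematics.

    Returns ``(C_tt, C_tz, C_zz, C_rr)`` where the indices are
    circumferential (theta), longitudinal (z) and radial (r).  Complex
    inputs are supported (complex-step differentiation).
    """
    C_tt = lam_theta * lam_theta
    C_tz = lam_theta * kappa
    C_zz = kappa * kappa + lam_z * lam_z
    C_rr = 1.0 / (C_tt * lam_z * lam_z)
    return C_tt, C_tz, C_zz, C_rr


def deformed_dimensions(region: RegionGeometry, lam_theta, lam_z):
    """Deformed (l, h, t) of a region under the given stretches.

    Thickness follows from wall incompressibility, so the wall material
    volume ``l*h*t = L*H*T`` is conserved exactly.
    """
    if np.any(np.real(lam_theta) <= 0) or np.any(np.real(lam_z) <= 0):
        raise InvalidKinematicsError("stretches must be strictly positive")
    l = lam_theta * region.L
    h = lam_z * region.H
    t = region.T / (lam_theta * lam_z)
    return l, h, t


def lv_radius(layout: LVLayout, state) -> float:
    """Mid-wall radius of the deformed cylinder.

    The deformed circumference is the sum of the two deformed column
    widths; the cylindrical-shape assumption gives
    ``r = circumference / (2 pi)``.
    """
    x = state.as_array() if isinstance(state, DeformationState) else np.asarray(state)
    L1, L2 = layout.column_widths
    circ = x[..., 0] * L1 + x[..., 1] * L2
    if np.any(np.real(circ) <= 0):
        raise DegenerateGeometryError("deformed circumference must be positive")
    return circ / (2.0 * np.pi)


def lv_height(layout: LVLayout, state):
    """Total deformed longitudinal height (sum of the two deformed rows)."""
    x = state.as_array() if isinstance(state, DeformationState) else np.asarray(state)
    H1, H2 = layout.row_heights
    return x[..., 2] * H1 + x[..., 3] * H2


def region_volume(l, h, t, r):
    """Lumen volume subtended by one wall sector.

    ``V = h * (l / (2 r)) * (r - t/2)**2`` -- the volume of the cylindrical
    sector of arc ``l`` at mid-wall radius ``r`` bounded by the inner wall
    surface at radius ``r - t/2``.
    """
    if np.any(np.real(r) <= 0):
        raise DegenerateGeometryError("radius must be positive")
    if np.any(np.real(t) >= 2.0 * np.real(r)):
        raise DegenerateGeometryError("wall thickness t >= 2 r: no lumen")
    return h * (l / (2.0 * r)) * (r - t / 2.0) ** 2


def total_volume(layout: LVLayout, state):
    """Total cavity volume: the four sector volumes at the common radius."""
    x = state.as_array() if isinstance(state, DeformationState) else np.asarray(state)
    r = lv_radius(layout, x)
    V = 0.0
    for i, region in enumerate(layout.regions):
        lt = x[..., _IDX_LAM_THETA[i]]
        lz = x[..., _IDX_LAM_Z[i]]
        l, h, t = deformed_dimensions(region, lt, lz)
        V = V + region_volume(l, h, t, r)
    return V


def cavity_volume_batched(layout: LVLayout, x: np.ndarray):
    """Vectorised cavity volume for solver-internal state arrays ``(..., 6)``.

    Identical algebra to :func:`total_volume` but without admissibility
    guards, so it stays analytic for complex-step differentiation.
    """
    L1, L2 = layout.column_widths
    r = (x[..., 0] * L1 + x[..., 1] * L2) / (2.0 * np.pi)
    V = 0.0
    for i, region in enumerate(layout.regions):
        lt = x[..., _IDX_LAM_THETA[i]]
        lz = x[..., _IDX_LAM_Z[i]]
        l = lt * region.L
        h = lz * region.H
        t = region.T / (lt * lz)
        V = V + h * (l / (2.0 * r)) * (r - t / 2.0) ** 2
    return V


def make_layout(total_circumference: float, total_height: float,
                healthy_thickness: float, scar_thickness: float,
                scar_circ_fraction: float = 0.5,
                scar_height_fraction: float = 0.5) -> LVLayout:
    """Build the standard 2x2 layout from overall dimensions (metres).

    The scar occupies the (row 2, column 2) block with the given fractions
    of the total circumference and height; the default halves give a scar
    covering 25% of the wall area.
    """
    if not 0 < scar_circ_fraction < 1 or not 0 < scar_height_fraction < 1:
        raise ValueError("scar fractions must lie strictly between 0 and 1")
    L2 = total_circumference * scar_circ_fraction
    L1 = total_circumference - L2
    H2 = total_height * scar_height_fraction
    H1 = total_height - H2
    th, ts = healthy_thickness, scar_thickness
    return LVLayout(
        regions=(
            RegionGeometry("RI", L1, H1, th),
            RegionGeometry("RII", L2, H1, th),
            RegionGeometry("RIII", L1, H2, th),
            RegionGeometry("S", L2, H2, ts),
        )
    )
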