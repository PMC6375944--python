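"""Voxelized coccolith / coccosphere phantoms with analytic ground truth.

The generator emulates the morphology of Noëlaerhabdaceae coccoliths: two
elliptical shields (distal outer full axes ``a, b``; proximal rim of radial
length ``L``) whose mid-surfaces rise conically away from the coccolith
plane at inclinations ``alpha_major / alpha_minor``, a tube of out-of-plane
height ``t`` built from ``n`` wedge segments around the grid ellipse
``(a_g, b_g)`` separated by 1-voxel radial gaps, and a central grid filled
to a fraction ``grid_fill`` by radial laths.  Population-level masses follow
the allometric law ``m = k_p * p**beta`` with multiplicative log-normal
scatter.

Every generated object comes with analytic ground truth (mass from the
continuum solid volume at calcite density 2.71 pg/µm³, perimeter from the
elliptical grid boundary, segment count, rim length, tube height,
inclinations) so that measurement operators can be scored against it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from ._geom import arc_fraction as _arc_fraction
from ._geom import arc_table as _arc_table
from ._geom import rotation_about as _rotation_about
from .exceptions import PackingError, SpecValidationError, UnresolvableSegmentsError
from .records import MorphoRecord
from .volume import VoxelVolume

__all__ = [
    "CALCITE_DENSITY_PG_UM3",
    "CoccolithSpec",
    "CoccosphereSpec",
    "PopulationParams",
    "build_coccolith",
    "build_coccosphere",
    "sample_population",
    "default_coccolith_spec",
    "geometry_for_mass",
    "analytic_mass",
]

#: density of calcite, pg per µm³ (equivalently g/cm³)
CALCITE_DENSITY_PG_UM3 = 2.71

#: default ratio of tube radial wall width to nothing — an absolute default, µm
DEFAULT_TUBE_WALL_UM = 0.18

#: plausibility band for the segment width w = p/n, µm
DEFAULT_W_BAND = (0.05, 0.3)


# ======================================================================
# parametric specs
# ======================================================================

@dataclass
class CoccolithSpec:
    """Ground-truth parametric geometry of a single coccolith.

    All axes are FULL axes (the circle limit of the perimeter formula
    forces this convention), lengths in µm, angles in degrees.
    """

    a: float                 # shield major axis
    b: float                 # shield minor axis
    a_g: float               # grid major axis
    b_g: float               # grid minor axis
    n: int                   # segment count
    t: float                 # tube height (out-of-plane)
    L: float = 0.0           # proximal rim length
    alpha_major: float = 30.0
    alpha_minor: float = 25.0
    grid_fill: float = 0.0   # fraction of central area occupied by calcite
    label: str = ""

    def validate(self, w_band: tuple[float, float] = DEFAULT_W_BAND) -> None:
        if not (self.a >= self.b > 0):
            raise SpecValidationError("shield axes must satisfy a >= b > 0")
        if not (self.a_g >= self.b_g > 0):
            raise SpecValidationError("grid axes must satisfy a_g >= b_g > 0")
        if not self.a > self.a_g:
            raise SpecValidationError("shield must enclose the grid (a > a_g)")
        if self.n < 3:
            raise SpecValidationError("segment count n must be >= 3")
        if self.t < 0:
            raise SpecValidationError("tube height t must be >= 0")
        if self.L < 0:
            raise SpecValidationError("rim length L must be >= 0")
        if not (0.0 <= self.grid_fill <= 1.0):
            raise SpecValidationError("grid_fill must lie in [0, 1]")
        w = self.w
        if not (w_band[0] <= w <= w_band[1]):
            raise SpecValidationError(
                f"segment width w = p/n = {w:.4f} µm outside plausibility "
                f"band {w_band}"
            )

    @property
    def p(self) -> float:
        """Peripheral grid perimeter from the ellipse formula, µm."""
        from .morphometrics import ellipse_perimeter

        return ellipse_perimeter(self.a_g, self.b_g)

    @property
    def w(self) -> float:
        """Average segment width p/n, µm."""
        return self.p / self.n

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CoccolithSpec":
        return cls(**json.loads(text))


@dataclass
class CoccosphereSpec:
    """A sphere of diameter ``phi_cs`` (µm) covered by ``c_n`` coccoliths."""

    phi_cs: float
    coccoliths: list[CoccolithSpec]
    placement_seed: int = 0

    @property
    def c_n(self) -> int:
        return len(self.coccoliths)

    def validate(self) -> None:
        if self.c_n < 1:
            raise SpecValidationError("a coccosphere needs at least one coccolith")
        for c in self.coccoliths:
            c.validate()
        if self.phi_cs < max(c.a for c in self.coccoliths):
            raise SpecValidationError(
                "coccosphere diameter must be >= the largest coccolith major axis"
            )

    def to_json(self) -> str:
        d = {
            "phi_cs": self.phi_cs,
            "placement_seed": self.placement_seed,
            "coccoliths": [asdict(c) for c in self.coccoliths],
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CoccosphereSpec":
        d = json.loads(text)
        return cls(
            phi_cs=d["phi_cs"],
            placement_seed=d.get("placement_seed", 0),
            coccoliths=[CoccolithSpec(**c) for c in d["coccoliths"]],
        )


@dataclass
class PopulationParams:
    """Generative parameters of a morphometric population.

    ``m = k_p * p**beta * exp(eps)`` with ``eps ~ N(0, sigma_log²)``,
    ``n = round(p / w)`` (round-half-to-even), ``L = L_over_p * p`` and
    ``t = t_over_p * p``.  Defaults are the fitted population-level
    coefficients for Noëlaerhabdaceae coccoliths.
    """

    k_p: float = 4.92e-2          # mass prefactor, pg µm^-beta
    beta: float = 3.175           # allometric exponent
    w: float = 0.112              # segment width, µm
    sigma_log: float = 0.0        # sd of multiplicative log-normal scatter
    p_range: tuple[float, float] = (3.0, 7.0)   # grid perimeter range, µm
    L_over_p: float = 0.12
    t_over_p: float = 0.18
    seed: int = 0

    def validate(self) -> None:
        if self.k_p <= 0 or self.beta <= 0 or self.w <= 0:
            raise SpecValidationError("k_p, beta and w must be positive")
        if self.sigma_log < 0:
            raise SpecValidationError("sigma_log must be >= 0")
        lo, hi = self.p_range
        if not (0 < lo <= hi <= 20):
            raise SpecValidationError("p_range must lie within (0, 20] µm")


# ======================================================================
# continuum occupancy
# ======================================================================

def _derived_thicknesses(
    spec: CoccolithSpec,
    shield_thickness_um: float | None,
    grid_thickness_um: float | None,
) -> tuple[float, float]:
    sh = 0.25 * spec.t if shield_thickness_um is None else shield_thickness_um
    gh = sh if grid_thickness_um is None else grid_thickness_um
    return sh, gh



def _effective_rim(spec: CoccolithSpec, tube_wall_um: float) -> float:
    """Proximal rim length clipped so the rim stays under the distal shield
    (the distal shield is the wider one in Noëlaerhabdaceae coccoliths)."""
    sa_cap = 0.97 * spec.a / 2.0 - (spec.a_g / 2.0 + tube_wall_um)
    sb_cap = 0.97 * spec.b / 2.0 - (spec.b_g / 2.0 + tube_wall_um)
    return max(0.0, min(spec.L, sa_cap, sb_cap))


def _occupancy(
    X: np.ndarray,
    Y: np.ndarray,
    Z: np.ndarray,
    spec: CoccolithSpec,
    *,
    gap_um: float,
    gaps: bool,
    tube_wall_um: float,
    shield_thickness_um: float,
    grid_thickness_um: float,
    arc_table: tuple[np.ndarray, np.ndarray, float] | None = None,
) -> np.ndarray:
    """Boolean solid-calcite indicator at physical points (X, Y, Z) in the
    coccolith frame (plane z = 0, center at the origin, major axis x)."""
    sa_g, sb_g = spec.a_g / 2.0, spec.b_g / 2.0
    sa_t, sb_t = sa_g + tube_wall_um, sb_g + tube_wall_um
    sa_a, sb_a = spec.a / 2.0, spec.b / 2.0
    L_eff = _effective_rim(spec, tube_wall_um)
    sa_p, sb_p = sa_t + L_eff, sb_t + L_eff
    sh, gh = shield_thickness_um, grid_thickness_um
    tanA = math.tan(math.radians(spec.alpha_major))
    tanB = math.tan(math.radians(spec.alpha_minor))

    rho_g = np.hypot(X / sa_g, Y / sb_g)
    rho_t = np.hypot(X / sa_t, Y / sb_t)
    rise = np.hypot(X * tanA, Y * tanB)

    occ = np.zeros(X.shape, dtype=bool)

    # --- tube: annulus between grid and tube-outer ellipses, height t ----
    if spec.t > 0:
        tube = (rho_g >= 1.0) & (rho_t <= 1.0) & (np.abs(Z) <= spec.t / 2.0)
        if gaps and tube.any():
            if arc_table is None:
                arc_table = _arc_table(sa_g, sb_g)
            perim = arc_table[2]
            E = np.arctan2(Y[tube] / sb_g, X[tube] / sa_g)
            s = _arc_fraction(E, arc_table)
            d = np.abs(s * spec.n - np.round(s * spec.n)) / spec.n  # s-dist to boundary
            # constant *physical* gap width at every radius: the tangential
            # distance grows with the local radius ratio rho_g
            tube_keep = d * perim * np.maximum(rho_g[tube], 1.0) >= gap_um / 2.0
            idx = np.where(tube)
            tube[idx] = tube_keep
        occ |= tube

    # --- shields: plates of vertical thickness sh on conical mid-surfaces
    if sh > 0:
        outside_tube = rho_t > 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            cone = rise * (1.0 - 1.0 / np.maximum(rho_t, 1e-12))
        # distal shield: from tube outer boundary out to the (a, b) ellipse
        distal = (
            outside_tube
            & (np.hypot(X / sa_a, Y / sb_a) <= 1.0)
            & (np.abs(Z - (spec.t / 2.0 + cone)) <= sh / 2.0)
        )
        occ |= distal
        if L_eff > 0:
            proximal = (
                outside_tube
                & (np.hypot(X / sa_p, Y / sb_p) <= 1.0)
                & (np.abs(Z - (-spec.t / 2.0 + cone)) <= sh / 2.0)
            )
            occ |= proximal

    # --- central grid: radial laths filling grid_fill of the area ---------
    # laths live on the outer half of the grid (rho in [0.5, 1], so they
    # never taper below the voxel size), are centered mid-segment (away
    # from the tube gaps, keeping them attached to the tube) and their
    # angular fill is widened to preserve grid_fill of the full area
    if spec.grid_fill > 0 and gh > 0:
        inside = (rho_g < 1.0) & (Z >= -spec.t / 2.0) & (Z <= -spec.t / 2.0 + gh)
        if spec.grid_fill >= 1.0:
            occ |= inside
        elif inside.any():
            if arc_table is None:
                arc_table = _arc_table(sa_g, sb_g)
            f_eff = _lath_fill(spec.grid_fill)
            E = np.arctan2(Y[inside] / sb_g, X[inside] / sa_g)
            s = _arc_fraction(E, arc_table)
            K = _lath_count(spec, f_eff, arc_table[2], gap_um)
            fill = (np.abs(np.mod(s * K, 1.0) - 0.5) < f_eff / 2.0) \
                & (rho_g[inside] >= _LATH_RHO_MIN)
            idx = np.where(inside)
            inside[idx] = fill
            occ |= inside

    return occ


#: laths span rho in [_LATH_RHO_MIN, 1] of the grid ellipse
_LATH_RHO_MIN = 0.5


def _lath_fill(grid_fill: float) -> float:
    """Angular fill fraction of the lath band that preserves ``grid_fill``
    of the full central area."""
    band_area_frac = 1.0 - _LATH_RHO_MIN ** 2
    return min(1.0, grid_fill / band_area_frac)


def _lath_count(spec: CoccolithSpec, f_eff: float, perim: float, gap_um: float) -> int:
    """Number of radial grid laths: as many as keep each lath >= ~2 voxels
    wide at its inner end (and no more than one per segment)."""
    if gap_um > 0:
        k = int(f_eff * perim * _LATH_RHO_MIN / (2.0 * gap_um))
    else:
        k = spec.n
    return max(4, min(spec.n, k))


# ======================================================================
# analytic (continuum) mass
# ======================================================================

def analytic_mass(
    spec: CoccolithSpec,
    *,
    gap_um: float = 0.0,
    gaps: bool = True,
    tube_wall_um: float = DEFAULT_TUBE_WALL_UM,
    shield_thickness_um: float | None = None,
    grid_thickness_um: float | None = None,
    n_quad: int = 8192,
) -> float:
    """Continuum solid volume of the phantom times the calcite density, pg.

    Shield plates have constant vertical thickness, so their volume is the
    exact in-plane elliptical-annulus area times the plate thickness.  The
    tube and grid, whose wedge gaps / laths are defined in the arc-length
    parametrization of the grid ellipse, are integrated by 1D quadrature
    over the parametric angle.
    """
    sh, gh = _derived_thicknesses(spec, shield_thickness_um, grid_thickness_um)
    sa_g, sb_g = spec.a_g / 2.0, spec.b_g / 2.0
    sa_t, sb_t = sa_g + tube_wall_um, sb_g + tube_wall_um
    sa_a, sb_a = spec.a / 2.0, spec.b / 2.0
    L_eff = _effective_rim(spec, tube_wall_um)
    sa_p, sb_p = sa_t + L_eff, sb_t + L_eff

    table = _arc_table(sa_g, sb_g, m=n_quad)
    E = 0.5 * (table[0][1:] + table[0][:-1])
    dE = np.diff(table[0])
    s = _arc_fraction(E, table)
    perim = table[2]

    volume = 0.0

    # tube via quadrature in the scaled polar frame u = x/sa_g, v = y/sb_g
    if spec.t > 0:
        R_out = 1.0 / np.hypot(np.cos(E) * sa_g / sa_t, np.sin(E) * sb_g / sb_t)
        sector_area = sa_g * sb_g * (R_out ** 2 - 1.0) / 2.0
        annulus = spec.t * float(np.sum(sector_area * dE))
        if gaps and gap_um > 0:
            # each of the n gaps is a radial slit of constant width gap_um
            # spanning the wall; subtract n rectangles (slit width x wall
            # radial length at the slit position)
            from ._geom import ellipse_radius

            Et, st, _ = table
            E_k = np.interp((np.arange(spec.n) + 0.0) / spec.n, st, Et)
            psi_k = np.arctan2(sb_g * np.sin(E_k), sa_g * np.cos(E_k))
            wall_len = ellipse_radius(psi_k, sa_t, sb_t) - ellipse_radius(psi_k, sa_g, sb_g)
            annulus -= spec.t * gap_um * float(np.sum(np.maximum(wall_len, 0.0)))
        volume += max(annulus, 0.0)

    # shields: area x vertical thickness (exact)
    if sh > 0:
        area_d = math.pi * max(0.0, sa_a * sb_a - sa_t * sb_t)
        volume += area_d * sh
        if L_eff > 0:
            area_p = math.pi * max(0.0, sa_p * sb_p - sa_t * sb_t)
            volume += area_p * sh

    # grid laths (restricted to rho in [_LATH_RHO_MIN, 1])
    if spec.grid_fill > 0 and gh > 0:
        if spec.grid_fill >= 1.0:
            area_frac = 1.0
            fill = 1.0
        else:
            f_eff = _lath_fill(spec.grid_fill)
            area_frac = 1.0 - _LATH_RHO_MIN ** 2
            K = _lath_count(spec, f_eff, perim, gap_um)
            fill = (np.abs(np.mod(s * K, 1.0) - 0.5) < f_eff / 2.0).astype(float)
        volume += gh * area_frac * float(np.sum(sa_g * sb_g * 0.5 * fill * dE))

    return CALCITE_DENSITY_PG_UM3 * volume


def geometry_for_mass(
    spec: CoccolithSpec,
    target_mass_pg: float,
    *,
    gap_um: float = 0.0,
    wall_range_um: tuple[float, float] = (0.04, 2.5),
) -> dict:
    """Solve for the tube wall width that makes the analytic mass hit a target.

    Most of a coccolith's calcite sits in the tube region, so the target
    mass is reached by widening or narrowing the radial tube wall while
    the shield and grid plate thicknesses stay at their defaults (a fixed
    fraction of the tube height).  Returns keyword arguments for
    :func:`build_coccolith`.
    """
    base_sh, base_gh = _derived_thicknesses(spec, None, None)

    def mass_at(wall: float) -> float:
        return analytic_mass(
            spec,
            gap_um=gap_um,
            tube_wall_um=wall,
            shield_thickness_um=base_sh,
            grid_thickness_um=base_gh,
            n_quad=2048,
        )

    lo, hi = wall_range_um
    if not (mass_at(lo) <= target_mass_pg <= mass_at(hi)):
        raise SpecValidationError(
            f"target mass {target_mass_pg:.3g} pg unreachable by tube-wall "
            f"scaling for this geometry"
        )
    wall = optimize.brentq(lambda f: mass_at(f) - target_mass_pg, lo, hi, xtol=1e-8)
    return {
        "tube_wall_um": wall,
        "shield_thickness_um": base_sh,
        "grid_thickness_um": base_gh,
    }


# ======================================================================
# voxelization
# ======================================================================

def _grid_axes(half_extents_um: np.ndarray, voxel_um: float) -> tuple[tuple[int, int, int], np.ndarray]:
    shape = tuple(int(math.ceil(2.0 * h / voxel_um)) for h in half_extents_um)
    origin = -np.asarray(shape) * voxel_um / 2.0
    return shape, origin  # type: ignore[return-value]


def _half_extents(spec: CoccolithSpec, sh: float, tube_wall_um: float, pad_um: float) -> np.ndarray:
    sa_t = spec.a_g / 2.0 + tube_wall_um
    sb_t = spec.b_g / 2.0 + tube_wall_um
    rise = max(
        math.tan(math.radians(spec.alpha_major)) * max(0.0, spec.a / 2.0 - sa_t),
        math.tan(math.radians(spec.alpha_minor)) * max(0.0, spec.b / 2.0 - sb_t),
    )
    hx = max(spec.a / 2.0, sa_t + spec.L) + pad_um
    hy = max(spec.b / 2.0, sb_t + spec.L) + pad_um
    hz = spec.t / 2.0 + sh / 2.0 + rise + pad_um
    return np.array([hx, hy, hz])


def build_coccolith(
    spec: CoccolithSpec,
    voxel_nm: float,
    *,
    rotation: np.ndarray | None = None,
    gaps: bool = True,
    pad_um: float = 0.15,
    tube_wall_um: float = DEFAULT_TUBE_WALL_UM,
    shield_thickness_um: float | None = None,
    grid_thickness_um: float | None = None,
    w_band: tuple[float, float] = DEFAULT_W_BAND,
) -> tuple[VoxelVolume, MorphoRecord]:
    """Voxelize one coccolith and return the volume plus analytic ground truth.

    Parameters
    ----------
    rotation : (3, 3) ndarray, optional
        Rotation applied to the coccolith (local frame -> volume frame);
        the output grid is then a bounding cube.
    gaps : bool
        Disable to build a plain (un-segmented) tube annulus.
    """
    spec.validate(w_band=w_band)
    voxel_um = voxel_nm / 1000.0
    if gaps and spec.t > 0 and spec.w / voxel_um < 2.0:
        raise UnresolvableSegmentsError(
            f"segment width w = {spec.w * 1000:.0f} nm is below 2 voxels at "
            f"{voxel_nm} nm; inter-segment gaps cannot be voxelized"
        )
    gap_um = 1.5 * voxel_um  # minimal radial gap that survives voxelization
    sh, gh = _derived_thicknesses(spec, shield_thickness_um, grid_thickness_um)

    half = _half_extents(spec, sh, tube_wall_um, pad_um)
    if rotation is not None:
        half = np.full(3, float(np.linalg.norm(half)))
    shape, origin = _grid_axes(half, voxel_um)
    if rotation is None and spec.t > 0:
        # align the tube base plane (z = -t/2) with a voxel boundary: the
        # sampled tube height then rounds to the nearest voxel count
        # instead of drifting coherently with the grid offset
        origin[2] += (-spec.t / 2.0 - origin[2]) % voxel_um

    x = origin[0] + (np.arange(shape[0]) + 0.5) * voxel_um
    y = origin[1] + (np.arange(shape[1]) + 0.5) * voxel_um
    z = origin[2] + (np.arange(shape[2]) + 0.5) * voxel_um
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    if rotation is not None:
        R = np.asarray(rotation, dtype=float)
        Xl = R[0, 0] * X + R[1, 0] * Y + R[2, 0] * Z
        Yl = R[0, 1] * X + R[1, 1] * Y + R[2, 1] * Z
        Zl = R[0, 2] * X + R[1, 2] * Y + R[2, 2] * Z
        X, Y, Z = Xl, Yl, Zl

    occ = _occupancy(
        X, Y, Z, spec,
        gap_um=gap_um, gaps=gaps, tube_wall_um=tube_wall_um,
        shield_thickness_um=sh, grid_thickness_um=gh,
    )
    vol = VoxelVolume(occ.astype(np.float32), voxel_nm, origin)

    truth = MorphoRecord(
        m=analytic_mass(
            spec, gap_um=gap_um, gaps=gaps,
            tube_wall_um=tube_wall_um, shield_thickness_um=sh,
            grid_thickness_um=gh,
        ),
        a=spec.a, b=spec.b, a_g=spec.a_g, b_g=spec.b_g,
        p=spec.p, n=spec.n if gaps else None,
        L=_effective_rim(spec, tube_wall_um), t=spec.t,
        alpha_major=spec.alpha_major, alpha_minor=spec.alpha_minor,
    )
    return vol, truth


# ======================================================================
# coccospheres
# ======================================================================

def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _frame_for_direction(d: np.ndarray) -> np.ndarray:
    """Rotation matrix whose third column is d (local z -> radial)."""
    d = d / np.linalg.norm(d)
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    x = np.cross(ref, d)
    x /= np.linalg.norm(x)
    y = np.cross(d, x)
    return np.stack([x, y, d], axis=1)


def build_coccosphere(
    spec: CoccosphereSpec,
    voxel_nm: float,
    *,
    pad_um: float = 0.2,
    max_retries: int = 30,
    tube_wall_um: float = DEFAULT_TUBE_WALL_UM,
) -> tuple[VoxelVolume, VoxelVolume, list[MorphoRecord]]:
    """Place coccoliths tangentially on a sphere and voxelize them.

    Directions follow a Fibonacci lattice, randomly rotated as a whole and
    jittered per coccolith under ``placement_seed``.  Each coccolith sits
    with its distal side outward; overlap (including a 1-voxel clearance)
    triggers jittered retries, then :class:`PackingError`.

    Returns the density volume, a companion integer label volume
    (0 = background, i = coccolith id i) and the per-coccolith ground-truth
    records.
    """
    spec.validate()
    voxel_um = voxel_nm / 1000.0
    rng = np.random.default_rng(spec.placement_seed)
    R_s = spec.phi_cs / 2.0

    dirs = _fibonacci_directions(spec.c_n)
    # random global rotation so lattices differ between seeds
    g = _rotation_about(rng.normal(size=3), rng.uniform(0, 2 * math.pi))
    dirs = dirs @ g.T

    # per-coccolith derived geometry
    geoms = []
    for c in spec.coccoliths:
        sh, gh = _derived_thicknesses(c, None, None)
        half = _half_extents(c, sh, tube_wall_um, 2 * voxel_um)
        z_top = half[2]
        geoms.append((sh, gh, half, z_top))

    extent = R_s + max(np.linalg.norm(h) for _, _, h, _ in geoms) + pad_um
    shape, origin = _grid_axes(np.full(3, extent), voxel_um)
    labels = np.zeros(shape, dtype=np.int32)

    x0 = origin[0] + 0.5 * voxel_um
    records: list[MorphoRecord] = []
    struct = ndimage.generate_binary_structure(3, 3)

    for i, (c, (sh, gh, half, z_top)) in enumerate(zip(spec.coccoliths, geoms)):
        placed = False
        d = dirs[i]
        for attempt in range(max_retries):
            if attempt > 0:
                jit = rng.normal(scale=0.08 * attempt, size=3)
                d = dirs[i] + jit
                d /= np.linalg.norm(d)
            R = _frame_for_direction(d)
            # spin about the local normal for variety
            R = R @ _rotation_about(np.array([0.0, 0.0, 1.0]), rng.uniform(0, 2 * math.pi))
            center = d * (R_s - z_top)

            rad = float(np.linalg.norm(half)) + voxel_um
            lo_idx = np.floor((center - rad - origin) / voxel_um).astype(int)
            hi_idx = np.ceil((center + rad - origin) / voxel_um).astype(int)
            lo_idx = np.clip(lo_idx, 0, np.asarray(shape))
            hi_idx = np.clip(hi_idx, 0, np.asarray(shape))
            sl = tuple(slice(lo, hi) for lo, hi in zip(lo_idx, hi_idx))

            axes = [
                origin[k] + (np.arange(lo_idx[k], hi_idx[k]) + 0.5) * voxel_um - center[k]
                for k in range(3)
            ]
            X, Y, Z = np.meshgrid(*axes, indexing="ij")
            Xl = R[0, 0] * X + R[1, 0] * Y + R[2, 0] * Z
            Yl = R[0, 1] * X + R[1, 1] * Y + R[2, 1] * Z
            Zl = R[0, 2] * X + R[1, 2] * Y + R[2, 2] * Z
            occ = _occupancy(
                Xl, Yl, Zl, c,
                gap_um=voxel_um, gaps=True, tube_wall_um=tube_wall_um,
                shield_thickness_um=sh, grid_thickness_um=gh,
            )
            grown = ndimage.binary_dilation(occ, structure=struct)
            if np.any(labels[sl][grown] != 0):
                continue
            labels[sl][occ] = i + 1
            placed = True
            break
        if not placed:
            raise PackingError(
                f"could not place coccolith {i + 1}/{spec.c_n} after "
                f"{max_retries} jittered retries"
            )
        truth = MorphoRecord(
            m=analytic_mass(
                c, gap_um=voxel_um, tube_wall_um=tube_wall_um,
                shield_thickness_um=sh, grid_thickness_um=gh,
            ),
            a=c.a, b=c.b, a_g=c.a_g, b_g=c.b_g, p=c.p, n=c.n,
            L=_effective_rim(c, tube_wall_um), t=c.t,
            alpha_major=c.alpha_major, alpha_minor=c.alpha_minor,
            coccolith_id=i + 1,
        )
        records.append(truth)

    density = VoxelVolume((labels > 0).astype(np.float32), voxel_nm, origin)
    label_vol = VoxelVolume(labels, voxel_nm, origin)
    return density, label_vol, records


# ======================================================================
# population sampling
# ======================================================================

def sample_population(params: PopulationParams, N: int) -> pd.DataFrame:
    """Draw a morphometric population from the allometric generative model.

    Each record draws ``p`` uniformly from ``p_range``; then
    ``n = round(p/w)`` (half-to-even), ``m = k_p p^beta exp(eps)`` with
    ``eps ~ N(0, sigma_log²)``, ``L = L_over_p p`` and ``t = t_over_p p``.
    Reproducible under ``params.seed``.
    """
    params.validate()
    if N < 1:
        raise SpecValidationError("population size N must be >= 1")
    rng = np.random.default_rng(params.seed)
    p = rng.uniform(params.p_range[0], params.p_range[1], size=N)
    n = np.round(p / params.w).astype(int)
    eps = rng.normal(0.0, params.sigma_log, size=N) if params.sigma_log > 0 else np.zeros(N)
    m = params.k_p * p ** params.beta * np.exp(eps)
    return pd.DataFrame(
        {
            "id": np.arange(1, N + 1),
            "p_um": p,
            "n": n,
            "m_pg": m,
            "L_um": params.L_over_p * p,
            "t_um": params.t_over_p * p,
        }
    )


def default_coccolith_spec(
    p: float,
    *,
    n: int | None = None,
    w: float = 0.112,
    e_grid: float = 0.74,
    e_shield: float = 0.57,
    shield_scale: float = 1.8,
    L: float | None = None,
    t: float | None = None,
    L_over_p: float = 0.12,
    t_over_p: float = 0.18,
    alpha_major: float = 30.0,
    alpha_minor: float = 25.0,
    grid_fill: float = 0.15,
    label: str = "",
) -> CoccolithSpec:
    """Realistic coccolith geometry for a requested grid perimeter ``p``.

    Solves the grid ellipse from ``p`` and the grid eccentricity, places the
    shield outline at ``shield_scale`` times the grid axes with the shield
    eccentricity, and derives ``n``, ``L`` and ``t`` from the population
    slopes unless given explicitly.
    """
    q_g = math.sqrt(1.0 - e_grid ** 2)
    # p = a_g * pi * sqrt((1 + q²)/2 - (1 - q)²/8)
    f = math.pi * math.sqrt((1.0 + q_g ** 2) / 2.0 - (1.0 - q_g) ** 2 / 8.0)
    a_g = p / f
    b_g = a_g * q_g
    a = shield_scale * a_g
    b = a * math.sqrt(1.0 - e_shield ** 2)
    if n is None:
        n = int(np.round(p / w))
    return CoccolithSpec(
        a=a, b=b, a_g=a_g, b_g=b_g, n=n,
        t=t_over_p * p if t is None else t,
        L=L_over_p * p if L is None else L,
        alpha_major=alpha_major, alpha_minor=alpha_minor,
        grid_fill=grid_fill, label=label,
    )
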