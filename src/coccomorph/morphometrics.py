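"""Per-coccolith measurement operators on 3D density volumes.

The operators mirror a volumetric-imaging workflow for coccoliths: the
thresholded volume is split into individual coccoliths (extract-and-
subtract with watershed splitting of touching pairs), each component is
oriented by its voxel inertia tensor, and mass, thickness map, shield /
grid ellipse fits, grid perimeter, segment count, proximal rim length,
tube height and shield inclination are extracted.

Conventions
-----------
* Densities are dimensionless (1.0 = solid calcite); the *isovalue* is the
  density below which a voxel counts as empty.
* All axes reported by ellipse fits are FULL axes, the convention forced by
  the circle limit of the perimeter formula (p = πd for a circle).
* Voxel indices are 0-based; physical positions refer to voxel centers.
* Oriented volumes have the coccolith plane normal along the third grid
  axis (distal side +z) and the major axis along the first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import EllipseModel, find_contours
from skimage.morphology import disk
from skimage.segmentation import watershed

from ._geom import ellipse_radius, uniform_arc_angles
from .exceptions import (
    EmptyVolumeError,
    FitError,
    MeasurementError,
    OrientationError,
)
from .records import MorphoRecord
from .volume import VoxelVolume

__all__ = [
    "MeasureConfig",
    "EllipseFit",
    "SegmentationResult",
    "ellipse_perimeter",
    "measure_mass",
    "mass_isovalue_sensitivity",
    "thickness_map",
    "orient_coccolith",
    "fit_ellipse",
    "extract_ellipses",
    "count_segments",
    "measure_rim_and_tube",
    "measure_inclination",
    "measure_coccolith",
    "segment_coccosphere",
]

#: thickness-map fraction above which a column belongs to the tube annulus
#: (must exceed two stacked shield plates, ~0.5 of the tube height, plus
#: voxel quantization, while staying below the tube height itself)
_TUBE_RING_FRACTION = 0.72
#: flatness ratio sqrt(λ_min/λ_max) above which a component is not plate-like
_PLATE_FLATNESS_MAX = 0.5


@dataclass
class MeasureConfig:
    """Measurement parameters.

    isovalue : density threshold as a fraction of solid calcite (0..1)
    calcite_density : pg/µm³, used for the volume-to-mass conversion
    min_coccolith_voxels : components smaller than this are excluded
    angular_bins : samples of the angular tube profile for segment counting
    """

    isovalue: float = 0.5
    calcite_density: float = 2.71
    min_coccolith_voxels: int = 400
    angular_bins: int = 1440

    def __post_init__(self) -> None:
        if not (0.0 < self.isovalue < 1.0):
            raise ValueError("isovalue must lie strictly between 0 and 1")
        if self.calcite_density <= 0:
            raise ValueError("calcite_density must be positive")


# ======================================================================
# elementary quantities
# ======================================================================

def ellipse_perimeter(a_g: float, b_g: float) -> float:
    """Perimeter of an ellipse with FULL axes a_g >= b_g (µm).

    Uses p = π·sqrt((a_g² + b_g²)/2 − (a_g − b_g)²/8), exact for a circle
    (p = πd) and accurate to <0.5% for eccentricities up to ~0.85.
    """
    if not (a_g >= b_g > 0.0):
        raise ValueError("axes must satisfy a_g >= b_g > 0")
    return math.pi * math.sqrt((a_g ** 2 + b_g ** 2) / 2.0 - (a_g - b_g) ** 2 / 8.0)


def measure_mass(volume: VoxelVolume, cfg: MeasureConfig | None = None) -> float:
    """Calcite mass in pg: above-isovalue voxel count × voxel volume × density."""
    cfg = cfg or MeasureConfig()
    count = int(np.count_nonzero(volume.grid > cfg.isovalue))
    return count * volume.voxel_volume_um3 * cfg.calcite_density


def mass_isovalue_sensitivity(
    volume: VoxelVolume,
    cfg: MeasureConfig | None = None,
    band: tuple[float, float] = (0.3, 0.7),
) -> tuple[float, float]:
    """Mass at the extremes of an isovalue band (upper iso → lower mass)."""
    cfg = cfg or MeasureConfig()
    lo = MeasureConfig(isovalue=band[0], calcite_density=cfg.calcite_density)
    hi = MeasureConfig(isovalue=band[1], calcite_density=cfg.calcite_density)
    return measure_mass(volume, hi), measure_mass(volume, lo)


def thickness_map(oriented: VoxelVolume, cfg: MeasureConfig | None = None) -> np.ndarray:
    """Per-(x, y)-column calcite thickness in nm.

    thickness = voxel edge × number of above-isovalue voxels along the
    plane normal (third axis).  Maximal over the tube for coccolith-like
    input.
    """
    cfg = cfg or MeasureConfig()
    counts = np.count_nonzero(oriented.grid > cfg.isovalue, axis=2)
    return counts.astype(np.float64) * oriented.voxel_nm


# ======================================================================
# orientation
# ======================================================================

def _weighted_moments(grid: np.ndarray, iso: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = np.nonzero(grid > iso)
    if idx[0].size == 0:
        raise EmptyVolumeError("no voxels above the isovalue")
    pts = np.stack(idx, axis=1).astype(np.float64)
    w = grid[idx].astype(np.float64)
    c = np.average(pts, axis=0, weights=w)
    d = pts - c
    cov = (d * w[:, None]).T @ d / w.sum()
    return c, cov, w


def orient_coccolith(
    volume: VoxelVolume,
    cfg: MeasureConfig | None = None,
) -> tuple[VoxelVolume, np.ndarray]:
    """Rotate a coccolith so its plane normal is the third grid axis.

    The normal is the eigenvector of the largest voxel-inertia eigenvalue
    (equivalently the smallest positional variance); the in-plane major
    axis is mapped to the first grid axis.  The distal side is oriented
    toward +z using the sign of the density skewness along the normal.

    Returns the resampled volume and the plane normal expressed in the
    input frame.
    """
    cfg = cfg or MeasureConfig()
    c, cov, _ = _weighted_moments(volume.grid, cfg.isovalue)
    evals, evecs = np.linalg.eigh(cov)  # ascending variances
    # inertia ordering: smallest variance <-> largest inertia <-> normal
    if evals[2] <= 0 or (evals[1] - evals[0]) / evals[2] < 5e-3:
        raise OrientationError(
            "near-degenerate inertia tensor: plane normal is ambiguous"
        )
    normal = evecs[:, 0]
    major = evecs[:, 2]
    minor = np.cross(normal, major)
    R = np.stack([major, minor, normal], axis=1)  # columns: out axes in in-frame
    if np.linalg.det(R) < 0:
        R[:, 1] *= -1

    side = int(math.ceil(math.sqrt(sum(s ** 2 for s in volume.grid.shape)))) + 2
    out_center = np.full(3, (side - 1) / 2.0)
    # snap the translation to whole voxels: when R is (near) axis-aligned the
    # resampling is then exact instead of landing half-voxel off, where
    # interpolated edge values of a binary volume tie at the isovalue and
    # the strict threshold would erode every surface by half a voxel
    offset = np.round(c - R @ out_center)
    rotated = ndimage.affine_transform(
        volume.grid.astype(np.float32), R, offset=offset,
        output_shape=(side, side, side), order=1, mode="constant", cval=0.0,
    )

    # distal side -> +z: the shields rise distally with radius, so the
    # radius-height covariance of the mass distribution is positive when
    # the distal side points up (degenerate for a perfectly flat object)
    idx = np.nonzero(rotated > cfg.isovalue)
    if idx[0].size:
        w = rotated[idx]
        xc = np.average(idx[0].astype(float), weights=w)
        yc = np.average(idx[1].astype(float), weights=w)
        zc = np.average(idx[2].astype(float), weights=w)
        rxy = np.hypot(idx[0] - xc, idx[1] - yc)
        cov_rz = np.average((rxy - np.average(rxy, weights=w)) * (idx[2] - zc),
                            weights=w)
        if cov_rz < 0:
            rotated = rotated[:, :, ::-1].copy()
            R[:, 2] *= -1
            R[:, 1] *= -1  # keep the frame right-handed

    origin = -np.full(3, side) * volume.voxel_um / 2.0
    return VoxelVolume(rotated, volume.voxel_nm, origin), R[:, 2].copy() * 1.0


# ======================================================================
# ellipse fitting
# ======================================================================

@dataclass
class EllipseFit:
    """Full-axis ellipse fit in physical µm coordinates of the x–y plane."""

    major_um: float
    minor_um: float
    center_um: np.ndarray
    theta_rad: float

    @property
    def eccentricity(self) -> float:
        r = min(self.minor_um / self.major_um, 1.0)
        return math.sqrt(max(0.0, 1.0 - r * r))

    @property
    def semi_axes_um(self) -> tuple[float, float]:
        return self.major_um / 2.0, self.minor_um / 2.0


def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Direct least-squares conic fit constrained to ellipses.

    ``points`` is an (N, 2) array of in-plane coordinates (µm);
    N >= 6 non-collinear points are required.  Axes are returned as FULL
    axes.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 6:
        raise FitError("ellipse fit needs >= 6 two-dimensional points")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise FitError("points are collinear")
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise FitError("direct ellipse fit failed (degenerate/hyperbolic conic)")
    (xc, yc), (sa, sb), theta = model.center, model.axis_lengths, model.theta
    if sa <= 0 or sb <= 0 or not np.all(np.isfinite([xc, yc, sa, sb, theta])):
        raise FitError("degenerate ellipse fit")
    if sb > sa:
        sa, sb = sb, sa
        theta += math.pi / 2.0
    theta = (theta + math.pi / 2.0) % math.pi - math.pi / 2.0
    return EllipseFit(2.0 * sa, 2.0 * sb, np.array([xc, yc]), theta)


# ======================================================================
# shield / grid / tube-outer outlines from the thickness map
# ======================================================================

@dataclass
class EllipseSet:
    """Ellipse fits extracted from an oriented coccolith."""

    shield: EllipseFit
    grid: EllipseFit | None           # None when the tube/grid frontier is unresolved
    tube_outer: EllipseFit | None
    thickness_nm: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    ring_mask: np.ndarray = field(repr=False, default=None)     # type: ignore[assignment]


def _shoelace_area(c: np.ndarray) -> float:
    x, y = c[:, 0], c[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _contour_points_um(mask: np.ndarray, oriented: VoxelVolume) -> np.ndarray:
    """Outline (largest enclosed area) of a 2D mask in physical µm."""
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise FitError("no contour found")
    best = max(contours, key=_shoelace_area)
    # contour indices -> physical µm (voxel centers at index + 0.5)
    return (best + 0.5) * oriented.voxel_um + oriented.origin_um[:2]


def extract_ellipses(oriented: VoxelVolume, cfg: MeasureConfig | None = None) -> EllipseSet:
    """Fit the shield outline, the grid boundary (= inner tube edge) and the
    tube outer edge on the thresholded thickness projection.

    The tube annulus is the set of columns thicker than a fixed fraction of
    the maximum thickness; its inter-segment slits are sealed by a small
    morphological closing before hole filling.  When no interior hole
    survives (grid as thick as the tube), the grid boundary is unresolved
    and ``grid`` / ``tube_outer`` are ``None``.
    """
    cfg = cfg or MeasureConfig()
    T = thickness_map(oriented, cfg)
    if T.max() <= 0:
        raise EmptyVolumeError("empty volume: no above-isovalue voxels")

    shield_fit = fit_ellipse(_contour_points_um(T > 0, oriented))

    ring = T >= _TUBE_RING_FRACTION * T.max()
    ring_closed = ndimage.binary_closing(ring, structure=disk(2))
    filled = ndimage.binary_fill_holes(ring_closed)
    hole = filled & ~ring_closed

    grid_fit = tube_fit = None
    if hole.any():
        lab, nlab = ndimage.label(hole)
        # keep the hole component closest to the shield center
        cx = (shield_fit.center_um - oriented.origin_um[:2]) / oriented.voxel_um - 0.5
        best, best_d = 0, np.inf
        for k in range(1, nlab + 1):
            pts = np.argwhere(lab == k)
            d = np.linalg.norm(pts.mean(axis=0) - cx)
            if d < best_d:
                best, best_d = k, d
        hole_c = lab == best
        # a credible grid hole is at least a few voxels across
        if hole_c.sum() >= 16:
            try:
                grid_fit = fit_ellipse(_contour_points_um(hole_c, oriented))
                tube_fit = fit_ellipse(_contour_points_um(filled, oriented))
                grid_fit = _refine_grid_ellipse(oriented, T, grid_fit)
            except FitError:
                grid_fit = tube_fit = None
    return EllipseSet(shield_fit, grid_fit, tube_fit, T, ring)


def _refine_grid_ellipse(
    oriented: VoxelVolume, T: np.ndarray, coarse: EllipseFit,
    n_rays: int = 720,
) -> EllipseFit:
    """Sub-voxel refinement of the grid boundary (inner tube edge).

    Along rays from the coarse fit center, the radius where the column
    thickness first rises through the tube threshold is located by linear
    interpolation; rays passing through inter-segment slits (no crossing
    near the coarse boundary) are discarded and a trimmed ellipse refit is
    returned.
    """
    # seal the inter-segment slits so every ray sees the wall, then locate
    # the edge at 50% of the wall thickness: for a sharp edge sampled at
    # voxel centers, the half-height crossing of the interpolated ramp is
    # an unbiased (±half-voxel jitter) estimate of the edge position
    T = ndimage.grey_closing(T, footprint=disk(3))
    thr = 0.5 * float(np.median(T[T >= _TUBE_RING_FRACTION * T.max()]))
    phi = (np.arange(n_rays) + 0.5) / n_rays * 2.0 * np.pi
    # coarse boundary radius along each ray (polar form in the fit frame)
    psi = phi - coarse.theta_rad
    r_c = ellipse_radius(psi, *coarse.semi_axes_um)
    step = 0.25 * oriented.voxel_um
    offsets = np.arange(-8, 9) * step  # +/- 2 voxels around the coarse edge
    r_samp = r_c[None, :] + offsets[:, None]
    x = coarse.center_um[0] + r_samp * np.cos(phi)[None, :]
    y = coarse.center_um[1] + r_samp * np.sin(phi)[None, :]
    ix = (x - oriented.origin_um[0]) / oriented.voxel_um - 0.5
    iy = (y - oriented.origin_um[1]) / oriented.voxel_um - 0.5
    prof = ndimage.map_coordinates(T, np.stack([ix, iy]), order=1, mode="nearest")

    pts = []
    for j in range(n_rays):
        col = prof[:, j]
        above = col >= thr
        if not above.any() or above[0]:
            continue  # slit ray, or already inside the wall
        k = int(np.argmax(above))
        t0, t1 = col[k - 1], col[k]
        frac = (thr - t0) / (t1 - t0) if t1 > t0 else 0.0
        r_edge = r_samp[k - 1, j] + frac * step
        pts.append((coarse.center_um[0] + r_edge * np.cos(phi[j]),
                    coarse.center_um[1] + r_edge * np.sin(phi[j])))
    if len(pts) < 40:
        return coarse
    pts_arr = np.asarray(pts)
    fit = fit_ellipse(pts_arr)
    # one trimming pass against gross outliers (leaks through wide slits)
    resid = _ellipse_residual_um(pts_arr, fit)
    keep = resid < 2.0 * oriented.voxel_um
    if keep.sum() >= 40 and keep.sum() < len(pts_arr):
        fit = fit_ellipse(pts_arr[keep])
    return fit


def _ellipse_residual_um(pts: np.ndarray, fit: EllipseFit) -> np.ndarray:
    d = pts - fit.center_um
    ct, st = math.cos(fit.theta_rad), math.sin(fit.theta_rad)
    u = ct * d[:, 0] + st * d[:, 1]
    v = -st * d[:, 0] + ct * d[:, 1]
    psi = np.arctan2(v, u)
    return np.abs(np.hypot(u, v) - ellipse_radius(psi, *fit.semi_axes_um))


# ======================================================================
# segment counting
# ======================================================================

def _angular_thickness_profile(
    oriented: VoxelVolume, ells: EllipseSet, bins: int,
    fractions: tuple[float, ...] = (0.35, 0.5, 0.65),
) -> np.ndarray:
    """Thickness sampled around the tube wall, averaged over a small radial
    band between the grid and outer edges.

    Angular positions are uniform in the *grid-ellipse* arc length — the
    parametrization in which segments are laid down — and pushed radially
    outward to the sampling band, so that a regular segment pattern stays
    strictly periodic in the profile regardless of the wall width.
    """
    g, o = ells.grid, ells.tube_outer
    sa_g, sb_g = g.semi_axes_um
    E = uniform_arc_angles(sa_g, sb_g, bins)
    # polar angle (in the grid frame) of each arc-uniform grid point
    psi = np.arctan2(sb_g * np.sin(E), sa_g * np.cos(E))
    r_g = ellipse_radius(psi, sa_g, sb_g)
    r_o = ellipse_radius(psi, *o.semi_axes_um)
    ct, st = math.cos(g.theta_rad), math.sin(g.theta_rad)
    acc = np.zeros(bins)
    for frac in fractions:
        r = (1.0 - frac) * r_g + frac * r_o
        u, v = r * np.cos(psi), r * np.sin(psi)
        x = g.center_um[0] + ct * u - st * v
        y = g.center_um[1] + st * u + ct * v
        ix = (x - oriented.origin_um[0]) / oriented.voxel_um - 0.5
        iy = (y - oriented.origin_um[1]) / oriented.voxel_um - 0.5
        acc += ndimage.map_coordinates(
            ells.thickness_nm, np.stack([ix, iy]), order=1, mode="nearest"
        )
    return acc / len(fractions)


def _count_dips(profile: np.ndarray, n_est: int) -> int:
    """Circular count of prominent minima (inter-segment gaps)."""
    from scipy.signal import find_peaks

    width = max(1, profile.size // (6 * max(n_est, 1)))
    sm = ndimage.uniform_filter1d(profile, size=width, mode="wrap")
    span = sm.max() - sm.min()
    if span <= 0:
        return 0
    tiled = np.tile(-sm, 3)
    peaks, _ = find_peaks(tiled, prominence=0.12 * span)
    B = profile.size
    return int(np.count_nonzero((peaks >= B) & (peaks < 2 * B)))


def count_segments(
    oriented: VoxelVolume,
    cfg: MeasureConfig | None = None,
    ellipses: EllipseSet | None = None,
) -> int | None:
    """Number of tube segments, or ``None`` when unresolved.

    The thickness profile is sampled on the elliptical ring just outside
    the grid boundary at arc-length-uniform positions; the dominant
    harmonic of the mean-subtracted profile over harmonics [8, 120] gives a
    candidate count, cross-checked by direct counting of the gaps between
    segments.  Disagreement or modulation below the noise floor yields
    ``None`` (e.g. a gap-free tube, or gaps finer than the voxel size).
    """
    cfg = cfg or MeasureConfig()
    ells = ellipses or extract_ellipses(oriented, cfg)
    if ells.grid is None or ells.tube_outer is None:
        return None
    prof = _angular_thickness_profile(oriented, ells, cfg.angular_bins)

    lo, hi = np.percentile(prof, [2, 98])
    if hi <= 0 or (hi - lo) / max(hi, 1e-12) < 0.2:
        return None  # no detectable modulation

    x = prof - prof.mean()
    spec = np.abs(np.fft.rfft(x))
    h_lo, h_hi = 8, min(120, len(spec) - 1)
    if h_hi <= h_lo:
        return None
    n_fft = int(h_lo + np.argmax(spec[h_lo : h_hi + 1]))

    # cross-check by direct counting of prominent gaps
    n_direct = _count_dips(prof, n_fft)
    if n_direct != n_fft:
        return None
    return n_fft


# ======================================================================
# rim length / tube height / inclination
# ======================================================================

def _column_geometry(oriented: VoxelVolume, ells: EllipseSet):
    """Per-column polar coordinates in the tube-outer ellipse frame."""
    o = ells.tube_outer if ells.tube_outer is not None else ells.shield
    nx, ny = ells.thickness_nm.shape
    x = oriented.origin_um[0] + (np.arange(nx) + 0.5) * oriented.voxel_um
    y = oriented.origin_um[1] + (np.arange(ny) + 0.5) * oriented.voxel_um
    X, Y = np.meshgrid(x - o.center_um[0], y - o.center_um[1], indexing="ij")
    ct, st = math.cos(o.theta_rad), math.sin(o.theta_rad)
    U = ct * X + st * Y      # along major axis
    V = -st * X + ct * Y     # along minor axis
    r = np.hypot(U, V)
    psi = np.arctan2(V, U)
    r_out = ellipse_radius(psi, *o.semi_axes_um)
    return U, V, r, psi, r_out


def _run_counts_and_top(grid: np.ndarray, iso: float) -> tuple[np.ndarray, np.ndarray]:
    """Per column: number of contiguous filled runs along z, and the top
    filled index (-1 where empty)."""
    filled = grid > iso
    prev = np.concatenate(
        [np.zeros(filled.shape[:2] + (1,), dtype=bool), filled[:, :, :-1]], axis=2
    )
    starts = filled & ~prev
    runs = starts.sum(axis=2)
    nz = filled.shape[2]
    top = np.where(
        filled.any(axis=2),
        nz - 1 - np.argmax(filled[:, :, ::-1], axis=2),
        -1,
    )
    return runs, top


def _column_bottom(grid: np.ndarray, iso: float) -> np.ndarray:
    filled = grid > iso
    return np.where(filled.any(axis=2), np.argmax(filled, axis=2), -1)


def measure_rim_and_tube(
    oriented: VoxelVolume,
    cfg: MeasureConfig | None = None,
    ellipses: EllipseSet | None = None,
) -> tuple[float, float]:
    """Proximal rim length L and tube height t, both in µm.

    t is the median column thickness over the tube annulus.  L is the
    median (over angular rays in ±20° sectors about the major and minor
    axes, averaged between axes) of the radial extent of two-run columns —
    columns crossed by both shields — beyond the tube outer boundary.
    """
    cfg = cfg or MeasureConfig()
    ells = ellipses or extract_ellipses(oriented, cfg)
    if not ells.ring_mask.any():
        raise MeasurementError("tube annulus is empty")
    t_um = float(np.median(ells.thickness_nm[ells.ring_mask])) / 1000.0

    if ells.tube_outer is None:
        raise MeasurementError("tube outer boundary unresolved; cannot measure L")
    runs, _ = _run_counts_and_top(oriented.grid, cfg.isovalue)
    _, _, r, psi, r_out = _column_geometry(oriented, ells)
    outside = r > r_out + oriented.voxel_um
    two_run = (runs >= 2) & outside

    sector_ls = []
    for axis_angle in (0.0, math.pi / 2.0):
        # distance of psi to the axis directions {axis, axis+pi}
        d1 = np.abs(np.angle(np.exp(1j * (psi - axis_angle))))
        d2 = np.abs(np.angle(np.exp(1j * (psi - axis_angle - math.pi))))
        sector = np.minimum(d1, d2) < math.radians(20.0)
        cols = two_run & sector
        if not cols.any():
            sector_ls.append(0.0)
            continue
        # per 2° angular bin, the outermost two-run column defines the rim edge
        bins = np.floor((psi[cols] + math.pi) / math.radians(2.0)).astype(int)
        extent = r[cols] - r_out[cols]
        edge = {}
        for b, e in zip(bins, extent):
            edge[b] = max(edge.get(b, 0.0), e)
        sector_ls.append(float(np.median(list(edge.values()))))
    L_um = max(0.0, float(np.mean(sector_ls)))
    return L_um, t_um


def measure_inclination(
    oriented: VoxelVolume,
    cfg: MeasureConfig | None = None,
    ellipses: EllipseSet | None = None,
) -> tuple[float, float]:
    """Shield inclinations (degrees) along the major and minor axes.

    The shield mid-surface — the midpoint between the highest and lowest
    filled voxel of columns crossed by both shields (the two plate offsets
    cancel there) — is regressed against the radial distance in ±12°
    sectors about each in-plane axis; the inclination is the arctangent of
    the slope, averaged over the two opposite sectors.  Rimless coccoliths
    (no two-run columns) fall back to the top-surface slope.
    """
    cfg = cfg or MeasureConfig()
    ells = ellipses or extract_ellipses(oriented, cfg)
    if ells.tube_outer is None:
        raise MeasurementError("tube outer boundary unresolved; cannot measure inclination")
    runs, top = _run_counts_and_top(oriented.grid, cfg.isovalue)
    bottom = _column_bottom(oriented.grid, cfg.isovalue)
    _, _, r, psi, r_out = _column_geometry(oriented, ells)
    # stay clear of the shield rim, where partial columns corrupt the surface
    r_shield = ellipse_radius(psi, *ells.shield.semi_axes_um)
    outside = (r > r_out + oriented.voxel_um) & (r < 0.95 * r_shield) & (top >= 0)
    z_top = oriented.origin_um[2] + (top + 0.5) * oriented.voxel_um
    z_mid = oriented.origin_um[2] + (0.5 * (top + bottom) + 0.5) * oriented.voxel_um

    two_run = outside & (runs >= 2)
    use_mid = np.count_nonzero(two_run) >= 80
    height = z_mid if use_mid else z_top
    usable = two_run if use_mid else outside

    angles = []
    for axis_angle in (0.0, math.pi / 2.0):
        slopes = []
        for sign in (0.0, math.pi):
            d = np.abs(np.angle(np.exp(1j * (psi - axis_angle - sign))))
            cols = usable & (d < math.radians(12.0))
            if np.count_nonzero(cols) < 20:
                continue
            rr, zz = r[cols], height[cols]
            A = np.stack([rr, np.ones_like(rr)], axis=1)
            slope = np.linalg.lstsq(A, zz, rcond=None)[0][0]
            slopes.append(slope)
        if not slopes:
            raise MeasurementError("too few shield columns in the axis sector")
        angles.append(math.degrees(math.atan(float(np.mean(slopes)))))
    return angles[0], angles[1]


# ======================================================================
# whole-coccolith measurement
# ======================================================================

def measure_coccolith(
    volume: VoxelVolume,
    cfg: MeasureConfig | None = None,
    coccolith_id: int = 0,
) -> MorphoRecord:
    """Full morphometric record for a single (already extracted) coccolith.

    Mass is counted on the input volume (no resampling bias); all shape
    quantities are measured on the inertia-oriented volume.  Unresolved
    quantities are flagged instead of raising.
    """
    cfg = cfg or MeasureConfig()
    rec = MorphoRecord(coccolith_id=coccolith_id)
    rec.m = measure_mass(volume, cfg)
    oriented, _ = orient_coccolith(volume, cfg)
    ells = extract_ellipses(oriented, cfg)
    rec.a, rec.b = ells.shield.major_um, ells.shield.minor_um
    if ells.grid is None:
        rec.flags.append("grid_unresolved")
    else:
        rec.a_g, rec.b_g = ells.grid.major_um, ells.grid.minor_um
        rec.p = ellipse_perimeter(rec.a_g, rec.b_g)
        n = count_segments(oriented, cfg, ells)
        if n is None:
            rec.flags.append("n_unresolved")
        else:
            rec.n = n
        try:
            rec.L, rec.t = measure_rim_and_tube(oriented, cfg, ells)
        except MeasurementError:
            rec.flags.append("rim_tube_failed")
        try:
            rec.alpha_major, rec.alpha_minor = measure_inclination(oriented, cfg, ells)
        except MeasurementError:
            rec.flags.append("inclination_failed")
    return rec


# ======================================================================
# coccosphere segmentation
# ======================================================================

@dataclass
class SegmentationResult:
    """Outcome of splitting a coccosphere volume into coccoliths.

    ``volumes[i]`` is the i-th extracted component (cropped, density
    preserved); ``flags[i]`` lists quality flags; components with an
    exclusion flag (too small, not plate-like) are reported but should be
    left out of mass statistics.
    """

    volumes: list[VoxelVolume]
    flags: list[list[str]]

    _EXCLUDING = {"too_small", "not_plate_like"}

    def kept(self) -> list[VoxelVolume]:
        return [
            v for v, f in zip(self.volumes, self.flags)
            if not (set(f) & self._EXCLUDING)
        ]

    def __len__(self) -> int:
        return len(self.volumes)


def _flatness_ratio(mask: np.ndarray) -> float:
    pts = np.argwhere(mask).astype(float)
    if len(pts) < 10:
        return 1.0
    cov = np.cov((pts - pts.mean(axis=0)).T)
    evals = np.linalg.eigvalsh(cov)
    if evals[-1] <= 0:
        return 1.0
    return math.sqrt(max(evals[0], 0.0) / evals[-1])


def _watershed_split(binary: np.ndarray, density: np.ndarray) -> np.ndarray:
    """Marker-based watershed split of a (suspected merged) component."""
    smooth = ndimage.gaussian_filter(density.astype(np.float32), 4.0)
    dist = ndimage.distance_transform_edt(binary)
    markers_mask = smooth >= 0.75 * smooth.max()
    markers, nm = ndimage.label(markers_mask)
    if nm < 2:
        return binary.astype(np.int32)
    return watershed(-dist, markers=markers, mask=binary).astype(np.int32)


def segment_coccosphere(
    volume: VoxelVolume,
    labels_hint: VoxelVolume | None = None,
    cfg: MeasureConfig | None = None,
) -> SegmentationResult:
    """Split a coccosphere volume into per-coccolith volumes.

    Emulates iterative extract-and-subtract: the thresholded volume is
    peeled one connected component at a time (largest first).  Components
    anomalously large relative to the population median are split by
    marker-based watershed on the distance transform.  Components below
    ``min_coccolith_voxels`` or failing the plate-flatness test (merged or
    broken objects) are flagged and excluded from downstream statistics.

    ``labels_hint`` (e.g. the phantom's ground-truth label volume) bypasses
    the connected-component stage entirely.
    """
    cfg = cfg or MeasureConfig()
    binary = volume.grid > cfg.isovalue
    if not binary.any():
        raise EmptyVolumeError("no voxels above the isovalue")

    # (slice, local mask, extra flags) per candidate component
    candidates: list[tuple[tuple, np.ndarray, list[str]]] = []

    if labels_hint is not None:
        lab = np.where(binary, labels_hint.grid, 0)
        objs = ndimage.find_objects(lab)
        for i, sl in enumerate(objs, start=1):
            if sl is None:
                continue
            candidates.append((sl, lab[sl] == i, []))
    else:
        # extract-and-subtract: peel connected components, largest first
        struct = ndimage.generate_binary_structure(3, 1)
        lab, nlab = ndimage.label(binary, structure=struct)
        sizes = ndimage.sum_labels(
            np.ones_like(lab, dtype=np.float64), lab, index=np.arange(1, nlab + 1)
        )
        objs = ndimage.find_objects(lab)
        order = np.argsort(sizes)[::-1]
        valid = sizes[sizes >= cfg.min_coccolith_voxels]
        med = float(np.median(valid)) if valid.size >= 3 else None

        for oi in order:
            k, sl = int(oi) + 1, objs[int(oi)]
            m = lab[sl] == k
            if med is not None and sizes[oi] > 1.6 * med:
                split = _watershed_split(m, np.where(m, volume.grid[sl], 0.0))
                pieces = [split == j for j in range(1, split.max() + 1)]
                pieces = [p for p in pieces if p.any()]
                if len(pieces) >= 2:
                    for p in pieces:
                        candidates.append((sl, p, ["split_from_merged"]))
                    continue
            candidates.append((sl, m, []))

    volumes, flags = [], []
    for sl, m, f0 in candidates:
        f = list(f0)
        if m.sum() < cfg.min_coccolith_voxels:
            f.append("too_small")
        if _flatness_ratio(m) > _PLATE_FLATNESS_MAX:
            f.append("not_plate_like")
        sub_density = np.where(m, volume.grid[sl], 0.0).astype(volume.grid.dtype)
        origin = volume.origin_um + np.array(
            [s.start for s in sl]
        ) * volume.voxel_um
        volumes.append(VoxelVolume(sub_density, volume.voxel_nm, origin))
        flags.append(f)
    return SegmentationResult(volumes, flags)
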