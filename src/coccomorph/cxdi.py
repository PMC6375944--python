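"""Desk-scale coherent diffraction tomography and phase retrieval.

Forward model: plane-wave illumination in the flat-Ewald (central-slice)
approximation — the diffraction pattern at tilt angle θ is the squared
magnitude of the central slice, perpendicular to the rotated beam axis, of
the 3D Fourier transform of the density.  Patterns from a tilt series are
assembled into a 3D diffraction volume by distance-weighted linear
interpolation; the limited tilt range leaves a missing wedge of unmeasured
voxels.  Real-space images are recovered by iterative phase retrieval
(alternating HIO and ER with shrinkwrap support refinement), several
independent starts are aligned, twin-resolved and averaged, the phase
retrieval transfer function (PRTF) estimates the achieved resolution at
its 0.5 crossing, and a fitted 3D Gaussian background is subtracted
("flattening") with negative densities clipped to zero.

All transforms use the unitary FFT convention (``norm="ortho"``) with the
zero-frequency voxel at the grid center (``N // 2``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import h5py
import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .volume import VoxelVolume
from .exceptions import SpecValidationError

__all__ = [
    "TiltSeries",
    "DiffractionVolume",
    "RetrievalConfig",
    "ReconstructionResult",
    "PRTFCurve",
    "simulate_tilt_series",
    "assemble_diffraction_volume",
    "diffraction_from_volume",
    "phase_retrieval",
    "average_reconstructions",
    "compute_prtf",
    "flatten_density",
    "nrmse_aligned",
    "pad_for_oversampling",
    "fft_centered",
    "ifft_centered",
]

logger = logging.getLogger(__name__)


def fft_centered(vol: np.ndarray) -> np.ndarray:
    """Unitary 3D FFT with DC at the grid center."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(vol), norm="ortho"))


def ifft_centered(F: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft_centered`."""
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(F), norm="ortho"))


# ======================================================================
# data containers
# ======================================================================

@dataclass
class TiltSeries:
    """2D diffraction patterns over a tilt series.

    patterns : (n_angles, N, N) non-negative intensities
    angles_deg : tilt angles about the y (rotation) axis, within ±90°
    beamstop_mask : (N, N) boolean, True = blocked by the beamstop
    photon_scale : expected photons at unit intensity (0 = noiseless)
    voxel_nm : real-space voxel size of the originating volume
    """

    patterns: np.ndarray
    angles_deg: np.ndarray
    beamstop_mask: np.ndarray
    photon_scale: float = 0.0
    voxel_nm: float = 32.5

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if len(self.patterns) != len(self.angles_deg):
            raise SpecValidationError("one tilt angle per pattern required")
        if np.any(np.abs(self.angles_deg) > 90.0):
            raise SpecValidationError("tilt angles must lie within ±90°")
        if np.any(self.patterns < 0):
            raise SpecValidationError("pattern intensities must be non-negative")

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("patterns", data=self.patterns, compression="gzip")
            f.create_dataset("angles_deg", data=self.angles_deg)
            f.create_dataset("beamstop_mask", data=self.beamstop_mask)
            f.attrs["photon_scale"] = self.photon_scale
            f.attrs["voxel_nm"] = self.voxel_nm

    @classmethod
    def load(cls, path) -> "TiltSeries":
        with h5py.File(path, "r") as f:
            return cls(
                patterns=f["patterns"][...],
                angles_deg=f["angles_deg"][...],
                beamstop_mask=f["beamstop_mask"][...].astype(bool),
                photon_scale=float(f.attrs["photon_scale"]),
                voxel_nm=float(f.attrs["voxel_nm"]),
            )


@dataclass
class DiffractionVolume:
    """Assembled 3D intensities on the Fourier grid with a sampling mask."""

    intensity: np.ndarray
    measured_mask: np.ndarray
    voxel_nm: float = 32.5

    def __post_init__(self) -> None:
        if self.intensity.shape != self.measured_mask.shape:
            raise SpecValidationError("intensity and mask shapes must match")
        if np.any(self.intensity[self.measured_mask] < 0):
            raise SpecValidationError("measured intensities must be non-negative")

    @property
    def unmeasured_fraction(self) -> float:
        return 1.0 - float(np.count_nonzero(self.measured_mask)) / self.measured_mask.size

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("intensity", data=self.intensity, compression="gzip")
            f.create_dataset("measured_mask", data=self.measured_mask)
            f.attrs["voxel_nm"] = self.voxel_nm

    @classmethod
    def load(cls, path) -> "DiffractionVolume":
        with h5py.File(path, "r") as f:
            return cls(
                intensity=f["intensity"][...],
                measured_mask=f["measured_mask"][...].astype(bool),
                voxel_nm=float(f.attrs["voxel_nm"]),
            )


@dataclass
class RetrievalConfig:
    """Phase-retrieval schedule: HIO blocks with feedback ``beta`` followed
    by ER, with shrinkwrap support updates from the thresholded blurred
    density."""

    hio_iters: int = 300
    er_iters: int = 100
    beta: float = 0.9
    shrinkwrap_every: int = 30
    shrink_sigma0: float = 3.0
    shrink_sigma_min: float = 1.5
    shrink_sigma_decay: float = 0.94
    shrink_threshold: float = 0.10
    positivity: bool = True
    autocorr_threshold: float = 0.04
    divergence_threshold: float = 0.5


@dataclass
class ReconstructionResult:
    """One phase-retrieval run: density, support, residual history, seed."""

    density: VoxelVolume
    support: np.ndarray
    error_history: np.ndarray
    seed: int
    diverged: bool = False


@dataclass
class PRTFCurve:
    """Shell-averaged phase retrieval transfer function.

    freq_bins : shell-center spatial frequencies, cycles/nm
    prtf : values in [0, 1]
    resolution_nm : 1 / (first downward 0.5 crossing); the voxel size when
        the PRTF never drops below 0.5 (``always_above`` set)
    """

    freq_bins: np.ndarray
    prtf: np.ndarray
    resolution_nm: float
    always_above: bool = False


# ======================================================================
# forward simulation
# ======================================================================

def _pad_to_cube(grid: np.ndarray, n: int | None = None) -> np.ndarray:
    n = max(grid.shape) if n is None else n
    pads = [((n - s) // 2, n - s - (n - s) // 2) for s in grid.shape]
    return np.pad(grid, pads)


def pad_for_oversampling(volume: VoxelVolume, factor: float = 2.0) -> VoxelVolume:
    """Embed a volume in a larger cube so its diffraction is oversampled.

    Phase retrieval needs the intensity sampled at least twice as finely
    as the object's Nyquist rate, i.e. the support must occupy at most
    1/factor of the cube along each axis.
    """
    n = int(math.ceil(max(volume.grid.shape) * factor))
    n += n % 2  # keep the grid even
    pads = [((n - s) // 2, n - s - (n - s) // 2) for s in volume.grid.shape]
    grid = np.pad(volume.grid, pads)
    origin = volume.origin_um - np.array([p[0] for p in pads]) * volume.voxel_um
    return VoxelVolume(grid, volume.voxel_nm, origin)


def _slice_coords(N: int, theta_deg: float) -> np.ndarray:
    """Index coordinates of the central slice perpendicular to the beam
    rotated by theta about the y axis; pattern axes are (u = rotation axis
    y, v = in-plane transverse)."""
    c = N // 2
    u = np.arange(N) - c
    v = np.arange(N) - c
    U, V = np.meshgrid(u, v, indexing="ij")
    th = math.radians(theta_deg)
    x = c + V * math.cos(th)
    y = c + U.astype(float)
    z = c + V * math.sin(th)
    return np.stack([x, y, z])


def simulate_tilt_series(
    volume: VoxelVolume,
    angles_deg,
    beamstop_radius: float = 0.0,
    photon_scale: float = 0.0,
    seed: int | None = None,
    pad: bool = True,
) -> TiltSeries:
    """Diffraction patterns of a tilt series in the flat-Ewald approximation.

    Each pattern is the squared magnitude of the central slice of the 3D
    Fourier transform perpendicular to the rotated beam axis.  Beamstop
    pixels (radius in pixels about the DC) are zeroed and flagged; Poisson
    shot noise is added when ``photon_scale > 0``.
    """
    grid = np.asarray(volume.grid, dtype=float)
    if len(set(grid.shape)) != 1:
        if not pad:
            raise SpecValidationError("volume must be cubic (enable padding)")
        grid = _pad_to_cube(grid)
    N = grid.shape[0]
    F = fft_centered(grid)
    rng = np.random.default_rng(seed)

    c = N // 2
    iu, iv = np.meshgrid(np.arange(N) - c, np.arange(N) - c, indexing="ij")
    beamstop = (iu ** 2 + iv ** 2) < beamstop_radius ** 2 if beamstop_radius > 0 \
        else np.zeros((N, N), dtype=bool)

    patterns = np.empty((len(list(angles_deg)), N, N))
    angles = np.asarray(list(angles_deg), dtype=float)
    # cubic spline slice interpolation of the complex field (prefilter once)
    re_f = ndimage.spline_filter(F.real, order=3)
    im_f = ndimage.spline_filter(F.imag, order=3)
    for k, th in enumerate(angles):
        coords = _slice_coords(N, th)
        re = ndimage.map_coordinates(re_f, coords, order=3, mode="constant",
                                     prefilter=False)
        im = ndimage.map_coordinates(im_f, coords, order=3, mode="constant",
                                     prefilter=False)
        I = re ** 2 + im ** 2
        if photon_scale > 0:
            I = rng.poisson(I * photon_scale) / photon_scale
        I[beamstop] = 0.0
        patterns[k] = I
    return TiltSeries(patterns, angles, beamstop, photon_scale, volume.voxel_nm)


def assemble_diffraction_volume(series: TiltSeries, grid_size: int) -> DiffractionVolume:
    """Deposit tilt patterns onto the 3D Fourier grid by trilinear splatting.

    Voxel values are the distance-weighted linear interpolation of all
    contributing pattern samples; voxels that receive no contribution
    (missing wedge beyond the maximum tilt, beamstop shadow) are flagged
    unmeasured.
    """
    if len(series.angles_deg) < 2:
        logger.warning("assembling from fewer than 2 tilt angles")
    N = grid_size
    M = series.patterns.shape[1]
    num = np.zeros((N, N, N))
    den = np.zeros((N, N, N))
    cM = M // 2
    cN = N // 2
    iu, iv = np.meshgrid(np.arange(M) - cM, np.arange(M) - cM, indexing="ij")
    keep = ~series.beamstop_mask
    u = iu[keep].astype(float)
    v = iv[keep].astype(float)

    for pat, th_deg in zip(series.patterns, series.angles_deg):
        th = math.radians(th_deg)
        x = cN + v * math.cos(th)
        y = cN + u
        z = cN + v * math.sin(th)
        vals = pat[keep]
        x0 = np.floor(x).astype(int)
        y0 = np.floor(y).astype(int)
        z0 = np.floor(z).astype(int)
        fx, fy, fz = x - x0, y - y0, z - z0
        for dx in (0, 1):
            wx = np.where(dx == 0, 1.0 - fx, fx)
            for dy in (0, 1):
                wy = np.where(dy == 0, 1.0 - fy, fy)
                for dz in (0, 1):
                    wz = np.where(dz == 0, 1.0 - fz, fz)
                    w = wx * wy * wz
                    xi, yi, zi = x0 + dx, y0 + dy, z0 + dz
                    ok = (
                        (xi >= 0) & (xi < N) & (yi >= 0) & (yi < N)
                        & (zi >= 0) & (zi < N) & (w > 0)
                    )
                    np.add.at(num, (xi[ok], yi[ok], zi[ok]), w[ok] * vals[ok])
                    np.add.at(den, (xi[ok], yi[ok], zi[ok]), w[ok])

    measured = den > 1e-9
    intensity = np.zeros_like(num)
    intensity[measured] = num[measured] / den[measured]
    intensity = np.maximum(intensity, 0.0)

    dv = DiffractionVolume(intensity, measured, series.voxel_nm)
    if dv.unmeasured_fraction > 0.5:
        logger.warning(
            "diffraction grid undersampled by the tilt series: %.0f%% of "
            "voxels unmeasured", 100 * dv.unmeasured_fraction,
        )
    return dv


def diffraction_from_volume(volume: VoxelVolume) -> DiffractionVolume:
    """Fully measured |FT|² of a volume (noiseless oracle input)."""
    grid = np.asarray(volume.grid, dtype=float)
    if len(set(grid.shape)) != 1:
        grid = _pad_to_cube(grid)
    I = np.abs(fft_centered(grid)) ** 2
    return DiffractionVolume(I, np.ones_like(I, dtype=bool), volume.voxel_nm)


# ======================================================================
# phase retrieval
# ======================================================================

def phase_retrieval(
    diffvol: DiffractionVolume,
    config: RetrievalConfig | None = None,
    seed: int = 0,
) -> ReconstructionResult:
    """Iterative phase retrieval (HIO + ER with shrinkwrap support).

    Measured Fourier amplitudes are enforced wherever ``measured_mask`` is
    true; unmeasured voxels are left unconstrained.  The support starts
    from the thresholded autocorrelation and is refined periodically by
    thresholding the Gaussian-blurred density.  Divergence (residual above
    threshold at the end) flags the result instead of raising.
    """
    cfg = config or RetrievalConfig()
    if not diffvol.measured_mask.any():
        raise SpecValidationError("measured_mask is empty")
    amp = np.sqrt(np.maximum(diffvol.intensity, 0.0))
    meas = diffvol.measured_mask
    amp_norm = float(np.linalg.norm(amp[meas])) or 1.0
    rng = np.random.default_rng(seed)

    # initial support from the autocorrelation of the measured intensity
    ac = np.abs(ifft_centered(np.where(meas, diffvol.intensity, 0.0)))
    support = ac > cfg.autocorr_threshold * ac.max()

    F = np.where(meas, amp * np.exp(2j * math.pi * rng.random(amp.shape)), 0.0)
    g = np.abs(ifft_centered(F)).real
    sigma = cfg.shrink_sigma0
    errors = []

    total = cfg.hio_iters + cfg.er_iters
    for it in range(total):
        G = fft_centered(g)
        err = float(np.linalg.norm(np.abs(G)[meas] - amp[meas]) / amp_norm)
        errors.append(err)
        phase = np.angle(G)
        Gc = np.where(meas, amp * np.exp(1j * phase), G)
        gp = ifft_centered(Gc).real
        er_phase = it >= cfg.hio_iters
        inside = support & ((gp >= 0) | (not cfg.positivity))
        if er_phase:
            g = np.where(inside, gp, 0.0)
        else:
            g = np.where(inside, gp, g - cfg.beta * gp)
            if (it + 1) % cfg.shrinkwrap_every == 0:
                sm = ndimage.gaussian_filter(np.maximum(g, 0.0), sigma)
                support = sm > cfg.shrink_threshold * sm.max()
                sigma = max(cfg.shrink_sigma_min, sigma * cfg.shrink_sigma_decay)

    density = np.where(support, np.maximum(g, 0.0), 0.0)
    diverged = errors[-1] > cfg.divergence_threshold
    if diverged:
        logger.warning("phase retrieval did not converge (residual %.3g)", errors[-1])
    vol = VoxelVolume(density.astype(np.float32), diffvol.voxel_nm)
    return ReconstructionResult(vol, support, np.asarray(errors), seed, diverged)


# ======================================================================
# alignment, averaging, NRMSE
# ======================================================================

def _twin(grid: np.ndarray) -> np.ndarray:
    """Inversion twin ρ(-r) on the same (even) grid."""
    return np.roll(grid[::-1, ::-1, ::-1], 1, axis=(0, 1, 2))


def _align_to(ref: np.ndarray, mov: np.ndarray) -> tuple[np.ndarray, float]:
    """Subvoxel-align ``mov`` to ``ref``; returns (aligned, correlation)."""
    shift, _, _ = phase_cross_correlation(
        ref, mov, upsample_factor=10, normalization=None
    )
    moved = np.fft.ifftn(ndimage.fourier_shift(np.fft.fftn(mov), shift)).real
    denom = np.linalg.norm(ref) * np.linalg.norm(moved)
    corr = float(np.vdot(ref, moved).real / denom) if denom > 0 else 0.0
    return moved, corr


def average_reconstructions(results: list) -> VoxelVolume:
    """Align (shift + inversion twin) and average an ensemble.

    Members are aligned to the first non-empty one by upsampled
    cross-correlation; the orientation (direct vs inversion twin) with the
    higher correlation wins.  All-zero members are excluded with a warning.
    """
    grids, meta = [], None
    for r in results:
        vol = r.density if isinstance(r, ReconstructionResult) else r
        if not np.any(vol.grid):
            logger.warning("excluding an all-zero reconstruction from the average")
            continue
        grids.append(np.asarray(vol.grid, dtype=float))
        meta = meta or vol
    if len(grids) < 1:
        raise SpecValidationError("no non-empty reconstructions to average")
    ref = grids[0]
    acc = ref.copy()
    for garr in grids[1:]:
        cand, corr = _align_to(ref, garr)
        cand_t, corr_t = _align_to(ref, _twin(garr))
        acc += cand if corr >= corr_t else cand_t
    avg = acc / len(grids)
    return VoxelVolume(avg.astype(np.float32), meta.voxel_nm, meta.origin_um.copy())


def nrmse_aligned(candidate: np.ndarray, truth: np.ndarray) -> float:
    """Scale-optimal NRMSE after shift registration and twin resolution."""
    best = np.inf
    for g in (candidate, _twin(np.asarray(candidate, dtype=float))):
        aligned, _ = _align_to(np.asarray(truth, dtype=float), np.asarray(g, dtype=float))
        denom = float(np.vdot(aligned, aligned).real)
        alpha = float(np.vdot(aligned, truth).real) / denom if denom > 0 else 0.0
        err = np.linalg.norm(alpha * aligned - truth) / np.linalg.norm(truth)
        best = min(best, float(err))
    return best


# ======================================================================
# PRTF
# ======================================================================

def compute_prtf(avg_density: VoxelVolume, diffvol: DiffractionVolume) -> PRTFCurve:
    """Phase retrieval transfer function of an averaged reconstruction.

    Per Fourier shell: PRTF = Σ|F_avg| / Σ√I over measured voxels.  The
    resolution is 1 / (frequency of the first downward 0.5 crossing,
    linearly interpolated); if the PRTF never drops below 0.5 the
    resolution is reported as the voxel size with ``always_above`` set.
    """
    if avg_density.grid.shape != diffvol.intensity.shape:
        raise SpecValidationError("reconstruction and diffraction grids differ")
    N = avg_density.grid.shape[0]
    F = fft_centered(np.asarray(avg_density.grid, dtype=float))
    num = np.abs(F)
    den = np.sqrt(np.maximum(diffvol.intensity, 0.0))
    c = N // 2
    idx = np.indices(num.shape)
    r = np.sqrt(((idx - np.array([c, c, c])[:, None, None, None]) ** 2).sum(axis=0))
    shells = np.round(r).astype(int)

    usable = diffvol.measured_mask & (den > 1e-12 * den.max())
    nbins = N // 2
    freq, prtf = [], []
    for s in range(nbins):
        sel = (shells == s) & usable
        if not sel.any():
            continue
        ratio = float(num[sel].sum() / den[sel].sum())
        prtf.append(min(max(ratio, 0.0), 1.0))
        freq.append(s / (N * diffvol.voxel_nm))
    freq_arr = np.asarray(freq)
    prtf_arr = np.asarray(prtf)

    below = np.nonzero(prtf_arr < 0.5)[0]
    first = next((i for i in below if i > 0), None)
    if first is None or freq_arr.size < 2:
        return PRTFCurve(freq_arr, prtf_arr, avg_density.voxel_nm, always_above=True)
    i0, i1 = first - 1, first
    f0, f1 = freq_arr[i0], freq_arr[i1]
    p0, p1 = prtf_arr[i0], prtf_arr[i1]
    fc = f0 + (0.5 - p0) * (f1 - f0) / (p1 - p0) if p1 != p0 else f1
    resolution = max(1.0 / fc, avg_density.voxel_nm)
    return PRTFCurve(freq_arr, prtf_arr, float(resolution), always_above=False)


# ======================================================================
# Gaussian background flattening
# ======================================================================

def flatten_density(
    volume: VoxelVolume,
    *,
    object_threshold: float = 0.5,
) -> VoxelVolume:
    """Subtract a fitted isotropic 3D Gaussian background; clip negatives.

    The Gaussian is centered at the density-weighted mass center.  Its
    amplitude and width are found by least squares against the background
    voxels: voxels above ``object_threshold``·max (the compact calcite
    object, dilated) are masked out of the fit.  A failed fit (flat
    volume) degrades to the identity transform with a warning — negatives
    are still clipped.
    """
    grid = np.asarray(volume.grid, dtype=float)
    total = grid.sum()
    if total <= 0 or grid.max() <= 0:
        logger.warning("flatten_density: empty volume, returning clipped input")
        return volume.with_grid(np.maximum(grid, 0.0).astype(volume.grid.dtype))

    idx = np.indices(grid.shape).astype(float)
    centroid = (idx * grid).sum(axis=(1, 2, 3)) / total
    r = np.sqrt(((idx - centroid[:, None, None, None]) ** 2).sum(axis=0))

    obj = grid > object_threshold * grid.max()
    obj = ndimage.binary_dilation(obj, iterations=2)
    sample = ~obj
    rr = r[sample].ravel()
    vv = grid[sample].ravel()
    try:
        popt, _ = optimize.curve_fit(
            lambda x, A, s: A * np.exp(-x ** 2 / (2.0 * s ** 2)),
            rr, vv,
            p0=[max(float(vv.max()), 1e-9), max(grid.shape) / 4.0],
            bounds=([0.0, 1.0], [np.inf, 10.0 * max(grid.shape)]),
            maxfev=5000,
        )
        A, s = float(popt[0]), float(popt[1])
    except (RuntimeError, ValueError):
        logger.warning("flatten_density: Gaussian fit failed; identity transform")
        A, s = 0.0, 1.0

    background = A * np.exp(-r ** 2 / (2.0 * s ** 2))
    out = np.maximum(grid - background, 0.0)
    return volume.with_grid(out.astype(np.float32))
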