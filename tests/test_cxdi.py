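"""Diffraction simulation, assembly, phase retrieval, PRTF, flattening."""

import numpy as np
import pytest

import coccomorph as cm
from coccomorph.cxdi import _twin, fft_centered, ifft_centered
from coccomorph.exceptions import SpecValidationError

N = 64


# ------------------------------------------------------------- simulation
def test_central_slice_identity_at_zero_tilt(ball64):
    """The zero-tilt pattern equals |2D FT of the beam-axis projection|²
    (up to the documented 1/N unitary-convention factor)."""
    ts = cm.simulate_tilt_series(ball64, [0.0])
    proj = ball64.grid.sum(axis=2)
    F2 = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(proj), norm="ortho"))
    expected = np.abs(F2) ** 2
    assert np.linalg.norm(ts.patterns[0] * N - expected) < 1e-5 * np.linalg.norm(expected)


def test_parseval_consistency(ball64):
    ts = cm.simulate_tilt_series(ball64, [0.0])
    proj = ball64.grid.sum(axis=2)
    assert ts.patterns[0].sum() * N == pytest.approx(float((proj ** 2).sum()), rel=1e-10)


def test_spherical_object_pattern_tilt_invariant(ball64):
    ts = cm.simulate_tilt_series(ball64, [0.0, 37.0])
    rel = np.linalg.norm(ts.patterns[0] - ts.patterns[1]) / np.linalg.norm(ts.patterns[0])
    assert rel < 0.02


def test_poisson_noise_seeded_and_scaled(ball64):
    a = cm.simulate_tilt_series(ball64, [0.0], photon_scale=50.0, seed=4)
    b = cm.simulate_tilt_series(ball64, [0.0], photon_scale=50.0, seed=4)
    c = cm.simulate_tilt_series(ball64, [0.0], photon_scale=50.0, seed=5)
    assert np.array_equal(a.patterns, b.patterns)
    assert not np.array_equal(a.patterns, c.patterns)


def test_beamstop_blocks_center(ball64):
    ts = cm.simulate_tilt_series(ball64, [0.0], beamstop_radius=3.0)
    assert ts.beamstop_mask[N // 2, N // 2]
    assert ts.patterns[0][N // 2, N // 2] == 0.0


def test_non_cubic_volume_padded_or_rejected():
    vol = cm.VoxelVolume(np.ones((8, 10, 6), dtype=np.float32), 32.5)
    ts = cm.simulate_tilt_series(vol, [0.0])
    assert ts.patterns.shape[1] == 10
    with pytest.raises(SpecValidationError):
        cm.simulate_tilt_series(vol, [0.0], pad=False)


# --------------------------------------------------------------- assembly
@pytest.fixture(scope="module")
def dense_assembly(ellipsoid64):
    angles = np.arange(-80.0, 80.01, 0.5)
    series = cm.simulate_tilt_series(ellipsoid64, angles)
    return cm.assemble_diffraction_volume(series, N)


def test_dense_assembly_matches_direct_transform(ellipsoid64, dense_assembly):
    I_true = np.abs(fft_centered(ellipsoid64.grid.astype(float))) ** 2
    m = dense_assembly.measured_mask
    rel = np.linalg.norm(dense_assembly.intensity[m] - I_true[m]) / np.linalg.norm(I_true[m])
    assert rel < 0.05


def test_missing_cone_geometry(dense_assembly):
    """±80° tilt about y leaves a 10° half-angle unmeasured wedge around
    the beam (z) axis in the x–z plane."""
    x = np.arange(N) - N // 2
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    phi = np.degrees(np.arctan2(np.abs(Z), np.abs(X)))
    r_xz = np.hypot(X, Z)
    inside_wedge = (phi > 85) & (r_xz > 6) & (r_xz < 25)
    outside_wedge = (phi < 75) & (r_xz > 3) & (r_xz < 28)
    assert dense_assembly.measured_mask[inside_wedge].mean() == 0.0
    assert dense_assembly.measured_mask[outside_wedge].mean() == 1.0


def test_single_angle_measures_one_plane(ellipsoid64):
    ts = cm.simulate_tilt_series(ellipsoid64, [0.0])
    dv = cm.assemble_diffraction_volume(ts, N)
    assert dv.unmeasured_fraction == pytest.approx(1 - 1 / N, abs=1e-12)


# ---------------------------------------------------------- phase retrieval
def test_noiseless_full_sampling_retrieval(ellipsoid64, ellipsoid64_retrieval):
    dv, res = ellipsoid64_retrieval
    assert not res.diverged
    assert cm.nrmse_aligned(res.density.grid, ellipsoid64.grid.astype(float)) < 1e-2


def test_error_history_non_increasing_in_final_er(ellipsoid64_retrieval):
    _, res = ellipsoid64_retrieval
    tail = res.error_history[-100:]
    assert np.all(np.diff(tail) <= 1e-6)


def test_density_zero_outside_support(ellipsoid64_retrieval):
    _, res = ellipsoid64_retrieval
    assert np.all(res.density.grid[~res.support] == 0)
    assert res.density.grid.min() >= 0


def test_two_seeds_agree(ellipsoid64, ellipsoid64_retrieval):
    dv, res0 = ellipsoid64_retrieval
    res1 = cm.phase_retrieval(dv, seed=77)
    assert cm.nrmse_aligned(res0.density.grid, res1.density.grid) < 5e-2


def test_centrosymmetric_twin_accepted(ball64):
    """A centrosymmetric object may reconstruct as either twin; the aligned
    NRMSE accepts both."""
    dv = cm.diffraction_from_volume(ball64)
    res = cm.phase_retrieval(dv, seed=9)
    truth = ball64.grid.astype(float)
    assert min(
        cm.nrmse_aligned(res.density.grid, truth),
        cm.nrmse_aligned(_twin(res.density.grid.astype(float)), truth),
    ) < 1e-2


def test_empty_mask_rejected(ellipsoid64):
    dv = cm.diffraction_from_volume(ellipsoid64)
    dv.measured_mask[:] = False
    with pytest.raises(SpecValidationError):
        cm.phase_retrieval(dv)


# ---------------------------------------------------------------- averaging
def test_average_idempotent(ellipsoid64):
    avg = cm.average_reconstructions([ellipsoid64] * 5)
    assert np.allclose(avg.grid, ellipsoid64.grid, atol=1e-5)


def test_average_shrinks_noise_like_sqrt_n(ellipsoid64):
    rng = np.random.default_rng(0)
    truth = ellipsoid64.grid.astype(float)
    noisy = [
        cm.VoxelVolume((truth + rng.normal(0, 0.1, truth.shape)).astype(np.float32), 32.5)
        for _ in range(10)
    ]
    avg = cm.average_reconstructions(noisy)
    shrink = np.linalg.norm(noisy[0].grid - truth) / np.linalg.norm(avg.grid - truth)
    assert shrink == pytest.approx(np.sqrt(10), rel=0.15)


def test_average_resolves_inversion_twin(ellipsoid64):
    truth = ellipsoid64.grid.astype(float)
    members = [ellipsoid64, cm.VoxelVolume(_twin(truth).astype(np.float32), 32.5)]
    avg = cm.average_reconstructions(members)
    assert np.linalg.norm(avg.grid - truth) / np.linalg.norm(truth) < 1e-6


def test_average_excludes_all_zero_member(ellipsoid64):
    zero = cm.VoxelVolume(np.zeros_like(ellipsoid64.grid), 32.5)
    avg = cm.average_reconstructions([ellipsoid64, zero, ellipsoid64])
    assert np.allclose(avg.grid, ellipsoid64.grid, atol=1e-5)


# --------------------------------------------------------------------- PRTF
def test_prtf_perfect_retrieval_is_one(ellipsoid64):
    dv = cm.diffraction_from_volume(ellipsoid64)
    curve = cm.compute_prtf(ellipsoid64, dv)
    assert np.all(curve.prtf >= 0) and np.all(curve.prtf <= 1)
    assert curve.prtf.min() == pytest.approx(1.0, abs=1e-6)
    assert curve.always_above
    assert curve.resolution_nm == ellipsoid64.voxel_nm


def test_prtf_crossing_at_constructed_cutoff(ellipsoid64):
    """Randomizing the ensemble phases above a cutoff frequency moves the
    0.5 crossing to that cutoff."""
    truth = ellipsoid64.grid.astype(float)
    dv = cm.diffraction_from_volume(ellipsoid64)
    F = fft_centered(truth)
    x = np.arange(N) - N // 2
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    r = np.sqrt(X ** 2 + Y ** 2 + Z ** 2)
    r_star = 12
    rng = np.random.default_rng(5)
    acc = np.zeros_like(truth)
    for _ in range(24):
        ph = np.where(r <= r_star, 0.0, rng.uniform(0, 2 * np.pi, truth.shape))
        acc += ifft_centered(np.abs(F) * np.exp(1j * (np.angle(F) + ph))).real
    avg = cm.VoxelVolume((acc / 24).astype(np.float32), 32.5)
    curve = cm.compute_prtf(avg, dv)
    assert not curve.always_above
    f_star = r_star / (N * 32.5)
    assert curve.resolution_nm == pytest.approx(1.0 / f_star, rel=0.05)


def test_retrieved_phantom_resolution_near_voxel(ellipsoid64, ellipsoid64_retrieval):
    dv, res = ellipsoid64_retrieval
    avg = cm.average_reconstructions([res, cm.phase_retrieval(dv, seed=41)])
    curve = cm.compute_prtf(avg, dv)
    assert 32.5 <= curve.resolution_nm <= 50.0


# ------------------------------------------------------------------ flatten
def test_flatten_recovers_phantom_under_gaussian_background(ellipsoid64):
    truth = ellipsoid64.grid.astype(float)
    x = np.arange(N) - N // 2
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    # background centered at the object's mass center, as the model assumes
    bg = 0.3 * np.exp(-(((X + 3) ** 2 + (Y - 2) ** 2 + Z ** 2)) / (2 * 10 ** 2))
    noisy = cm.VoxelVolume((truth + bg).astype(np.float32), 32.5)
    flat = cm.flatten_density(noisy)
    assert np.linalg.norm(flat.grid - truth) / np.linalg.norm(truth) < 0.05


def test_flatten_noop_without_background(ellipsoid64):
    flat = cm.flatten_density(ellipsoid64)
    truth = ellipsoid64.grid.astype(float)
    assert np.linalg.norm(flat.grid - truth) / np.linalg.norm(truth) < 0.01


def test_flatten_output_non_negative():
    rng = np.random.default_rng(0)
    vol = cm.VoxelVolume(rng.normal(0, 1, (24, 24, 24)).astype(np.float32), 32.5)
    assert cm.flatten_density(vol).grid.min() >= 0.0


# ----------------------------------------------------------- end-to-end
def test_end_to_end_identity_recovers_mass(small_spec):
    """Phantom → diffract → retrieve → average → flatten → mass within 10%."""
    vol, truth = cm.build_coccolith(small_spec, 65.0, gaps=False)
    padded = cm.pad_for_oversampling(vol, 2.0)
    dv = cm.diffraction_from_volume(padded)
    cfg = cm.RetrievalConfig(hio_iters=120, er_iters=40)
    results = [cm.phase_retrieval(dv, cfg, seed=s) for s in (0, 1)]
    avg = cm.average_reconstructions(results)
    flat = cm.flatten_density(avg)
    assert cm.measure_mass(flat) == pytest.approx(truth.m, rel=0.10)


def test_missing_cone_monotonicity(ball64):
    """Shrinking the tilt range from ±80° to ±60° never improves the
    reconstruction (checked over 5 seeds on the same phantom)."""
    truth = ball64.grid.astype(float)
    cfg = cm.RetrievalConfig(hio_iters=80, er_iters=30)
    errs = {}
    for tilt in (80.0, 60.0):
        angles = np.arange(-tilt, tilt + 0.01, 2.0)
        series = cm.simulate_tilt_series(ball64, angles)
        dv = cm.assemble_diffraction_volume(series, N)
        errs[tilt] = np.median([
            cm.nrmse_aligned(cm.phase_retrieval(dv, cfg, seed=s).density.grid, truth)
            for s in range(5)
        ])
    assert errs[60.0] >= errs[80.0]
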