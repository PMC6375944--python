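"""Measurement operators: masses, ellipses, segments, rims, inclinations,
segmentation — scored against analytic phantom ground truth."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import coccomorph as cm
from coccomorph._geom import rotation_about
from coccomorph.exceptions import EmptyVolumeError, FitError, OrientationError
from coccomorph.morphometrics import MeasureConfig, _flatness_ratio


# --------------------------------------------------------- ellipse_perimeter
def test_perimeter_circle_limit():
    assert cm.ellipse_perimeter(2.0, 2.0) == pytest.approx(2 * math.pi, rel=1e-15)


def test_perimeter_printed_formula_value():
    assert cm.ellipse_perimeter(4.0, 3.0) == pytest.approx(11.0516, abs=2e-4)


def test_perimeter_degenerate_flat_ellipse():
    # the formula's documented breakdown: flat ellipse gives pi*3*sqrt(3/8)
    assert cm.ellipse_perimeter(3.0, 1e-12) == pytest.approx(
        math.pi * 3 * math.sqrt(3 / 8), rel=1e-6
    )
    with pytest.raises(ValueError):
        cm.ellipse_perimeter(3.0, 0.0)
    with pytest.raises(ValueError):
        cm.ellipse_perimeter(2.0, 3.0)


def _arc_length(a, b):
    sa, sb = a / 2, b / 2
    val, _ = quad(lambda t: math.hypot(sa * math.sin(t), sb * math.cos(t)),
                  0.0, 2 * math.pi, limit=200)
    return val


@settings(deadline=None, max_examples=60)
@given(a=st.floats(0.5, 10.0), e=st.floats(0.0, 0.85))
def test_perimeter_matches_quadrature_below_e085(a, e):
    b = a * math.sqrt(1.0 - e * e)
    assert cm.ellipse_perimeter(a, b) == pytest.approx(_arc_length(a, b), rel=5e-3)


# ----------------------------------------------------------------- mass
def test_filled_unit_cube_weighs_calcite_density():
    grid = np.ones((40, 40, 40), dtype=np.float32)   # 1 µm cube at 25 nm
    vol = cm.VoxelVolume(grid, 25.0)
    assert cm.measure_mass(vol) == pytest.approx(2.71, rel=1e-12)
    assert cm.measure_mass(vol.with_grid(np.zeros_like(grid))) == 0.0


def test_phantom_mass_recovery(goceanica_volume):
    vol, truth = goceanica_volume
    assert cm.measure_mass(vol) == pytest.approx(truth.m, rel=0.03)


def test_mass_monotone_in_isovalue(goceanica_volume):
    vol, _ = goceanica_volume
    masses = [
        cm.measure_mass(vol, MeasureConfig(isovalue=iso))
        for iso in (0.2, 0.4, 0.6, 0.8)
    ]
    assert all(a >= b for a, b in zip(masses, masses[1:]))


# ----------------------------------------------------------- thickness map
def test_thickness_map_direct_product():
    grid = np.zeros((4, 4, 12), dtype=np.float32)
    grid[1, 1, 1:11] = 1.0
    T = cm.thickness_map(cm.VoxelVolume(grid, 32.5))
    assert T[1, 1] == pytest.approx(325.0)
    assert T[0, 0] == 0.0


def test_thickness_max_over_tube(goceanica_volume, goceanica_spec):
    vol, _ = goceanica_volume
    oriented, _ = cm.orient_coccolith(vol)
    T = cm.thickness_map(oriented)
    assert T.max() == pytest.approx(goceanica_spec.t * 1000, abs=vol.voxel_nm)
    # the thickest column lies over the tube annulus
    i, j = np.unravel_index(np.argmax(T), T.shape)
    x = oriented.origin_um[0] + (i + 0.5) * oriented.voxel_um
    y = oriented.origin_um[1] + (j + 0.5) * oriented.voxel_um
    sa_g, sb_g = goceanica_spec.a_g / 2, goceanica_spec.b_g / 2
    rho = math.hypot(x / sa_g, y / sb_g)
    assert 0.95 < rho < 1.5


# ------------------------------------------------------------- fit_ellipse
def test_fit_ellipse_analytic_eccentricity():
    t = np.linspace(0, 2 * math.pi, 200, endpoint=False)
    pts = np.stack([2.0 * np.cos(t), 1.5 * np.sin(t)], axis=1)  # a=4, b=3
    fit = cm.fit_ellipse(pts)
    assert fit.major_um == pytest.approx(4.0, rel=5e-3)
    assert fit.minor_um == pytest.approx(3.0, rel=5e-3)
    assert fit.eccentricity == pytest.approx(0.661, abs=5e-3)

    circ = np.stack([np.cos(t), np.sin(t)], axis=1)
    assert cm.fit_ellipse(circ).eccentricity == pytest.approx(0.0, abs=1e-6)


def test_fit_ellipse_errors():
    with pytest.raises(FitError):
        cm.fit_ellipse(np.zeros((4, 2)))
    line = np.stack([np.arange(10.0), 2 * np.arange(10.0)], axis=1)
    with pytest.raises(FitError):
        cm.fit_ellipse(line)


def test_phantom_eccentricities_inside_printed_bands(goceanica_record):
    rec = goceanica_record
    assert 0.48 <= rec.e_shield <= 0.65
    assert 0.66 <= rec.e_grid <= 0.81


# ------------------------------------------------------------- orientation
def test_orientation_recovers_known_rotation(goceanica_spec):
    R = rotation_about(np.array([0.3, 1.0, 0.2]), 0.6)
    vol, _ = cm.build_coccolith(goceanica_spec, 32.5, rotation=R)
    _, normal = cm.orient_coccolith(vol)
    angle = math.degrees(math.acos(min(1.0, abs(float(np.dot(normal, R[:, 2]))))))
    assert angle < 2.0


def test_orientation_identity_on_oriented_phantom(goceanica_volume):
    vol, truth = goceanica_volume
    oriented, normal = cm.orient_coccolith(vol)
    assert abs(normal[2]) > 0.999
    assert cm.measure_mass(oriented) == pytest.approx(cm.measure_mass(vol), rel=0.02)


def test_orientation_rejects_degenerate_sphere():
    x = np.arange(40) - 20
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    ball = ((X ** 2 + Y ** 2 + Z ** 2) < 15 ** 2).astype(np.float32)
    with pytest.raises(OrientationError):
        cm.orient_coccolith(cm.VoxelVolume(ball, 32.5))


def test_mirror_flip_keeps_distal_up(goceanica_spec):
    R = rotation_about(np.array([1.0, 0.0, 0.0]), math.pi)
    vol, _ = cm.build_coccolith(goceanica_spec, 32.5, rotation=R)
    rec = cm.measure_coccolith(vol)
    assert rec.alpha_major > 0          # shields still rise toward +z


# ------------------------------------------------------------ full record
def test_goceanica_full_recovery(goceanica_record, goceanica_volume, goceanica_spec):
    rec, (vol, truth) = goceanica_record, goceanica_volume
    assert rec.n == 61
    assert rec.p == pytest.approx(truth.p, rel=0.05)
    assert rec.m == pytest.approx(truth.m, rel=0.03)
    assert rec.a == pytest.approx(truth.a, rel=0.03)
    assert rec.b == pytest.approx(truth.b, rel=0.03)
    assert rec.t == pytest.approx(truth.t, abs=vol.voxel_um)
    assert rec.L == pytest.approx(truth.L, abs=2 * vol.voxel_um)
    assert rec.alpha_major == pytest.approx(30.0, abs=3.0)
    assert rec.alpha_minor == pytest.approx(25.0, abs=3.0)
    assert rec.alpha_major > rec.alpha_minor
    assert rec.w == pytest.approx(truth.p / 61, rel=0.05)


def test_small_phantom_recovery(small_spec):
    vol, truth = cm.build_coccolith(small_spec, 28.8)
    rec = cm.measure_coccolith(vol)
    assert rec.n == 29
    assert rec.p == pytest.approx(truth.p, rel=0.05)
    assert rec.m == pytest.approx(truth.m, rel=0.03)
    assert rec.alpha_major == pytest.approx(30.0, abs=3.0)


def test_flat_phantom_measures_no_inclination():
    spec = cm.default_coccolith_spec(5.0, alpha_major=0.0, alpha_minor=0.0)
    vol, _ = cm.build_coccolith(spec, 32.5)
    rec = cm.measure_coccolith(vol)
    assert abs(rec.alpha_major) < 2.0
    assert abs(rec.alpha_minor) < 2.0


def test_segment_count_rotation_invariant(small_spec):
    R = rotation_about(np.array([0.0, 0.0, 1.0]), math.radians(33))
    vol, _ = cm.build_coccolith(small_spec, 28.8, rotation=R)
    assert cm.measure_coccolith(vol).n == 29


def test_uniform_ring_unresolved(goceanica_spec):
    vol, _ = cm.build_coccolith(goceanica_spec, 32.5, gaps=False)
    rec = cm.measure_coccolith(vol)
    assert rec.n is None
    assert "n_unresolved" in rec.flags


def test_thick_grid_makes_perimeter_unresolved():
    """When the central area is as thick as the tube the grid/tube frontier
    disappears and p must be reported as unresolved (the E. huxleyi P41
    exclusion)."""
    spec = cm.default_coccolith_spec(5.0, grid_fill=1.0)
    vol, _ = cm.build_coccolith(spec, 32.5, grid_thickness_um=spec.t)
    rec = cm.measure_coccolith(vol)
    assert "grid_unresolved" in rec.flags
    assert math.isnan(rec.p)


def test_rimless_phantom_recovers_zero_rim():
    spec = cm.default_coccolith_spec(5.0, L=0.0)
    vol, _ = cm.build_coccolith(spec, 32.5)
    rec = cm.measure_coccolith(vol)
    assert rec.L <= vol.voxel_um


def test_rim_ratio_ordering_preserved():
    long_rim = cm.default_coccolith_spec(3.0, shield_scale=2.6, L=0.405)
    short_rim = cm.default_coccolith_spec(3.0, shield_scale=2.6, L=0.225)
    r1 = cm.measure_coccolith(cm.build_coccolith(long_rim, 28.8)[0])
    r2 = cm.measure_coccolith(cm.build_coccolith(short_rim, 28.8)[0])
    assert r1.L > r2.L


def test_tube_height_recovery():
    spec = cm.default_coccolith_spec(4.5, t=0.5)
    vol, _ = cm.build_coccolith(spec, 32.5)
    rec = cm.measure_coccolith(vol)
    assert rec.t == pytest.approx(0.5, abs=vol.voxel_um)


# ------------------------------------------------------------ segmentation
def test_sphere_segmentation_counts_and_masks(sphere14, sphere14_segmented):
    density, labels, truths = sphere14
    seg = sphere14_segmented
    kept = seg.kept()
    assert len(kept) == 14
    # each kept component matches a ground-truth label with high Jaccard
    for v in kept:
        lo = np.round((v.origin_um - labels.origin_um) / labels.voxel_um).astype(int)
        sl = tuple(slice(a, a + s) for a, s in zip(lo, v.grid.shape))
        hint = labels.grid[sl]
        m = v.grid > 0.5
        ids, counts = np.unique(hint[m], return_counts=True)
        best = ids[np.argmax(counts)]
        inter = np.count_nonzero(m & (hint == best))
        union = np.count_nonzero(m) + np.count_nonzero(labels.grid == best) - inter
        assert inter / union > 0.95


def test_mass_additivity(sphere14, sphere14_segmented):
    density, _, _ = sphere14
    seg = sphere14_segmented
    total = cm.measure_mass(density)
    parts = sum(cm.measure_mass(v) for v in seg.volumes)
    assert parts <= total * (1 + 1e-9)
    assert parts == pytest.approx(total, rel=0.01)


def test_labels_hint_bypasses_segmentation(sphere14):
    density, labels, _ = sphere14
    seg = cm.segment_coccosphere(density, labels_hint=labels)
    assert len(seg) == 14
    assert len(seg.kept()) == 14


def test_single_coccolith_passthrough(goceanica_volume):
    vol, _ = goceanica_volume
    seg = cm.segment_coccosphere(vol)
    assert len(seg.kept()) == 1
    assert cm.measure_mass(seg.kept()[0]) == pytest.approx(cm.measure_mass(vol), rel=1e-6)


def test_empty_volume_raises():
    vol = cm.VoxelVolume(np.zeros((8, 8, 8), dtype=np.float32), 32.5)
    with pytest.raises(EmptyVolumeError):
        cm.segment_coccosphere(vol)


def test_fused_pair_flagged_excluded():
    """Two deeply interpenetrating coccoliths at a steep mutual tilt form a
    single non-plate-like component that must be flagged."""
    spec = cm.default_coccolith_spec(4.0)
    v1, _ = cm.build_coccolith(spec, 32.5, rotation=np.eye(3))
    R = rotation_about(np.array([1.0, 0.0, 0.0]), math.radians(55))
    v2, _ = cm.build_coccolith(spec, 32.5, rotation=R)
    n = max(v1.grid.shape[0], v2.grid.shape[0])
    grid = np.zeros((n, n, n), dtype=np.float32)

    def blit(v):
        s = v.grid.shape
        o = [(n - d) // 2 for d in s]
        sl = tuple(slice(a, a + d) for a, d in zip(o, s))
        grid[sl] = np.maximum(grid[sl], v.grid)

    blit(v1)
    blit(v2)
    fused = cm.VoxelVolume(grid, 32.5)
    seg = cm.segment_coccosphere(fused)
    big = max(zip(seg.volumes, seg.flags), key=lambda vf: vf[0].grid.sum())
    assert "not_plate_like" in big[1]
    # sanity: an isolated coccolith is plate-like
    assert _flatness_ratio(v1.grid > 0.5) < 0.5
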