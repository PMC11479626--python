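"""Surface estimation: background normalization, detection, RANSAC, spline."""

import numpy as np
import pytest
from scipy import stats

from edfrim import (
    GridGeometry,
    detect_bright_points,
    estimate_background,
    fit_surface_ransac,
    interpolate_surface,
    make_pupil,
    make_topography,
    normalize_volume,
    project_onto_surface,
)
from edfrim.topography import BrightPoints, NormalizedVolume

from conftest import NA, WAVELENGTH


def _gain_volume(shape, cv=0.1, base=100.0, seed=0):
    """Smooth separable gain ramp times multiplicative Gaussian noise."""
    nz, ny, nx = shape
    rng = np.random.default_rng(seed)
    gx = 1.0 + 0.4 * np.linspace(-1, 1, nx)
    gy = 1.0 - 0.3 * np.linspace(-1, 1, ny)
    gz = 1.0 + 0.2 * np.linspace(0, 1, nz)
    gain = base * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    return gain * (1.0 + cv * rng.standard_normal(shape)), gain


class TestBackground:
    def test_constant_volume_recovered_exactly(self):
        bg, sigma0 = estimate_background(np.full((6, 32, 32), 5.0), seed=0)
        assert np.allclose(bg.evaluate_volume(), 5.0, rtol=0.01)
        assert sigma0 == pytest.approx(0.0, abs=1e-9)

    def test_ramp_gain_and_noise_scale_recovered(self):
        vol, gain = _gain_volume((8, 64, 64), cv=0.1, seed=1)
        bg, sigma0 = estimate_background(vol, fraction=5e-3, seed=2)
        a = bg.evaluate_volume()
        rel = np.sqrt(np.mean((a - gain) ** 2)) / gain.mean()
        assert rel < 0.03
        assert sigma0 == pytest.approx(0.10, abs=0.02)

    def test_subsampling_is_stable_across_seeds(self):
        vol, _ = _gain_volume((8, 64, 64), cv=0.1, seed=3)
        a1 = estimate_background(vol, fraction=5e-3, seed=10)[0].evaluate_volume()
        a2 = estimate_background(vol, fraction=5e-3, seed=11)[0].evaluate_volume()
        # two subsamples agree within ~2x the subsample standard error
        # (noise CV 0.1, ~1600 samples, 54 coefficients, edge leverage)
        assert np.sqrt(np.mean((a1 - a2) ** 2)) / a1.mean() < 0.06

    def test_rejects_empty_volume(self):
        with pytest.raises(ValueError):
            estimate_background(np.zeros((4, 8, 8)))


class TestNormalization:
    def test_signal_equal_background_gives_zero(self):
        vol, gain = _gain_volume((6, 32, 32), cv=0.0, seed=0)
        bg, _ = estimate_background(vol, fraction=0.05, seed=1)
        norm = normalize_volume(vol, bg, 0.1, 38.5, 38.5, np.arange(6) * 2000.0)
        assert np.abs(norm.values[np.isfinite(norm.values)]).max() < 0.2

    def test_background_is_standard_normal(self):
        vol, _ = _gain_volume((8, 64, 64), cv=0.1, seed=4)
        bg, sigma0 = estimate_background(vol, fraction=5e-3, seed=5)
        norm = normalize_volume(vol, bg, sigma0, 38.5, 38.5, np.arange(8) * 2000.0)
        r = norm.values[np.isfinite(norm.values)]
        assert abs(r.mean()) < 0.05
        assert r.std() == pytest.approx(1.0, abs=0.1)

    def test_planted_bright_surface_stands_out(self):
        vol, gain = _gain_volume((6, 32, 32), cv=0.1, seed=6)
        # compact 10-sigma patch (a full bright plane would be absorbed by
        # the per-plane background freedom)
        vol[3, 10:16, 10:16] += 10 * 0.1 * gain[3, 10:16, 10:16]
        bg, sigma0 = estimate_background(vol, fraction=0.05, seed=7)
        norm = normalize_volume(vol, bg, sigma0, 38.5, 38.5, np.arange(6) * 2000.0)
        assert np.median(norm.values[3, 10:16, 10:16]) > 5.0


class TestDetection:
    def test_threshold_is_inverse_normal_quantile(self):
        norm = NormalizedVolume(
            values=np.zeros((2, 4, 4)), background_gain=np.ones((2, 4, 4)),
            noise_scale=1.0, pfa=None, dx=1.0, dy=1.0, z_planes=np.array([0.0, 1.0]),
        )
        # pfa=0.01 -> threshold 2.3263 (inverse standard-normal CDF)
        norm.values[0, 0, 0] = 2.33
        norm.values[1, 0, 0] = 2.32
        pts = detect_bright_points(norm, pfa=0.01)
        assert len(pts) == 1 and pts.z[0] == 0.0

    def test_false_alarm_rate_on_standard_normal_volume(self):
        rng = np.random.default_rng(8)
        values = rng.standard_normal((16, 256, 256))
        norm = NormalizedVolume(
            values=values, background_gain=np.ones_like(values), noise_scale=1.0,
            pfa=None, dx=1.0, dy=1.0, z_planes=np.arange(16, dtype=float),
        )
        rate = len(detect_bright_points(norm, pfa=0.01)) / values.size
        assert rate == pytest.approx(0.01, abs=0.001)

    def test_median_threshold_at_half(self):
        assert float(stats.norm.isf(0.5)) == pytest.approx(0.0, abs=1e-12)
        rng = np.random.default_rng(9)
        values = rng.standard_normal((4, 64, 64))
        norm = NormalizedVolume(
            values=values, background_gain=np.ones_like(values), noise_scale=1.0,
            pfa=None, dx=1.0, dy=1.0, z_planes=np.arange(4, dtype=float),
        )
        rate = len(detect_bright_points(norm, pfa=0.499)) / values.size
        assert rate == pytest.approx(0.5, abs=0.01)

    def test_rejects_silly_pfa(self):
        norm = NormalizedVolume(
            values=np.zeros((1, 2, 2)), background_gain=np.ones((1, 2, 2)),
            noise_scale=1.0, pfa=None, dx=1.0, dy=1.0, z_planes=np.array([0.0]),
        )
        with pytest.raises(ValueError):
            detect_bright_points(norm, pfa=0.7)


def _points_on_quadratic(n, coeffs, seed, noise=0.0, outlier_frac=0.0, z_range=10000.0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 10000.0, n)
    y = rng.uniform(0, 10000.0, n)
    c0, cx, cy, cxx, cxy, cyy = coeffs
    u, v = x / 10000.0, y / 10000.0
    z = c0 + cx * u + cy * v + cxx * u * u + cxy * u * v + cyy * v * v
    z += noise * rng.standard_normal(n)
    is_out = rng.uniform(size=n) < outlier_frac
    z[is_out] = rng.uniform(0, z_range, is_out.sum())
    return BrightPoints(x=x, y=y, z=z, value=np.full(n, 5.0)), ~is_out


class TestRansac:
    def test_noiseless_quadratic_is_fully_consensual(self):
        pts, _ = _points_on_quadratic(400, (500, 300, -200, 150, 80, -120), seed=0)
        fit = fit_surface_ransac(pts, n_windows=(2, 2), inlier_tol=50.0, seed=1)
        assert fit.labels.all()
        wf = next(w for w in fit.window_fits if w.coeffs is not None)
        sub = wf.point_index
        # the refit surface reproduces the generating quadratic at the points
        from edfrim.topography import _quad_design

        center = ((wf.x_bounds[0] + wf.x_bounds[1]) / 2, (wf.y_bounds[0] + wf.y_bounds[1]) / 2)
        half = ((wf.x_bounds[1] - wf.x_bounds[0]) / 2, (wf.y_bounds[1] - wf.y_bounds[0]) / 2)
        order = np.lexsort((pts.z, pts.y, pts.x))
        xs, ys, zs = pts.x[order][sub], pts.y[order][sub], pts.z[order][sub]
        pred = _quad_design(xs, ys, center, half) @ wf.coeffs
        assert np.allclose(pred, zs, atol=1e-6)

    def test_outliers_rejected_on_noisy_surface(self):
        pts, truth = _points_on_quadratic(
            2000, (2000, 1500, -800, 600, 300, -400), seed=2,
            noise=20.0, outlier_frac=0.4,
        )
        fit = fit_surface_ransac(pts, n_windows=(3, 3), inlier_tol=100.0, seed=3)
        true_found = fit.labels[truth].mean()
        false_kept = fit.labels[~truth].mean()
        assert true_found >= 0.95
        assert false_kept <= 0.05

    def test_labels_invariant_under_shuffling(self):
        pts, _ = _points_on_quadratic(
            800, (2000, 1500, -800, 600, 300, -400), seed=4,
            noise=20.0, outlier_frac=0.3,
        )
        fit1 = fit_surface_ransac(pts, n_windows=(2, 2), inlier_tol=100.0, seed=5)
        rng = np.random.default_rng(6)
        perm = rng.permutation(len(pts))
        shuffled = BrightPoints(
            x=pts.x[perm], y=pts.y[perm], z=pts.z[perm], value=pts.value[perm]
        )
        fit2 = fit_surface_ransac(shuffled, n_windows=(2, 2), inlier_tol=100.0, seed=5)
        assert np.array_equal(fit1.labels[perm], fit2.labels)

    def test_too_few_points_rejected(self):
        pts = BrightPoints(
            x=np.arange(3.0), y=np.arange(3.0), z=np.zeros(3), value=np.ones(3)
        )
        with pytest.raises(ValueError):
            fit_surface_ransac(pts)


class TestInterpolation:
    def test_plane_is_reproduced_inside_hull(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1000, 200)
        y = rng.uniform(0, 1000, 200)
        z = 100.0 + 0.5 * x - 0.25 * y
        z_grid, valid = interpolate_surface(x, y, z, (28, 28), 38.5, 38.5)
        xx = np.arange(28) * 38.5
        expected = 100.0 + 0.5 * xx[None, :] - 0.25 * (np.arange(28) * 38.5)[:, None]
        assert np.allclose(z_grid[valid], expected[valid], atol=1e-6)

    def test_interpolant_passes_through_the_points(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1000, 60)
        y = rng.uniform(0, 1000, 60)
        z = rng.uniform(0, 500, 60)
        from scipy.interpolate import RBFInterpolator

        z_grid, _ = interpolate_surface(x, y, z, (16, 16), 38.5, 38.5)
        interp = RBFInterpolator(np.column_stack([x, y]), z, kernel="thin_plate_spline")
        # evaluate our grid interpolant back at the data sites
        probe = interp(np.column_stack([x, y]))
        assert np.allclose(probe, z, atol=1e-6)

    def test_degenerate_geometry_rejected(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            interpolate_surface(x, x, x, (8, 8), 1.0, 1.0)


class TestProjection:
    def test_flat_surface_keeps_intensities_bitwise(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 1, (16, 16))
        zs = np.full((16, 16), 500.0)
        mesh = project_onto_surface(img, zs, 38.5, 38.5)
        assert np.array_equal(mesh.intensity, img)
        assert np.ptp(mesh.vertices[..., 2]) == 0.0

    def test_total_intensity_conserved(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 1, (16, 16))
        mesh = project_onto_surface(img, rng.uniform(0, 100, (16, 16)), 38.5, 38.5)
        assert mesh.intensity.sum() == pytest.approx(img.sum())

    def test_cone_vertex_range_matches_phantom(self):
        grid = GridGeometry(64, 64, 32, 38.5, 38.5, 87.5)
        cone = make_topography(grid, "cone")
        mesh = project_onto_surface(np.ones(grid.shape2d), cone, grid.dx, grid.dy)
        assert np.ptp(mesh.vertices[..., 2]) == pytest.approx(grid.z_range, abs=grid.dz)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            project_onto_surface(np.ones((4, 4)), np.ones((5, 5)), 1.0, 1.0)
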