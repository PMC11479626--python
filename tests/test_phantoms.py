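"""Synthetic objects and the speckled-acquisition forward model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edfrim import (
    GridGeometry,
    compute_edf_psf,
    compute_psf3d,
    embed_on_surface,
    form_edf_image,
    form_image,
    make_pupil,
    make_star_density,
    make_topography,
    generate_speckle,
    simulate_acquisition,
)

from conftest import NA, WAVELENGTH


class TestStarDensity:
    def test_bright_ray_along_theta_zero(self, grid64):
        star = make_star_density(grid64, n_lobes=40)
        row = star[grid64.ny // 2, grid64.nx // 2 + 1 :]
        assert np.allclose(row, 2.0, atol=1e-12)

    def test_dark_ray_at_half_period(self):
        # theta = pi/40 for 40 lobes: cos(40 theta) = -1; test the pixels
        # whose centers fall close to that dark ray
        grid = GridGeometry(64, 64, 1, 38.5, 38.5, 87.5)
        star = make_star_density(grid, n_lobes=40)
        theta = np.arctan2(grid.y[:, None], grid.x[None, :])
        r = np.hypot(grid.y[:, None], grid.x[None, :])
        near_ray = (np.abs(theta - np.pi / 40) < 0.01) & (r > 15 * grid.dx)
        assert near_ray.sum() > 0
        assert star[near_ray].max() < 0.3

    def test_angular_periodicity(self, grid64):
        star = make_star_density(grid64, n_lobes=40)
        theta = np.arctan2(grid64.y[:, None], grid64.x[None, :])
        rotated = 1.0 + np.cos(40 * (theta + 2 * np.pi / 40))
        assert np.allclose(star, rotated, atol=1e-9)

    def test_rejects_odd_lobe_count(self, grid64):
        with pytest.raises(ValueError):
            make_star_density(grid64, n_lobes=39)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(n_lobes=st.sampled_from([2, 8, 40, 80]))
    def test_values_within_zero_two(self, grid32, n_lobes):
        star = make_star_density(grid32, n_lobes=n_lobes)
        assert star.min() >= 0.0 and star.max() <= 2.0 + 1e-12


class TestTopography:
    def test_cone_apex_height_is_full_z_range(self):
        grid = GridGeometry(512, 512, 128, 38.5, 38.5, 87.5)
        cone = make_topography(grid, "cone")
        assert cone[grid.ny // 2, grid.nx // 2] == pytest.approx(128 * 87.5)
        assert cone[grid.ny // 2, grid.nx // 2] == pytest.approx(11200.0)

    def test_cone_is_zero_outside_base(self, grid64):
        cone = make_topography(grid64, "cone")
        assert cone[0, 0] == 0.0

    def test_flat_is_constant(self, grid64):
        flat = make_topography(grid64, "flat")
        assert np.ptp(flat) == 0.0

    def test_random_heights_are_uniform_and_uncorrelated(self):
        grid = GridGeometry(512, 512, 128, 38.5, 38.5, 87.5)
        z = make_topography(grid, "random", seed=0)
        mean, half = z.mean(), grid.z_range / 2
        se = grid.z_range / np.sqrt(12) / np.sqrt(z.size)
        assert abs(mean - half) < 3 * se
        d = z - mean
        lag1 = (d[:, :-1] * d[:, 1:]).mean() / d.var()
        assert abs(lag1) < 0.02

    def test_random_requires_seed(self, grid64):
        with pytest.raises(ValueError):
            make_topography(grid64, "random")


class TestEmbedding:
    def test_flat_surface_occupies_single_slice(self, grid64):
        k = 12
        sample = embed_on_surface(
            np.ones(grid64.shape2d), np.full(grid64.shape2d, k * grid64.dz), grid64
        )
        occupied = np.nonzero(sample.density3d.any(axis=(1, 2)))[0]
        assert list(occupied) == [k]
        assert np.array_equal(sample.density3d[k], np.ones(grid64.shape2d))

    def test_rejects_out_of_range_heights(self, grid64):
        with pytest.raises(ValueError):
            embed_on_surface(
                np.ones(grid64.shape2d),
                np.full(grid64.shape2d, grid64.z_range * 1.5),
                grid64,
            )

    def test_cone_slice_index_nonincreasing_with_radius(self, grid64):
        cone = make_topography(grid64, "cone")
        sample = embed_on_surface(np.ones(grid64.shape2d), cone, grid64)
        row = sample.slice_index[grid64.ny // 2, grid64.nx // 2 :]
        assert np.all(np.diff(row.astype(int)) <= 0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_projection_conservation_for_random_surfaces(self, grid32, seed):
        rng = np.random.default_rng(seed)
        density = rng.uniform(0, 3, grid32.shape2d)
        z = rng.uniform(0, grid32.z_range, grid32.shape2d)
        sample = embed_on_surface(density, z, grid32)
        assert np.allclose(sample.density3d.sum(axis=0), density, atol=1e-12)


class TestImageFormation:
    @pytest.fixture()
    def small(self):
        grid = GridGeometry(16, 16, 4, 38.5, 38.5, 87.5)
        pupil = make_pupil(NA, WAVELENGTH, grid)
        psf = compute_psf3d(pupil, grid)
        return grid, pupil, psf

    def test_point_source_reproduces_psf_slice(self, small):
        grid, _, psf = small
        rho = np.zeros(grid.shape3d)
        z_f = 2 * grid.dz
        rho[2, grid.ny // 2, grid.nx // 2] = 1.0
        img = form_image(rho, np.ones_like(rho), psf, z_f, grid)
        focal = psf.values[grid.nz // 2]
        assert np.allclose(img, focal, atol=1e-12 * focal.max())

    def test_linearity_in_density(self, small):
        grid, _, psf = small
        rng = np.random.default_rng(0)
        rho = rng.uniform(0, 1, grid.shape3d)
        s = rng.uniform(0, 2, grid.shape3d)
        a = form_image(rho, s, psf, grid.dz, grid)
        b = form_image(2 * rho, s, psf, grid.dz, grid)
        assert np.allclose(b, 2 * a, atol=1e-12)

    def test_matches_direct_sum_oracle(self, small):
        grid, _, psf = small
        rng = np.random.default_rng(1)
        rho = rng.uniform(0, 1, grid.shape3d)
        s = rng.uniform(0, 2, grid.shape3d)
        z_f = 1 * grid.dz
        img = form_image(rho, s, psf, z_f, grid)
        # brute-force: roll a centered PSF slice to every source voxel
        oracle = np.zeros(grid.shape2d)
        excited = rho * s
        cy, cx = grid.ny // 2, grid.nx // 2
        for k in range(grid.nz):
            i = (1 - k) % grid.nz  # offset z_f - k*dz, circular
            sl = psf.values[(i + grid.nz // 2) % grid.nz]
            for yy in range(grid.ny):
                for xx in range(grid.nx):
                    w = excited[k, yy, xx]
                    if w:
                        oracle += w * np.roll(sl, (yy - cy, xx - cx), axis=(0, 1))
        assert np.allclose(img, oracle, rtol=1e-8, atol=1e-10)

    def test_edf_equals_sum_over_focal_planes(self, small):
        grid, _, psf = small
        rng = np.random.default_rng(2)
        rho = rng.uniform(0, 1, grid.shape3d)
        s = rng.uniform(0, 2, grid.shape3d)
        total = sum(
            form_image(rho, s, psf, k * grid.dz, grid) for k in range(grid.nz)
        )
        edf = form_edf_image(rho, s, psf, grid)
        assert np.allclose(total, edf, atol=1e-10 * edf.max())

    def test_uniform_illumination_reduces_to_widefield(self, small):
        grid, _, psf = small
        rng = np.random.default_rng(3)
        density = rng.uniform(0, 1, grid.shape2d)
        sample = embed_on_surface(density, np.full(grid.shape2d, grid.dz), grid)
        edf_psf = compute_edf_psf(psf)
        img = form_edf_image(sample.density3d, np.ones(grid.shape3d), psf, grid)
        expected = np.fft.ifft2(np.fft.fft2(density) * edf_psf.otf).real
        assert np.allclose(img, expected, atol=1e-12)

    def test_edf_invariant_under_axial_shift(self, small):
        grid, _, psf = small
        rng = np.random.default_rng(4)
        density = rng.uniform(0, 1, grid.shape2d)
        imgs = []
        for k in (1, 3):
            sample = embed_on_surface(
                density, np.full(grid.shape2d, k * grid.dz), grid
            )
            imgs.append(form_edf_image(sample.density3d, np.ones(grid.shape3d), psf, grid))
        assert np.allclose(imgs[0], imgs[1], atol=1e-10)

    def test_forward_linearity_of_edf_images(self, small):
        grid, _, psf = small
        rng = np.random.default_rng(5)
        s = rng.uniform(0, 2, grid.shape3d)
        r1 = rng.uniform(0, 1, grid.shape3d)
        r2 = rng.uniform(0, 1, grid.shape3d)
        a, b = 0.7, 1.9
        lhs = form_edf_image(a * r1 + b * r2, s, psf, grid)
        rhs = a * form_edf_image(r1, s, psf, grid) + b * form_edf_image(r2, s, psf, grid)
        assert np.allclose(lhs, rhs, atol=1e-10)


class TestAcquisition:
    def test_seeded_stacks_are_reproducible(self, grid64, pupil64, psf64):
        sample = embed_on_surface(
            make_star_density(grid64), make_topography(grid64, "flat"), grid64
        )
        a = simulate_acquisition(sample, pupil64, 4, 500.0, "edf", seed=9, psf=psf64)
        b = simulate_acquisition(sample, pupil64, 4, 500.0, "edf", seed=9, psf=psf64)
        assert np.array_equal(a.images, b.images)
        assert a.seeds == b.seeds

    def test_mean_image_converges_to_widefield(self, grid64, pupil64, psf64, edf64):
        sample = embed_on_surface(
            make_star_density(grid64), make_topography(grid64, "flat"), grid64
        )
        stack = simulate_acquisition(
            sample, pupil64, 500, photon_budget=None, modality="edf", seed=21, psf=psf64
        )
        mean = stack.images.mean(axis=0)
        expected = np.fft.ifft2(np.fft.fft2(sample.density2d) * edf64.otf).real
        bright = expected > 0.1 * expected.max()
        rel = np.sqrt(np.mean((mean[bright] - expected[bright]) ** 2)) / np.sqrt(
            np.mean(expected[bright] ** 2)
        )
        assert rel < 0.05

    def test_poisson_statistics_without_speckle(self, grid64, pupil64, psf64):
        sample = embed_on_surface(
            np.ones(grid64.shape2d), make_topography(grid64, "flat"), grid64
        )
        stack = simulate_acquisition(
            sample, pupil64, 400, photon_budget=800.0, modality="edf",
            seed=13, psf=psf64, illumination="uniform",
        )
        mean = stack.images.mean(axis=0)
        var = stack.images.var(axis=0)
        bright = mean > 0.5 * mean.max()
        ratio = (var[bright] / mean[bright]).mean()
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_rejects_bad_photon_budget(self, grid64, pupil64, psf64):
        sample = embed_on_surface(
            np.ones(grid64.shape2d), make_topography(grid64, "flat"), grid64
        )
        with pytest.raises(ValueError):
            simulate_acquisition(sample, pupil64, 4, -5.0, "edf", seed=1, psf=psf64)
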