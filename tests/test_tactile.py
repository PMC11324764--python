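"""Tactile image filtering, moments, ellipse fitting and area statistics."""

import numpy as np
import pytest

from mazeskill.synthetic import generate_tactile_stream, tactile_day_blob
from mazeskill.tactile import (GRID, VMAX, PressureMap, TactileFrame,
                               compare_areas, mean_image, median_filter_frame,
                               pressure_ellipse)

CLEAN = {"noise_sd": 0.0, "outlier_rate": 0.0,
         "sigma_jitter_sd": 0.0, "center_jitter_sd": 0.0}


def _gauss(center, sigma, amp=1000.0):
    rows, cols = np.mgrid[0:GRID, 0:GRID]
    sr, sc = (sigma, sigma) if np.isscalar(sigma) else sigma
    return amp * np.exp(-0.5 * (((rows - center[0]) / sr) ** 2
                                + ((cols - center[1]) / sc) ** 2))


class TestMedianFilter:
    def test_constant_frame_unchanged(self):
        out = median_filter_frame(np.full((GRID, GRID), 123))
        assert np.array_equal(out, np.full((GRID, GRID), 123))

    def test_single_hot_taxel_removed(self):
        frame = np.zeros((GRID, GRID), dtype=int)
        frame[5, 9] = VMAX
        assert np.array_equal(median_filter_frame(frame),
                              np.zeros((GRID, GRID), dtype=int))

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            frame = rng.integers(0, VMAX + 1, (GRID, GRID))
            got = median_filter_frame(frame)
            padded = np.pad(frame, 1, mode="symmetric")
            expect = np.empty_like(frame)
            for r in range(GRID):
                for c in range(GRID):
                    expect[r, c] = np.median(padded[r:r + 3, c:c + 3])
            assert np.array_equal(got, expect)

    def test_idempotent_after_denoising_salt(self, rng):
        # isolated full-scale spikes vanish in one pass; a second pass is
        # then a no-op (the filter is idempotent on its own output here)
        frame = np.zeros((GRID, GRID), dtype=int)
        for r, c in [(2, 3), (7, 11), (12, 4), (14, 14)]:
            frame[r, c] = VMAX
        once = median_filter_frame(frame)
        assert np.array_equal(once, np.zeros_like(frame))
        assert np.array_equal(median_filter_frame(once), once)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            median_filter_frame(np.zeros((GRID, GRID), dtype=int), kernel=4)


class TestMeanImage:
    def _frames(self, grids):
        return [TactileFrame(side="R", t=i * 0.1, grid=g)
                for i, g in enumerate(grids)]

    def test_single_frame_is_itself(self):
        g = np.full((GRID, GRID), 50)
        out = mean_image(self._frames([g]))
        assert np.allclose(out.grid, 50)

    def test_two_frames_average(self):
        out = mean_image(self._frames([np.zeros((GRID, GRID), int),
                                       np.full((GRID, GRID), 100)]))
        assert np.allclose(out.grid, 50.0)

    @pytest.mark.parametrize("n", [1, 2, 5])
    def test_mean_of_identical_frames(self, n, rng):
        g = rng.integers(0, 500, (GRID, GRID))
        filtered = median_filter_frame(g)
        out = mean_image(self._frames([g] * n))
        assert np.allclose(out.grid, filtered)

    def test_mixed_sides_rejected(self):
        frames = [TactileFrame("L", 0.0, np.zeros((GRID, GRID), int)),
                  TactileFrame("R", 0.1, np.zeros((GRID, GRID), int))]
        with pytest.raises(ValueError, match="sides"):
            mean_image(frames)


class TestPressureEllipse:
    def test_symmetric_blob_centroid(self):
        ell = pressure_ellipse(_gauss((7.5, 7.5), 2.5))
        assert ell.centroid[0] == pytest.approx(7.5, abs=0.05)
        assert ell.centroid[1] == pytest.approx(7.5, abs=0.05)

    def test_isotropic_blob_axes_equal(self):
        ell = pressure_ellipse(_gauss((7.5, 7.5), 2.5))
        assert ell.major_axis == pytest.approx(ell.minor_axis, rel=0.02)
        assert ell.orientation == 0.0

    def test_area_quadruples_when_sigma_doubles(self):
        small = pressure_ellipse(_gauss((7.5, 7.5), 1.6)).area
        big = pressure_ellipse(_gauss((7.5, 7.5), 3.2)).area
        assert big == pytest.approx(4 * small, rel=0.1)

    def test_intensity_scale_invariance(self):
        a = pressure_ellipse(_gauss((7.5, 7.5), (2.0, 3.0), amp=10.0))
        b = pressure_ellipse(_gauss((7.5, 7.5), (2.0, 3.0), amp=4000.0))
        assert a.centroid == pytest.approx(b.centroid)
        assert a.area == pytest.approx(b.area, rel=1e-6)
        assert a.orientation == pytest.approx(b.orientation, abs=1e-6)

    def test_anisotropic_orientation(self):
        # wider along columns -> major axis along the column direction
        ell = pressure_ellipse(_gauss((7.5, 7.5), (1.5, 3.5)))
        assert abs(ell.orientation) == pytest.approx(0.0, abs=5.0)
        ell2 = pressure_ellipse(_gauss((7.5, 7.5), (3.5, 1.5)))
        assert abs(ell2.orientation) == pytest.approx(90.0, abs=5.0)

    def test_largest_component_chosen(self):
        two = _gauss((4.0, 4.0), 2.2) + _gauss((12.0, 12.0), 1.0)
        ell = pressure_ellipse(two)
        assert ell.centroid[0] < 8 and ell.centroid[1] < 8

    def test_centroid_inside_active_region_hull(self, rng):
        for seed in range(20):
            frames = generate_tactile_stream(
                3, blob=dict(tactile_day_blob(1), noise_sd=40.0), seed=seed)
            pmap = mean_image(frames)
            ell = pressure_ellipse(pmap)
            mask = pmap.grid >= 0.5 * pmap.grid.max()
            rr, cc = np.where(mask)
            assert rr.min() - 1 <= ell.centroid[0] <= rr.max() + 1
            assert cc.min() - 1 <= ell.centroid[1] <= cc.max() + 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all zero"):
            pressure_ellipse(np.zeros((GRID, GRID)))

    def test_moments_match_bruteforce_oracle(self):
        skimage = pytest.importorskip("skimage.measure")
        grid = _gauss((6.0, 9.0), (2.0, 3.0))
        mask = grid >= 0.5 * grid.max()
        w = np.where(mask, grid, 0.0)
        m = skimage.moments_central(
            w, center=None, order=2)
        m00 = w.sum()
        ell = pressure_ellipse(grid)
        # centroid from raw moments
        mraw = skimage.moments(w, order=1)
        assert ell.centroid[0] == pytest.approx(mraw[1, 0] / mraw[0, 0],
                                                abs=1e-9)
        assert ell.centroid[1] == pytest.approx(mraw[0, 1] / mraw[0, 0],
                                                abs=1e-9)
        # second central moments -> axes
        cov = np.array([[m[2, 0], m[1, 1]], [m[1, 1], m[0, 2]]]) / m00
        lam = np.linalg.eigvalsh(cov)
        assert ell.major_axis == pytest.approx(4 * np.sqrt(lam[1]), rel=1e-9)
        assert ell.minor_axis == pytest.approx(4 * np.sqrt(lam[0]), rel=1e-9)


class TestCompareAreas:
    def test_identical_groups(self, rng):
        g = rng.normal(60, 5, 100)
        res = compare_areas(g, g)
        assert res["p"] > 0.9 and res["F"] == pytest.approx(0.0, abs=1e-20)

    def test_anova_equals_pooled_t_squared(self, rng):
        from scipy import stats
        for _ in range(20):
            a = rng.normal(60, 10, 40)
            b = rng.normal(55, 10, 40)
            res = compare_areas(a, b)
            if res["test_used"] != "anova":
                continue
            t = stats.ttest_ind(a, b).statistic
            assert res["F"] == pytest.approx(t ** 2, rel=1e-10)

    def test_unbalanced_groups_use_mannwhitney(self, rng):
        res = compare_areas(rng.normal(60, 5, 100), rng.normal(55, 5, 30))
        assert res["test_used"] == "mann-whitney"

    def test_nonnormal_groups_use_mannwhitney(self, rng):
        a = rng.exponential(10, 100)
        b = rng.exponential(10, 100)
        res = compare_areas(a, b)
        assert res["test_used"] == "mann-whitney"

    def test_noncentral_f_expectation(self, rng):
        # two-group ANOVA mean F against the closed-form noncentral mean:
        # E[F] ~ (df2/(df2-2)) * (1 + lambda/df1) with
        # lambda = n/2 * delta^2 / sigma^2 per group size n
        n, delta, sigma = 100, 4.2, 10.0
        lam = (n / 2) * delta ** 2 / sigma ** 2
        df2 = 2 * n - 2
        expect = (df2 / (df2 - 2)) * (1 + lam)
        fs = []
        for _ in range(500):
            a = rng.normal(60, sigma, n)
            b = rng.normal(60 - delta, sigma, n)
            res = compare_areas(a, b)
            if res["test_used"] == "anova":
                fs.append(res["F"])
        assert np.mean(fs) == pytest.approx(expect, rel=0.15)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_areas([1.0], [2.0, 3.0])


class TestGeneratorContract:
    def test_zero_amplitude_all_zero(self):
        frames = generate_tactile_stream(3, blob=dict(CLEAN, amplitude=0.0),
                                         seed=0)
        assert all((f.grid == 0).all() for f in frames)

    def test_clean_symmetric_blob_centroid(self):
        frames = generate_tactile_stream(
            1, blob=dict(CLEAN, center=(7.5, 7.5), sigma=2.5), seed=0)
        ell = pressure_ellipse(frames[0].grid.astype(float))
        assert ell.centroid == pytest.approx((7.5, 7.5), abs=0.05)

    def test_outlier_rate_expectation(self):
        # 256 taxels x 0.01 -> about 2.56 expected outliers per frame
        frames = generate_tactile_stream(
            1000, blob=dict(CLEAN, amplitude=0.0, outlier_rate=0.01), seed=1)
        counts = [int((f.grid > 0).sum()) for f in frames]
        assert np.mean(counts) == pytest.approx(2.56, rel=0.1)
        # Poisson-consistent dispersion
        assert np.var(counts) == pytest.approx(np.mean(counts), rel=0.25)

    def test_center_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            generate_tactile_stream(1, blob=dict(CLEAN, center=(20.0, 5.0)))

    def test_deterministic_per_seed(self):
        a = generate_tactile_stream(5, seed=77)
        b = generate_tactile_stream(5, seed=77)
        assert all(np.array_equal(x.grid, y.grid) for x, y in zip(a, b))

    def test_day_shrink_programmed(self):
        a1 = np.mean([pressure_ellipse(mean_image(generate_tactile_stream(
            4, blob=tactile_day_blob(1, "R"), seed=s))).area
            for s in range(40)])
        a3 = np.mean([pressure_ellipse(mean_image(generate_tactile_stream(
            4, blob=tactile_day_blob(3, "R"), seed=1000 + s))).area
            for s in range(40)])
        assert a3 < a1
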