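"""Segmentation, per-cell metrics, exponential fits, macro/micro, rendering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skimage import measure

from chanclust import clusters, synthetic
from chanclust.clusters import LocalizationMap, SegmentationConfig
from chanclust.core import ImageStack

from conftest import make_population


class TestSegmentation:
    def test_cubic_blob_yields_27_voxel_cluster(self):
        data = np.zeros((9, 9, 9))
        data[3:6, 3:6, 3:6] = 100.0
        stack = ImageStack(data, (0.1, 0.1, 0.13))
        pop = clusters.segment_stack(stack, SegmentationConfig(intensity_threshold=50.0))
        assert len(pop) == 1
        assert pop.table.loc[0, "n_voxels"] == 27
        assert pop.table.loc[0, "volume_um3"] == pytest.approx(27 * 0.1 * 0.1 * 0.13)

    def test_two_voxel_blob_rejected(self):
        """A bright signal must exceed two voxels to count as a cluster."""
        data = np.zeros((9, 9, 9))
        data[4, 4, 4:6] = 100.0
        stack = ImageStack(data, (0.1, 0.1, 0.13))
        pop = clusters.segment_stack(stack, SegmentationConfig(intensity_threshold=50.0))
        assert len(pop) == 0

    def test_three_voxel_blob_with_sufficient_extent_kept(self):
        data = np.zeros((9, 9, 9))
        data[4:6, 4, 4:6] = 100.0
        data[4, 4, 4] = 100.0
        stack = ImageStack(data, (0.1, 0.1, 0.13))
        pop = clusters.segment_stack(stack, SegmentationConfig(intensity_threshold=50.0))
        assert len(pop) == 1

    def test_axial_extent_minimum_enforced(self):
        # 150 nm z-minimum: a single 0.13 μm plane fails, two planes pass
        data = np.zeros((9, 9, 9))
        data[4, 3:6, 3:6] = 100.0  # 9 voxels but one z-plane (130 nm)
        stack = ImageStack(data, (0.1, 0.1, 0.13))
        pop = clusters.segment_stack(stack, SegmentationConfig(intensity_threshold=50.0))
        assert len(pop) == 0

    def test_recovers_exact_count_of_separated_blobs(self):
        pop = synthetic.grid_cluster_population(50, 0.1, 2.0, (20.0, 20.0, 4.0))
        spec = synthetic.ImageRenderSpec(poisson_noise=False, background_level=0.0)
        stack = synthetic.render_image_stack(pop, spec, domain=(20.0, 20.0, 4.0))
        seg = clusters.segment_stack(stack, SegmentationConfig(intensity_threshold=30.0))
        assert len(seg) == 50

    def test_recovery_with_noise_at_high_snr(self):
        pop = synthetic.grid_cluster_population(50, 0.3, 2.0, (20.0, 20.0, 4.0))
        spec = synthetic.ImageRenderSpec(poisson_noise=True, background_level=10.0, seed=1)
        stack = synthetic.render_image_stack(pop, spec, domain=(20.0, 20.0, 4.0))
        seg = clusters.segment_stack(stack, SegmentationConfig(intensity_threshold=50.0))
        assert len(seg) == 50

    def test_membrane_restriction(self):
        data = np.zeros((9, 9, 9))
        data[2:4, 2:4, 2:4] = 100.0
        data[6:8, 6:8, 6:8] = 100.0
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[2:4, 2:4, 2:4] = True
        stack = ImageStack(data, (0.1, 0.1, 0.13))
        cfg = SegmentationConfig(intensity_threshold=50.0, membrane_restrict=True)
        pop = clusters.segment_stack(stack, cfg, membrane_mask=mask)
        assert len(pop) == 1
        assert bool(pop.table.loc[0, "on_membrane"])

    def test_idempotent_on_own_binary_output(self):
        pop = synthetic.grid_cluster_population(10, 0.1, 3.0, (15.0, 15.0, 4.0))
        spec = synthetic.ImageRenderSpec(poisson_noise=False, background_level=0.0)
        stack = synthetic.render_image_stack(pop, spec, domain=(15.0, 15.0, 4.0))
        seg1 = clusters.segment_stack(stack, SegmentationConfig(intensity_threshold=30.0))
        binary = ImageStack((stack.data > 30.0).astype(float), stack.voxel_size)
        seg2 = clusters.segment_stack(binary, SegmentationConfig(intensity_threshold=0.5))
        assert len(seg1) == len(seg2)
        assert np.allclose(
            np.sort(seg1.table["n_voxels"]), np.sort(seg2.table["n_voxels"])
        )


class TestCellMetrics:
    def test_totals_and_mean(self):
        pop = make_population([0.05, 0.07])
        m = clusters.cell_metrics(pop, membrane_area_um2=100.0)
        assert m.clusters_per_cell == 2
        assert m.total_cluster_volume == pytest.approx(0.12)
        assert m.mean_cluster_volume == pytest.approx(0.06)

    def test_empty_population_zero_metrics(self):
        pop = make_population([])
        m = clusters.cell_metrics(pop, membrane_area_um2=100.0)
        assert m.clusters_per_cell == 0
        assert m.membrane_occupancy_pct == 0.0
        assert not m.mean_defined

    def test_sampled_mean_near_generator_mean(self):
        pop = synthetic.gen_cluster_population(
            synthetic.SyntheticClusterSpec(500, 0.14, seed=2)
        )
        m = clusters.cell_metrics(pop, membrane_area_um2=1000.0)
        se = 0.14 / np.sqrt(500)
        assert abs(m.mean_cluster_volume - 0.14) < 3 * se

    def test_total_volume_is_exact_sum(self):
        pop = make_population([0.01, 0.02, 0.035])
        m = clusters.cell_metrics(pop, 10.0)
        assert m.total_cluster_volume == pop.volumes.sum()

    def test_occupancy_uses_membrane_clusters_only(self):
        on = make_population([0.1, 0.1], on_membrane=True)
        off = make_population([0.1, 0.1], on_membrane=False)
        m_on = clusters.cell_metrics(on, 100.0)
        m_off = clusters.cell_metrics(off, 100.0)
        assert m_on.membrane_occupancy_pct > 0
        assert m_off.membrane_occupancy_pct == 0


class TestExponentialFit:
    def test_recovers_decay_constant_within_5_percent(self):
        rng = np.random.default_rng(11)
        vols = rng.exponential(0.07, size=10_000)
        dist = clusters.histogram_distribution(vols, 0.02)
        _, tau, r2 = clusters.fit_exponential(dist)
        assert abs(tau - 0.07) / 0.07 < 0.05
        assert r2 > 0.95

    def test_tau_order_preserved(self):
        rng = np.random.default_rng(12)
        d1 = clusters.histogram_distribution(rng.exponential(0.07, 5000), 0.02)
        d2 = clusters.histogram_distribution(rng.exponential(0.14, 5000), 0.02)
        _, tau1, _ = clusters.fit_exponential(d1)
        _, tau2, _ = clusters.fit_exponential(d2)
        assert tau1 < tau2

    def test_single_occupied_bin_rejected(self):
        from chanclust.core import SizeDistribution

        dist = SizeDistribution(np.array([0.01, 0.03, 0.05]), np.array([0.0, 50.0, 0.0]))
        with pytest.raises(ValueError, match="3 non-empty"):
            clusters.fit_exponential(dist)


class TestMacroMicro:
    def test_printed_mean_and_sd_give_published_threshold(self):
        thr = clusters.macro_threshold(0.12, 0.03)
        assert thr.threshold == pytest.approx(0.06)

    def test_zero_sd_threshold_is_mean(self):
        assert clusters.macro_threshold(0.08, 0.0).threshold == pytest.approx(0.08)

    def test_sphere_formula_equivalent_diameter(self):
        thr = clusters.macro_threshold(0.12, 0.03)
        assert thr.equivalent_diameter_nm == pytest.approx(485.7, abs=0.5)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            clusters.macro_threshold(0.1, -0.1)

    def test_nonpositive_threshold_warns(self):
        with pytest.warns(UserWarning, match="non-positive"):
            clusters.macro_threshold(0.05, 0.05)

    def test_strict_inequality_at_boundary(self):
        pop = make_population([0.05, 0.06, 0.07])
        macro, micro, frac = clusters.classify_macro_micro(pop, 0.06)
        assert (macro, micro) == (1, 2)  # exactly-at-threshold counts as micro

    def test_all_below_threshold(self):
        pop = make_population([0.01, 0.02])
        macro, micro, frac = clusters.classify_macro_micro(pop, 0.06)
        assert macro == 0 and frac == 0.0

    def test_macro_fraction_matches_exponential_tail(self, exponential_population):
        mu, thr, n = 0.07, 0.06, len(exponential_population)
        _, _, frac = clusters.classify_macro_micro(exponential_population, thr)
        expected = np.exp(-thr / mu)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se

    @given(st.floats(0.01, 0.5), st.floats(0.01, 0.5))
    def test_threshold_monotonicity(self, t1, t2):
        rng = np.random.default_rng(99)
        pop = make_population(rng.exponential(0.07, 200))
        lo, hi = sorted((t1, t2))
        macro_lo, _, _ = clusters.classify_macro_micro(pop, lo)
        macro_hi, _, _ = clusters.classify_macro_micro(pop, hi)
        assert macro_hi <= macro_lo


class TestLocalization:
    def test_point_to_pixel_coordinate_arithmetic(self):
        rendered = clusters.render_points(np.array([[100.0, 100.0]]), 20.0, (10, 10))
        assert rendered[5, 5] == 1.0
        assert rendered.sum() == 1.0

    def test_single_emitter_localizes_to_true_position(self):
        true = (3200.0, 3000.0)
        spec = synthetic.BlinkMovieSpec(
            emitter_positions=(true,), frames=300, blink_prob=0.5,
            localization_noise_sd=15.0, seed=2,
        )
        movie = synthetic.gen_blink_movie(spec)
        lm = clusters.localize_and_render(movie, photon_threshold=100.0)
        assert len(lm.points) > 50
        se = 15.0 / np.sqrt(len(lm.points))
        assert abs(lm.points[:, 0].mean() - true[0]) < 3 * se + 1.0
        assert abs(lm.points[:, 1].mean() - true[1]) < 3 * se + 1.0

    def test_empty_movie_rejected(self):
        from chanclust.core import Movie

        movie = Movie(np.zeros((0, 8, 8)), pixel_size_nm=100.0)
        with pytest.raises(ValueError, match="at least one frame"):
            clusters.localize_and_render(movie, 10.0)


class TestGaussianBlur:
    def test_delta_image_conserves_intensity(self):
        pts = np.array([[500.0, 500.0]])
        lm = LocalizationMap(pts, clusters.render_points(pts, 20.0, (100, 100)))
        blurred = clusters.gaussian_blur_gsd(lm, 200.0)
        assert abs(blurred.rendered.sum() - lm.rendered.sum()) < 1e-6
        assert blurred.rendered.max() < lm.rendered.max()

    def test_close_micro_clusters_merge_after_blur(self):
        """Two point groups < 200 nm apart blur into one connected blob."""
        pts = np.array([[400.0, 500.0], [550.0, 500.0]])
        lm = LocalizationMap(pts, clusters.render_points(pts, 20.0, (100, 100)))
        sharp_labels = measure.label(lm.rendered > 0, connectivity=2)
        assert sharp_labels.max() == 2
        blurred = clusters.gaussian_blur_gsd(lm, 200.0)
        merged = measure.label(blurred.rendered > 0.5 * blurred.rendered.max(), connectivity=2)
        assert merged.max() == 1

    def test_zero_radius_returns_input(self):
        pts = np.array([[300.0, 700.0]])
        lm = LocalizationMap(pts, clusters.render_points(pts, 20.0, (64, 64)))
        out = clusters.gaussian_blur_gsd(lm, 0.0)
        assert np.array_equal(out.rendered, lm.rendered)

    def test_translation_invariance(self):
        base = np.zeros((64, 64))
        base[20, 20] = 1.0
        shifted = np.roll(base, (7, 3), axis=(0, 1))
        b1 = clusters.gaussian_blur_gsd(LocalizationMap(np.empty((0, 2)), base), 200.0)
        b2 = clusters.gaussian_blur_gsd(LocalizationMap(np.empty((0, 2)), shifted), 200.0)
        assert np.allclose(np.roll(b1.rendered, (7, 3), axis=(0, 1)), b2.rendered)


class TestPla:
    def test_density_arithmetic(self):
        import pandas as pd

        from chanclust.core import ClusterPopulation

        table = pd.DataFrame(
            {"id": range(10), "area_nm2": [1e4] * 10, "x": 0.0, "y": 0.0,
             "on_membrane": True}
        )
        res = clusters.pla_quantify(ClusterPopulation(table), cell_area_um2=100.0)
        assert res.puncta_density_per_um2 == pytest.approx(0.1)
        assert res.total_puncta_area_um2 == pytest.approx(10 * 1e4 * 1e-6)

    def test_empty_population(self):
        import pandas as pd

        from chanclust.core import ClusterPopulation

        empty = ClusterPopulation(
            pd.DataFrame({"id": [], "area_nm2": [], "x": [], "y": [], "on_membrane": []})
        )
        res = clusters.pla_quantify(empty, 50.0)
        assert res.puncta_count == 0
        assert res.puncta_density_per_um2 == 0.0

    def test_poisson_density_recovery(self):
        rng = np.random.default_rng(8)
        rho, area = 0.5, 400.0
        n = rng.poisson(rho * area)
        import pandas as pd

        from chanclust.core import ClusterPopulation

        table = pd.DataFrame(
            {"id": range(n), "area_nm2": np.full(n, 5e3), "x": 0.0, "y": 0.0,
             "on_membrane": True}
        )
        res = clusters.pla_quantify(ClusterPopulation(table), area)
        se = np.sqrt(rho / area)
        assert abs(res.puncta_density_per_um2 - rho) < 3 * se
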