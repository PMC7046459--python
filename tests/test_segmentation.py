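"""Imaging primitives: thresholds, morphology, size/shape filters, projections."""

from __future__ import annotations

import numpy as np
import pytest

from plaquekit import (
    ColorClassifier,
    ColorRange,
    ImageGrid,
    ShapeLimits,
    color_classify,
    control_background_threshold,
    max_projection,
    percentile_threshold_mask,
    plaque_density_3d,
    segment_fluorescence,
    tissue_mask,
)
from plaquekit.grids import BinaryMask
from plaquekit.segmentation import label_and_filter, object_table

from conftest import disk_image, stack_of
from oracles import max_projection_oracle, percentile_oracle, roundness_oracle


class TestSegmentFluorescence:
    def test_blank_image_gives_no_objects(self):
        img = ImageGrid(np.zeros((120, 120)), 1.0)
        labels, table = segment_fluorescence(img)
        assert labels.n_objects == 0
        assert table.empty

    def test_scene_recovery_at_high_snr(self, separated_scene, default_shape_limits):
        spec, channels, truth = separated_scene
        labels, table = segment_fluorescence(
            channels["X04"],
            local_offset=3 * spec.noise_sd,
            min_size_um2=34.0,
            shape_limits=default_shape_limits,
        )
        assert labels.n_objects == len(truth.plaques) == 25
        true_area = truth.plaques[0].total_area_um2
        rel_err = np.abs(table["area_um2"].values - true_area) / true_area
        assert rel_err.max() < 0.10

    def test_min_size_filter_34um2(self):
        # one 30 um^2 object and one 40 um^2 object at 1 um/px
        img = np.zeros((60, 60))
        img[5:10, 5:11] = 100.0    # 30 px = 30 um^2
        img[30:35, 30:38] = 100.0  # 40 px = 40 um^2
        labels, table = label_and_filter(BinaryMask(img > 0, 1.0), min_size_um2=34.0)
        assert labels.n_objects == 1
        assert table["area_um2"].iloc[0] == pytest.approx(40.0)

    @pytest.mark.parametrize("pixel_size", [0.25, 0.5, 1.0])
    def test_min_size_filter_across_pixel_sizes(self, pixel_size):
        # blocks of exactly 30/q^2 and 40/q^2 pixels: true areas 30 and 40 um^2
        n_small = int(round(30.0 / pixel_size**2))
        n_large = int(round(40.0 / pixel_size**2))
        side = int(60 / pixel_size)
        canvas = np.zeros((2 * side + 10, side), dtype=bool)
        flat = np.zeros(side * side, dtype=bool)
        flat[:n_small] = True
        canvas[:side, :] = flat.reshape(side, side)
        flat = np.zeros(side * side, dtype=bool)
        flat[:n_large] = True
        canvas[side + 10 :, :] = flat.reshape(side, side)
        labels, table = label_and_filter(BinaryMask(canvas, pixel_size), min_size_um2=34.0)
        assert labels.n_objects == 1
        assert table["area_um2"].iloc[0] == pytest.approx(40.0, rel=1e-9)

    def test_idempotent_on_binarized_output(self, separated_scene, default_shape_limits):
        spec, channels, _ = separated_scene
        labels, table = segment_fluorescence(
            channels["X04"],
            local_offset=3 * spec.noise_sd,
            min_size_um2=34.0,
            shape_limits=default_shape_limits,
        )
        rerun_img = ImageGrid((labels.data > 0) * 100.0, spec.pixel_size_um)
        labels2, table2 = segment_fluorescence(rerun_img, local_offset=1.0, min_size_um2=34.0)
        assert labels2.n_objects == labels.n_objects
        np.testing.assert_allclose(
            np.sort(table2["area_um2"].values), np.sort(table["area_um2"].values), rtol=0.02
        )

    def test_area_scale_invariance_under_resolution(self):
        for px in (1.0, 0.5):
            spec_img = disk_image(int(10 / px), value=100.0, pixel_size_um=px)
            labels, table = segment_fluorescence(
                spec_img, tophat_radius_um=15.0, local_window_um=30.0,
                local_offset=1.0, min_size_um2=9.0,
            )
            assert labels.n_objects == 1
            if px == 1.0:
                coarse = table["area_um2"].iloc[0]
            else:
                fine = table["area_um2"].iloc[0]
        assert abs(fine - coarse) / coarse < 0.02

    def test_window_too_small_raises(self):
        img = ImageGrid(np.zeros((50, 50)), 10.0)
        with pytest.raises(ValueError, match="at least 3 px"):
            segment_fluorescence(img, local_window_um=15.0)


class TestShapeFilter:
    def test_disk_retained_bar_removed(self):
        img = np.zeros((60, 60), dtype=bool)
        img[5, 5:35] = True  # 1x30 bar, 30 px
        rr, cc = np.ogrid[:60, :60]
        disk = (rr - 40) ** 2 + (cc - 40) ** 2 <= 3.0**2  # 29 px, comparable area
        labels, table = label_and_filter(
            BinaryMask(img | disk, 1.0),
            shape_limits=ShapeLimits(solidity=0.5, roundness=0.2),
        )
        assert labels.n_objects == 1
        assert table["roundness"].iloc[0] > 0.5  # the disk survived

    def test_bar_roundness_matches_bruteforce_oracle_decision(self):
        bar = np.zeros((10, 40), dtype=bool)
        bar[5, 5:35] = True
        labels, _ = label_and_filter(BinaryMask(bar, 1.0))
        feats = object_table(labels)
        oracle = roundness_oracle(bar)
        assert feats["roundness"].iloc[0] < 0.3
        assert oracle < 0.3

    def test_no_limits_is_identity(self):
        img = disk_image(5)
        labels, table = label_and_filter(BinaryMask(img.data > 0, 1.0), shape_limits=None)
        assert labels.n_objects == 1

    def test_disk_features_approach_one_with_radius(self):
        prev = None
        for r in (8, 20, 40):
            img = disk_image(r)
            labels, table = label_and_filter(BinaryMask(img.data > 0, 1.0))
            row = table.iloc[0]
            for feat in ("shape_factor", "roundness", "solidity"):
                assert row[feat] <= 1.05
            if r >= 20:
                assert min(row["shape_factor"], row["roundness"], row["solidity"]) > 0.9
            if prev is not None:
                assert row["solidity"] >= prev - 1e-6
            prev = row["solidity"]


class TestColorClassify:
    def _rgb(self, arr):
        return tuple(ImageGrid(arr[..., i], 1.0) for i in range(3))

    def test_no_matching_pixel_gives_empty_mask(self):
        rgb = np.full((8, 8, 3), 200.0)
        cls = ColorClassifier((ColorRange("rgb", (0, 0, 0), (10, 10, 10)),))
        mask = color_classify(*self._rgb(rgb), cls)
        assert not mask.data.any()

    def test_single_pixel_bracketing(self):
        rgb = np.zeros((8, 8, 3))
        rgb[3, 4] = (120.0, 60.0, 30.0)
        cls = ColorClassifier((ColorRange("rgb", (119, 59, 29), (121, 61, 31)),))
        mask = color_classify(*self._rgb(rgb), cls)
        assert mask.data.sum() == 1 and mask.data[3, 4]

    def test_negative_range_vetoes(self):
        rgb = np.zeros((4, 4, 3))
        rgb[0, 0] = (50.0, 50.0, 50.0)
        rgb[1, 1] = (50.0, 50.0, 200.0)
        cls = ColorClassifier(
            (
                ColorRange("rgb", (40, 40, 40), (255, 255, 255)),
                ColorRange("rgb", (None, None, 150), (None, None, 255), positive=False),
            )
        )
        mask = color_classify(*self._rgb(rgb), cls)
        assert mask.data[0, 0] and not mask.data[1, 1]

    def test_dark_plaque_on_amber_background_recovered(self):
        # painted truth: dark (low V) plaque blob on a bright amber field
        rng = np.random.default_rng(0)
        rgb = np.empty((80, 80, 3))
        rgb[..., 0] = 220 + rng.normal(0, 2, (80, 80))
        rgb[..., 1] = 160 + rng.normal(0, 2, (80, 80))
        rgb[..., 2] = 60 + rng.normal(0, 2, (80, 80))
        rr, cc = np.ogrid[:80, :80]
        blob = (rr - 40) ** 2 + (cc - 40) ** 2 <= 12**2
        rgb[blob] = (30.0, 30.0, 30.0)
        cls = ColorClassifier((ColorRange("hsv", (None, None, 0.0), (None, None, 0.3)),))
        mask = color_classify(*self._rgb(rgb), cls)
        painted = blob.sum()
        assert abs(mask.data.sum() - painted) / painted < 0.10

    def test_inverted_range_rejected_at_construction(self):
        with pytest.raises(ValueError, match="inverted"):
            ColorRange("rgb", (10, 0, 0), (5, 255, 255))

    def test_requires_positive_range(self):
        with pytest.raises(ValueError, match="positive"):
            ColorClassifier((ColorRange("rgb", (0, 0, 0), (1, 1, 1), positive=False),))


class TestTissueMask:
    def test_uniform_bright_gives_full_frame(self):
        mask = tissue_mask(ImageGrid(np.full((40, 40), 100.0), 1.0), threshold=10.0)
        assert mask.data.all()

    def test_uniform_zero_gives_empty(self):
        mask = tissue_mask(ImageGrid(np.zeros((40, 40)), 1.0), threshold=10.0)
        assert not mask.data.any()

    def test_holes_filled_and_area_close_to_silhouette(self):
        rr, cc = np.ogrid[:200, :200]
        silhouette = (rr - 100) ** 2 + (cc - 100) ** 2 <= 80**2
        img = np.where(silhouette, 100.0, 0.0)
        holes = (rr - 90) ** 2 + (cc - 110) ** 2 <= 10**2
        img[holes] = 0.0
        mask = tissue_mask(ImageGrid(img, 1.0), threshold=50.0)
        assert mask.data[90, 110]  # hole filled
        assert abs(mask.data.sum() - silhouette.sum()) / silhouette.sum() < 0.05


class TestProjectionsAndPercentiles:
    def test_single_slice_projection_is_identity(self):
        arr = np.random.default_rng(1).random((1, 6, 6))
        proj = max_projection(stack_of(arr))
        np.testing.assert_array_equal(proj.data, arr[0])

    def test_constant_slices_project_to_max(self):
        arr = np.stack([np.full((4, 4), v) for v in (1.0, 5.0, 3.0)])
        assert (max_projection(stack_of(arr)).data == 5.0).all()

    def test_projection_matches_loop_oracle(self, rng):
        arr = rng.random((5, 8, 8))
        np.testing.assert_array_equal(
            max_projection(stack_of(arr)).data, max_projection_oracle(arr)
        )

    def test_control_threshold_trivial_cases(self):
        zeros = [ImageGrid(np.zeros((10, 10)), 1.0)]
        assert control_background_threshold(zeros) == 0.0
        consts = [ImageGrid(np.full((10, 10), 7.5), 1.0)]
        assert control_background_threshold(consts) == 7.5

    def test_control_threshold_matches_sort_oracle(self):
        vals = np.arange(10000, dtype=float)
        img = ImageGrid(vals.reshape(100, 100), 1.0)
        got = control_background_threshold([img])
        assert got == pytest.approx(percentile_oracle(vals, 99.99), rel=1e-12)

    @pytest.mark.parametrize("q", [50.0, 80.0, 99.99])
    def test_percentiles_match_oracle_on_random_pools(self, rng, q):
        for n in (17, 1001, 100_000):
            vals = rng.random(n) * 1e4
            img = ImageGrid(vals.reshape(1, -1), 1.0)
            got = control_background_threshold([img], percentile=q)
            assert got == pytest.approx(percentile_oracle(vals, q), rel=1e-9)

    def test_percentile_zero_recovers_positive_mask(self):
        rng = np.random.default_rng(2)
        img = ImageGrid(rng.uniform(10, 100, (40, 40)), 1.0)
        rr, cc = np.ogrid[:40, :40]
        pos = BinaryMask((rr - 20) ** 2 + (cc - 20) ** 2 <= 10**2, 1.0)
        masks, thr = percentile_threshold_mask([img], [pos], percentile=0.0, cleanup=False)
        np.testing.assert_array_equal(masks[0].data, pos.data)

    def test_80th_percentile_threshold_from_masked_pixels(self):
        vals = np.arange(1.0, 101.0)
        img = ImageGrid(np.pad(vals.reshape(10, 10), 2, constant_values=0.0), 1.0)
        pos = BinaryMask(img.data > 0, 1.0)
        _, thr = percentile_threshold_mask([img], [pos], percentile=80.0, cleanup=False)
        assert thr == pytest.approx(percentile_oracle(vals, 80.0), rel=1e-12)

    def test_two_plateau_masks_isolate_core_then_whole_plaque(self):
        # core plateau 200 on 30% of plaque pixels, halo plateau 100 on 70%
        img = np.zeros((60, 60))
        rr, cc = np.ogrid[:60, :60]
        plaque = (rr - 30) ** 2 + (cc - 30) ** 2 <= 20**2
        core = (rr - 30) ** 2 + (cc - 30) ** 2 <= 11**2  # ~30% of plaque area
        img[plaque] = 100.0
        img[core] = 200.0
        grid = ImageGrid(img, 1.0)
        pos = BinaryMask(plaque, 1.0)
        compact, _ = percentile_threshold_mask([grid], [pos], 80.0, cleanup=False)
        diffuse, _ = percentile_threshold_mask([grid], [pos], 50.0, cleanup=False)
        np.testing.assert_array_equal(compact[0].data, core)
        np.testing.assert_array_equal(diffuse[0].data, plaque)

    def test_empty_pool_raises(self):
        img = ImageGrid(np.ones((5, 5)), 1.0)
        empty = BinaryMask(np.zeros((5, 5), dtype=bool), 1.0)
        with pytest.raises(ValueError, match="empty"):
            percentile_threshold_mask([img], [empty], 80.0)


class TestPlaqueDensity3D:
    def test_empty_volume_is_zero_density(self):
        vol = stack_of(np.zeros((10, 50, 50)), pixel_size_um=1.0, spacing=2.0)
        count, density = plaque_density_3d(vol, threshold=10.0)
        assert count == 0 and density == 0.0

    def test_single_sphere_in_known_volume(self):
        # 0.001 mm^3 = 1e6 um^3: 10 slices x 2 um x (223.6 um)^2 ~ use exact dims
        arr = np.zeros((10, 100, 100))
        arr[4:6, 40:44, 40:44] = 50.0
        # volume = 10*2 * 100*5 * 100*5 um^3 = 5e6 um^3 = 0.005 mm^3
        vol = stack_of(arr, pixel_size_um=5.0, spacing=2.0)
        count, density = plaque_density_3d(vol, threshold=10.0)
        assert count == 1
        assert density == pytest.approx(1 / 0.005)

    def test_synthetic_spheres_counted(self, rng):
        arr = np.zeros((12, 80, 80))
        centers = [(3, 10, 10), (6, 40, 40), (9, 70, 20), (3, 20, 60),
                   (8, 60, 60), (5, 70, 70), (10, 10, 70), (2, 50, 15)]
        zz, yy, xx = np.ogrid[:12, :80, :80]
        for z, y, x in centers:
            arr[(zz - z) ** 2 + (yy - y) ** 2 + (xx - x) ** 2 <= 4] = 100.0
        vol = stack_of(arr, pixel_size_um=1.0, spacing=2.0)
        count, density = plaque_density_3d(vol, threshold=50.0, min_voxels=3)
        assert count == 8
        vol_mm3 = (12 * 2.0 * 80 * 80) / 1e9
        assert density == pytest.approx(8 / vol_mm3)

    def test_min_voxel_filter_drops_specks(self):
        arr = np.zeros((6, 20, 20))
        arr[2, 5, 5] = 100.0          # single voxel speck
        arr[3:5, 10:13, 10:13] = 100.0  # 18-voxel blob
        vol = stack_of(arr, pixel_size_um=1.0, spacing=2.0)
        count, _ = plaque_density_3d(vol, threshold=50.0, min_voxels=5)
        assert count == 1
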