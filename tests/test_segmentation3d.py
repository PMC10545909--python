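"""Median filtering, 3D segmentation, volumes and fluorescence integration."""

import numpy as np
import pytest

import pulsescope as ps
from pulsescope.segmentation3d import LabeledVolume


def brute_force_median(volume, radius):
    """Edge-replicated box median, computed voxel by voxel."""
    padded = np.pad(volume, radius, mode="edge")
    out = np.empty_like(volume)
    r = radius
    for z in range(volume.shape[0]):
        for y in range(volume.shape[1]):
            for x in range(volume.shape[2]):
                box = padded[z : z + 2 * r + 1, y : y + 2 * r + 1, x : x + 2 * r + 1]
                out[z, y, x] = np.median(box)
    return out


class TestMedianFilter:
    def test_constant_volume_unchanged(self):
        vol = np.full((4, 5, 6), 7.0)
        assert np.array_equal(ps.median_filter3d(vol, 1), vol)

    def test_impulse_removed(self):
        vol = np.zeros((5, 5, 5))
        vol[2, 2, 2] = 100.0
        out = ps.median_filter3d(vol, 1)
        assert out[2, 2, 2] == 0.0
        np.testing.assert_array_equal(out, brute_force_median(vol, 1))

    def test_step_edge_preserved_and_matches_oracle(self):
        vol = np.zeros((5, 5, 5))
        vol[:, :, 2:] = 10.0
        out = ps.median_filter3d(vol, 1)
        np.testing.assert_array_equal(out, brute_force_median(vol, 1))
        # the step edge stays at x = 2
        assert np.all(out[:, :, :2] == 0.0)
        assert np.all(out[:, :, 2:] == 10.0)

    def test_random_volume_matches_oracle(self):
        rng = np.random.default_rng(5)
        vol = rng.integers(0, 255, size=(6, 6, 6)).astype(float)
        np.testing.assert_array_equal(
            ps.median_filter3d(vol, 1), brute_force_median(vol, 1)
        )

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ps.median_filter3d(np.zeros((3, 10, 10)), radius=2)

    def test_radius_below_one_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            ps.median_filter3d(np.zeros((5, 5, 5)), radius=0)


class TestSegmentObjects:
    def two_cube_volume(self):
        vol = np.zeros((10, 12, 12))
        vol[1:4, 1:4, 1:4] = 100.0  # 27 voxels
        vol[6:9, 7:11, 7:11] = 80.0  # 48 voxels
        return vol

    def test_two_separated_cubes(self):
        labeled = ps.segment_objects(self.two_cube_volume(), threshold=50.0)
        assert labeled.n_objects == 2
        counts = np.bincount(labeled.labels.ravel())
        # labels sorted by decreasing size: the 48-voxel cube is label 1
        assert counts[1] == 48
        assert counts[2] == 27

    def test_threshold_above_max_yields_empty_labelling(self):
        labeled = ps.segment_objects(self.two_cube_volume(), threshold=1e6)
        assert labeled.n_objects == 0

    def test_min_voxels_filters_small_components(self):
        labeled = ps.segment_objects(self.two_cube_volume(), threshold=50.0, min_voxels=30)
        assert labeled.n_objects == 1
        assert (labeled.labels > 0).sum() == 48

    def test_diagonal_voxels_are_26_connected(self):
        vol = np.zeros((4, 4, 4))
        vol[0, 0, 0] = vol[1, 1, 1] = 10.0
        labeled = ps.segment_objects(vol, threshold=5.0)
        assert labeled.n_objects == 1

    def test_simulator_blobs_counted_at_high_contrast(self, standard_timeline):
        from dataclasses import replace

        scene = replace(
            ps.SceneParams(),
            plastids_per_cell=2,
            n_cells=2,
            motion_step_um=0.0,
            noise=ps.synthetic.NoiseParams(poisson=False, gaussian_sd=0.0),
        )
        stack, truth = ps.render_scene(scene, standard_timeline)
        vol = stack.data[0]
        thr = scene.background.level + 0.5 * (vol.max() - scene.background.level)
        labeled = ps.segment_objects(vol, threshold=thr, min_voxels=4)
        # plastids that touch merge into one component, so compare against
        # the connected components of the ground-truth masks
        from skimage.measure import label as cc_label

        expected = int(cc_label(truth.masks[0] > 0, connectivity=3).max())
        assert labeled.n_objects == expected

    def test_otsu_default_threshold_used(self):
        labeled = ps.segment_objects(self.two_cube_volume())
        assert labeled.n_objects == 2


class TestObjectStats:
    def test_volume_hand_arithmetic(self):
        labels = np.zeros((5, 10, 10), dtype=np.int32)
        labels[0, :10, :10] = 1  # 100 voxels
        lv = LabeledVolume(labels, voxel_size=(2.0, 0.5, 0.5))
        stats = ps.object_volume(lv)
        assert stats.loc[0, "voxel_count"] == 100
        assert stats.loc[0, "volume_um3"] == pytest.approx(50.0)

    def test_empty_labelling_gives_empty_stats(self):
        lv = LabeledVolume(np.zeros((2, 2, 2), dtype=np.int32))
        assert len(ps.object_volume(lv)) == 0

    def test_digitized_sphere_volume_within_15pct(self):
        r = 5
        zz, yy, xx = np.mgrid[-8:9, -8:9, -8:9]
        sphere = (zz**2 + yy**2 + xx**2 <= r**2).astype(np.int32)
        lv = LabeledVolume(sphere, voxel_size=(1.0, 1.0, 1.0))
        stats = ps.object_volume(lv)
        continuous = 4.0 / 3.0 * np.pi * r**3
        brute = int(sphere.sum())
        assert stats.loc[0, "voxel_count"] == brute
        assert abs(stats.loc[0, "volume_um3"] - continuous) / continuous < 0.15

    def test_integration_hand_arithmetic(self):
        labels = np.zeros((3, 3, 3), dtype=np.int32)
        labels[0, 0, :3] = 1
        labels[2, 2, :2] = 2
        vol = np.full((3, 3, 3), 7.0)
        stats = ps.integrate_fluorescence(LabeledVolume(labels), vol)
        assert stats.loc[0, "integrated_fluorescence"] == pytest.approx(21.0)
        assert stats.loc[0, "mean_fluorescence"] == pytest.approx(7.0)
        assert stats.loc[1, "integrated_fluorescence"] == pytest.approx(14.0)

    def test_integration_matches_loop_oracle(self):
        rng = np.random.default_rng(9)
        vol = rng.uniform(0, 100, size=(4, 5, 6))
        labels = rng.integers(0, 3, size=(4, 5, 6)).astype(np.int32)
        if labels.max() == 0:
            labels[0, 0, 0] = 1
        stats = ps.integrate_fluorescence(LabeledVolume(labels), vol)
        for _, row in stats.iterrows():
            acc, n = 0.0, 0
            for z in range(4):
                for y in range(5):
                    for x in range(6):
                        if labels[z, y, x] == row["label"]:
                            acc += vol[z, y, x]
                            n += 1
            assert row["integrated_fluorescence"] == pytest.approx(acc)
            assert row["voxel_count"] == n

    def test_union_integral_equals_masked_sum(self):
        rng = np.random.default_rng(13)
        vol = rng.uniform(0, 100, size=(5, 6, 7))
        labels = (vol > 50).astype(np.int32)
        labels = ps.segment_objects(vol, threshold=50.0).labels
        stats = ps.integrate_fluorescence(LabeledVolume(labels), vol)
        assert stats["integrated_fluorescence"].sum() == pytest.approx(
            vol[labels > 0].sum()
        )

    def test_geometry_mismatch_rejected(self):
        lv = LabeledVolume(np.ones((2, 2, 2), dtype=np.int32))
        with pytest.raises(ValueError, match="match"):
            ps.integrate_fluorescence(lv, np.zeros((3, 3, 3)))


class TestAreaFraction:
    def test_full_occupancy(self):
        cell = np.ones((10, 10), dtype=bool)
        assert ps.area_fraction(cell, cell) == pytest.approx(100.0)

    def test_quarter_occupancy(self):
        cell = np.ones((10, 10), dtype=bool)
        plastid = np.zeros((10, 10), dtype=bool)
        plastid[:5, :5] = True
        assert ps.area_fraction(cell, plastid) == pytest.approx(25.0)

    def test_empty_plastid_mask_is_zero(self):
        cell = np.ones((4, 4), dtype=bool)
        assert ps.area_fraction(cell, np.zeros((4, 4), dtype=bool)) == 0.0

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ps.area_fraction(np.zeros((4, 4), dtype=bool), np.zeros((4, 4), dtype=bool))

    def test_plastid_outside_cell_rejected(self):
        cell = np.zeros((4, 4), dtype=bool)
        cell[:2] = True
        plastid = np.zeros((4, 4), dtype=bool)
        plastid[3, 3] = True
        with pytest.raises(ValueError, match="outside"):
            ps.area_fraction(cell, plastid)
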