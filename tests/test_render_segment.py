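"""Rendering contracts and watershed segmentation fidelity."""
import numpy as np
import pandas as pd
import pytest

from morphodyn import segment as S
from morphodyn import tissue
from morphodyn.images import LabelImage, VoxelImage
from morphodyn.render import RenderParams, render_stack
from morphodyn.segment import (NoSeedsError, SegmentationParams, classify_edu,
                               detect_seeds, filter_labels, match_labels,
                               measure_cells, segment_stack,
                               watershed_segment)


class TestRender:
    def test_wall_only_on_boundaries_and_labels_partition(self, rendered_sheet):
        snap, img, gt = rendered_sheet
        wall = img.channel("wall").data
        lab = gt.labels
        # interior voxels (label unchanged in a 3x3x3 neighbourhood away
        # from the slab faces) carry no wall signal
        from scipy import ndimage
        interior = (ndimage.minimum_filter(lab, 3)
                    == ndimage.maximum_filter(lab, 3)) & (lab > 0)
        assert wall[interior].max() == 0.0
        assert wall.max() == 1.0
        # label ids are exactly the simulated cells
        assert set(gt.ids) == {c.id for c in snap.cells}

    def test_no_edu_means_empty_nuclear_channel(self, small_sheet):
        img, _ = render_stack(small_sheet, RenderParams())
        assert img.channel("edu").data.max() == 0.0

    def test_poisson_noise_deterministic_per_seed(self, small_sheet):
        p = RenderParams(noise_model="poisson", noise_scale=0.05, rng_seed=3)
        a, _ = render_stack(small_sheet, p)
        b, _ = render_stack(small_sheet, p)
        np.testing.assert_array_equal(a.data, b.data)

    def test_empty_snapshot_rejected(self):
        with pytest.raises(ValueError):
            render_stack(tissue.TissueSnapshot(0.0, []), RenderParams())

    def test_coarse_voxels_warn(self, small_sheet):
        with pytest.warns(UserWarning):
            render_stack(small_sheet, RenderParams(voxel_size=(8.0, 8.0, 8.0)))


class TestSeeds:
    def test_one_seed_per_cell_plus_background(self, rendered_sheet):
        snap, img, _ = rendered_sheet
        seeds = detect_seeds(img.channel("wall"))
        n = int(seeds.labels.max())
        assert len(snap.cells) <= n <= len(snap.cells) + 1

    def test_constant_image_has_no_seeds(self):
        img = VoxelImage(np.zeros((10, 20, 20), np.float32), (0.5, 0.25, 0.25))
        with pytest.raises(NoSeedsError):
            detect_seeds(img)

    def test_seed_count_nonincreasing_in_h(self, rendered_sheet):
        _, img, _ = rendered_sheet
        wall = img.channel("wall")
        counts = []
        for h in (0.1, 0.3, 0.6, 0.9):
            try:
                counts.append(int(detect_seeds(
                    wall, SegmentationParams(h_depth=h)).labels.max()))
            except NoSeedsError:
                counts.append(0)
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestWatershed:
    def test_recovers_cells_against_ground_truth(self, rendered_sheet):
        snap, img, gt = rendered_sheet
        labels, table = segment_stack(img)
        assert len(table) == len(snap.cells)
        m = match_labels(gt, labels)
        assert (m["jaccard"] >= 0.95).all()

    def test_ground_truth_seeding_matches_detected_seeding(self, rendered_sheet):
        """Seeding at true centroids reproduces the detect_seeds result."""
        snap, img, gt = rendered_sheet
        wall = img.channel("wall")
        params = SegmentationParams()
        auto = watershed_segment(wall, detect_seeds(wall, params), params)
        oracle_seeds = np.zeros_like(gt.labels)
        vz, vy, vx = gt.voxel_size
        oz, oy, ox = gt.origin
        for c in snap.cells:
            cx, cy = c.centroid
            iz = int(round((c.thickness / 2 - oz) / vz))
            iy = int(round((cy - oy) / vy))
            ix = int(round((cx - ox) / vx))
            oracle_seeds[iz, iy, ix] = c.id
        # add a background seed in a corner
        oracle_seeds[0, 0, 0] = max(c.id for c in snap.cells) + 1
        oracle = watershed_segment(
            wall, LabelImage(oracle_seeds, gt.voxel_size, gt.origin), params)
        m = match_labels(oracle, auto)
        assert (m["jaccard"] >= 0.99).mean() >= 0.99

    def test_no_seeds_rejected(self, rendered_sheet):
        _, img, gt = rendered_sheet
        empty = LabelImage(np.zeros_like(gt.labels), gt.voxel_size)
        with pytest.raises(ValueError):
            watershed_segment(img.channel("wall"), empty)

    def test_partition_property(self, rendered_sheet):
        _, img, _ = rendered_sheet
        labels, table = segment_stack(img)
        fg = labels.labels > 0
        assert table["voxel_count"].sum() == int(fg.sum())
        ratio = table["volume_um3"] / table["voxel_count"]
        np.testing.assert_allclose(ratio, labels.voxel_volume, rtol=1e-12)


class TestFilterAndMeasure:
    def _toy_labels(self):
        arr = np.zeros((4, 6, 6), np.int32)
        arr[1, 0, 0] = 1                      # 1 voxel
        arr[1:3, 1:4, 1:4] = 2                # 18 voxels
        arr[1:4, 4:6, 0:4] = 3                # 24 voxels
        return LabelImage(arr, (1.0, 1.0, 1.0))

    def test_volume_window(self):
        out = filter_labels(self._toy_labels(),
                            SegmentationParams(min_volume=10, max_volume=20))
        assert list(np.unique(out.labels)) == [0, 1]
        assert (out.labels == 1).sum() == 18

    def test_identity_when_all_pass(self):
        lab = self._toy_labels()
        out = filter_labels(lab, SegmentationParams(min_volume=0.5,
                                                    max_volume=1e9))
        np.testing.assert_array_equal(out.labels, lab.labels)

    def test_volume_formula(self):
        arr = np.zeros((10, 10, 10), np.int32)
        arr[:10, :10, :10] = 1
        lab = LabelImage(arr, (0.5, 0.5, 0.5))
        t = measure_cells(lab)
        assert t["volume_um3"].iloc[0] == pytest.approx(1000 * 0.125)
        single = np.zeros((3, 3, 3), np.int32)
        single[1, 1, 1] = 1
        t2 = measure_cells(LabelImage(single, (0.25, 0.25, 0.25)))
        assert t2["volume_um3"].iloc[0] == pytest.approx(0.015625)

    def test_empty_labels_empty_table(self):
        t = measure_cells(LabelImage(np.zeros((3, 3, 3), np.int32),
                                     (1., 1., 1.)))
        assert t.empty

    def test_volume_error_vs_polygon_truth(self, rendered_sheet):
        snap, img, gt = rendered_sheet
        labels, table = segment_stack(img)
        m = match_labels(gt, labels).merge(table, left_on="pred_id",
                                           right_on="cell_id")
        truth = {c.id: c.volume for c in snap.cells}
        err = [abs(r.volume_um3 - truth[r.truth_id]) / truth[r.truth_id]
               for r in m.itertuples()]
        assert np.median(err) <= 0.05


class TestEdU:
    def test_zero_channel_all_negative(self, rendered_sheet):
        _, img, gt = rendered_sheet
        zero = VoxelImage(np.zeros_like(gt.labels, np.float32),
                          gt.voxel_size, origin=gt.origin)
        t = classify_edu(gt, zero)
        assert not t["edu"].any()

    @pytest.mark.parametrize("noise", [0.0, 0.2])
    def test_flag_accuracy(self, rendered_sheet, noise):
        snap, _, _ = rendered_sheet
        truth = {c.id: c.edu_positive for c in snap.cells}
        accs = []
        seeds = [0] if noise == 0 else range(5)
        for k in seeds:
            p = RenderParams(noise_model="gaussian" if noise else "none",
                             noise_scale=noise, rng_seed=k)
            img, gt = render_stack(snap, p)
            sp = SegmentationParams(edu_threshold_method="fixed",
                                    edu_fixed_threshold=0.5)
            labels, table = segment_stack(img, sp)
            m = match_labels(gt, labels).merge(table, left_on="pred_id",
                                               right_on="cell_id")
            accs.append(np.mean([truth[r.truth_id] == r.edu
                                 for r in m.itertuples()]))
        target = 1.0 if noise == 0 else 0.95
        assert np.mean(accs) >= target


def test_recovery_nonincreasing_with_noise(small_sheet):
    """Cell-recovery rate (Jaccard >= 0.5 one-to-one) does not improve as
    rendering noise grows."""
    rates = []
    for noise in (0.0, 0.15, 0.3, 0.45):
        p = RenderParams(noise_model="gaussian", noise_scale=noise,
                         rng_seed=1, psf_sigma=0.3)
        img, gt = render_stack(small_sheet, p)
        try:
            labels, _ = segment_stack(img)
            m = match_labels(gt, labels)
            rates.append(float((m["jaccard"] >= 0.5).mean()))
        except NoSeedsError:
            rates.append(0.0)
    assert all(a >= b - 0.02 for a, b in zip(rates, rates[1:]))
    assert rates[0] == 1.0
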