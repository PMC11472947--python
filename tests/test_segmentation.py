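from collections import deque

import numpy as np
import pytest

from vascprint import (
    BinaryMask,
    EmptyMaskError,
    OrganConfig,
    VoxelVolume,
    close_mask,
    denoise,
    keep_largest_component,
    mask_volume,
    remove_speckles,
    threshold_adaptive,
    threshold_range,
    total_volume_pipeline,
    vessel_pipeline,
)
from vascprint.segmentation import ball_structure

from conftest import random_blob_mask


def flood_label(data, connectivity):
    """Pure-Python BFS connected-component labelling (test oracle)."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                order = abs(dz) + abs(dy) + abs(dx)
                if order == 0:
                    continue
                if (connectivity == 6 and order > 1) or \
                   (connectivity == 18 and order > 2):
                    continue
                offsets.append((dz, dy, dx))
    labels = np.zeros(data.shape, dtype=int)
    current = 0
    for idx in np.argwhere(data):
        if labels[tuple(idx)]:
            continue
        current += 1
        queue = deque([tuple(idx)])
        labels[tuple(idx)] = current
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= n[i] < data.shape[i] for i in range(3)) \
                        and data[n] and not labels[n]:
                    labels[n] = current
                    queue.append(n)
    return labels, current


class TestThresholdRange:
    def test_inclusive_at_both_ends(self):
        vol = VoxelVolume(np.array([[[49, 50, 255]]], dtype=np.uint8)
                          .reshape(1, 1, 3), 5.0)
        mask = threshold_range(vol, 50, 255)
        np.testing.assert_array_equal(mask.data.ravel(), [False, True, True])

    def test_full_range_selects_everything(self, small_volume):
        assert threshold_range(small_volume, 0, 255).data.all()

    def test_matches_per_voxel_scan(self, rng):
        vol = VoxelVolume(rng.integers(0, 256, size=(4, 4, 4)), 5.0)
        mask = threshold_range(vol, 80, 180)
        expected = np.array(
            [[[80 <= vol.data[z, y, x] <= 180 for x in range(4)]
              for y in range(4)] for z in range(4)]
        )
        np.testing.assert_array_equal(mask.data, expected)

    def test_inverted_range_raises(self, small_volume):
        with pytest.raises(ValueError):
            threshold_range(small_volume, 200, 100)


class TestKeepLargestComponent:
    def test_keeps_bigger_of_two(self):
        data = np.zeros((5, 5, 10), dtype=bool)
        data[1:3, 1:3, 1:4] = True   # 12 voxels
        data[4, 4, 7:10] = True      # 3 voxels
        out = keep_largest_component(BinaryMask(data, 5.0))
        assert out.count() == 12
        assert not out.data[4, 4, 7]

    def test_idempotent_on_single_component(self, rng):
        mask = random_blob_mask(rng, (10, 10, 10), fill=0.5)
        once = keep_largest_component(mask)
        twice = keep_largest_component(once)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_tie_broken_by_scan_order(self):
        data = np.zeros((4, 4, 10), dtype=bool)
        data[0, 0, 5:10] = True   # 5 voxels, first in scan order
        data[3, 3, 0:5] = True    # 5 voxels, later
        out = keep_largest_component(BinaryMask(data, 5.0))
        assert out.data[0, 0, 5] and not out.data[3, 3, 0]

    def test_exactly_one_component_remains(self, rng):
        for _ in range(5):
            mask = random_blob_mask(rng, (12, 12, 12), smooth=1.0, fill=0.3)
            out = keep_largest_component(mask)
            _, n = flood_label(out.data, 26)
            assert n == 1

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            keep_largest_component(BinaryMask(np.zeros((3, 3, 3), bool), 5.0))


class TestRemoveSpeckles:
    def test_white_removes_small_keeps_large(self):
        data = np.zeros((4, 6, 6), dtype=bool)
        data[1, 1:4, 1] = True          # 3-voxel island
        data[2:4, 1:3, 3:5] = True      # 8-voxel island
        out = remove_speckles(BinaryMask(data, 5.0), "white", 5)
        assert out.count() == 8

    def test_black_fills_interior_hole_not_exterior(self):
        data = np.ones((5, 5, 5), dtype=bool)
        data[2, 2, 2] = False           # 1-voxel interior hole
        data[:, :, 0] = False           # background slab touching border
        out = remove_speckles(BinaryMask(data, 5.0), "black", 5)
        assert out.data[2, 2, 2]
        assert not out.data[0, 0, 0]

    @pytest.mark.parametrize("phase,conn", [("white", 26), ("black", 6)])
    def test_matches_bruteforce_label_and_filter(self, rng, phase, conn):
        for _ in range(3):
            mask = BinaryMask(rng.random((16, 16, 16)) < 0.35, 5.0)
            out = remove_speckles(mask, phase, 4)
            if phase == "white":
                labels, n = flood_label(mask.data, conn)
                expected = np.zeros_like(mask.data)
                for lab in range(1, n + 1):
                    comp = labels == lab
                    if comp.sum() >= 4:
                        expected |= comp
            else:
                labels, n = flood_label(~mask.data, conn)
                expected = mask.data.copy()
                for lab in range(1, n + 1):
                    comp = labels == lab
                    touches = (comp[0].any() or comp[-1].any()
                               or comp[:, 0].any() or comp[:, -1].any()
                               or comp[:, :, 0].any() or comp[:, :, -1].any())
                    if comp.sum() < 4 and not touches:
                        expected |= comp
            np.testing.assert_array_equal(out.data, expected)

    def test_empty_mask_passes_through(self):
        mask = BinaryMask(np.zeros((3, 3, 3), bool), 5.0)
        assert remove_speckles(mask, "white", 10).count() == 0


class TestCloseMask:
    def test_radius_zero_is_identity(self, rng):
        mask = random_blob_mask(rng, (8, 8, 8))
        np.testing.assert_array_equal(close_mask(mask, 0).data, mask.data)

    def test_fills_one_voxel_gap_between_slabs(self):
        data = np.zeros((7, 7, 7), dtype=bool)
        data[:, :, 2] = True
        data[:, :, 4] = True
        out = close_mask(BinaryMask(data, 5.0), 1)
        # the gap is bridged in the slab interior (border voxels of the gap
        # plane are legitimately outside the closing in unbounded background)
        assert out.data[1:-1, 1:-1, 3].all()
        assert (out.data >= data).all()

    def test_matches_bruteforce_dilate_erode(self):
        # brute-force closing in an unbounded background on a small grid
        rng = np.random.default_rng(5)
        data = rng.random((6, 6, 6)) < 0.3
        r = 1
        ball = np.argwhere(ball_structure(r)) - r
        pad = 2 * r
        big = np.pad(data, pad)
        dil = np.zeros_like(big)
        for idx in np.argwhere(big):
            for off in ball:
                dil[tuple(idx + off)] = True
        # dilated set stays >= r away from the pad border, so the erosion
        # never indexes outside the padded array
        ero = np.zeros_like(big)
        for idx in np.argwhere(dil):
            if all(dil[tuple(idx + off)] for off in ball):
                ero[tuple(idx)] = True
        expected = ero[pad:-pad, pad:-pad, pad:-pad]
        out = close_mask(BinaryMask(data, 5.0), r)
        np.testing.assert_array_equal(out.data, expected)

    def test_all_true_stays_all_true(self):
        mask = BinaryMask(np.ones((5, 5, 5), bool), 5.0)
        assert close_mask(mask, 2).data.all()

    def test_extensive_even_at_borders(self, rng):
        for _ in range(5):
            mask = random_blob_mask(rng, (9, 9, 9), fill=0.4)
            out = close_mask(mask, 2)
            assert (out.data | mask.data == out.data).all()


class TestMaskVolume:
    def test_voxel_count_arithmetic(self):
        data = np.zeros((10, 10, 10), dtype=bool)
        data.ravel()[:1000] = True
        assert mask_volume(BinaryMask(data, 5.0)) == pytest.approx(1.25e-4)

    def test_empty_mask_is_zero(self):
        assert mask_volume(BinaryMask(np.zeros((3, 3, 3), bool), 5.0)) == 0.0

    def test_additivity_on_disjoint_masks(self, rng):
        a = rng.random((6, 6, 6)) < 0.3
        b = (rng.random((6, 6, 6)) < 0.3) & ~a
        va = mask_volume(BinaryMask(a, 5.0))
        vb = mask_volume(BinaryMask(b, 5.0))
        vu = mask_volume(BinaryMask(a | b, 5.0))
        assert vu == pytest.approx(va + vb)


class TestDenoise:
    def test_none_is_identity(self, small_volume):
        np.testing.assert_array_equal(
            denoise(small_volume, "none", 0).data, small_volume.data)

    @pytest.mark.parametrize("kind,size", [("gaussian", 1.0), ("median", 1)])
    def test_constant_volume_unchanged(self, kind, size):
        vol = VoxelVolume(np.full((6, 6, 6), 80, dtype=np.uint8), 5.0)
        np.testing.assert_array_equal(denoise(vol, kind, size).data, vol.data)

    def test_median_suppresses_hot_voxel(self):
        data = np.full((5, 5, 5), 10, dtype=np.uint8)
        data[2, 2, 2] = 250
        out = denoise(VoxelVolume(data, 5.0), "median", 1)
        # brute-force 3^3 windowed median at the hot voxel
        window = np.sort(data[1:4, 1:4, 1:4].ravel())
        assert out.data[2, 2, 2] == window[len(window) // 2]

    def test_invalid_size_raises(self, small_volume):
        with pytest.raises(ValueError):
            denoise(small_volume, "gaussian", 0)


class TestThresholdAdaptive:
    def test_constant_volume_offset_sign(self):
        vol = VoxelVolume(np.full((6, 6, 6), 100.0), 5.0)
        assert not threshold_adaptive(vol, 2, 1.0).data.any()
        assert threshold_adaptive(vol, 2, 0.0).data.all()
        assert threshold_adaptive(vol, 2, -1.0).data.all()

    def test_recovers_tube_on_ramp_that_defeats_global(self):
        # background ramps 0..200 along x; tube sits at +60 above local
        # background, so no single global cut separates it everywhere
        shape = (9, 9, 60)
        ramp = np.broadcast_to(
            np.linspace(0, 200, shape[2]), shape).astype(float).copy()
        tube = np.zeros(shape, dtype=bool)
        tube[4, 4, :] = True
        vol = VoxelVolume(ramp + 60.0 * tube, 5.0)
        lows = vol.data[tube].min()      # faint end of the tube
        bright_bg = vol.data[~tube].max()
        assert bright_bg > lows          # global threshold must fail
        mask = threshold_adaptive(vol, 2, 20.0)
        assert mask.data[tube].all()
        assert mask.data[~tube].mean() < 0.05

    def test_matches_bruteforce_windowed_mean(self, rng):
        vol = VoxelVolume(rng.random((8, 8, 8)) * 100, 5.0)
        radius, offset = 2, 5.0
        out = threshold_adaptive(vol, radius, offset)
        expected = np.zeros(vol.shape, dtype=bool)
        for z in range(8):
            for y in range(8):
                for x in range(8):
                    win = vol.data[max(z - radius, 0):z + radius + 1,
                                   max(y - radius, 0):y + radius + 1,
                                   max(x - radius, 0):x + radius + 1]
                    expected[z, y, x] = vol.data[z, y, x] >= win.mean() + offset
        np.testing.assert_array_equal(out.data, expected)


def _ball_phantom_volume(shape=(24, 24, 24), radius=9):
    zz, yy, xx = np.indices(shape)
    c = (np.array(shape) - 1) / 2
    ball = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= radius**2
    return ball


def _simple_cfg(**kw):
    base = dict(
        organ_name="test", total_threshold=(50, 255),
        vessel_threshold_mode=("global", 150, 255),
        black_speckle_min_voxels=10, white_speckle_min_voxels=0,
        closing_radius_voxels=1,
    )
    base.update(kw)
    return OrganConfig(**base)


class TestPipelines:
    def test_total_pipeline_fills_pores_and_drops_debris(self):
        ball = _ball_phantom_volume()
        data = np.where(ball, 120, 0).astype(np.uint8)
        data[12, 12, 12] = 0            # interior pore (1 voxel)
        data[1, 1, 1] = 200             # detached debris blob
        vol = VoxelVolume(data, 5.0)
        mask, volume = total_volume_pipeline(vol, _simple_cfg())
        assert mask.data[12, 12, 12]    # pore filled
        assert not mask.data[1, 1, 1]   # debris swept
        filled = ball.copy()
        assert volume == pytest.approx(
            mask_volume(BinaryMask(filled, 5.0)), rel=0.05)

    def test_all_background_raises(self):
        vol = VoxelVolume(np.zeros((6, 6, 6), np.uint8), 5.0)
        with pytest.raises(EmptyMaskError):
            total_volume_pipeline(vol, _simple_cfg())

    def test_composites_equal_explicit_chaining(self, rng):
        vol = VoxelVolume(rng.integers(0, 256, (16, 16, 16)), 5.0)
        cfg = _simple_cfg(black_speckle_min_voxels=3, closing_radius_voxels=1,
                          white_speckle_min_voxels=2, filter_kind="median",
                          filter_size=1)
        organ, _ = total_volume_pipeline(vol, cfg)
        manual = threshold_range(vol, 50, 255)
        manual = keep_largest_component(manual)
        manual = remove_speckles(manual, "black", 3)
        manual = close_mask(manual, 1)
        np.testing.assert_array_equal(organ.data, manual.data)

        vessels, _ = vessel_pipeline(vol, organ, cfg)
        vm = denoise(vol, "median", 1)
        vm = threshold_range(vm, 150, 255)
        vm = BinaryMask(vm.data & organ.data, 5.0)
        vm = remove_speckles(vm, "white", 2)
        vm = close_mask(vm, 1)
        vm = BinaryMask(vm.data & organ.data, 5.0)
        np.testing.assert_array_equal(vessels.data, vm.data)

    def test_vessels_subset_of_organ_and_artifact_excluded(self):
        ball = _ball_phantom_volume()
        data = np.where(ball, 100, 0).astype(np.uint8)
        data[12, 12, 8:17] = 200        # vessel inside organ
        data[0, :, :] = 220             # bright foil outside the organ
        vol = VoxelVolume(data, 5.0)
        cfg = _simple_cfg(closing_radius_voxels=0, black_speckle_min_voxels=0)
        organ, vo = total_volume_pipeline(vol, cfg)
        vessels, vv = vessel_pipeline(vol, organ, cfg)
        assert not (vessels.data & ~organ.data).any()
        assert not vessels.data[0].any()
        assert vv <= vo

    def test_noise_free_tube_recovers_ground_truth_volume(self):
        ball = _ball_phantom_volume()
        tube = np.zeros_like(ball)
        tube[10:14, 10:14, 4:20] = True
        tube &= ball
        data = np.where(ball, 100, 0).astype(np.uint8)
        data[tube] = 200
        vol = VoxelVolume(data, 5.0)
        cfg = _simple_cfg(closing_radius_voxels=0, black_speckle_min_voxels=0)
        organ, _ = total_volume_pipeline(vol, cfg)
        vessels, vv = vessel_pipeline(vol, organ, cfg)
        assert vv == pytest.approx(mask_volume(BinaryMask(tube, 5.0)))

    def test_empty_vessel_mask_warns_not_raises(self):
        ball = _ball_phantom_volume()
        vol = VoxelVolume(np.where(ball, 100, 0).astype(np.uint8), 5.0)
        cfg = _simple_cfg(closing_radius_voxels=0, black_speckle_min_voxels=0)
        organ, _ = total_volume_pipeline(vol, cfg)
        with pytest.warns(UserWarning, match="empty"):
            vessels, vv = vessel_pipeline(vol, organ, cfg)
        assert vv == 0.0

    def test_grid_mismatch_raises(self, small_volume):
        organ = BinaryMask(np.ones((3, 3, 3), bool), 5.0)
        with pytest.raises(ValueError, match="mismatch"):
            vessel_pipeline(small_volume, organ, _simple_cfg())


class TestRotationInvariance:
    """Ball structuring elements and cubic windows are discretely isotropic,
    so mask operations commute with 90-degree axis rotations."""

    @pytest.mark.parametrize("op", [
        lambda m: close_mask(m, 2),
        lambda m: remove_speckles(m, "white", 4),
        lambda m: remove_speckles(m, "black", 4),
        lambda m: keep_largest_component(m),
    ])
    def test_op_commutes_with_rot90(self, rng, op):
        mask = random_blob_mask(rng, (10, 10, 10), fill=0.4)
        rotated = BinaryMask(np.rot90(mask.data, axes=(0, 2)).copy(), 5.0)
        a = op(rotated).data
        b = np.rot90(op(mask).data, axes=(0, 2))
        np.testing.assert_array_equal(a, b)
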