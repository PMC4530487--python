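"""Preprocessing chain: I/O round trips, downsampling, thresholding, crops."""

import numpy as np
import pytest
import SimpleITK as sitk
import tifffile

from bonefe.imageproc import (
    BoneMask,
    SpanCrop,
    VoxelImage,
    crop_to_span,
    downsample_to,
    largest_component,
    local_span_crop,
    read_volume,
    reorient,
    threshold_permille,
    write_volume,
)
from bonefe.phantoms import PhantomSpec, generate_femur_phantom


class TestVolumeIO:
    def test_mha_roundtrip_preserves_grid_and_spacing(self, tmp_path):
        rng = np.random.default_rng(0)
        img = VoxelImage(rng.random((10, 10, 10)), 25.0)
        path = tmp_path / "vol.mha"
        write_volume(img, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.grid, img.grid)
        assert back.voxel_size_um == pytest.approx(25.0)

    def test_nifti_roundtrip(self, tmp_path):
        img = VoxelImage(np.random.default_rng(1).random((6, 7, 8)), 50.0)
        path = tmp_path / "vol.nii.gz"
        write_volume(img, path)
        back = read_volume(path)
        np.testing.assert_allclose(back.grid, img.grid, rtol=1e-6)
        assert back.voxel_size_um == pytest.approx(50.0, rel=1e-5)

    def test_tiff_without_spacing_rejected(self, tmp_path):
        path = tmp_path / "stack.tif"
        tifffile.imwrite(path, np.zeros((4, 5, 6), dtype=np.uint16))
        with pytest.raises(ValueError, match="spacing_um"):
            read_volume(path)
        img = read_volume(path, spacing_um=25.0)
        assert img.voxel_size_um == 25.0
        assert img.data_range_max == 65535.0

    def test_anisotropic_volume_rejected(self, tmp_path):
        itk = sitk.GetImageFromArray(np.zeros((5, 5, 5), dtype=np.float32))
        itk.SetSpacing((0.025, 0.025, 0.05))
        path = str(tmp_path / "aniso.mha")
        sitk.WriteImage(itk, path)
        with pytest.raises(ValueError, match="[Aa]nisotropic"):
            read_volume(path)


class TestReorient:
    def test_identity(self):
        img = VoxelImage(np.random.default_rng(2).random((4, 5, 6)), 25.0)
        out = reorient(img)
        np.testing.assert_array_equal(out.grid, img.grid)

    def test_two_quarter_turns_equal_half_turn(self):
        img = VoxelImage(np.random.default_rng(3).random((4, 5, 5)), 25.0)
        quarter = ((0, 2, 1), (False, True, False))  # 90 deg about axis 0
        twice = reorient(reorient(img, quarter), quarter)
        half = ((0, 1, 2), (False, True, True))      # 180 deg about axis 0
        np.testing.assert_array_equal(twice.grid, reorient(img, half).grid)

    def test_small_rotation_and_back_within_interpolation_tolerance(self):
        from scipy import ndimage

        rng = np.random.default_rng(6)
        smooth = ndimage.gaussian_filter(rng.random((32, 32, 32)), sigma=4.0)
        smooth = (smooth - smooth.min()) / (smooth.max() - smooth.min())
        img = VoxelImage(smooth, 50.0)
        there = reorient(img, angles_deg=(10.0, 0.0, 0.0))
        back = reorient(there, angles_deg=(-10.0, 0.0, 0.0))
        interior = (slice(6, -6),) * 3
        err = np.abs(back.grid[interior] - img.grid[interior]).max()
        assert err <= 0.02 * img.data_range_max

    def test_invalid_permutation_rejected(self):
        img = VoxelImage(np.zeros((3, 3, 3)), 25.0)
        with pytest.raises(ValueError, match="permutation"):
            reorient(img, ((0, 0, 1), (False, False, False)))


class TestDownsample:
    def test_constant_volume_preserved(self):
        img = VoxelImage(np.full((4, 4, 4), 0.3), 25.0)
        out = downsample_to(img, 50.0)
        assert out.grid.shape == (2, 2, 2)
        np.testing.assert_allclose(out.grid, 0.3)
        assert out.voxel_size_um == 50.0

    def test_block_mean_of_arithmetic_sequence(self):
        c = 0.1
        img = VoxelImage(np.arange(8).reshape(2, 2, 2) * c, 25.0)
        out = downsample_to(img, 50.0)
        assert out.grid[0, 0, 0] == pytest.approx(3.5 * c)

    def test_total_intensity_conserved(self):
        rng = np.random.default_rng(4)
        img = VoxelImage(rng.random((6, 4, 8)), 25.0)
        out = downsample_to(img, 50.0)
        assert out.grid.sum() * 8 == pytest.approx(img.grid.sum())

    def test_non_integer_factor_rejected(self):
        img = VoxelImage(np.zeros((4, 4, 4)), 30.0)
        with pytest.raises(ValueError, match="integer multiple"):
            downsample_to(img, 50.0)


class TestThreshold:
    def test_16bit_cut_at_half_range(self):
        grid = np.array([[[16383, 16384, 32767]]], dtype=np.int16)
        img = VoxelImage(grid, 50.0, data_range_max=32767.0)
        mask = threshold_permille(img, 500)
        np.testing.assert_array_equal(mask.grid[0, 0], [False, True, True])

    def test_permille_bounds(self):
        img = VoxelImage(np.array([[[0.4, 1.0]]]), 50.0)
        with pytest.raises(ValueError):
            threshold_permille(img, 0)
        mask = threshold_permille(img, 1000)  # keeps only saturated voxels
        np.testing.assert_array_equal(mask.grid[0, 0], [False, True])

    @pytest.mark.parametrize("lo,hi", [(300, 500), (500, 700), (100, 999)])
    def test_raising_permille_never_adds_voxels(self, lo, hi):
        img = VoxelImage(np.random.default_rng(5).random((5, 5, 5)), 50.0)
        m_lo = threshold_permille(img, lo).grid
        m_hi = threshold_permille(img, hi).grid
        assert not np.any(m_hi & ~m_lo)

    def test_observed_reference_mode(self):
        img = VoxelImage(np.array([[[0.15, 0.4]]]), 50.0)
        assert threshold_permille(img, 500, reference="observed").grid.sum() == 1
        assert threshold_permille(img, 500, reference="range").grid.sum() == 0


class TestCrop:
    def test_roller_example_index_range(self):
        grid = np.zeros((240, 4, 4), dtype=bool)
        grid[:, 1:3, 1:3] = True
        mask = BoneMask(grid, 50.0)
        crop = SpanCrop((1.0, 11.0), margin_mm=0.5)
        out = crop_to_span(mask, crop)
        assert out.grid.shape[0] == 230 - 10

    def test_zero_margin_exact_span(self):
        grid = np.ones((100, 2, 2), dtype=bool)
        out = crop_to_span(BoneMask(grid, 50.0), SpanCrop((1.0, 4.0), margin_mm=0.0))
        assert out.grid.shape[0] == 80 - 20

    def test_idempotent(self):
        grid = np.ones((100, 2, 2), dtype=bool)
        crop = SpanCrop((0.5, 4.0), margin_mm=0.5)
        once = crop_to_span(BoneMask(grid, 50.0), crop)
        twice = crop_to_span(once, crop)
        np.testing.assert_array_equal(once.grid, twice.grid)

    def test_empty_crop_rejected(self):
        grid = np.zeros((100, 2, 2), dtype=bool)
        grid[:10] = True
        with pytest.raises(ValueError, match="empty"):
            crop_to_span(BoneMask(grid, 50.0), SpanCrop((2.0, 4.0), margin_mm=0.0))

    def test_local_span_crop_shifts_coordinates(self):
        grid = np.ones((240, 2, 2), dtype=bool)
        mask = BoneMask(grid, 50.0)
        crop = SpanCrop((1.0, 11.0), margin_mm=0.5)
        local = local_span_crop(mask, crop)
        assert local.roller_positions_mm == pytest.approx((0.5, 10.5))
        assert local.load_position_mm == pytest.approx(5.5)

    def test_invalid_spans_rejected(self):
        with pytest.raises(ValueError):
            SpanCrop((1.0, 1.0))
        with pytest.raises(ValueError):
            SpanCrop((1.0, 5.0), load_position_mm=6.0)
        with pytest.raises(ValueError):
            SpanCrop((1.0, 5.0), margin_mm=-0.1)


class TestLargestComponent:
    def test_connected_mask_unchanged(self):
        spec = PhantomSpec(length_mm=0.5, outer_radius_mm=0.8,
                           cortical_thickness_mm=0.3, voxel_size_um=50.0)
        mask = threshold_permille(generate_femur_phantom(spec))
        out = largest_component(mask)
        np.testing.assert_array_equal(out.grid, mask.grid)

    def test_isolated_speck_removed(self):
        grid = np.zeros((10, 10, 10), dtype=bool)
        grid[2:8, 2:8, 2:8] = True
        grid[0, 0, 0] = True
        out = largest_component(BoneMask(grid, 50.0))
        assert not out.grid[0, 0, 0]
        assert out.n_voxels == 6**3

    def test_tie_broken_by_lexicographic_seed(self):
        grid = np.zeros((10, 3, 3), dtype=bool)
        grid[0:2, 0, 0] = True   # component touching voxel (0,0,0)
        grid[5:7, 1, 1] = True   # equal-sized component later in scan order
        out = largest_component(BoneMask(grid, 50.0))
        assert out.grid[0, 0, 0] and not out.grid[5, 1, 1]
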