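import numpy as np
import pytest

from conftest import brute_force_gaussian_kernel, flood_fill_label
from osteoflow.uct_pipeline import (
    BinaryMask,
    FilterParams,
    VoxelVolume,
    cylinder_mask,
    density_to_grey,
    filter_components,
    gaussian_filter,
    grey_to_density,
    morphometry,
    segment,
    timelapse_bvtv,
)

VOX = 36e-6


def _vol(data, week=None):
    return VoxelVolume(np.asarray(data, dtype=float), VOX, week=week)


class TestGaussianFilter:
    def test_constant_volume_preserved(self):
        v = _vol(np.full((8, 8, 8), 123.4))
        out = gaussian_filter(v, 1.2, 1)
        assert np.allclose(out.data, 123.4, rtol=1e-12)

    def test_impulse_response_matches_brute_force_kernel(self):
        imp = np.zeros((9, 9, 9))
        imp[4, 4, 4] = 1.0
        out = gaussian_filter(_vol(imp), 1.2, 1).data
        kernel = brute_force_gaussian_kernel(1.2, 1)
        assert np.allclose(out[3:6, 3:6, 3:6], kernel, rtol=1e-12)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_support_zero_is_identity(self):
        rng = np.random.default_rng(0)
        v = _vol(rng.uniform(0, 300, (6, 6, 6)))
        assert np.array_equal(gaussian_filter(v, 1.2, 0).data, v.data)

    def test_non_integer_support_rejected(self):
        with pytest.raises(ValueError):
            gaussian_filter(_vol(np.zeros((4, 4, 4))), 1.2, 1.5)

    def test_commutes_with_affine_rescale(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 300, (8, 8, 8))
        a = gaussian_filter(_vol(2.0 * v), 1.2, 1).data
        b = 2.0 * gaussian_filter(_vol(v), 1.2, 1).data
        assert np.allclose(a, b, rtol=1e-12)


class TestSegment:
    def test_sub_threshold_volume_gives_empty_mask(self):
        assert segment(_vol(np.full((5, 5, 5), 50.0))).count() == 0

    def test_threshold_value_is_included(self):
        data = np.zeros((3, 3, 3))
        data[1, 1, 1] = 97.5
        assert segment(_vol(data)).count() == 1

    def test_known_blob_count(self):
        data = np.zeros((20, 20, 20))
        data[:10, :10, :10] = 200.0  # 1000 voxels
        assert segment(_vol(data)).count() == 1000

    def test_idempotent_on_binary_content(self):
        rng = np.random.default_rng(2)
        m = segment(_vol(rng.uniform(0, 300, (8, 8, 8))))
        recast = _vol(np.where(m.data, 200.0, 0.0))
        assert np.array_equal(segment(recast).data, m.data)


class TestGreyCalibration:
    def test_anchor_points(self):
        assert grey_to_density(12.7) == pytest.approx(97.5)
        assert grey_to_density(0.0) == 0.0
        assert grey_to_density(100.0) == pytest.approx(767.7, abs=0.05)

    def test_round_trip(self):
        assert density_to_grey(grey_to_density(33.3)) == pytest.approx(33.3, rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            grey_to_density(101.0)


class TestFilterComponents:
    def _line_blob(self, n):
        data = np.zeros((3, 3, n + 4), dtype=bool)
        data[1, 1, 2:2 + n] = True
        return BinaryMask(data, VOX)

    def test_strictly_smaller_removed_equal_kept(self):
        assert filter_components(self._line_blob(49), 50).count() == 0
        assert filter_components(self._line_blob(50), 50).count() == 50

    def test_corner_touching_voxels_connected_under_26(self):
        data = np.zeros((4, 4, 4), dtype=bool)
        data[0, 0, 0] = data[1, 1, 1] = True
        m = BinaryMask(data, VOX)
        assert filter_components(m, 2, connectivity=26).count() == 2
        assert filter_components(m, 2, connectivity=6).count() == 0

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(3)
        m = BinaryMask(rng.uniform(size=(16, 16, 16)) < 0.3, VOX)
        out = filter_components(m, 10)
        assert not (out.data & ~m.data).any()

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(4)
        for _ in range(20):
            mask = rng.uniform(size=(16, 16, 16)) < 0.25
            ours = filter_components(BinaryMask(mask, VOX), 5, connectivity).data
            labels = flood_fill_label(mask, connectivity)
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            oracle = (sizes >= 5)[labels] & mask
            assert np.array_equal(ours, oracle)


class TestMorphometry:
    def test_full_region_is_100_percent(self):
        tv = cylinder_mask((20, 20, 10), VOX, 0.3e-3)
        res = morphometry(tv, tv)
        assert res.bvtv == pytest.approx(100.0)

    def test_voxel_volume_arithmetic(self):
        data = np.zeros((20, 20, 10), dtype=bool)
        data.flat[:1000] = True
        tv = BinaryMask(np.ones_like(data), VOX)
        res = morphometry(BinaryMask(data, VOX), tv)
        assert res.bv == pytest.approx(1000 * 0.036**3)  # 0.046656 mm^3

    def test_one_percent_phantom(self):
        tv = cylinder_mask((32, 32, 16), VOX, 0.5e-3, 0.55e-3)
        n_tv = tv.count()
        n_fill = round(0.01 * n_tv)
        data = np.zeros(tv.data.shape, dtype=bool)
        idx = np.nonzero(tv.data)
        data[idx[0][:n_fill], idx[1][:n_fill], idx[2][:n_fill]] = True
        res = morphometry(BinaryMask(data, VOX), tv)
        assert res.bvtv == pytest.approx(1.0, abs=100.0 / n_tv)

    def test_monotone_under_mask_inclusion(self):
        rng = np.random.default_rng(5)
        tv = cylinder_mask((16, 16, 8), VOX, 0.25e-3)
        small = tv.data & (rng.uniform(size=tv.data.shape) < 0.2)
        big = small | (tv.data & (rng.uniform(size=tv.data.shape) < 0.2))
        bv_small = morphometry(BinaryMask(small, VOX), tv).bv
        bv_big = morphometry(BinaryMask(big, VOX), tv).bv
        assert bv_big >= bv_small

    def test_empty_tv_rejected(self):
        empty = BinaryMask(np.zeros((4, 4, 4), dtype=bool), VOX)
        with pytest.raises(ValueError):
            morphometry(empty, empty)


class TestTimelapse:
    def test_single_week_equals_direct_morphometry(self):
        rng = np.random.default_rng(6)
        vol = _vol(rng.uniform(0, 150, (16, 16, 8)), week=2)
        tv = cylinder_mask(vol.data.shape, VOX, 0.25e-3)
        table = timelapse_bvtv([vol], tv)
        from osteoflow.uct_pipeline import process_volume
        direct = morphometry(process_volume(vol), tv)
        assert len(table) == 1
        assert table.loc[0, "BVTV_percent"] == pytest.approx(direct.bvtv)
        assert table.loc[0, "week"] == 2

    def test_empty_series_rejected(self):
        tv = cylinder_mask((4, 4, 4), VOX, 0.05e-3)
        with pytest.raises(ValueError):
            timelapse_bvtv([], tv)

    def test_inconsistent_lattices_rejected(self):
        tv = cylinder_mask((8, 8, 4), VOX, 0.1e-3)
        v1 = _vol(np.zeros((8, 8, 4)))
        v2 = VoxelVolume(np.zeros((8, 8, 4)), voxel_size=50e-6)
        with pytest.raises(ValueError):
            timelapse_bvtv([v1, v2], tv)
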