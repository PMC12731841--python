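import numpy as np
import pytest

import histotex as hx


def series_from_curve(curve, baseline=(0,), shape=(2, 2, 2)):
    curve = np.asarray(curve, float)
    sig = np.broadcast_to(curve, (*shape, curve.size)).copy()
    times = np.arange(curve.size) * 60.0
    return hx.DCESeries(signal=sig, times=times, baseline_frames=baseline)


class TestPercentEnhancement:
    def test_simple_arithmetic(self):
        s = series_from_curve([100.0, 150.0])
        pe = hx.percent_enhancement(s)
        assert pe[0, 0, 0, 1] == pytest.approx(50.0)

    def test_flat_signal_zero_curve(self):
        s = series_from_curve([80.0, 80.0, 80.0])
        np.testing.assert_allclose(hx.percent_enhancement(s), 0.0)

    def test_multiframe_baseline_mean(self):
        s = series_from_curve([90.0, 110.0, 200.0], baseline=(0, 1))
        pe = hx.percent_enhancement(s)
        assert pe[0, 0, 0, 2] == pytest.approx(100.0)

    def test_zero_baseline_raises(self):
        s = series_from_curve([0.0, 10.0])
        with pytest.raises(ValueError):
            hx.percent_enhancement(s)


class TestAUC:
    def test_trapezoid_oracle(self):
        """Enhancement 0/40/60 at 0/60/120 s integrates to 4200."""
        s = series_from_curve([100.0, 100.0, 140.0, 160.0], baseline=(0,))
        auc = hx.auc_initial(s, injection_time=60.0, window=120.0)
        assert auc.auc[0, 0, 0] == pytest.approx(4200.0)

    def test_flat_signal_zero_auc(self):
        s = series_from_curve([50.0] * 5)
        auc = hx.auc_initial(s, injection_time=0.0)
        np.testing.assert_allclose(auc.auc, 0.0)

    def test_linearity_in_enhancement(self):
        base = np.array([100.0, 100.0, 120.0, 130.0])
        s1 = series_from_curve(base)
        s2 = series_from_curve(100.0 + 2 * (base - 100.0))
        a1 = hx.auc_initial(s1, 60.0).auc
        a2 = hx.auc_initial(s2, 60.0).auc
        np.testing.assert_allclose(a2, 2 * a1)

    def test_short_series_truncates_with_warning(self, caplog):
        s = series_from_curve([100.0, 120.0, 130.0])
        with caplog.at_level("WARNING", logger="histotex"):
            auc = hx.auc_initial(s, injection_time=0.0, window=500.0)
        assert "last frame" in caplog.text
        assert np.isfinite(auc.auc).all()

    def test_too_few_frames_raises(self):
        s = series_from_curve([100.0, 120.0])
        with pytest.raises(ValueError):
            hx.auc_initial(s, injection_time=60.0, window=30.0)


class TestNormalizeAUC:
    def test_division(self):
        amap = hx.AUCMap(auc=np.full((2, 2, 1), 4200.0))
        muscle = np.zeros((2, 2, 1), bool)
        muscle[0, 0, 0] = True
        amap.auc[0, 0, 0] = 2100.0
        out = hx.normalize_auc(amap, muscle)
        assert out.auc_norm[1, 1, 0] == pytest.approx(2.0)
        assert out.muscle_auc == pytest.approx(2100.0)

    def test_self_normalization_is_one(self):
        amap = hx.AUCMap(auc=np.full((3, 3, 2), 7.0))
        out = hx.normalize_auc(amap, np.ones((3, 3, 2), bool))
        np.testing.assert_allclose(out.auc_norm, 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        base = np.array([100.0, 100.0, 150.0, 170.0])
        sig = np.broadcast_to(base, (3, 3, 2, 4)) * \
            (1 + rng.random((3, 3, 2, 1)))
        muscle = np.zeros((3, 3, 2), bool)
        muscle[0, :, :] = True
        for c in (1.0, 3.7):
            s = hx.DCESeries(signal=c * sig, times=np.arange(4) * 60.0,
                             baseline_frames=(0,))
            out = hx.normalize_auc(hx.auc_initial(s, 60.0), muscle)
            if c == 1.0:
                ref = out.auc_norm
            else:
                np.testing.assert_allclose(out.auc_norm, ref, rtol=1e-12)

    def test_nonpositive_muscle_raises(self):
        amap = hx.AUCMap(auc=np.zeros((2, 2, 1)))
        with pytest.raises(ValueError):
            hx.normalize_auc(amap, np.ones((2, 2, 1), bool))


class TestMIP:
    def test_columnwise_max(self):
        vol = np.zeros((1, 1, 3))
        vol[0, 0] = [1.0, 5.0, 3.0]
        mip = hx.mip_transverse(hx.AUCMap(auc=vol))
        assert mip.values[0, 0] == 5.0

    def test_single_slice_identity(self, rng):
        vol = rng.random((4, 4, 1))
        mip = hx.mip_transverse(hx.AUCMap(auc=vol))
        np.testing.assert_array_equal(mip.values, vol[:, :, 0])

    def test_matches_elementwise_max_oracle(self, rng):
        vol = rng.random((4, 4, 3))
        mip = hx.mip_transverse(hx.AUCMap(auc=vol))
        expected = np.maximum(np.maximum(vol[:, :, 0], vol[:, :, 1]),
                              vol[:, :, 2])
        np.testing.assert_array_equal(mip.values, expected)


class TestExclusionMask:
    def test_nine_distinct_low_target(self):
        mip = hx.MIPImage(values=np.arange(1.0, 10.0).reshape(3, 3))
        res = hx.exclusion_mask(mip, np.ones((3, 3), bool), mode="low_target")
        assert set(mip.values[res.excluded]) == {7.0, 8.0, 9.0}
        assert res.treated_percent_floor == 66
        assert res.treated_fraction == pytest.approx(2 / 3)

    def test_nine_distinct_high_target(self):
        mip = hx.MIPImage(values=np.arange(1.0, 10.0).reshape(3, 3))
        res = hx.exclusion_mask(mip, np.ones((3, 3), bool), mode="high_target")
        assert set(mip.values[res.excluded]) == {1.0, 2.0, 3.0}
        assert res.treated_percent_floor == 66

    def test_modes_disjoint_for_distinct_values(self, rng):
        vals = rng.permutation(30).astype(float).reshape(5, 6)
        mip = hx.MIPImage(values=vals)
        foot = np.ones((5, 6), bool)
        low = hx.exclusion_mask(mip, foot, "low_target")
        high = hx.exclusion_mask(mip, foot, "high_target")
        assert not (low.excluded & high.excluded).any()

    def test_tie_break_stable_with_warning(self, caplog):
        mip = hx.MIPImage(values=np.ones((3, 3)))
        with caplog.at_level("WARNING", logger="histotex"):
            res = hx.exclusion_mask(mip, np.ones((3, 3), bool))
        assert "stable voxel order" in caplog.text
        # last third in flat order is excluded
        np.testing.assert_array_equal(
            res.excluded.ravel(),
            [False] * 6 + [True] * 3)

    def test_too_few_voxels_raises(self):
        mip = hx.MIPImage(values=np.ones((1, 2)))
        with pytest.raises(ValueError):
            hx.exclusion_mask(mip, np.ones((1, 2), bool))


class TestCellGrid:
    def test_fifteen_cells_per_axis(self):
        grid = hx.build_cell_grid(18.0, 1.2, voxel_spacing=0.6)
        assert grid.n_per_axis == 15

    def test_single_cell(self):
        grid = hx.build_cell_grid(6.0, 6.0, voxel_spacing=1.0)
        assert grid.n_per_axis == 1
        assert len(grid.cells) == 1

    def test_partition_of_in_region_voxels(self):
        grid = hx.build_cell_grid(18.0, 1.2, voxel_spacing=0.5)
        in_region = grid.cell_of_voxel >= 0
        # every in-region voxel belongs to exactly one cell index
        idx = grid.cell_of_voxel[in_region]
        assert idx.min() >= 0
        assert idx.max() < 15 * 15
        total = sum(c.n_voxels for c in grid.cells)
        assert total == int(in_region.sum())

    def test_any_voxel_rule_drops_cell(self):
        grid = hx.build_cell_grid(6.0, 2.0, voxel_spacing=1.0)
        shape = grid.cell_of_voxel.shape
        excluded = np.zeros(shape, bool)
        # exclude one voxel of the central cell
        center = tuple(s // 2 for s in shape)
        excluded[center] = True
        res = hx.ExclusionResult(excluded=excluded,
                                 treated=~excluded,
                                 n_tumor_voxels=int(np.prod(shape)),
                                 treated_fraction=1.0,
                                 treated_percent_floor=100)
        out = hx.apply_cell_exclusion(grid, res)
        dropped = [c for c in out.cells if not c.included]
        assert len(dropped) == 1
        assert grid.cell_of_voxel[center] == (dropped[0].index[0] * 3
                                              + dropped[0].index[1])

    def test_cell_level_never_exceeds_voxel_level(self, rng):
        series, auc_gt, p = hx.gen_dce_phantom(seed=5)
        amap = hx.auc_initial(series, p["injection_time"])
        mip = hx.mip_transverse(amap)
        foot = np.ones(mip.values.shape, bool)
        res = hx.exclusion_mask(mip, foot, "low_target")
        grid = hx.build_cell_grid(18.0, 1.2, voxel_spacing=0.75,
                                  grid_shape=mip.values.shape)
        grid = hx.apply_cell_exclusion(grid, res)
        in_region = grid.cell_of_voxel >= 0
        cell_frac = hx.cell_level_treated_fraction(grid, foot & in_region)
        vox_frac = res.treated[in_region].sum() / in_region.sum()
        assert cell_frac <= vox_frac + 1e-12

    def test_bad_sizes_raise(self):
        with pytest.raises(ValueError):
            hx.build_cell_grid(-1.0, 1.2)
        with pytest.raises(ValueError):
            hx.build_cell_grid(10.0, 20.0)
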