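"""CBT construction and overlap/distance metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from thalatrack.grid import centered_grid
from thalatrack.metrics import (
    ThresholdSpec,
    cog,
    cog_distance,
    dice,
    percentile_threshold,
    sweep,
)


def brute_force_cutoff(values, p):
    """Sorted-order linear-interpolation quantile (independent of numpy)."""
    v = sorted(values)
    h = (len(v) - 1) * p / 100.0
    lo = int(np.floor(h))
    if lo == len(v) - 1:
        return v[-1]
    return v[lo] + (h - lo) * (v[lo + 1] - v[lo])


@pytest.fixture(scope="module")
def grid10():
    return centered_grid((10, 1, 1), 2.0)


class TestPercentileThreshold:
    def test_values_one_to_ten_at_median(self, grid10):
        """Values {1..10}, p=50: cutoff 5.5, five voxels survive."""
        values = np.arange(1.0, 11.0).reshape(10, 1, 1)
        cbt = percentile_threshold(values, grid10, 50)
        assert cbt.cutoff == pytest.approx(5.5)
        assert cbt.n_voxels == 5
        assert np.array_equal(np.flatnonzero(cbt.mask[:, 0, 0]), np.arange(5, 10))

    def test_p100_keeps_only_maxima(self, grid10):
        values = np.array([1, 3, 7, 7, 2, 0, 0, 1, 7, 5], float).reshape(10, 1, 1)
        cbt = percentile_threshold(values, grid10, 100)
        assert set(np.flatnonzero(cbt.mask[:, 0, 0])) == {2, 3, 8}

    def test_positive_scaling_invariance(self, grid10):
        rng = np.random.default_rng(0)
        values = rng.random((10, 1, 1)) * (rng.random((10, 1, 1)) > 0.3)
        if not values.any():
            values[0] = 0.5
        for c in (1e-6, 0.37, 1.0, 1e4):
            a = percentile_threshold(values, grid10, 73)
            b = percentile_threshold(c * values, grid10, 73)
            assert np.array_equal(a.mask, b.mask)

    def test_all_zero_map_rejected(self, grid10):
        with pytest.raises(ValueError):
            percentile_threshold(np.zeros((10, 1, 1)), grid10, 60)

    def test_spec_bounds(self):
        with pytest.raises(ValueError):
            ThresholdSpec(45)
        with pytest.raises(ValueError):
            ThresholdSpec(101)

    @given(
        values=hnp.arrays(float, 30, elements=st.floats(0, 100)),
        p=st.integers(50, 100),
    )
    def test_matches_sorted_interpolation_oracle(self, values, p):
        grid = centered_grid((30, 1, 1), 1.0)
        positive = values[values > 0]
        if positive.size == 0:
            return
        cbt = percentile_threshold(values.reshape(30, 1, 1), grid, p)
        cutoff = brute_force_cutoff(positive, p)
        expected = {int(i) for i in np.flatnonzero(values >= cutoff * (1 - 1e-9))}
        got = {int(i) for i in np.flatnonzero(cbt.mask[:, 0, 0])}
        assert got == expected

    def test_nested_in_percentile(self, grid10):
        rng = np.random.default_rng(3)
        values = rng.random((10, 1, 1))
        prev = None
        for p in range(50, 101):
            cbt = percentile_threshold(values, grid10, p)
            if prev is not None:
                assert not (cbt.mask & ~prev).any()  # CBT(p2) subset CBT(p1)
            prev = cbt.mask


class TestDice:
    def test_identity_disjoint_and_half(self):
        grid = centered_grid((4, 4, 4), 1.0)
        x = np.zeros((4, 4, 4), bool)
        x[:2, :2, :2] = True  # 8 voxels
        assert dice(x, x) == 1.0
        y = np.zeros_like(x)
        y[2:, 2:, 2:] = True
        assert dice(x, y) == 0.0
        z = np.zeros_like(x)
        z[:2, :2, 1:3] = True  # 8 voxels, 4 shared with x
        assert dice(x, z) == pytest.approx(0.5)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a = rng.random((5, 5, 5)) > 0.6
            b = rng.random((5, 5, 5)) > 0.6
            if not (a.any() or b.any()):
                continue
            d1, d2 = dice(a, b), dice(b, a)
            assert d1 == d2
            assert 0.0 <= d1 <= 1.0
            assert (d1 == 1.0) == np.array_equal(a, b)

    def test_both_empty_rejected(self):
        e = np.zeros((3, 3, 3), bool)
        with pytest.raises(ValueError):
            dice(e, e)

    def test_grid_mismatch_rejected(self):
        from thalatrack.metrics import CBT, ThresholdSpec as TS

        g1, g2 = centered_grid((3, 3, 3), 1.0), centered_grid((3, 3, 3), 2.0)
        m = np.ones((3, 3, 3), bool)
        a = CBT(mask=m, grid=g1, threshold=TS(50), cutoff=1.0)
        b = CBT(mask=m, grid=g2, threshold=TS(50), cutoff=1.0)
        with pytest.raises(ValueError):
            dice(a, b)


class TestCog:
    def test_identical_binary_volumes(self):
        grid = centered_grid((6, 6, 6), 2.0)
        m = np.zeros((6, 6, 6), bool)
        m[2:4, 2:4, 2:4] = True
        assert cog_distance(m, m, grid) == pytest.approx(0.0)

    def test_single_voxels_five_apart_at_2mm(self):
        grid = centered_grid((8, 8, 8), 2.0)
        x = np.zeros((8, 8, 8))
        y = np.zeros((8, 8, 8))
        x[1, 4, 4] = 1.0
        y[6, 4, 4] = 1.0
        assert cog_distance(x, y, grid) == pytest.approx(10.0)

    def test_translation_bounded_by_triangle_inequality(self):
        grid = centered_grid((12, 12, 12), 1.0)
        rng = np.random.default_rng(8)
        x = np.zeros((12, 12, 12))
        x[3:6, 3:6, 3:6] = rng.random((3, 3, 3)) + 0.1
        y = rng.random((12, 12, 12)) > 0.8
        y[0, 0, 0] = True
        d0 = cog_distance(x, y, grid)
        x_shift = np.roll(x, 2, axis=0)  # translation by 2 voxels = 2 mm
        d1 = cog_distance(x_shift, y, grid)
        assert abs(d1 - d0) <= 2.0 + 1e-9

    def test_invariant_under_joint_rigid_translation(self):
        grid = centered_grid((12, 12, 12), 1.5)
        rng = np.random.default_rng(9)
        x = np.zeros((12, 12, 12))
        x[2:5, 2:5, 2:5] = rng.random((3, 3, 3)) + 0.1
        y = np.zeros((12, 12, 12), bool)
        y[6:9, 3:6, 2:4] = True
        d0 = cog_distance(x, y, grid)
        shift = (3, -2, 1)
        xs = np.roll(x, shift, axis=(0, 1, 2))
        ys = np.roll(y, shift, axis=(0, 1, 2))
        assert cog_distance(xs, ys, grid) == pytest.approx(d0, abs=1e-9)

    def test_weighted_vs_binary_centroid(self):
        grid = centered_grid((4, 1, 1), 1.0)
        w = np.array([3.0, 0, 0, 1.0]).reshape(4, 1, 1)
        c_w = cog(w, grid, weighted=True)
        c_b = cog(w, grid, weighted=False)
        assert c_w[0] < c_b[0]  # weight pulls toward the heavy voxel

    def test_empty_volume_rejected(self):
        grid = centered_grid((3, 3, 3), 1.0)
        with pytest.raises(ValueError):
            cog(np.zeros((3, 3, 3)), grid)


class TestSweep:
    def test_indicator_map_gives_unit_dice(self):
        grid = centered_grid((8, 8, 8), 2.0)
        atlas = np.zeros((8, 8, 8), bool)
        atlas[2:5, 2:5, 2:5] = True
        dice_curve, cog_curve, _ = sweep(atlas.astype(float), atlas, grid)
        assert np.all(dice_curve.values[np.isfinite(dice_curve.values)] == 1.0)
        assert np.allclose(cog_curve.values[np.isfinite(cog_curve.values)], 0.0)

    def test_voxel_count_non_increasing(self):
        grid = centered_grid((8, 8, 8), 2.0)
        rng = np.random.default_rng(11)
        values = rng.random((8, 8, 8)) * (rng.random((8, 8, 8)) > 0.4)
        atlas = rng.random((8, 8, 8)) > 0.7
        _, _, records = sweep(values, atlas, grid)
        counts = [r.vol_x for r in records if r.vol_x > 0]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_blob_offset_dice_maximum_matches_brute_force(self):
        """Gaussian blob vs an offset atlas blob: the sweep's Dice maximum
        location equals an exhaustive per-percentile recomputation."""
        grid = centered_grid((12, 12, 12), 2.0)
        coords = grid.coordinate_volume()
        blob = np.exp(-np.sum((coords - [2, 0, 0]) ** 2, -1) / 30.0)
        blob[blob < 0.05] = 0.0
        atlas = np.sum((coords - [6, 0, 0]) ** 2, -1) <= 36.0
        dice_curve, _, _ = sweep(blob, atlas, grid)
        # brute force at each integer percentile
        best_p, best_d = None, -1
        positive = blob[blob > 0]
        for p in range(50, 101):
            cutoff = brute_force_cutoff(positive, p)
            mask = blob >= cutoff - 1e-12
            inter = (mask & atlas).sum()
            d = 2 * inter / (mask.sum() + atlas.sum())
            if d > best_d:
                best_p, best_d = p, d
        i = np.nanargmax(dice_curve.values)
        assert dice_curve.percentiles[i] == best_p
        assert dice_curve.values[i] == pytest.approx(best_d)

    def test_out_of_range_grid_rejected(self):
        grid = centered_grid((4, 4, 4), 1.0)
        with pytest.raises(ValueError):
            sweep(np.ones((4, 4, 4)), np.ones((4, 4, 4), bool), grid,
                  percentiles=[40, 60])
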