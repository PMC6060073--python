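"""Line/pair morphology against brute-force and scipy oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from streamspot import morphology as M

from oracles import (brute_dilate, brute_erode, brute_open,
                     brute_pair_dilate, brute_pair_erode)


def random_rows(rng, n, W, hi=255):
    return rng.integers(0, hi + 1, size=(n, W), dtype=np.int64)


class TestLineOps:
    def test_constant_row_is_fixed_point(self):
        row = np.full(4, 5)
        for op in (M.erode_line, M.dilate_line, M.open_line):
            assert np.array_equal(op(row, M.line(3)), row)

    def test_plateau_removed_when_longer_se(self):
        # a bright plateau of width 7 vanishes under erosion with L=8
        row = np.zeros(31, dtype=np.int64)
        row[12:19] = 100
        assert np.array_equal(M.erode_line(row, M.line(8)), np.zeros(31))

    def test_dark_pit_filled_by_dilation(self):
        row = np.full(21, 100, dtype=np.int64)
        row[10] = 50
        assert np.array_equal(M.dilate_line(row, M.line(3)), np.full(21, 100))

    @pytest.mark.parametrize("L", [1, 2, 3, 5, 8, 15, 31, 40])
    def test_matches_bruteforce_and_scipy(self, rng, L):
        """Every operator equals the O(W*L) window scan on random rows;
        scipy's nearest-padded filters agree because clipped windows always
        contain their own edge pixel."""
        rows = random_rows(rng, 40, 32)
        for row in rows:
            er = M.erode_line(row, M.line(L))
            di = M.dilate_line(row, M.line(L))
            op = M.open_line(row, M.line(L))
            assert np.array_equal(er, brute_erode(row, L))
            assert np.array_equal(di, brute_dilate(row, L))
            assert np.array_equal(op, brute_open(row, L))
            # independent library oracle (window origin: scipy centres at
            # size//2, same anchor convention as ours)
            assert np.array_equal(
                er, minimum_filter1d(row, L, mode="nearest"))
            assert np.array_equal(
                di, maximum_filter1d(row, L, mode="nearest"))

    def test_thousand_random_rows_against_oracle(self, rng):
        rows = random_rows(rng, 1000, 32)
        for L in (5,):
            got = M.erode_line(rows, M.line(L))
            exp = minimum_filter1d(rows, L, axis=1, mode="nearest")
            assert np.array_equal(got, exp)
            got = M.dilate_line(rows, M.line(L))
            exp = maximum_filter1d(rows, L, axis=1, mode="nearest")
            assert np.array_equal(got, exp)

    def test_errors(self):
        with pytest.raises(ValueError):
            M.erode_line(np.array([]), M.line(3))
        with pytest.raises(ValueError):
            M.line(0)
        with pytest.raises(ValueError):
            M.erode_line(np.arange(4), M.pair())


@settings(max_examples=150, derandomize=True)
@given(st.lists(st.integers(0, 255), min_size=1, max_size=40),
       st.integers(1, 12))
def test_duality_ordering_idempotence(values, L):
    """dilate(f) == -erode(-f); erode <= id <= dilate; opening idempotent
    and anti-extensive — for every row and SE length, odd or even."""
    row = np.array(values, dtype=np.int64)
    se = M.line(L)
    er, di, op = M.erode_line(row, se), M.dilate_line(row, se), M.open_line(row, se)
    assert np.array_equal(di, -M.erode_line(-row, se))
    assert np.all(er <= row) and np.all(row <= di)
    assert np.all(op <= row)
    assert np.array_equal(M.open_line(op, se), op)


def test_plateau_truth_table_exhaustive():
    """A flat width-K plateau vanishes under line erosion iff L > K,
    checked for every K, L in 1..12."""
    for K in range(1, 13):
        for L in range(1, 13):
            W = K + 2 * (L + 2)
            row = np.zeros(W, dtype=np.int64)
            start = (W - K) // 2
            row[start:start + K] = 100
            eroded = M.erode_line(row, M.line(L))
            vanished = not eroded.any()
            assert vanished == (L > K), (K, L)


def test_tophat_retains_only_target_scale():
    """scene = target(width K) + interference(width K_l) on flat ground:
    with K < L < K_l the residue input - opening keeps the target only."""
    for K in range(2, 8):
        for K_l in range(K + 2, 16):
            for L in range(K + 1, K_l):
                W = K + K_l + 4 * L + 12
                row = np.zeros(W, dtype=np.int64)
                row[2 * L:2 * L + K] = 80                    # target
                row[W - K_l - 2:W - 2] = 50                   # interference
                tophat = row - M.open_line(row, M.line(L))
                expect = np.zeros(W, dtype=np.int64)
                expect[2 * L:2 * L + K] = 80
                assert np.array_equal(tophat, expect), (K, K_l, L)


def test_feature_scale_invariant():
    M.FeatureScale(K=5, K_s=1, K_l=20)
    with pytest.raises(ValueError):
        M.FeatureScale(K=5, K_s=6, K_l=20)


class TestPairOps:
    def test_isolated_pixel_removed_by_either_axis(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert not M.erode_pair(mask, M.IN_ROW).any()
        assert not M.erode_pair(mask, M.CROSS_ROW).any()

    def test_block_erosion_shapes(self):
        # 3x3 block -> 3x2 after in-row, then 2x2 after cross-row
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 1:4] = True
        he = M.erode_pair(mask, M.IN_ROW)
        assert he.sum() == 6 and he[1:4, 1:3].all()
        ve = M.erode_pair(he, M.CROSS_ROW)
        assert ve.sum() == 4 and ve[1:3, 1:3].all()

    def test_dilation_recovers_block(self):
        core = np.zeros((5, 5), dtype=bool)
        core[1:3, 1:3] = True
        out = M.dilate_pair(M.dilate_pair(core, M.CROSS_ROW), M.IN_ROW)
        expect = np.zeros((5, 5), dtype=bool)
        expect[1:4, 1:4] = True
        assert np.array_equal(out, expect)

    def test_trivial_masks(self):
        empty = np.zeros((3, 4), dtype=bool)
        full = np.ones((3, 4), dtype=bool)
        assert not M.dilate_pair(empty, M.IN_ROW).any()
        assert M.dilate_pair(full, M.CROSS_ROW).all()
        # all-set row pair unchanged by in-row erosion except last column
        pair_rows = np.ones((2, 6), dtype=bool)
        assert M.erode_pair(pair_rows, M.CROSS_ROW)[0].all() is not None
        assert np.array_equal(M.erode_pair(pair_rows, M.CROSS_ROW)[0],
                              np.ones(6, dtype=bool))

    @pytest.mark.parametrize("axis", [M.IN_ROW, M.CROSS_ROW])
    def test_random_masks_match_oracle(self, rng, axis):
        for _ in range(200):
            mask = rng.random((6, 9)) < 0.45
            assert np.array_equal(M.erode_pair(mask, axis),
                                  brute_pair_erode(mask, axis))
            assert np.array_equal(M.dilate_pair(mask, axis),
                                  brute_pair_dilate(mask, axis))

    def test_cross_row_requires_2d(self):
        with pytest.raises(ValueError):
            M.erode_pair(np.ones(4, dtype=bool), M.CROSS_ROW)
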