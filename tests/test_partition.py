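"""Longest-k-blocks DP, traceback, and minimum-block full segmentation."""

import numpy as np
import pytest

import hapblock as hb
from hapblock.errors import UncoverableColumnError

from conftest import random_complete_matrix, with_missing
import oracles


def one_hot_matrix(n: int) -> hb.HaplotypeMatrix:
    """n rows / n columns; interval [j,k] of width w has delta = w/n, so at
    D = 1.5/n only single columns are feasible."""
    return hb.HaplotypeMatrix(np.eye(n, dtype=np.int8))


class TestLongestKBlocks:
    def test_identical_rows_whole_range(self):
        mat = hb.from_strings(["0011"] * 5)
        tbl = hb.good_partner_table(mat, D=0.0, W=10)
        dp = hb.longest_k_blocks(tbl, 1)
        assert dp.optimum(1) == 4
        seg = hb.traceback(dp, tbl, 1)
        assert [(b.start, b.end) for b in seg.blocks] == [(1, 4)]

    def test_width_one_only_blocks(self):
        n = 8
        mat = one_hot_matrix(n)
        tbl = hb.good_partner_table(mat, D=1.5 / n, W=n)
        for k in (1, 3, 10):
            dp = hb.longest_k_blocks(tbl, k)
            assert dp.optimum(k) == min(k, n)

    def test_dp_grid_invariants(self):
        rng = np.random.default_rng(17)
        mat = random_complete_matrix(rng, 10, 16)
        tbl = hb.good_partner_table(mat, D=0.2, W=16)
        dp = hb.longest_k_blocks(tbl, 5)
        f = dp.f
        assert (np.diff(f, axis=0) >= 0).all()  # non-decreasing in k
        assert (np.diff(f, axis=1) >= 0).all()  # non-decreasing in j
        assert (f <= np.arange(f.shape[1])).all()  # f(k, j) <= j
        assert (f[0] == 0).all() and (f[:, 0] == 0).all()
        # concave-like in k: increments non-increasing
        inc = np.diff(f[:, -1])
        assert (np.diff(inc) <= 0).all()

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("D", [0.0, 0.2, 0.5])
    def test_matches_all_blocks_recursion_oracle(self, seed, D):
        rng = np.random.default_rng(1000 + seed)
        m, n = int(rng.integers(4, 13)), int(rng.integers(6, 21))
        mat = random_complete_matrix(rng, m, n)
        tbl = hb.good_partner_table(mat, D=D, W=n)
        dp = hb.longest_k_blocks(tbl, 3)
        for k in (1, 2, 3):
            assert dp.optimum(k) == oracles.longest_k_oracle(mat, D, n, k)

    @pytest.mark.parametrize("seed", range(4))
    def test_oracle_agrees_with_literal_enumeration_tiny(self, seed):
        """The recursion oracle itself equals literal subset enumeration."""
        rng = np.random.default_rng(50 + seed)
        mat = random_complete_matrix(rng, 5, 9)
        for D in (0.2, 0.5):
            for k in (1, 2, 3):
                assert oracles.longest_k_oracle(mat, D, 9, k) == (
                    oracles.longest_k_enumeration(mat, D, 9, k)
                )


class TestTraceback:
    def test_excess_budget_returns_fewer_blocks(self):
        mat = hb.from_strings(["0101"] * 4)
        tbl = hb.good_partner_table(mat, D=0.0, W=10)
        dp = hb.longest_k_blocks(tbl, 5)
        seg = hb.traceback(dp, tbl, 5)
        assert seg.k_used == 1 and seg.total_length == 4

    @pytest.mark.parametrize("seed", range(8))
    def test_blocks_feasible_disjoint_and_optimal(self, seed):
        rng = np.random.default_rng(2000 + seed)
        mat = random_complete_matrix(rng, 8, 15)
        D, W = 0.2, 15
        tbl = hb.good_partner_table(mat, D=D, W=W)
        for k in (1, 2, 3):
            seg = hb.traceback(hb.longest_k_blocks(tbl, k), tbl, k)
            seg.validate()
            assert seg.k_used <= k
            for b in seg.blocks:  # post-hoc re-verification
                assert b.width <= W
                assert hb.diversity(mat, b.start, b.end) <= D + 1e-12
            assert seg.total_length == oracles.longest_k_oracle(mat, D, W, k)


class TestMinBlocksFullCover:
    def test_identical_rows_single_block(self):
        mat = hb.from_strings(["111"] * 4)
        tbl = hb.good_partner_table(mat, D=0.0, W=10)
        seg = hb.min_blocks_full_cover(tbl)
        assert [(b.start, b.end) for b in seg.blocks] == [(1, 3)]

    def test_width_one_only_gives_n_blocks(self):
        n = 7
        mat = one_hot_matrix(n)
        tbl = hb.good_partner_table(mat, D=1.5 / n, W=n)
        seg = hb.min_blocks_full_cover(tbl)
        assert seg.k_used == n
        assert seg.total_length == n

    def test_uncoverable_column_raises_with_column(self):
        mat = hb.from_strings(["00", "01"])  # column 2 has delta = 1
        tbl = hb.good_partner_table(mat, D=0.2, W=2)
        with pytest.raises(UncoverableColumnError) as err:
            hb.min_blocks_full_cover(tbl)
        assert err.value.column == 2

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("D", [0.2, 0.5])
    def test_matches_brute_force_minimum(self, seed, D):
        rng = np.random.default_rng(3000 + seed)
        m, n = int(rng.integers(4, 13)), int(rng.integers(6, 26))
        mat = random_complete_matrix(rng, m, n)
        tbl = hb.good_partner_table(mat, D=D, W=n)
        expected = oracles.min_blocks_oracle(mat, D, n)
        if expected is None:
            with pytest.raises(UncoverableColumnError):
                hb.min_blocks_full_cover(tbl)
            return
        seg = hb.min_blocks_full_cover(tbl)
        assert seg.k_used == expected
        assert seg.total_length == n
        for b in seg.blocks:
            assert hb.diversity(mat, b.start, b.end) <= D + 1e-12

    @pytest.mark.parametrize("seed", range(4))
    def test_missing_data_uses_explicit_feasibility(self, seed):
        """With missing data the feasible-start sets may be non-contiguous;
        the full-cover DP must still match the brute-force minimum."""
        rng = np.random.default_rng(4000 + seed)
        mat = with_missing(random_complete_matrix(rng, 8, 12), rng, 0.15)
        D = 0.25
        tbl = hb.good_partner_table(mat, D=D, W=12)

        def delta(m_, j, k):
            return hb.diversity(m_, j, k)

        expected = oracles.min_blocks_oracle(mat, D, 12, delta=delta)
        if expected is None:
            with pytest.raises(UncoverableColumnError):
                hb.min_blocks_full_cover(tbl)
        else:
            assert hb.min_blocks_full_cover(tbl).k_used == expected
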