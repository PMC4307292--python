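"""Interval classification, δ, and the good-partner table."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hapblock as hb
from hapblock.diversity import score_starts, table_from_scores

from conftest import FIG_SAMPLE, random_complete_matrix, with_missing
import oracles


class TestClassifyRows:
    def test_worked_sample_counts(self, fig_sample_matrix):
        """Six distinct strings, two duplicated: 4 common in 2 classes,
        4 singletons, delta = 4/8."""
        s = hb.classify_rows(fig_sample_matrix.interval(1, 5))
        assert (s.U, s.C, s.S, s.ambiguous) == (8, 4, 4, 0)
        assert s.delta == pytest.approx(0.5)

    def test_identical_rows_all_common(self):
        mat = hb.from_strings(["0110"] * 7)
        s = hb.classify_rows(mat.interval(1, 4))
        assert (s.U, s.C, s.S, s.delta) == (7, 7, 0, 0.0)

    def test_missing_row_compatible_with_conflicting_pair_is_ambiguous(self):
        mat = hb.from_strings(["10", "11", "1?"])
        s = hb.classify_rows(mat.interval(1, 2))
        assert s.ambiguous == 1
        assert (s.U, s.C, s.S) == (2, 0, 2)
        assert s.delta == 1.0

    def test_all_rows_ambiguous_delta_defined_zero(self):
        # every complete row conflicts with the other; the ?? rows are
        # compatible with both -> ambiguous; the complete rows stay singleton
        mat = hb.from_strings(["??", "??", "01", "10"])
        s = hb.classify_rows(mat.interval(1, 2))
        assert s.ambiguous == 2 and s.U == 2
        mat2 = hb.from_strings(["??", "0?", "?1"])  # pairwise compatible
        s2 = hb.classify_rows(mat2.interval(1, 2))
        assert s2.delta == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_conservation_with_missing(self, seed):
        """ambiguous + C + S = m on every interval, 10% missing calls."""
        rng = np.random.default_rng(seed)
        mat = with_missing(random_complete_matrix(rng, 9, 10), rng, 0.10)
        for j in range(1, 11):
            for k in range(j, 11):
                s = hb.classify_rows(mat.interval(j, k))
                assert s.ambiguous + s.C + s.S == mat.m
                assert s.U == s.C + s.S
                assert 0.0 <= s.delta <= 1.0
        # counts must also match the loop-based definitional classifier
        full = hb.classify_rows(mat.interval(1, mat.n))
        sub = mat.interval(1, mat.n).submatrix()
        assert (full.U, full.C, full.S, full.ambiguous) == oracles.classify_oracle(sub)


class TestDiversity:
    def test_worked_sample(self, fig_sample_matrix):
        assert hb.diversity(fig_sample_matrix, 1, 5) == pytest.approx(4 / 8)

    def test_single_column_all_matched(self):
        mat = hb.from_strings(["0", "0", "1", "1", "0"])
        assert hb.diversity(mat, 1, 1) == 0.0

    def test_out_of_range_interval_rejected(self, fig_sample_matrix):
        with pytest.raises(IndexError):
            hb.diversity(fig_sample_matrix, 0, 3)
        with pytest.raises(IndexError):
            hb.diversity(fig_sample_matrix, 3, 6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_substring_grouping_oracle(self, seed):
        """All 36 intervals of a seeded complete 10x8 matrix."""
        rng = np.random.default_rng(100 + seed)
        mat = random_complete_matrix(rng, 10, 8)
        for j in range(1, 9):
            for k in range(j, 9):
                assert hb.diversity(mat, j, k) == pytest.approx(
                    oracles.delta_oracle(mat, j, k)
                )

    @pytest.mark.parametrize("seed", range(6))
    def test_monotone_on_complete_data(self, seed):
        """delta(j', k') <= delta(j, k) for every nested interval pair."""
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(6, 13))
        mat = random_complete_matrix(rng, int(rng.integers(4, 12)), n)
        d = {
            (j, k): hb.diversity(mat, j, k)
            for j in range(1, n + 1)
            for k in range(j, n + 1)
        }
        for (j, k), (j2, k2) in itertools.product(d, repeat=2):
            if j <= j2 and k2 <= k:
                assert d[(j2, k2)] <= d[(j, k)] + 1e-12


class TestScoreStarts:
    def test_work_conservation_and_sequential_union(self):
        rng = np.random.default_rng(7)
        mat = random_complete_matrix(rng, 10, 30)
        W = 12
        scores = score_starts(mat, 1, mat.n, W)
        n = mat.n
        assert len(scores) == n * W - W * (W - 1) // 2
        keys = set(zip(scores["start"].tolist(), scores["end"].tolist()))
        assert len(keys) == len(scores)  # no duplicates
        for j, k, d in scores:
            assert d == pytest.approx(hb.diversity(mat, int(j), int(k)))

    def test_general_and_fast_paths_agree(self):
        rng = np.random.default_rng(11)
        mat = random_complete_matrix(rng, 8, 15)
        from hapblock.diversity import _deltas_from_start_general, _deltas_from_start_py

        for j0 in range(mat.n):
            np.testing.assert_allclose(
                _deltas_from_start_general(mat.alleles, j0, 10),
                _deltas_from_start_py(mat.alleles, j0, 10),
            )


class TestGoodPartnerTable:
    def test_identical_rows_any_limit(self):
        mat = hb.from_strings(["1010"] * 5)
        tbl = hb.good_partner_table(mat, D=0.0, W=10)
        assert list(tbl.L[1:]) == [1, 1, 1, 1]

    def test_window_only_constraint(self):
        rng = np.random.default_rng(3)
        mat = random_complete_matrix(rng, 6, 10)
        tbl = hb.good_partner_table(mat, D=1.0, W=3)
        assert [int(tbl.L[i]) for i in range(1, 11)] == [
            max(1, i - 2) for i in range(1, 11)
        ]

    @pytest.mark.parametrize("seed,missing", [(0, 0.0), (1, 0.1), (2, 0.1)])
    def test_equals_exhaustive_recomputation(self, seed, missing):
        """L[i] is the smallest start in the window with delta <= D,
        verified by scoring every interval from scratch (12x20, D=0.2,
        W=20, with and without 10% missing data)."""
        rng = np.random.default_rng(300 + seed)
        mat = random_complete_matrix(rng, 12, 20)
        if missing:
            mat = with_missing(mat, rng, missing)
        D, W = 0.2, 20
        tbl = hb.good_partner_table(mat, D=D, W=W)
        for i in range(1, 21):
            feas = [
                s
                for s in range(max(1, i - W + 1), i + 1)
                if hb.diversity(mat, s, i) <= D + 1e-12
            ]
            assert int(tbl.L[i]) == (feas[0] if feas else 0)
            np.testing.assert_array_equal(tbl.feasible_starts(i), feas)

    def test_table_invariants(self):
        rng = np.random.default_rng(4)
        mat = random_complete_matrix(rng, 10, 15)
        tbl = hb.good_partner_table(mat, D=0.25, W=8)
        prev = 1
        for i in range(1, 16):
            L = int(tbl.L[i])
            if L == 0:
                continue
            assert max(1, i - 8 + 1) <= L <= i
            assert L >= prev  # monotone under complete data
            prev = L
            assert hb.diversity(mat, L, i) <= 0.25
            if L > max(1, i - 8 + 1):
                assert hb.diversity(mat, L - 1, i) > 0.25


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    m=st.integers(2, 8),
    n=st.integers(1, 10),
    seed=st.integers(0, 2**20),
)
def test_delta_bounds_and_zero_when_all_compatible(m, n, seed):
    rng = np.random.default_rng(seed)
    mat = hb.HaplotypeMatrix(rng.integers(0, 2, (m, n)).astype(np.int8))
    d = hb.diversity(mat, 1, n)
    assert 0.0 <= d <= 1.0
    dup = hb.HaplotypeMatrix(np.repeat(mat.alleles[:1], m, axis=0))
    assert hb.diversity(dup, 1, n) == 0.0


def test_table_from_scores_detects_missing_coverage():
    rng = np.random.default_rng(5)
    mat = random_complete_matrix(rng, 6, 10)
    scores = score_starts(mat, 1, mat.n, 5)
    broken = scores[scores["start"] != 4]
    with pytest.raises(hb.errors.MissingScoresError):
        table_from_scores(broken, n=10, D=0.2, W=5)
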