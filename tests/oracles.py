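"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and shares no code path with the
package internals: diversity by exact substring grouping, block selection by
first-principles recursion over all feasible intervals, tagSNP minimality by
subset enumeration.
"""

from __future__ import annotations

import itertools
from collections import Counter
from functools import lru_cache

import numpy as np

from hapblock.matrix import MISSING, HaplotypeMatrix


def delta_oracle(mat: HaplotypeMatrix, j: int, k: int) -> float:
    """Diversity on complete data: group rows by exact substring and count
    singleton groups."""
    subs = [
        "".join(str(int(a)) for a in mat.alleles[i, j - 1 : k])
        for i in range(mat.m)
    ]
    counts = Counter(subs)
    s = sum(1 for x in subs if counts[x] == 1)
    return s / mat.m


def feasible_intervals(mat: HaplotypeMatrix, D: float, W: int, delta=None):
    """All 1-based intervals [j, k] with width <= W and delta <= D."""
    delta = delta or delta_oracle
    out = []
    for j in range(1, mat.n + 1):
        for k in range(j, min(mat.n, j + W - 1) + 1):
            if delta(mat, j, k) <= D + 1e-12:
                out.append((j, k))
    return out


def longest_k_oracle(mat: HaplotypeMatrix, D: float, W: int, k: int, delta=None) -> int:
    """Max total length over all sets of <= k disjoint feasible intervals,
    by complete recursion over every feasible interval (no good-partner
    table, no widest-block shortcut)."""
    feas = feasible_intervals(mat, D, W, delta)
    by_start: dict[int, list[int]] = {}
    for j, kk in feas:
        by_start.setdefault(j, []).append(kk)

    @lru_cache(maxsize=None)
    def best(pos: int, left: int) -> int:
        if pos > mat.n or left == 0:
            return 0
        res = best(pos + 1, left)  # leave pos uncovered
        for end in by_start.get(pos, ()):
            res = max(res, end - pos + 1 + best(end + 1, left - 1))
        return res

    return best(1, k)


def longest_k_enumeration(mat: HaplotypeMatrix, D: float, W: int, k: int) -> int:
    """Literal enumeration of every set of <= k disjoint feasible intervals
    (exponential; keep n tiny).  Validates ``longest_k_oracle``."""
    feas = sorted(feasible_intervals(mat, D, W))
    best = 0
    for size in range(1, k + 1):
        for combo in itertools.combinations(feas, size):
            ok = all(combo[i][1] < combo[i + 1][0] for i in range(size - 1))
            if ok:
                best = max(best, sum(e - s + 1 for s, e in combo))
    return best


def min_blocks_oracle(mat: HaplotypeMatrix, D: float, W: int, delta=None):
    """Minimum number of feasible blocks tiling [1, n], or None when no full
    segmentation exists; recursion over every feasible block starting at
    each uncovered position."""
    feas = set(feasible_intervals(mat, D, W, delta))

    @lru_cache(maxsize=None)
    def best(pos: int):
        if pos > mat.n:
            return 0
        res = None
        for end in range(pos, min(mat.n, pos + W - 1) + 1):
            if (pos, end) in feas:
                sub = best(end + 1)
                if sub is not None and (res is None or sub + 1 < res):
                    res = sub + 1
        return res

    return best(1)


def classify_oracle(sub: np.ndarray):
    """(U, C, S, ambiguous) straight from the definitions, O(m^3) loops."""
    m = sub.shape[0]

    def compatible(a, b):
        return all(
            sub[a, c] == sub[b, c]
            for c in range(sub.shape[1])
            if sub[a, c] != MISSING and sub[b, c] != MISSING
        )

    comp = [[compatible(a, b) for b in range(m)] for a in range(m)]
    ambiguous = [
        any(
            comp[i][a] and comp[i][b] and not comp[a][b]
            for a in range(m)
            for b in range(m)
        )
        for i in range(m)
    ]
    unamb = [i for i in range(m) if not ambiguous[i]]
    common = [
        i for i in unamb if any(comp[i][j] for j in unamb if j != i)
    ]
    U = len(unamb)
    C = len(common)
    return U, C, U - C, m - U


def tagsnp_min_size_oracle(reps: np.ndarray) -> int | None:
    """Size of the smallest locus subset whose patterns pairwise conflict
    (differ at a co-called locus), by subset enumeration."""
    k, w = reps.shape

    def distinguishes(combo):
        for a in range(k):
            for b in range(a + 1, k):
                if not any(
                    reps[a, c] != reps[b, c]
                    and reps[a, c] != MISSING
                    and reps[b, c] != MISSING
                    for c in combo
                ):
                    return False
        return True

    for size in range(1, w + 1):
        for combo in itertools.combinations(range(w), size):
            if distinguishes(combo):
                return size
    return None


def tagsnp_lex_first_oracle(reps: np.ndarray):
    """The first distinguishing combination in (size, lexicographic) order."""
    k, w = reps.shape

    def distinguishes(combo):
        for a in range(k):
            for b in range(a + 1, k):
                if not any(
                    reps[a, c] != reps[b, c]
                    and reps[a, c] != MISSING
                    and reps[b, c] != MISSING
                    for c in combo
                ):
                    return False
        return True

    for size in range(1, w + 1):
        for combo in itertools.combinations(range(w), size):
            if distinguishes(combo):
                return tuple(c + 1 for c in combo)
    return None
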