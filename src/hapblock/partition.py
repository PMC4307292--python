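"""Block partitioning by dynamic programming over the good-partner table.

Two objectives are solved:

* ``longest_k_blocks`` — choose at most k disjoint feasible blocks maximising
  the total number of SNPs covered, via the recurrence

      f(k, j) = max{ f(k, j−1),  f(k−1, L[j]−1) + j − L[j] + 1 }

  which either skips site j or closes the widest feasible block [L[j], j].
  With a monotone diversity function the widest block ending at j dominates
  every shorter one for this objective, so only [L[j], j] need be considered.

* ``min_blocks_full_cover`` — cover every SNP with the fewest feasible
  blocks.  Here shorter last blocks can matter (full coverage changes the
  trade-off), so the DP minimises over *all* feasible starts for each end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diversity import DiversitySummary, GoodPartnerTable
from .errors import UncoverableColumnError

__all__ = [
    "Block",
    "Segmentation",
    "DPTable",
    "longest_k_blocks",
    "traceback",
    "min_blocks_full_cover",
]


@dataclass
class Block:
    """A 1-based inclusive SNP interval with optional annotations."""

    start: int
    end: int
    delta: float | None = None
    summary: DiversitySummary | None = None
    tagsnps: "object | None" = None  # TagSNPResult, filled by the tagsnp module

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class Segmentation:
    """Ordered, pairwise-disjoint feasible blocks."""

    blocks: list[Block] = field(default_factory=list)
    D: float | None = None
    W: int | None = None

    @property
    def k_used(self) -> int:
        return len(self.blocks)

    @property
    def total_length(self) -> int:
        return sum(b.width for b in self.blocks)

    @property
    def average_length(self) -> float:
        return self.total_length / len(self.blocks) if self.blocks else 0.0

    def cut_points(self, n: int) -> list[int]:
        """Internal segmentation edges: column c means a cut between c and
        c + 1.  Block starts and ends both induce cuts; the matrix edges
        (0 and n) are excluded."""
        cuts = set()
        for b in self.blocks:
            cuts.add(b.start - 1)
            cuts.add(b.end)
        cuts.discard(0)
        cuts.discard(n)
        return sorted(cuts)

    def validate(self) -> None:
        prev_end = 0
        for b in self.blocks:
            if not (0 < b.start <= b.end):
                raise ValueError(f"malformed block [{b.start}, {b.end}]")
            if b.start <= prev_end:
                raise ValueError("blocks overlap or are out of order")
            prev_end = b.end


@dataclass
class DPTable:
    """Prefix DP grid: ``f[k, j]`` = best covered length in columns 1..j
    using at most k blocks."""

    f: np.ndarray  # (k_max + 1, n + 1) int64
    k_max: int

    def optimum(self, k: int | None = None) -> int:
        k = self.k_max if k is None else min(k, self.k_max)
        return int(self.f[k, -1])


def longest_k_blocks(table: GoodPartnerTable, k: int) -> DPTable:
    """Fill the longest-k-blocks DP grid for block budgets 0..k."""
    if k < 1:
        raise ValueError("block budget k must be >= 1")
    n = table.n
    L = table.L.astype(np.int64)
    f = np.zeros((k + 1, n + 1), dtype=np.int64)
    j = np.arange(n + 1, dtype=np.int64)
    has_block = L > 0
    width = np.where(has_block, j - L + 1, 0)
    prev_idx = np.maximum(L - 1, 0)
    for kappa in range(1, k + 1):
        cand = np.where(has_block, f[kappa - 1][prev_idx] + width, 0)
        cand[0] = 0
        f[kappa] = np.maximum.accumulate(cand)
    return DPTable(f=f, k_max=k)


def traceback(dp: DPTable, table: GoodPartnerTable, k: int | None = None) -> Segmentation:
    """Recover one optimal segmentation from the DP grid.

    Ties prefer the skip branch, which deterministically yields the solution
    with the fewest, rightmost blocks among optima of equal total length.
    """
    k = dp.k_max if k is None else k
    if k > dp.k_max:
        raise ValueError(f"DP grid only filled up to k = {dp.k_max}")
    f = dp.f
    blocks: list[Block] = []
    j, kappa = table.n, k
    while j > 0 and kappa > 0 and f[kappa, j] > 0:
        if f[kappa, j] == f[kappa, j - 1]:
            j -= 1
        else:
            s = int(table.L[j])
            blocks.append(Block(start=s, end=j))
            j = s - 1
            kappa -= 1
    blocks.reverse()
    seg = Segmentation(blocks=blocks, D=table.D, W=table.W)
    seg.validate()
    return seg


def min_blocks_full_cover(table: GoodPartnerTable) -> Segmentation:
    """Cover all n columns with the minimum number of feasible blocks.

    ``g(j) = 1 + min over feasible blocks [s, j] of g(s − 1)``, scanning every
    feasible start (not only the good partner).  Raises
    :class:`UncoverableColumnError` when some prefix cannot be completed.
    Ties prefer the smallest start, i.e. the widest last block.
    """
    n = table.n
    INF = n + 2
    g = np.full(n + 1, INF, dtype=np.int64)
    bp = np.zeros(n + 1, dtype=np.int64)
    g[0] = 0
    for j in range(1, n + 1):
        starts = table.feasible_starts(j)
        if starts.size == 0:
            continue
        vals = g[starts - 1]
        i = int(np.argmin(vals))  # first minimum -> leftmost start
        if vals[i] < INF:
            g[j] = vals[i] + 1
            bp[j] = starts[i]
    if g[n] >= INF:
        bad = int(np.nonzero(g >= INF)[0][0])
        raise UncoverableColumnError(bad)
    blocks: list[Block] = []
    j = n
    while j > 0:
        s = int(bp[j])
        blocks.append(Block(start=s, end=j))
        j = s - 1
    blocks.reverse()
    seg = Segmentation(blocks=blocks, D=table.D, W=table.W)
    seg.validate()
    return seg
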