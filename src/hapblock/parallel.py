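"""Chunked map/reduce execution of interval-diversity scoring.

The start-index space 1..n is split into contiguous, balanced chunks, one
per worker.  Each map worker independently scores every interval whose start
lies in its chunk and whose width is at most W, emitting
((start, end), delta) records.  A single reduce pass merges the streams,
verifies coverage, builds the good-partner table and runs the sequential
block-selection DP — so the output is identical, byte for byte, to a
single-worker run regardless of the worker count.

The pool is in-process (threads; the complete-data scoring kernel releases
the GIL).  A chunk whose worker fails is re-submitted once before the error
is propagated.
"""

from __future__ import annotations

import logging
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .diversity import (
    SCORE_DTYPE,
    GoodPartnerTable,
    score_starts,
    table_from_scores,
)
from .errors import MissingScoresError
from .matrix import HaplotypeMatrix
from .partition import (
    Segmentation,
    longest_k_blocks,
    min_blocks_full_cover,
    traceback,
)

__all__ = [
    "ChunkPlan",
    "plan_chunks",
    "map_score_chunk",
    "reduce_select",
    "partition_matrix",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChunkPlan:
    """Balanced partition of the start-index space among workers."""

    n_workers: int
    chunk_ranges: tuple[tuple[int, int], ...]  # 1-based inclusive start ranges
    W: int


def plan_chunks(n: int, W: int, n_workers: int) -> ChunkPlan:
    """Split starts 1..n into ``n_workers`` contiguous ranges balanced to
    within one start index; worker counts above n are clamped to n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    p = min(n_workers, n)
    base, extra = divmod(n, p)
    ranges = []
    lo = 1
    for i in range(p):
        size = base + (1 if i < extra else 0)
        ranges.append((lo, lo + size - 1))
        lo += size
    return ChunkPlan(n_workers=p, chunk_ranges=tuple(ranges), W=W)


def map_score_chunk(
    mat: HaplotypeMatrix, chunk: tuple[int, int], W: int
) -> np.ndarray:
    """Score one worker's chunk; a structured (start, end, delta) array."""
    lo, hi = chunk
    return score_starts(mat, lo, hi, W)


def _run_pool(mat: HaplotypeMatrix, plan: ChunkPlan) -> list[np.ndarray]:
    results: list[np.ndarray | None] = [None] * len(plan.chunk_ranges)

    def work(i: int) -> None:
        t0 = time.perf_counter()
        results[i] = map_score_chunk(mat, plan.chunk_ranges[i], plan.W)
        log.debug(
            "chunk %d %s scored %d intervals in %.3fs",
            i, plan.chunk_ranges[i], len(results[i]), time.perf_counter() - t0,
        )

    if plan.n_workers == 1:
        work(0)
    else:
        with ThreadPoolExecutor(max_workers=plan.n_workers) as pool:
            futures = {pool.submit(work, i): i for i in range(len(plan.chunk_ranges))}
            retried: set[int] = set()
            for fut, i in list(futures.items()):
                try:
                    fut.result()
                except Exception:
                    if i in retried:
                        raise
                    retried.add(i)
                    log.warning("chunk %d failed; re-submitting once", i)
                    pool.submit(work, i).result()
    return results  # type: ignore[return-value]


def reduce_select(
    scores: Iterable[np.ndarray] | np.ndarray,
    *,
    n: int,
    D: float,
    W: int,
    mode: str = "min-blocks",
    k: int | None = None,
) -> tuple[Segmentation, GoodPartnerTable]:
    """Single reduce: merge score streams, build the good-partner table and
    select blocks.  Raises :class:`MissingScoresError` on incomplete
    coverage of the width-≤-W interval set."""
    if isinstance(scores, np.ndarray):
        merged = scores
    else:
        chunks = list(scores)
        merged = (
            np.concatenate(chunks) if chunks else np.empty(0, dtype=SCORE_DTYPE)
        )
    if n < 1 or merged.size == 0:
        raise MissingScoresError("empty interval set (n = 0)")
    table = table_from_scores(merged, n=n, D=D, W=W, check_coverage=True)
    if mode == "min-blocks":
        seg = min_blocks_full_cover(table)
    elif mode == "longest-k":
        if k is None:
            raise ValueError("mode 'longest-k' requires a block budget k")
        seg = traceback(longest_k_blocks(table, k), table, k)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return seg, table


def partition_matrix(
    mat: HaplotypeMatrix,
    *,
    D: float = 0.2,
    W: int | None = None,
    mode: str = "min-blocks",
    k: int | None = None,
    n_workers: int = 1,
) -> tuple[Segmentation, GoodPartnerTable]:
    """End-to-end map/shuffle/reduce partitioning of a haplotype matrix."""
    W_eff = mat.n if W is None else W
    plan = plan_chunks(mat.n, W_eff, n_workers)
    chunks = _run_pool(mat, plan)
    seg, table = reduce_select(chunks, n=mat.n, D=D, W=W_eff, mode=mode, k=k)
    from .diversity import classify_rows  # annotate per-block summaries

    for b in seg.blocks:
        b.summary = classify_rows(mat.interval(b.start, b.end))
        b.delta = b.summary.delta
    return seg, table
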