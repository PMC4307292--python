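"""Haplotype diversity within marker intervals.

The diversity of an interval is δ = 1 − C/U = S/U, where U, C and S count the
unambiguous, common and singleton haplotypes among the rows restricted to the
interval.  Two rows are *compatible* when their alleles agree at every locus
where both are called; a row is *ambiguous* when it is compatible with two
rows that are mutually incompatible (only possible with missing data).  Among
unambiguous rows, a row compatible with at least one other unambiguous row is
*common*, otherwise *singleton*.

δ ≤ D with D = 1 − α expresses the coverage criterion that at least a
fraction α of unambiguous haplotypes in a block are common (the classical
choice is α = 80%, i.e. D = 0.2).

On complete data δ is monotone: a subinterval never has larger diversity than
an enclosing interval.  Missing data can break monotonicity, so every sweep
here re-verifies feasibility instead of assuming it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .matrix import MISSING, HaplotypeMatrix, IntervalView

__all__ = [
    "DiversitySummary",
    "GoodPartnerTable",
    "classify_rows",
    "diversity",
    "good_partner_table",
    "score_starts",
]

DEFAULT_DIVERSITY_LIMIT = 0.2  # equivalently 80% common-haplotype coverage


@dataclass(frozen=True)
class DiversitySummary:
    """Interval classification counts and the resulting diversity score."""

    U: int
    C: int
    S: int
    ambiguous: int
    delta: float

    @property
    def m(self) -> int:
        return self.U + self.ambiguous

    @property
    def coverage(self) -> float:
        """Fraction of unambiguous haplotypes that are common (α)."""
        return 1.0 - self.delta


# ---------------------------------------------------------------------------
# pairwise-compatibility classification (general, handles missing data)
# ---------------------------------------------------------------------------

def _compat_matrix(sub: np.ndarray) -> np.ndarray:
    """Boolean m×m compatibility matrix of the interval slab ``sub``."""
    valid = sub != MISSING
    conflict = (
        (sub[:, None, :] != sub[None, :, :])
        & valid[:, None, :]
        & valid[None, :, :]
    )
    return ~conflict.any(axis=2)


def _classify_from_compat(compat: np.ndarray) -> DiversitySummary:
    m = compat.shape[0]
    # row i is ambiguous iff some a, b are both compatible with i while
    # incompatible with each other: diag(B · ¬B · B) > 0 with B symmetric
    B = compat.astype(np.int32)
    amb = ((B @ (~compat).astype(np.int32)) * B).sum(axis=1) > 0
    unamb = ~amb
    U = int(unamb.sum())
    if U == 0:
        return DiversitySummary(0, 0, 0, m, 0.0)
    Bu = compat[unamb][:, unamb]
    matches = Bu.sum(axis=1) - 1  # other unambiguous rows compatible with each
    S = int((matches == 0).sum())
    C = U - S
    return DiversitySummary(U, C, S, m - U, S / U)


def classify_rows(view: IntervalView) -> DiversitySummary:
    """Classify every haplotype row of the interval and compute δ.

    δ is defined as 0 when all rows are ambiguous (U = 0), so a fully
    ambiguous interval is never excluded from feasibility by a 0/0.
    """
    sub = view.submatrix()
    if not (sub == MISSING).any():
        # complete data: classes are exact substring groups
        _, counts = np.unique(sub, axis=0, return_counts=True)
        m = sub.shape[0]
        S = int((counts == 1).sum())
        return DiversitySummary(m, m - S, S, 0, S / m)
    return _classify_from_compat(_compat_matrix(sub))


def diversity(mat: HaplotypeMatrix, j: int, k: int) -> float:
    """δ of the 1-based inclusive interval [j, k]."""
    return classify_rows(mat.interval(j, k)).delta


# ---------------------------------------------------------------------------
# per-start sweeps: δ for all widths 1..W from a fixed start
# ---------------------------------------------------------------------------

def _deltas_from_start_py(A: np.ndarray, j0: int, W: int) -> np.ndarray:
    """Python fallback for the complete-data refinement sweep."""
    m, n = A.shape
    kmax = min(n, j0 + W)
    out = np.empty(kmax - j0, dtype=np.float64)
    ids = np.zeros(m, dtype=np.intp)
    for t in range(kmax - j0):
        key = ids * 2 + A[:, j0 + t]
        _, ids, counts = np.unique(key, return_inverse=True, return_counts=True)
        out[t] = (counts == 1).sum() / m
    return out


def _deltas_from_start_general(A: np.ndarray, j0: int, W: int) -> np.ndarray:
    """Sweep with missing data: incremental pairwise compatibility."""
    m, n = A.shape
    kmax = min(n, j0 + W)
    out = np.empty(kmax - j0, dtype=np.float64)
    compat = np.ones((m, m), dtype=bool)
    for t in range(kmax - j0):
        col = A[:, j0 + t]
        valid = col != MISSING
        conflict = (col[:, None] != col[None, :]) & valid[:, None] & valid[None, :]
        compat &= ~conflict
        out[t] = _classify_from_compat(compat).delta
    return out


def _deltas_from_start(A: np.ndarray, j0: int, W: int) -> np.ndarray:
    slab = A[:, j0 : min(A.shape[1], j0 + W)]
    if (slab == MISSING).any():
        return _deltas_from_start_general(A, j0, W)
    if _kernels.HAVE_NUMBA:
        return _kernels.deltas_from_start(A, j0, W)
    return _deltas_from_start_py(A, j0, W)


def score_starts(mat: HaplotypeMatrix, start_lo: int, start_hi: int, W: int):
    """Score every interval with start in [start_lo, start_hi] (1-based,
    inclusive) and width ≤ W.

    Returns a structured array with fields ``start``, ``end`` (1-based) and
    ``delta``, ordered by (start, end).  This is the unit of work handed to
    one map worker in the chunked decomposition.
    """
    if not (1 <= start_lo <= start_hi <= mat.n):
        raise IndexError(f"start range [{start_lo}, {start_hi}] out of 1..{mat.n}")
    if W < 1:
        raise ValueError("W must be >= 1")
    A = mat.alleles
    n = mat.n
    total = sum(min(W, n - j + 1) for j in range(start_lo, start_hi + 1))
    out = np.empty(total, dtype=SCORE_DTYPE)
    pos = 0
    for j in range(start_lo, start_hi + 1):
        deltas = _deltas_from_start(A, j - 1, W)
        w = deltas.shape[0]
        out["start"][pos : pos + w] = j
        out["end"][pos : pos + w] = np.arange(j, j + w)
        out["delta"][pos : pos + w] = deltas
        pos += w
    return out


SCORE_DTYPE = np.dtype(
    [("start", np.int32), ("end", np.int32), ("delta", np.float64)]
)


# ---------------------------------------------------------------------------
# good-partner table
# ---------------------------------------------------------------------------

@dataclass
class GoodPartnerTable:
    """Per-locus leftmost feasible block start under (D, W).

    ``L[i]`` (1-based; index 0 unused) is the smallest start s in the window
    ``[max(1, i − W + 1), i]`` such that δ(s, i) ≤ D, or 0 when no start is
    feasible.  ``starts`` lists, per end index, every feasible start; when it
    is None the feasible starts are exactly the contiguous run
    ``[L[i], i]`` (guaranteed by monotone δ on complete data).
    """

    n: int
    D: float
    W: int
    L: np.ndarray  # int32, length n + 1
    starts: list | None = None  # per-end arrays of feasible starts, or None

    def feasible_starts(self, end: int) -> np.ndarray:
        if self.starts is not None:
            return self.starts[end]
        if self.L[end] == 0:
            return np.empty(0, dtype=np.int32)
        return np.arange(self.L[end], end + 1, dtype=np.int32)


def _delta_complete(A: np.ndarray, j0: int, k0: int) -> float:
    if _kernels.HAVE_NUMBA:
        return float(_kernels.delta_complete(A, j0, k0))
    return float(_deltas_from_start_py(A, j0, k0 - j0 + 1)[-1])


def good_partner_table(
    mat: HaplotypeMatrix, D: float = DEFAULT_DIVERSITY_LIMIT, W: int | None = None
) -> GoodPartnerTable:
    """Build the good-partner table L for diversity limit D and width cap W.

    Complete data: a two-pointer sweep — monotone δ makes the feasible starts
    for each end a contiguous run, and the left pointer never retreats.
    Missing data: δ may be non-monotone, so every window position is scored
    and feasibility is recorded explicitly per end.
    """
    if not (0.0 <= D <= 1.0):
        raise ValueError("D must lie in [0, 1]")
    n = mat.n
    if W is None:
        W = n
    if W < 1:
        raise ValueError("W must be >= 1")
    L = np.zeros(n + 1, dtype=np.int32)
    if not mat.has_missing():
        A = mat.alleles
        left = 1
        for i in range(1, n + 1):
            left = max(left, i - W + 1)
            while left <= i and _delta_complete(A, left - 1, i - 1) > D:
                left += 1
            L[i] = left if left <= i else 0
            if left > i:
                left = i + 1
        return GoodPartnerTable(n=n, D=D, W=W, L=L)

    scores = score_starts(mat, 1, n, W)
    return table_from_scores(scores, n=n, D=D, W=W, check_coverage=False)


def table_from_scores(
    scores: np.ndarray, *, n: int, D: float, W: int, check_coverage: bool = True
) -> GoodPartnerTable:
    """Assemble a good-partner table from a merged (start, end, delta) stream.

    When ``check_coverage`` is set, every interval of width ≤ W must be
    present exactly once; shortfalls raise :class:`MissingScoresError`.
    """
    from .errors import MissingScoresError

    if n < 1:
        raise MissingScoresError("empty interval set (n = 0)")
    if check_coverage:
        seen = np.bincount(scores["start"], minlength=n + 1)
        expected = np.minimum(W, n - np.arange(n + 1) + 1)
        expected[0] = 0
        bad = np.nonzero(seen != expected)[0]
        if bad.size:
            detail = ", ".join(
                f"start {j}: expected {expected[j]} scores, got {seen[j]}"
                for j in bad[:10]
            )
            if bad.size > 10:
                detail += f", ... ({bad.size} starts affected)"
            raise MissingScoresError(detail)

    feas = scores[scores["delta"] <= D]
    starts_per_end: list = [np.empty(0, dtype=np.int32) for _ in range(n + 1)]
    order = np.lexsort((feas["start"], feas["end"]))
    feas = feas[order]
    ends, first = np.unique(feas["end"], return_index=True)
    bounds = np.append(first, feas.shape[0])
    for idx, e in enumerate(ends):
        starts_per_end[int(e)] = feas["start"][bounds[idx] : bounds[idx + 1]].astype(
            np.int32
        )
    L = np.zeros(n + 1, dtype=np.int32)
    for e in range(1, n + 1):
        if starts_per_end[e].size:
            L[e] = int(starts_per_end[e][0])
    return GoodPartnerTable(n=n, D=D, W=W, L=L, starts=starts_per_end)
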