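"""Numba kernels for complete-data (no missing calls) diversity scoring.

On complete data two haplotypes are compatible within an interval iff their
substrings are identical, so classification reduces to grouping rows by
substring.  Both kernels grow the interval one column at a time, refining the
row grouping incrementally; each refinement is O(m log m).

Pure-python equivalents live in :mod:`hapblock.diversity` and are used when
numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=True, nogil=True)
def _refine(ids, col, out_ids):
    """Split groups ``ids`` by the binary column ``col``; return
    (n_singleton_rows, next grouping in ``out_ids``)."""
    m = ids.shape[0]
    key = ids * 2 + col
    order = np.argsort(key)
    cur = 0
    run = 0
    singletons = 0
    prev = key[order[0]]
    for t in range(m):
        v = key[order[t]]
        if v != prev:
            if run == 1:
                singletons += 1
            cur += 1
            run = 0
            prev = v
        out_ids[order[t]] = cur
        run += 1
    if run == 1:
        singletons += 1
    return singletons


@njit(cache=True, nogil=True)
def deltas_from_start(A, j0, W):
    """Diversity of every interval starting at 0-based column ``j0`` with
    width up to ``W`` (capped at the matrix edge), in width order."""
    m, n = A.shape
    kmax = min(n, j0 + W)
    out = np.empty(kmax - j0, dtype=np.float64)
    ids = np.zeros(m, dtype=np.int64)
    nxt = np.empty(m, dtype=np.int64)
    for t in range(kmax - j0):
        col = A[:, j0 + t].astype(np.int64)
        s = _refine(ids, col, nxt)
        ids, nxt = nxt, ids
        out[t] = s / m
    return out


@njit(cache=True, nogil=True)
def delta_complete(A, j0, k0):
    """Diversity of the single 0-based inclusive interval [j0, k0]."""
    m = A.shape[0]
    ids = np.zeros(m, dtype=np.int64)
    nxt = np.empty(m, dtype=np.int64)
    s = 0
    for c in range(j0, k0 + 1):
        col = A[:, c].astype(np.int64)
        s = _refine(ids, col, nxt)
        ids, nxt = nxt, ids
    return s / m
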