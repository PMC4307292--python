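"""Minimal tagSNP selection within a haplotype block.

The common haplotypes of a block fall into k distinct groups.  A tagSNP set
is a set of loci T whose joint allele patterns distinguish all k groups; we
search for the minimum-cardinality T, enumerating γ-combinations of the
block's loci in lexicographic order for γ = ⌈log2 k⌉, ⌈log2 k⌉ + 1, … and
returning the first distinguishing combination.  The result is therefore the
lexicographically smallest set of minimum size, and |T| always satisfies the
information bound 2^|T| ≥ k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import NoDistinguishingSetError
from .matrix import MISSING, IntervalView
from .diversity import _compat_matrix, _classify_from_compat

__all__ = [
    "HaplotypeGrouping",
    "TagSNPResult",
    "group_common_haplotypes",
    "select_tagsnps",
    "select_tagsnps_greedy",
]


@dataclass
class HaplotypeGrouping:
    """Disjoint row-index groups, one per distinct common haplotype."""

    groups: list[np.ndarray]  # 0-based row indices, each of size >= 2

    @property
    def k_groups(self) -> int:
        return len(self.groups)


@dataclass
class TagSNPResult:
    """A minimum distinguishing locus set for one block.

    ``loci`` are 1-based block-local column indices.
    """

    loci: tuple[int, ...]
    k_groups: int

    @property
    def gamma(self) -> int:
        return len(self.loci)


def group_common_haplotypes(view: IntervalView) -> HaplotypeGrouping:
    """Partition the block's common haplotypes into compatibility classes.

    On complete data the classes are exactly the distinct strings with
    multiplicity ≥ 2.  With missing data compatibility is not transitive, so
    classes are the connected components of the compatibility graph
    restricted to common (unambiguous, non-singleton) rows.
    """
    sub = view.submatrix()
    m = sub.shape[0]
    if not (sub == MISSING).any():
        _, inverse, counts = np.unique(
            sub, axis=0, return_inverse=True, return_counts=True
        )
        groups = [
            np.nonzero(inverse == g)[0]
            for g in range(counts.size)
            if counts[g] >= 2
        ]
        groups.sort(key=lambda g: int(g[0]))
        return HaplotypeGrouping(groups=groups)

    compat = _compat_matrix(sub)
    summary = _classify_from_compat(compat)
    B = compat.astype(np.int32)
    amb = ((B @ (~compat).astype(np.int32)) * B).sum(axis=1) > 0
    unamb = np.nonzero(~amb)[0]
    Bu = compat[np.ix_(unamb, unamb)]
    common_local = (Bu.sum(axis=1) - 1) >= 1
    common = unamb[common_local]
    assert common.size == summary.C
    if common.size == 0:
        return HaplotypeGrouping(groups=[])
    sub_g = csr_matrix(compat[np.ix_(common, common)])
    _, labels = connected_components(sub_g, directed=False)
    groups = [common[labels == g] for g in range(labels.max() + 1)]
    groups.sort(key=lambda g: int(g[0]))
    return HaplotypeGrouping(groups=groups)


def group_representatives(
    grouping: HaplotypeGrouping, view: IntervalView
) -> np.ndarray:
    """Consensus string per group: majority allele per locus over the group's
    rows, ignoring missing cells (ties break to the major allele, 0); a locus
    with no called cell in a group stays MISSING.  On complete data this is
    the group's shared string."""
    sub = view.submatrix()
    reps = np.full((grouping.k_groups, sub.shape[1]), MISSING, dtype=np.int8)
    for gi, rows in enumerate(grouping.groups):
        slab = sub[rows]
        ones = (slab == 1).sum(axis=0)
        zeros = (slab == 0).sum(axis=0)
        called = (ones + zeros) > 0
        reps[gi, called] = (ones[called] > zeros[called]).astype(np.int8)
    return reps


def _pair_separation_masks(reps: np.ndarray) -> tuple[list[int], int]:
    """Per locus, a bitmask of the group pairs it separates (a pair is
    separated at a locus when both representatives are called there and
    differ).  Returns (masks, full_mask)."""
    k, w = reps.shape
    iu, ju = np.triu_indices(k, k=1)
    valid = reps != MISSING
    sep = (reps[iu] != reps[ju]) & valid[iu] & valid[ju]  # (n_pairs, w)
    weights = 1 << np.arange(iu.size, dtype=object)
    masks = [int((sep[:, c] * weights).sum()) for c in range(w)]
    return masks, (1 << iu.size) - 1


def _pair_locus_lists(masks: list[int], full: int) -> list[list[int]]:
    """For each group pair, the ascending list of loci separating it."""
    pair_loci: list[list[int]] = [[] for _ in range(full.bit_count())]
    for locus, msk in enumerate(masks):
        rest = msk
        while rest:
            p = (rest & -rest).bit_length() - 1
            pair_loci[p].append(locus)
            rest &= rest - 1
    return pair_loci


def _lex_smallest_cover(
    masks: list[int], full: int, gamma: int
) -> tuple[int, ...] | None:
    """Lexicographically smallest γ-subset of loci whose separation masks
    union to ``full``, given that γ is the minimum cover size.

    Equivalent to enumerating γ-combinations in lexicographic order and
    returning the first cover, but built by prefix forcing: the next locus
    is the smallest index whose inclusion still leaves a feasible
    completion, decided by branch and bound on the uncovered pair with the
    fewest remaining separating loci.
    """
    from bisect import bisect_left

    w = len(masks)
    pair_loci = _pair_locus_lists(masks, full)

    def completable(uncov: int, start: int, left: int) -> bool:
        """Can ``left`` loci with index >= start cover ``uncov``?"""
        if uncov == 0:
            return True
        if left == 0:
            return False
        branch: list[int] | None = None
        rest = uncov
        while rest:
            p = (rest & -rest).bit_length() - 1
            lst = pair_loci[p]
            i0 = bisect_left(lst, start)
            if i0 == len(lst):
                return False
            if branch is None or len(lst) - i0 < len(branch):
                branch = lst[i0:]
            rest &= rest - 1
        assert branch is not None
        return any(
            completable(uncov & ~masks[locus], start, left - 1)
            for locus in branch
        )

    chosen: list[int] = []
    mask, start, left = 0, 0, gamma
    while left:
        for i in range(start, w - left + 1):
            if masks[i] | mask == mask:
                # contributes nothing to the prefix: cannot belong to any
                # minimum-size cover extending it
                continue
            if completable(full & ~(mask | masks[i]), i + 1, left - 1):
                chosen.append(i)
                mask |= masks[i]
                start, left = i + 1, left - 1
                break
        else:
            return None
    return tuple(chosen)


def _min_cover_size(masks: list[int], full: int, upper: int, c_max: int) -> int:
    """Exact minimum number of loci whose separation masks cover ``full``.

    Branch and bound on the uncovered pair with the fewest covering loci;
    ``upper`` is a known achievable size (e.g. from the greedy cover).
    """
    pair_loci = _pair_locus_lists(masks, full)
    best = upper

    def bb(uncov: int, depth: int) -> None:
        nonlocal best
        if uncov == 0:
            best = min(best, depth)
            return
        if depth + max(1, -(-uncov.bit_count() // c_max)) >= best:
            return
        # branch on the uncovered pair with the fewest covering loci
        p_best, fan = -1, None
        rest = uncov
        while rest:
            p = (rest & -rest).bit_length() - 1
            if fan is None or len(pair_loci[p]) < fan:
                p_best, fan = p, len(pair_loci[p])
            rest &= rest - 1
        for locus in pair_loci[p_best]:
            bb(uncov & ~masks[locus], depth + 1)

    bb(full, 0)
    return best


def select_tagsnps(
    grouping: HaplotypeGrouping,
    view: IntervalView,
    max_gamma: int | None = None,
) -> TagSNPResult:
    """Lexicographic enumeration of minimum distinguishing locus sets.

    Enumeration starts at the information-theoretic floor γ = ⌈log2 k⌉ (no
    smaller set can separate k groups) and grows γ until a distinguishing
    combination is found; the result is the lexicographically smallest set
    of minimum cardinality.  Blocks with fewer than two groups need no
    tagSNP.
    """
    k = grouping.k_groups
    if k <= 1:
        return TagSNPResult(loci=(), k_groups=k)
    w = view.width
    budget = min(w, 20 if max_gamma is None else max_gamma)
    reps = group_representatives(grouping, view)
    masks, full = _pair_separation_masks(reps)
    union = 0
    for msk in masks:
        union |= msk
    if union != full:
        raise NoDistinguishingSetError(
            f"two of the {k} haplotype groups of block "
            f"[{view.start}, {view.end}] share alleles at every locus"
        )
    c_max = max(msk.bit_count() for msk in masks)
    # exact minimum cardinality first (seeded by the greedy cover), then the
    # lexicographically first combination of exactly that size; identical to
    # enumerating gamma-combinations for growing gamma, but avoids
    # exhausting the infeasible sizes
    greedy = select_tagsnps_greedy(grouping, view)
    gamma0 = max(1, math.ceil(math.log2(k)))
    g_star = max(gamma0, _min_cover_size(masks, full, greedy.gamma, c_max))
    if g_star > budget:
        raise NoDistinguishingSetError(
            f"the {k} haplotype groups of block [{view.start}, {view.end}] "
            f"need {g_star} loci, above the budget of {budget}"
        )
    combo = _lex_smallest_cover(masks, full, g_star)
    assert combo is not None
    return TagSNPResult(loci=tuple(c + 1 for c in combo), k_groups=k)


def select_tagsnps_greedy(
    grouping: HaplotypeGrouping, view: IntervalView
) -> TagSNPResult:
    """Set-cover-style heuristic: repeatedly add the locus separating the
    most still-confounded group pairs.  Fast but not guaranteed minimal."""
    k = grouping.k_groups
    if k <= 1:
        return TagSNPResult(loci=(), k_groups=k)
    reps = group_representatives(grouping, view)
    w = view.width
    valid = reps != MISSING
    iu, ju = np.triu_indices(k, k=1)
    # pair_sep[p, locus]: locus separates pair p
    pair_sep = (
        (reps[iu] != reps[ju]) & valid[iu] & valid[ju]
    )  # (n_pairs, w)
    unresolved = np.ones(pair_sep.shape[0], dtype=bool)
    chosen: list[int] = []
    while unresolved.any():
        gains = pair_sep[unresolved].sum(axis=0)
        best = int(np.argmax(gains))
        if gains[best] == 0:
            raise NoDistinguishingSetError(
                f"groups of block [{view.start}, {view.end}] cannot be "
                f"separated at any locus"
            )
        chosen.append(best)
        unresolved &= ~pair_sep[:, best]
    return TagSNPResult(loci=tuple(sorted(c + 1 for c in chosen)), k_groups=k)


def annotate_segmentation(seg, mat, method: str = "exact", max_gamma: int | None = None):
    """Attach per-block groupings and tagSNP sets to a segmentation in place.

    Returns the total tagSNP count (blocks with < 2 groups contribute 0).
    """
    total = 0
    for b in seg.blocks:
        view = mat.interval(b.start, b.end)
        grouping = group_common_haplotypes(view)
        if method == "greedy":
            b.tagsnps = select_tagsnps_greedy(grouping, view)
        else:
            b.tagsnps = select_tagsnps(grouping, view, max_gamma=max_gamma)
        total += b.tagsnps.gamma
    return total
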