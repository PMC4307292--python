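"""scikit-learn-compatible wrappers around the partition and tagSNP core.

``HaplotypeBlockPartitioner.fit(X)`` segments the SNP columns of a phased
0/1 haplotype matrix (NaN = missing) into low-diversity blocks;
``TagSNPSelector`` is a feature selector whose ``transform`` keeps only the
tag loci.  Both compose with sklearn pipelines and model selection; the
heavy lifting lives in :mod:`hapblock.diversity`, :mod:`hapblock.partition`,
:mod:`hapblock.tagsnp` and :mod:`hapblock.parallel`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .matrix import HaplotypeMatrix
from .parallel import partition_matrix
from .tagsnp import annotate_segmentation

__all__ = ["HaplotypeBlockPartitioner", "TagSNPSelector"]


def _as_matrix(X) -> HaplotypeMatrix:
    if isinstance(X, HaplotypeMatrix):
        return X
    return HaplotypeMatrix(np.asarray(X))


class HaplotypeBlockPartitioner(BaseEstimator):
    """Segment SNP columns into haplotype blocks of bounded diversity.

    Parameters
    ----------
    diversity_limit : float, default 0.2
        Upper bound D on block diversity δ = S/U; equivalent to requiring
        common-haplotype coverage α = 1 − D (the classical α = 80%).
    coverage : float, optional
        Alternative parameterisation; exactly one of ``diversity_limit`` /
        ``coverage`` may be set explicitly (D = 1 − α).
    max_block_size : int, optional
        Width cap W in SNPs; None means unbounded.
    mode : {"min-blocks", "longest-k"}
        Full cover with the fewest blocks, or at most ``k`` blocks
        maximising the number of SNPs covered.
    k : int, optional
        Block budget for ``mode="longest-k"``.
    n_workers : int, default 1
        Map workers for chunked diversity scoring; the result is identical
        for every worker count.

    Attributes
    ----------
    segmentation_ : Segmentation
    blocks_ : list of (start, end) 1-based inclusive column intervals
    labels_ : ndarray of shape (n,), block index per column (−1 = gap)
    n_blocks_, total_length_ : summary statistics
    """

    def __init__(
        self,
        diversity_limit: float = 0.2,
        coverage: float | None = None,
        max_block_size: int | None = None,
        mode: str = "min-blocks",
        k: int | None = None,
        n_workers: int = 1,
    ):
        self.diversity_limit = diversity_limit
        self.coverage = coverage
        self.max_block_size = max_block_size
        self.mode = mode
        self.k = k
        self.n_workers = n_workers

    def _resolved_limit(self) -> float:
        if self.coverage is not None:
            return 1.0 - self.coverage
        return self.diversity_limit

    def fit(self, X, y=None):
        mat = _as_matrix(X)
        seg, table = partition_matrix(
            mat,
            D=self._resolved_limit(),
            W=self.max_block_size,
            mode=self.mode,
            k=self.k,
            n_workers=self.n_workers,
        )
        self.segmentation_ = seg
        self.good_partner_table_ = table
        self.blocks_ = [(b.start, b.end) for b in seg.blocks]
        labels = np.full(mat.n, -1, dtype=np.int64)
        for i, b in enumerate(seg.blocks):
            labels[b.start - 1 : b.end] = i
        self.labels_ = labels
        self.n_blocks_ = seg.k_used
        self.total_length_ = seg.total_length
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Block label per SNP column (−1 for columns outside any block)."""
        return self.fit(X).labels_


class TagSNPSelector(BaseEstimator, TransformerMixin):
    """Select the tagSNP columns of a blocked haplotype matrix.

    Fits a :class:`HaplotypeBlockPartitioner` (with the given parameters),
    then picks, per block, the lexicographically smallest minimum locus set
    distinguishing the block's common-haplotype groups.  ``transform``
    reduces a matrix to the selected columns.
    """

    def __init__(
        self,
        diversity_limit: float = 0.2,
        max_block_size: int | None = None,
        max_gamma: int | None = None,
        method: str = "exact",
        n_workers: int = 1,
    ):
        self.diversity_limit = diversity_limit
        self.max_block_size = max_block_size
        self.max_gamma = max_gamma
        self.method = method
        self.n_workers = n_workers

    def fit(self, X, y=None):
        mat = _as_matrix(X)
        part = HaplotypeBlockPartitioner(
            diversity_limit=self.diversity_limit,
            max_block_size=self.max_block_size,
            n_workers=self.n_workers,
        ).fit(mat)
        seg = part.segmentation_
        self.n_tagsnps_ = annotate_segmentation(
            seg, mat, method=self.method, max_gamma=self.max_gamma
        )
        self.partitioner_ = part
        loci = []
        for b in seg.blocks:
            loci.extend(b.start + t - 1 for t in b.tagsnps.loci)
        self.tag_loci_ = np.asarray(sorted(loci), dtype=np.int64)  # 1-based
        self.n_features_in_ = mat.n
        return self

    def transform(self, X) -> np.ndarray:
        mat = _as_matrix(X)
        if mat.n != self.n_features_in_:
            raise ValueError(
                f"X has {mat.n} columns, fitted on {self.n_features_in_}"
            )
        return np.asarray(mat.alleles[:, self.tag_loci_ - 1])

    def get_support(self) -> np.ndarray:
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.tag_loci_ - 1] = True
        return mask
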