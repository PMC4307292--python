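"""Canonical in-memory container for phased haplotype data.

A haplotype matrix holds ``m`` phased chromosomes (rows) typed at ``n``
biallelic SNP loci (columns).  Cells take one of three states: 0 (major
allele), 1 (minor allele) or :data:`MISSING`.  Column indices in the public
API are 1-based and intervals ``[j, k]`` are inclusive on both ends; the
underlying numpy array is 0-based as usual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError

#: Sentinel for an unknown allele call.
MISSING: int = -1


def _as_allele_array(alleles) -> np.ndarray:
    arr = np.asarray(alleles)
    if arr.dtype.kind == "f":
        # NaN encodes missing in float input (e.g. sklearn-style X)
        out = np.full(arr.shape, MISSING, dtype=np.int8)
        ok = ~np.isnan(arr)
        vals = arr[ok]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ConfigError("allele values must be 0, 1 or NaN/MISSING")
        out[ok] = vals.astype(np.int8)
        return out
    arr = arr.astype(np.int8, copy=True)
    if not np.isin(arr, (0, 1, MISSING)).all():
        raise ConfigError("allele values must be 0, 1 or MISSING (-1)")
    return arr


@dataclass
class HaplotypeMatrix:
    """``m`` haplotype rows by ``n`` SNP columns over {0, 1, MISSING}."""

    alleles: np.ndarray
    row_ids: list[str] = field(default_factory=list)
    locus_ids: list[str] = field(default_factory=list)
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = _as_allele_array(self.alleles)
        if self.alleles.ndim != 2 or self.alleles.shape[0] < 1 or self.alleles.shape[1] < 1:
            raise ConfigError("haplotype matrix must be 2-D with m >= 1 and n >= 1")
        m, n = self.alleles.shape
        if not self.row_ids:
            self.row_ids = [f"hap{i + 1}" for i in range(m)]
        if not self.locus_ids:
            self.locus_ids = [f"snp{j + 1}" for j in range(n)]
        if len(self.row_ids) != m:
            raise ConfigError(f"{len(self.row_ids)} row ids for {m} rows")
        if len(self.locus_ids) != n:
            raise ConfigError(f"{len(self.locus_ids)} locus ids for {n} columns")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if self.positions.shape != (n,):
                raise ConfigError("positions must map 1:1 to columns")
            if np.any(np.diff(self.positions) < 0):
                raise ConfigError("positions must be sorted ascending")

    # -- basic geometry ---------------------------------------------------
    @property
    def m(self) -> int:
        return self.alleles.shape[0]

    @property
    def n(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_haplotypes(self) -> int:
        return self.m

    @property
    def n_loci(self) -> int:
        return self.n

    def has_missing(self) -> bool:
        return bool((self.alleles == MISSING).any())

    # -- derived per-locus statistics -------------------------------------
    def allele1_freq(self) -> np.ndarray:
        """Frequency of allele 1 among non-missing calls, per column."""
        a = self.alleles
        ones = (a == 1).sum(axis=0)
        called = (a != MISSING).sum(axis=0)
        return np.where(called > 0, ones / np.maximum(called, 1), 0.0)

    @property
    def minor_allele_freq(self) -> np.ndarray:
        """Frequency of the rarer allele per column: min(p, 1 - p) over
        non-missing calls (0 for uncalled columns)."""
        p = self.allele1_freq()
        called = (self.alleles != MISSING).any(axis=0)
        return np.where(called, np.minimum(p, 1.0 - p), 0.0)

    def canonicalized(self) -> "HaplotypeMatrix":
        """Flip columns where allele 1 is the majority so that allele 0 is
        always the major allele.

        Ties (frequency exactly 0.5) are left unchanged, matching the
        lexicographic tie-break used when coding nucleotide input.
        """
        a = self.alleles.copy()
        flip = self.allele1_freq() > 0.5
        cols = a[:, flip]
        called = cols != MISSING
        cols[called] = 1 - cols[called]
        a[:, flip] = cols
        return HaplotypeMatrix(a, list(self.row_ids), list(self.locus_ids),
                               None if self.positions is None else self.positions.copy())

    def filter_maf(self, min_maf: float) -> "HaplotypeMatrix":
        """Keep only columns with minor-allele frequency >= ``min_maf``."""
        if min_maf <= 0:
            return self
        keep = self.minor_allele_freq >= min_maf
        if not keep.any():
            raise ConfigError(f"no column passes the MAF >= {min_maf} filter")
        return HaplotypeMatrix(
            self.alleles[:, keep],
            list(self.row_ids),
            [lid for lid, k in zip(self.locus_ids, keep) if k],
            None if self.positions is None else self.positions[keep],
        )

    # -- interval access ---------------------------------------------------
    def interval(self, j: int, k: int) -> "IntervalView":
        return IntervalView(self, j, k)

    def __eq__(self, other) -> bool:  # value semantics, used by round-trip tests
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        pos_eq = (
            (self.positions is None and other.positions is None)
            or (self.positions is not None and other.positions is not None
                and np.array_equal(self.positions, other.positions))
        )
        return (
            np.array_equal(self.alleles, other.alleles)
            and self.row_ids == other.row_ids
            and self.locus_ids == other.locus_ids
            and pos_eq
        )


@dataclass(frozen=True)
class IntervalView:
    """A 1-based inclusive column window ``[start, end]`` of a matrix."""

    matrix: HaplotypeMatrix
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end <= self.matrix.n):
            raise IndexError(
                f"interval [{self.start}, {self.end}] out of range for n={self.matrix.n}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def submatrix(self) -> np.ndarray:
        """The m x width allele slab (0-based numpy view)."""
        return self.matrix.alleles[:, self.start - 1 : self.end]

    def row_string(self, i: int) -> str:
        """Row ``i`` (1-based) as a string over {0, 1, ?}."""
        row = self.submatrix()[i - 1]
        return "".join("?" if a == MISSING else str(int(a)) for a in row)


def from_strings(rows: Sequence[str], **kwargs) -> HaplotypeMatrix:
    """Build a matrix from equal-length strings over ``{0, 1, ?}``."""
    if not rows:
        raise ConfigError("at least one haplotype row is required")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ConfigError("all haplotype strings must have equal length")
    lut = {"0": 0, "1": 1, "?": MISSING}
    try:
        arr = np.array([[lut[c] for c in r] for r in rows], dtype=np.int8)
    except KeyError as exc:
        raise ConfigError(f"illegal allele character {exc.args[0]!r}") from None
    return HaplotypeMatrix(arr, **kwargs)
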