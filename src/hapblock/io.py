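"""Readers and writers for phased haplotype data and block reports.

Supported inputs:

* HapMap3 phased-haplotype text — header line of column labels, then one
  line per SNP: rsID, base-pair position, one nucleotide per phased
  chromosome.  Loaded transposed (rows = haplotypes) with per-locus
  major/minor coding: the more frequent nucleotide becomes 0, ties break to
  the lexicographically smaller nucleotide.
* Plain allele-matrix text — one line per haplotype over {0, 1, ?}.
* Phased VCF — converted through the allele-matrix path, two haplotype rows
  per sample; unphased genotypes are rejected, not imputed.

Outputs: allele-matrix text, HapMap3-style phased text, and BED / TSV block
reports.  The core uses 1-based inclusive intervals; BED output converts to
0-based half-open at the boundary.
"""

from __future__ import annotations

import os
from typing import IO, Iterable

import numpy as np

from .errors import BiallelicViolationError, ParseError
from .matrix import MISSING, HaplotypeMatrix
from .partition import Segmentation

__all__ = [
    "read_hapmap_phased",
    "write_hapmap_phased",
    "read_allele_matrix",
    "write_allele_matrix",
    "read_phased_vcf",
    "write_blocks",
]

_MISSING_CHARS = {"N", "?", "-", "."}  # missing-call codes in nucleotide input
_NUCLEOTIDES = {"A", "C", "G", "T"}


# ---------------------------------------------------------------------------
# HapMap3 phased text
# ---------------------------------------------------------------------------

def read_hapmap_phased(path: str | os.PathLike) -> HaplotypeMatrix:
    """Read a HapMap3 phased-haplotype text file.

    The file lists SNPs in rows; the matrix is returned transposed so that
    rows are haplotypes.  At each locus the more frequent nucleotide codes
    as 0 and the other as 1 (ties: lexicographically smaller nucleotide
    codes 0); characters outside {A, C, G, T} become MISSING.
    """
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError("empty file", line=1)
        labels = header.split()
        if len(labels) < 3:
            raise ParseError("header must list rsID, position and at least "
                             "one chromosome label", line=1)
        hap_ids = labels[2:]
        n_chrom = len(hap_ids)
        locus_ids: list[str] = []
        positions: list[int] = []
        columns: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2 + n_chrom:
                raise ParseError(
                    f"expected {2 + n_chrom} fields, found {len(parts)}",
                    line=lineno,
                )
            rsid, pos = parts[0], parts[1]
            try:
                positions.append(int(pos))
            except ValueError:
                raise ParseError(f"non-integer position {pos!r}", line=lineno)
            locus_ids.append(rsid)
            chars = [c.upper() for c in parts[2:]]
            observed = sorted({c for c in chars if c in _NUCLEOTIDES})
            if len(observed) > 2:
                raise BiallelicViolationError(
                    f"{len(observed)} distinct alleles {observed} at {rsid}",
                    line=lineno,
                )
            bad = {c for c in chars if c not in _NUCLEOTIDES and c not in _MISSING_CHARS}
            if bad:
                raise ParseError(
                    f"illegal allele character(s) {sorted(bad)} at {rsid}",
                    line=lineno,
                )
            col = np.full(n_chrom, MISSING, dtype=np.int8)
            if observed:
                counts = {a: chars.count(a) for a in observed}
                # majority nucleotide -> 0; ties -> lexicographically smaller
                major = sorted(observed, key=lambda a: (-counts[a], a))[0]
                for idx, c in enumerate(chars):
                    if c in _NUCLEOTIDES:
                        col[idx] = 0 if c == major else 1
            columns.append(col)
    if not columns:
        raise ParseError("no SNP rows in file")
    if any(np.diff(positions) < 0):
        raise ParseError("positions are not sorted ascending")
    alleles = np.stack(columns, axis=1)
    return HaplotypeMatrix(
        alleles,
        row_ids=hap_ids,
        locus_ids=locus_ids,
        positions=np.asarray(positions, dtype=np.int64),
    )


def write_hapmap_phased(mat: HaplotypeMatrix, path: str | os.PathLike) -> None:
    """Write in HapMap3 phased layout, coding allele 0 as A and 1 as G.

    A is lexicographically smaller than G, so a canonically coded matrix
    (per-column MAF ≤ 0.5) round-trips exactly through
    :func:`read_hapmap_phased`.
    """
    lut = {0: "A", 1: "G", MISSING: "N"}
    positions = (
        mat.positions
        if mat.positions is not None
        else (np.arange(mat.n, dtype=np.int64) + 1)
    )
    with open(path, "w") as fh:
        fh.write("rsID position " + " ".join(mat.row_ids) + "\n")
        for j in range(mat.n):
            col = " ".join(lut[int(a)] for a in mat.alleles[:, j])
            fh.write(f"{mat.locus_ids[j]} {positions[j]} {col}\n")


# ---------------------------------------------------------------------------
# plain allele matrix
# ---------------------------------------------------------------------------

def read_allele_matrix(path: str | os.PathLike) -> HaplotypeMatrix:
    """Read one haplotype per line over the alphabet {0, 1, ?}."""
    lut = {"0": 0, "1": 1, "?": MISSING}
    rows: list[list[int]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if width is None:
                width = len(s)
            elif len(s) != width:
                raise ParseError(
                    f"ragged line: {len(s)} characters, expected {width}",
                    line=lineno,
                )
            try:
                rows.append([lut[c] for c in s])
            except KeyError:
                bad = next(c for c in s if c not in lut)
                raise ParseError(f"illegal character {bad!r}", line=lineno)
    if not rows:
        raise ParseError("empty file: no haplotype rows")
    return HaplotypeMatrix(np.asarray(rows, dtype=np.int8))


def write_allele_matrix(mat: HaplotypeMatrix, path: str | os.PathLike) -> None:
    lut = {0: "0", 1: "1", MISSING: "?"}
    with open(path, "w") as fh:
        for i in range(mat.m):
            fh.write("".join(lut[int(a)] for a in mat.alleles[i]) + "\n")


# ---------------------------------------------------------------------------
# phased VCF (via pysam)
# ---------------------------------------------------------------------------

def read_phased_vcf(path: str | os.PathLike) -> HaplotypeMatrix:
    """Load a phased, biallelic VCF as two haplotype rows per sample.

    REF codes as 0 and ALT as 1 (coding does not affect partitioning, which
    depends only on allele identity patterns).  Unphased genotypes and
    multi-allelic records are rejected.
    """
    import pysam

    with pysam.VariantFile(os.fspath(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ParseError("VCF has no samples")
        rows_per_sample: dict[str, list[list[int]]] = {s: [] for s in samples}
        locus_ids: list[str] = []
        positions: list[int] = []
        ploidy: int | None = None
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise BiallelicViolationError(
                    f"record {rec.chrom}:{rec.pos} is not biallelic"
                )
            locus_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            positions.append(rec.pos)
            for s in samples:
                call = rec.samples[s]
                gt = call["GT"]
                if gt is None or any(a is None for a in gt):
                    alleles = [MISSING if a is None else int(a) for a in gt or ()]
                else:
                    alleles = [int(a) for a in gt]
                if len(gt or ()) > 1 and not call.phased:
                    raise ParseError(
                        f"unphased genotype for sample {s} at "
                        f"{rec.chrom}:{rec.pos}; phase the data first"
                    )
                if ploidy is None:
                    ploidy = len(alleles)
                elif len(alleles) != ploidy:
                    raise ParseError(
                        f"inconsistent ploidy at {rec.chrom}:{rec.pos}"
                    )
                rows_per_sample[s].append(alleles)
    if not locus_ids:
        raise ParseError("VCF has no variant records")
    assert ploidy is not None
    arr = np.empty((len(samples) * ploidy, len(locus_ids)), dtype=np.int8)
    row_ids = []
    r = 0
    for s in samples:
        per_locus = np.asarray(rows_per_sample[s], dtype=np.int8)  # (n, ploidy)
        for p in range(ploidy):
            arr[r] = per_locus[:, p]
            row_ids.append(f"{s}_{chr(ord('A') + p)}")
            r += 1
    order = np.argsort(positions, kind="stable")
    return HaplotypeMatrix(
        arr[:, order],
        row_ids=row_ids,
        locus_ids=[locus_ids[i] for i in order],
        positions=np.asarray(positions, dtype=np.int64)[order],
    )


# ---------------------------------------------------------------------------
# block reports
# ---------------------------------------------------------------------------

def _block_rows(seg: Segmentation, mat: HaplotypeMatrix) -> Iterable[tuple]:
    for bid, b in enumerate(seg.blocks, start=1):
        delta = b.delta if b.delta is not None else float("nan")
        n_tag = b.tagsnps.gamma if b.tagsnps is not None else 0
        tag_local = b.tagsnps.loci if b.tagsnps is not None else ()
        tag_global = tuple(b.start + t - 1 for t in tag_local)
        yield bid, b, delta, n_tag, tag_local, tag_global


def write_blocks(
    seg: Segmentation,
    mat: HaplotypeMatrix,
    path: str | os.PathLike,
    format: str = "tsv",
    chrom: str = "hap",
) -> None:
    """Write a segmentation as BED (0-based half-open) or TSV (1-based
    inclusive, with a summary footer)."""
    if format not in {"bed", "tsv"}:
        raise ValueError(f"unknown block format {format!r}")
    with open(path, "w") as fh:
        if format == "bed":
            _write_bed(seg, mat, fh, chrom)
        else:
            _write_tsv(seg, mat, fh)


def _write_bed(seg: Segmentation, mat: HaplotypeMatrix, fh: IO[str], chrom: str) -> None:
    fh.write("#chrom\tstart\tend\tname\tdelta\tn_tagsnps\n")
    for bid, b, delta, n_tag, _, _ in _block_rows(seg, mat):
        fh.write(
            f"{chrom}\t{b.start - 1}\t{b.end}\tblock{bid}\t{delta:.6g}\t{n_tag}\n"
        )


def _write_tsv(seg: Segmentation, mat: HaplotypeMatrix, fh: IO[str]) -> None:
    fh.write(
        "block_id\tstart_snp\tend_snp\tlength\tdelta\tn_tagsnps\t"
        "tagsnps_local\ttagsnps_global\n"
    )
    total_tag = 0
    for bid, b, delta, n_tag, tag_local, tag_global in _block_rows(seg, mat):
        total_tag += n_tag
        fh.write(
            f"{bid}\t{b.start}\t{b.end}\t{b.width}\t{delta:.6g}\t{n_tag}\t"
            f"{','.join(map(str, tag_local)) or '-'}\t"
            f"{','.join(map(str, tag_global)) or '-'}\n"
        )
    nb = seg.k_used
    fh.write(f"# No. of Blocks\t{nb}\n")
    fh.write(f"# Length\t{seg.total_length}\n")
    fh.write(f"# Avg. Length\t{seg.average_length:.6g}\n")
    fh.write(f"# Tag SNP\t{total_tag}\n")


def read_blocks_tsv(path: str | os.PathLike) -> Segmentation:
    """Load the TSV block report back into a bare segmentation."""
    from .partition import Block

    blocks = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("block_id"):
            raise ParseError("not a block TSV report", line=1)
        for lineno, line in enumerate(fh, start=2):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise ParseError("truncated block row", line=lineno)
            blocks.append(
                Block(start=int(parts[1]), end=int(parts[2]), delta=float(parts[4]))
            )
    seg = Segmentation(blocks=blocks)
    seg.validate()
    return seg
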