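"""Synthetic block-structured haplotype matrices with known ground truth.

Each planted block carries a small pool of founder haplotypes with skewed
frequencies; every row copies one founder per block (chosen independently
across blocks, which is what creates a diversity jump across block
boundaries), a configurable fraction of row-segments is replaced by uniform
random noise (these become singleton haplotypes), and finally a fraction of
cells is masked as missing.  Generation is fully deterministic under the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .matrix import MISSING, HaplotypeMatrix
from .partition import Segmentation

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_haplotypes",
    "score_boundary_recovery",
]


@dataclass
class SimConfig:
    """Generator settings.

    ``boundaries`` are internal cut points: a value c plants a block edge
    between columns c and c + 1 (1-based).  When None, cuts are drawn from
    ``mean_block_width``.  ``founder_freqs`` defaults to a geometric profile
    (ratio 1/2) so the leading founders cover well over 80% of rows — the
    regime in which the 80%-coverage block criterion is informative.
    """

    m: int = 30
    n: int = 60
    boundaries: Sequence[int] | None = (20, 40)
    mean_block_width: float | None = None
    founders_per_block: int = 3
    founder_freqs: Sequence[float] | None = None
    singleton_rate: float = 0.05
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ConfigError("m and n must be >= 1")
        for name in ("singleton_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.founders_per_block < 1:
            raise ConfigError("founders_per_block must be >= 1")
        if self.boundaries is not None:
            b = sorted(int(c) for c in self.boundaries)
            if b and not (0 < b[0] and b[-1] < self.n):
                raise ConfigError("boundaries must lie strictly inside 1..n")
            if len(set(b)) != len(b):
                raise ConfigError("duplicate boundary")
            self.boundaries = tuple(b)

    def resolved_freqs(self) -> np.ndarray:
        f = self.founders_per_block
        if self.founder_freqs is None:
            w = 0.5 ** np.arange(f)
        else:
            w = np.asarray(self.founder_freqs, dtype=float)
            if w.size != f or (w < 0).any() or w.sum() <= 0:
                raise ConfigError("founder_freqs must be a non-negative vector "
                                  "of length founders_per_block")
        return w / w.sum()


@dataclass
class SimTruth:
    """Planted structure of one simulated matrix."""

    boundaries: tuple[int, ...]  # internal cut points (1-based, between c and c+1)
    founders: list[np.ndarray]  # per block: (founders_per_block, width) arrays
    assignment: np.ndarray  # (m, n_blocks) founder index; -1 marks a noise row
    block_spans: list[tuple[int, int]] = field(default_factory=list)


def _draw_boundaries(cfg: SimConfig, rng: np.random.Generator) -> tuple[int, ...]:
    if cfg.boundaries is not None:
        return tuple(cfg.boundaries)
    if cfg.mean_block_width is None:
        raise ConfigError("either boundaries or mean_block_width is required")
    cuts, pos = [], 0
    while True:
        width = max(1, int(rng.geometric(1.0 / cfg.mean_block_width)))
        pos += width
        if pos >= cfg.n:
            break
        cuts.append(pos)
    return tuple(cuts)


def simulate_haplotypes(cfg: SimConfig) -> tuple[HaplotypeMatrix, SimTruth]:
    """Draw one matrix and its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    cuts = _draw_boundaries(cfg, rng)
    edges = [0, *cuts, cfg.n]
    spans = [(edges[i] + 1, edges[i + 1]) for i in range(len(edges) - 1)]
    freqs = cfg.resolved_freqs()
    f = cfg.founders_per_block

    alleles = np.empty((cfg.m, cfg.n), dtype=np.int8)
    founders_all: list[np.ndarray] = []
    assignment = np.empty((cfg.m, len(spans)), dtype=np.int64)
    for bi, (s, e) in enumerate(spans):
        width = e - s + 1
        if cfg.boundaries is not None and f > 2**width:
            raise ConfigError(
                f"{f} distinct founders cannot exist in a block of width {width}"
            )
        # randomly drawn narrow blocks cannot host more founders than 2^width
        f_eff = min(f, 2 ** min(width, 30))
        # rejection-sample distinct founder strings
        while True:
            founders = rng.integers(0, 2, size=(f_eff, width)).astype(np.int8)
            if np.unique(founders, axis=0).shape[0] == f_eff:
                break
        founders_all.append(founders)
        w_eff = freqs[:f_eff] / freqs[:f_eff].sum()
        pick = rng.choice(f_eff, size=cfg.m, p=w_eff)
        assignment[:, bi] = pick
        alleles[:, s - 1 : e] = founders[pick]
        noisy = rng.random(cfg.m) < cfg.singleton_rate
        if noisy.any():
            alleles[noisy, s - 1 : e] = rng.integers(
                0, 2, size=(int(noisy.sum()), width)
            ).astype(np.int8)
            assignment[noisy, bi] = -1
    if cfg.missing_rate > 0:
        mask = rng.random((cfg.m, cfg.n)) < cfg.missing_rate
        alleles[mask] = MISSING
    positions = (np.arange(cfg.n, dtype=np.int64) + 1) * 1000
    mat = HaplotypeMatrix(alleles, positions=positions)
    truth = SimTruth(
        boundaries=cuts,
        founders=founders_all,
        assignment=assignment,
        block_spans=spans,
    )
    return mat, truth


def score_boundary_recovery(
    found: Segmentation, truth: SimTruth, tol: int = 0, n: int | None = None
) -> float:
    """Fraction of planted cut points matched by a found cut within ±tol.

    Vacuously 1.0 when no cut was planted (single-block truth).
    """
    if not truth.boundaries:
        return 1.0
    if n is None:
        n = truth.block_spans[-1][1] if truth.block_spans else max(
            b.end for b in found.blocks
        )
    found_cuts = np.asarray(found.cut_points(n), dtype=np.int64)
    hit = 0
    for c in truth.boundaries:
        if found_cuts.size and np.min(np.abs(found_cuts - c)) <= tol:
            hit += 1
    return hit / len(truth.boundaries)
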