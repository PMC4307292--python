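import sys
from pathlib import Path

import numpy as np
import pytest

import hapblock as hb

sys.path.insert(0, str(Path(__file__).parent))  # for `import oracles`


FIG_SAMPLE = ["10001", "11100", "00011", "11110", "00001", "01001"]


@pytest.fixture
def fig_sample_matrix() -> hb.HaplotypeMatrix:
    """8 rows over 5 loci: six distinct strings with the first two
    duplicated; 4 common rows in 2 classes, 4 singletons."""
    return hb.from_strings(FIG_SAMPLE + [FIG_SAMPLE[0], FIG_SAMPLE[1]])


def random_complete_matrix(
    rng: np.random.Generator, m: int, n: int, structured: bool = True
) -> hb.HaplotypeMatrix:
    """Small complete matrix, optionally with crude block structure so that
    feasible intervals of many widths occur."""
    if structured and n >= 4:
        n_blocks = int(rng.integers(1, max(2, n // 4)))
        edges = np.sort(rng.choice(np.arange(1, n), size=n_blocks - 1, replace=False)) if n_blocks > 1 else np.array([], dtype=int)
        spans = np.diff(np.concatenate(([0], edges, [n])))
        max_f = min(5, m, 2 ** int(spans.min()))
        cfg = hb.SimConfig(
            m=m,
            n=n,
            boundaries=edges.tolist(),
            founders_per_block=int(rng.integers(1, max_f + 1)),
            singleton_rate=float(rng.uniform(0, 0.3)),
            missing_rate=0.0,
            seed=int(rng.integers(2**31)),
        )
        return hb.simulate_haplotypes(cfg)[0]
    return hb.HaplotypeMatrix(rng.integers(0, 2, size=(m, n)).astype(np.int8))


def with_missing(mat: hb.HaplotypeMatrix, rng: np.random.Generator, rate: float) -> hb.HaplotypeMatrix:
    a = mat.alleles.copy()
    a[rng.random(a.shape) < rate] = hb.MISSING
    return hb.HaplotypeMatrix(
        a, list(mat.row_ids), list(mat.locus_ids), mat.positions
    )
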