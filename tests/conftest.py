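import numpy as np
import pandas as pd
import pytest

from chromacal.io import GENOME_TARGET


def frag_frame(rows):
    """rows: (chrom, start, end[, genome[, mapq]])"""
    full = []
    for r in rows:
        chrom, start, end = r[:3]
        genome = r[3] if len(r) > 3 else GENOME_TARGET
        mapq = r[4] if len(r) > 4 else 42
        full.append((chrom, start, end, genome, mapq))
    return pd.DataFrame(
        full, columns=["chrom", "start", "end", "genome", "mapq"]
    ).astype({"start": np.int64, "end": np.int64, "mapq": np.int64})


def interval_frame(rows, score=False):
    cols = ["chrom", "start", "end"] + (["score"] if score else [])
    return pd.DataFrame(rows, columns=cols).astype(
        {"start": np.int64, "end": np.int64}
    )


def random_fragments(rng, n, contigs, max_len=300):
    chroms = rng.choice(list(contigs), size=n)
    lengths = np.array([contigs[c] for c in chroms])
    starts = (rng.random(n) * (lengths - max_len)).astype(np.int64)
    ends = starts + rng.integers(50, max_len, size=n)
    return frag_frame(list(zip(chroms, starts, np.minimum(ends, lengths))))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
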