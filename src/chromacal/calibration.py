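"""Spike-in calibration: quality filtering, factor computation, downsampling.

Each sample's calibration factor is the ratio of the smallest spike-in count
across samples to that sample's own spike-in count, so the sample with the
fewest spike-in fragments anchors the group at factor 1 and every other
sample is randomly downsampled toward it. Because the spike-in is added at a
constant amount per cell, equalising spike-in-implied depth puts target-genome
signal on a per-cell scale and preserves genuine global differences between
conditions — which naive library-size normalisation erases.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .io import GENOME_SPIKEIN, GENOME_TARGET


def filter_quality(
    frags: pd.DataFrame, mapq_min: int = 20, dedupe: bool = True
) -> pd.DataFrame:
    """Retain records with MAPQ strictly greater than ``mapq_min``.

    With ``dedupe``, at most one record per (chrom, start, end, genome) is
    kept — "unique" fragments in the deduplicated-coordinates sense.
    """
    out = frags[frags["mapq"] > mapq_min]
    if dedupe:
        out = out.drop_duplicates(subset=["chrom", "start", "end", "genome"])
    return out.reset_index(drop=True)


def spikein_count(frags: pd.DataFrame) -> int:
    return int((frags["genome"] == GENOME_SPIKEIN).sum())


def compute_calibration_factors(
    spikein_counts: Mapping[str, int]
) -> pd.DataFrame:
    """factor_s = min_t(count_t) / count_s; the minimum-count sample gets 1.

    Returns a DataFrame with columns sample, spikein_count, factor.
    """
    for sample, count in spikein_counts.items():
        if count == 0:
            raise ValueError(
                f"sample {sample!r} has no spike-in; cannot calibrate"
            )
    low = min(spikein_counts.values())
    return pd.DataFrame(
        {
            "sample": list(spikein_counts),
            "spikein_count": [spikein_counts[s] for s in spikein_counts],
            "factor": [low / spikein_counts[s] for s in spikein_counts],
        }
    )


def downsample(frags: pd.DataFrame, factor: float, seed: int) -> pd.DataFrame:
    """Keep exactly round(factor * N) target fragments, sampled uniformly
    without replacement; spike-in records are dropped (their job is done).

    Rounding is round-half-to-even; the selection is deterministic under
    ``seed`` and always a subset of the input, in input order.
    """
    if not 0 < factor <= 1:
        raise ValueError(f"factor must be in (0, 1], got {factor}")
    target = frags[frags["genome"] == GENOME_TARGET]
    n = len(target)
    k = round(factor * n)
    if k == n:
        return target.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=k, replace=False))
    return target.iloc[keep].reset_index(drop=True)


def calibrate_experiment(
    samples: Mapping[str, pd.DataFrame],
    mapq_min: int = 20,
    dedupe: bool = True,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Filter, compute factors from spike-in counts, downsample targets.

    Returns (calibrated fragment sets, calibration table). The anchor sample
    (factor 1) passes through unscaled. Samples that should be calibrated in
    separate groups (e.g. different antibodies) are separate calls.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to calibrate")
    filtered = {
        name: filter_quality(df, mapq_min=mapq_min, dedupe=dedupe)
        for name, df in samples.items()
    }
    counts = {name: spikein_count(df) for name, df in filtered.items()}
    table = compute_calibration_factors(counts)
    factors = dict(zip(table["sample"], table["factor"]))
    calibrated = {}
    for i, name in enumerate(sorted(filtered)):
        sub_seed = np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)
        calibrated[name] = downsample(filtered[name], factors[name], int(sub_seed))
    return calibrated, table
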