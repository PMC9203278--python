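"""Global quantification of calibrated signal.

1-kb binned counts and their log2 kernel density, fraction of reads in peaks
(FRiP), repeat-class fractions, base-resolution coverage tracks and replicate
correlation. Fragments are assigned to intervals by their midpoint throughout,
under the 0-based half-open convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, pearsonr


@dataclass
class GenomeBins:
    """Fixed-width bins tiling each contig, with per-bin fragment counts."""

    bin_size: int
    bins: pd.DataFrame  # chrom, start, end, count


@dataclass
class DensityCurve:
    grid: np.ndarray
    density: np.ndarray


def _midpoints(frags: pd.DataFrame) -> np.ndarray:
    return (frags["start"].to_numpy() + frags["end"].to_numpy()) // 2


def make_bins(contigs: Mapping[str, int], bin_size: int = 1000) -> pd.DataFrame:
    """Tile each contig with half-open bins; the last bin may be short."""
    rows = []
    for chrom, length in contigs.items():
        edges = np.arange(0, length, bin_size, dtype=np.int64)
        for s in edges:
            rows.append((chrom, int(s), int(min(s + bin_size, length))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def bin_counts(
    frags: pd.DataFrame, contigs: Mapping[str, int], bin_size: int = 1000
) -> GenomeBins:
    """Count fragment midpoints per bin. Total counted == number of fragments."""
    unknown = set(frags["chrom"]) - set(contigs)
    if unknown:
        raise ValueError(f"fragments on unknown contigs: {sorted(unknown)}")
    bins = make_bins(contigs, bin_size)
    counts = np.zeros(len(bins), dtype=np.int64)
    offsets = {}
    pos = 0
    for chrom, length in contigs.items():
        n_bins = int(np.ceil(length / bin_size)) if length else 0
        offsets[chrom] = pos
        pos += n_bins
    mids = _midpoints(frags)
    for chrom, sub_idx in frags.groupby("chrom", sort=False).indices.items():
        idx = offsets[chrom] + mids[sub_idx] // bin_size
        np.add.at(counts, idx, 1)
    bins = bins.copy()
    bins["count"] = counts
    return GenomeBins(bin_size=bin_size, bins=bins)


def log_density(
    gbins: GenomeBins, pseudocount: float | None = None, gridsize: int = 512
) -> DensityCurve:
    """Gaussian KDE (Silverman bandwidth) of log2 per-bin counts.

    Zero-count bins are excluded by default, since log2(0) is undefined; pass
    a ``pseudocount`` to instead transform log2(count + pseudocount) over all
    bins. The grid spans the data range +- 4 bandwidths so the curve
    integrates to ~1.
    """
    counts = gbins.bins["count"].to_numpy(dtype=float)
    if pseudocount is None:
        counts = counts[counts > 0]
        if len(counts) < 2:
            raise ValueError("need at least 2 nonzero bins for a density")
        x = np.log2(counts)
    else:
        x = np.log2(counts + pseudocount)
    if np.ptp(x) == 0:
        # degenerate: all equal; widen with a token jitter-free bandwidth
        h = max(abs(x[0]) * 1e-3, 1e-3)
        grid = np.linspace(x[0] - 4 * h, x[0] + 4 * h, gridsize)
        dens = np.exp(-0.5 * ((grid - x[0]) / h) ** 2) / (h * np.sqrt(2 * np.pi))
        return DensityCurve(grid=grid, density=dens)
    kde = gaussian_kde(x, bw_method="silverman")
    h = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 4 * h, x.max() + 4 * h, gridsize)
    return DensityCurve(grid=grid, density=kde(grid))


def _assign_midpoints(frags: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask: fragment midpoint falls in any of the (disjoint, sorted)
    intervals."""
    mids = _midpoints(frags)
    hit = np.zeros(len(frags), dtype=bool)
    by_chrom = {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
        for chrom, sub in intervals.groupby("chrom", sort=False)
    }
    chroms = frags["chrom"].to_numpy()
    for chrom, (starts, ends) in by_chrom.items():
        mask = chroms == chrom
        if not mask.any():
            continue
        m = mids[mask]
        idx = np.searchsorted(starts, m, side="right") - 1
        ok = (idx >= 0) & (m < ends[np.clip(idx, 0, len(ends) - 1)])
        hit[np.flatnonzero(mask)[ok]] = True
    return hit


def coalesce(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: sort and merge overlapping or book-ended ones."""
    if len(intervals) == 0:
        return intervals[["chrom", "start", "end"]].copy()
    df = intervals.sort_values(["chrom", "start", "end"], kind="mergesort")
    rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        rows.append((chrom, cur_s, cur_e))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return out.astype({"start": np.int64, "end": np.int64})


def frip(frags: pd.DataFrame, peaks: pd.DataFrame) -> float:
    """Percentage of fragments whose midpoint falls inside any peak."""
    if len(frags) == 0:
        raise ValueError("cannot compute FRiP of an empty fragment set")
    if len(peaks) == 0:
        return 0.0
    hit = _assign_midpoints(frags, coalesce(peaks))
    return 100.0 * hit.sum() / len(frags)


def repeat_class_fractions(
    frags: pd.DataFrame, repeat_annotation: Mapping[str, pd.DataFrame]
) -> dict[str, float]:
    """Per repeat class, the percentage of fragments with midpoints inside it.

    Classes may overlap each other; each is computed independently.
    """
    if len(frags) == 0:
        raise ValueError("empty fragment set")
    return {
        cls: (
            100.0 * _assign_midpoints(frags, coalesce(iv)).sum() / len(frags)
            if len(iv)
            else 0.0
        )
        for cls, iv in repeat_annotation.items()
    }


def bin_correlation(a: GenomeBins, b: GenomeBins) -> float:
    """Pearson correlation of log(1 + count) across identical bin frames."""
    if a.bin_size != b.bin_size or len(a.bins) != len(b.bins):
        raise ValueError("bin frames differ")
    if not (
        a.bins[["chrom", "start", "end"]]
        .reset_index(drop=True)
        .equals(b.bins[["chrom", "start", "end"]].reset_index(drop=True))
    ):
        raise ValueError("bin frames differ")
    x = np.log1p(a.bins["count"].to_numpy(dtype=float))
    y = np.log1p(b.bins["count"].to_numpy(dtype=float))
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in binned counts")
    return float(pearsonr(x, y)[0])


def coverage_track(frags: pd.DataFrame, scale: float = 1.0) -> pd.DataFrame:
    """Base-resolution coverage as maximal constant-value bedGraph intervals.

    Value = scale x number of overlapping fragments; zero-coverage runs are
    omitted. Conservation: sum(value x width) == scale x sum of fragment
    lengths.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    rows = []
    order = sorted(frags["chrom"].unique())
    by_chrom = frags.groupby("chrom", sort=False).indices
    starts_all = frags["start"].to_numpy()
    ends_all = frags["end"].to_numpy()
    for chrom in order:
        idx = by_chrom[chrom]
        edges = np.concatenate([starts_all[idx], ends_all[idx]])
        deltas = np.concatenate(
            [np.ones(len(idx), dtype=np.int64), -np.ones(len(idx), dtype=np.int64)]
        )
        uniq, inv = np.unique(edges, return_inverse=True)
        depth_delta = np.zeros(len(uniq), dtype=np.int64)
        np.add.at(depth_delta, inv, deltas)
        depth = np.cumsum(depth_delta)[:-1]  # coverage on [uniq[i], uniq[i+1])
        for s, e, d in zip(uniq[:-1], uniq[1:], depth):
            if d <= 0:
                continue
            if rows and rows[-1][0] == chrom and rows[-1][2] == int(s) and (
                rows[-1][3] == scale * float(d)
            ):
                rows[-1] = (chrom, rows[-1][1], int(e), rows[-1][3])
            else:
                rows.append((chrom, int(s), int(e), scale * float(d)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return df.astype({"start": np.int64, "end": np.int64, "value": float})
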