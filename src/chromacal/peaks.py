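"""Sparse-enrichment peak calling, peak-set algebra and differential regions.

Peak calling follows the sparse-enrichment idea: candidate peaks are maximal
contiguous runs of positive coverage in a calibrated track, scored by their
area under the coverage curve, and only the top fraction (default 1%) of
blocks by score is retained. Peak sets are then merged (gap < 300 bp),
intersected across replicates, combined across conditions, and screened
against an exclusion list before per-region differential testing.

The differential test is a negative-binomial Wald test on per-region midpoint
counts of calibrated fragments (size factors fixed at 1 — calibration already
equalised depth), with a single dispersion pooled across regions by the method
of moments; with two replicates per condition a per-region dispersion is not
estimable. Regions with BH-adjusted q < alpha are classed toward the condition
with the higher mean; everything else is "common".
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .signal import coalesce

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# peak calling


def call_peaks_sparse(
    track: pd.DataFrame, retain_fraction: float = 0.01
) -> pd.DataFrame:
    """Retain the top-scoring fraction of contiguous positive-coverage blocks.

    ``track`` is a bedGraph frame (chrom, start, end, value). Blocks are
    maximal runs of adjacent intervals with value > 0; the block score is the
    area sum(value x width). Blocks scoring at or above the
    (1 - retain_fraction) quantile of block scores are retained, ties
    included. Returns a peak frame (chrom, start, end, score).
    """
    pos = track[track["value"] > 0]
    if len(pos) == 0:
        raise ValueError("track has no positive coverage; nothing to call")
    blocks = []
    for chrom, sub in pos.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        values = sub["value"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        cur_score = float(values[0]) * (ends[0] - starts[0])
        for s, e, v in zip(starts[1:], ends[1:], values[1:]):
            if s == cur_e:  # adjacent: same block
                cur_e = int(e)
                cur_score += float(v) * (e - s)
            else:
                blocks.append((chrom, cur_s, cur_e, cur_score))
                cur_s, cur_e, cur_score = int(s), int(e), float(v) * (e - s)
        blocks.append((chrom, cur_s, cur_e, cur_score))
    df = pd.DataFrame(blocks, columns=["chrom", "start", "end", "score"])
    threshold = np.quantile(df["score"].to_numpy(), 1.0 - retain_fraction)
    out = df[df["score"] >= threshold]
    return out.reset_index(drop=True).astype({"start": np.int64, "end": np.int64})


def merge_peaks(ps: pd.DataFrame, max_gap: int = 300) -> pd.DataFrame:
    """Transitively merge peaks on the same chrom with gap strictly < max_gap.

    Merged scores are summed. Output is sorted with pairwise gaps >= max_gap.
    """
    if len(ps) == 0:
        return ps.copy()
    df = ps.sort_values(["chrom", "start", "end"], kind="mergesort")
    has_score = "score" in df.columns
    rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        scores = sub["score"].to_numpy() if has_score else np.zeros(len(sub))
        cur_s, cur_e, cur_sc = int(starts[0]), int(ends[0]), float(scores[0])
        for s, e, sc in zip(starts[1:], ends[1:], scores[1:]):
            if s - cur_e < max_gap:
                cur_e = max(cur_e, int(e))
                cur_sc += float(sc)
            else:
                rows.append((chrom, cur_s, cur_e, cur_sc))
                cur_s, cur_e, cur_sc = int(s), int(e), float(sc)
        rows.append((chrom, cur_s, cur_e, cur_sc))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    if not has_score:
        out = out.drop(columns="score")
    return out.astype({"start": np.int64, "end": np.int64})


def _overlaps_any(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Boolean per row of ``a``: overlaps >= 1 bp with any interval of ``b``."""
    hit = np.zeros(len(a), dtype=bool)
    b_by_chrom = {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
        for chrom, sub in coalesce(b).groupby("chrom", sort=False)
    }
    chroms = a["chrom"].to_numpy()
    starts = a["start"].to_numpy()
    ends = a["end"].to_numpy()
    for i in range(len(a)):
        pair = b_by_chrom.get(chroms[i])
        if pair is None:
            continue
        bs, be = pair
        # b is coalesced (sorted, disjoint) so ends are increasing: the last
        # interval starting before a.end is the only overlap candidate
        j = np.searchsorted(bs, ends[i], side="left")
        if j > 0 and be[j - 1] > starts[i]:
            hit[i] = True
    return hit


def intersect_replicates(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Peaks of ``a`` overlapping (>= 1 bp) any peak of ``b``; ``a``'s
    coordinates are retained."""
    if len(a) == 0 or len(b) == 0:
        return a.iloc[0:0].copy()
    return a[_overlaps_any(a, b)].reset_index(drop=True)


def combine_peak_lists(sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate peak lists and coalesce overlaps into their union
    (de-duplication), yielding a sorted, disjoint combined region list."""
    non_empty = [s for s in sets if len(s)]
    if not non_empty:
        return pd.DataFrame(columns=["chrom", "start", "end"]).astype(
            {"start": np.int64, "end": np.int64}
        )
    return coalesce(pd.concat(non_empty, ignore_index=True))


def filter_exclusion(ps: pd.DataFrame, exclusion: pd.DataFrame) -> pd.DataFrame:
    """Remove peaks overlapping any exclusion-list interval entirely."""
    if len(ps) == 0 or len(exclusion) == 0:
        return ps.reset_index(drop=True).copy()
    return ps[~_overlaps_any(ps, exclusion)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# differential regions


def region_counts(
    regions: pd.DataFrame, samples: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Midpoint fragment counts per region (rows) per sample (columns)."""
    regions = regions.sort_values(["chrom", "start"], kind="mergesort").reset_index(
        drop=True
    )
    out = regions[["chrom", "start", "end"]].copy()
    for name, frags in samples.items():
        counts = np.zeros(len(regions), dtype=np.int64)
        by_chrom = {
            chrom: (sub.index.to_numpy(), sub["start"].to_numpy(), sub["end"].to_numpy())
            for chrom, sub in regions.groupby("chrom", sort=False)
        }
        mids = (frags["start"].to_numpy() + frags["end"].to_numpy()) // 2
        chroms = frags["chrom"].to_numpy()
        for chrom, (ridx, rs, re_) in by_chrom.items():
            m = mids[chroms == chrom]
            if len(m) == 0:
                continue
            pos = np.searchsorted(rs, m, side="right") - 1
            ok = (pos >= 0) & (m < re_[np.clip(pos, 0, len(re_) - 1)])
            np.add.at(counts, ridx[pos[ok]], 1)
        out[name] = counts
    return out


def _pooled_dispersion(counts: np.ndarray, groups: list[np.ndarray]) -> float:
    """Method-of-moments NB dispersion pooled across regions and conditions.

    For NB, Var = mu + alpha mu^2, so alpha = sum(s^2 - m) / sum(m^2) over all
    (region, condition) cells with positive mean, floored at 1e-8.
    """
    num = 0.0
    den = 0.0
    for idx in groups:
        sub = counts[:, idx]
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        keep = m > 0
        num += float((s2[keep] - m[keep]).sum())
        den += float((m[keep] ** 2).sum())
    if den == 0:
        return 1e-8
    return max(num / den, 1e-8)


def differential_regions(
    regions: pd.DataFrame,
    samples: Mapping[str, pd.DataFrame],
    design: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Three-way classification of regions from calibrated per-sample counts.

    Per region: log2FC of condition means (pseudocount 1), NB Wald test with
    pooled method-of-moments dispersion, BH correction across regions, and a
    class in {cond1_enriched, cond2_enriched, common} where "common" means
    not significantly enriched in either condition (q >= alpha).
    """
    if len(regions) == 0:
        raise ValueError("empty region list")
    conditions = sorted(set(design.values()))
    if len(conditions) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conditions}")
    cond1, cond2 = conditions
    names = list(samples)
    for cond in conditions:
        if sum(design[n] == cond for n in names) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 samples")

    tbl = region_counts(regions, samples)
    counts = tbl[names].to_numpy(dtype=float)
    g1 = np.array([i for i, n in enumerate(names) if design[n] == cond1])
    g2 = np.array([i for i, n in enumerate(names) if design[n] == cond2])
    disp = _pooled_dispersion(counts, [g1, g2])

    m1 = counts[:, g1].mean(axis=1)
    m2 = counts[:, g2].mean(axis=1)
    log2fc = np.log2(m1 + 1.0) - np.log2(m2 + 1.0)
    # delta method on log2(mean + 1); Var(mean) = (mu + alpha mu^2)/n
    v1 = (m1 + disp * m1**2) / len(g1) / ((m1 + 1.0) ** 2 * LN2**2)
    v2 = (m2 + disp * m2**2) / len(g2) / ((m2 + 1.0) ** 2 * LN2**2)
    se = np.sqrt(v1 + v2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = multipletests(p, method="fdr_bh")[1]

    classes = np.where(
        q < alpha,
        np.where(log2fc > 0, f"{cond1}_enriched", f"{cond2}_enriched"),
        "common",
    )
    out = tbl.copy()
    out[f"mean_{cond1}"] = m1
    out[f"mean_{cond2}"] = m2
    out["log2fc"] = log2fc
    out["p"] = p
    out["q"] = q
    out["region_class"] = classes
    return out


# ---------------------------------------------------------------------------
# gene annotation


def annotate_regions(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_halfwidth: int = 3000,
    marked_gene_dist: int = 10000,
) -> pd.DataFrame:
    """Annotate each region with a promoter flag and its nearest gene by TSS.

    A region is a promoter region if it overlaps [tss - halfwidth,
    tss + halfwidth) of any gene. The nearest gene is the one whose TSS is
    closest (distance 0 if the TSS lies inside the region); it is recorded as
    the region's marked gene only within ``marked_gene_dist``.
    """
    if len(genes) == 0:
        raise ValueError("empty gene list")
    tss = genes["tss"].to_numpy()
    gchrom = genes["chrom"].to_numpy()
    gids = genes["gene_id"].to_numpy()
    rows = []
    for r in regions.itertuples(index=False):
        on_chrom = gchrom == r.chrom
        if not on_chrom.any():
            rows.append((r.chrom, r.start, r.end, False, None, np.nan, None))
            continue
        t = tss[on_chrom]
        ids = gids[on_chrom]
        # distance from region [start, end) to each TSS point
        dist = np.maximum.reduce([r.start - t, t - (r.end - 1), np.zeros(len(t), int)])
        k = int(np.argmin(dist))
        promoter = bool(
            ((r.start < t + promoter_halfwidth) & (r.end > t - promoter_halfwidth)).any()
        )
        marked = ids[k] if dist[k] <= marked_gene_dist else None
        rows.append((r.chrom, r.start, r.end, promoter, ids[k], int(dist[k]), marked))
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "promoter",
            "nearest_gene",
            "tss_distance",
            "marked_gene",
        ],
    )
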