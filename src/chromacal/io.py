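"""Readers and writers for the interval and tabular formats the pipeline touches.

Coordinate convention: 0-based half-open (BED standard) everywhere in memory and
on disk. Fragment sets are plain :class:`pandas.DataFrame` objects with columns
``chrom, start, end, genome, mapq``; bedGraph tracks carry
``chrom, start, end, value``; gene models carry
``gene_id, chrom, start, end, strand, tss``.
"""

from __future__ import annotations

import io as _stdio
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GENOME_TARGET = "target"
GENOME_SPIKEIN = "spikein"

FRAGMENT_COLUMNS = ["chrom", "start", "end", "genome", "mapq"]


class ParseError(ValueError):
    """Malformed line in an input file; message names the offending line."""


def make_genome_map(
    target_contigs: Sequence[str], spikein_contigs: Sequence[str]
) -> dict[str, str]:
    """Build a contig -> genome-tag mapping from two contig lists."""
    overlap = set(target_contigs) & set(spikein_contigs)
    if overlap:
        raise ValueError(f"contigs assigned to both genomes: {sorted(overlap)}")
    gm = {c: GENOME_TARGET for c in target_contigs}
    gm.update({c: GENOME_SPIKEIN for c in spikein_contigs})
    return gm


def fragments_frame(
    chrom, start, end, genome, mapq=None
) -> pd.DataFrame:
    """Assemble a fragment DataFrame, validating the interval invariants."""
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "start": np.asarray(start, dtype=np.int64),
            "end": np.asarray(end, dtype=np.int64),
            "genome": np.asarray(genome, dtype=object),
            "mapq": np.full(len(np.atleast_1d(chrom)), 255, dtype=np.int64)
            if mapq is None
            else np.asarray(mapq, dtype=np.int64),
        }
    )
    _validate_fragments(df)
    return df


def _validate_fragments(df: pd.DataFrame) -> None:
    if len(df) == 0:
        return
    bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])]
    if len(bad):
        row = df.loc[bad[0]]
        raise ValueError(
            f"invalid interval {row['chrom']}:{row['start']}-{row['end']}"
        )
    unknown = set(df["genome"]) - {GENOME_TARGET, GENOME_SPIKEIN}
    if unknown:
        raise ValueError(f"unknown genome tags: {sorted(unknown)}")


def read_fragments(path, genome_map: Mapping[str, str]) -> pd.DataFrame:
    """Read a BED-like fragment file, tagging each record by genome of origin.

    The file is tab-separated with at least three columns
    (chrom, start, end); an optional 5th column is interpreted as MAPQ.
    Records with no MAPQ column are treated as passing any quality filter
    (MAPQ 255). Record order is preserved.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    mapqs: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if start < 0 or start >= end:
                raise ParseError(
                    f"{path}: line {lineno}: start >= end ({start} >= {end})"
                )
            if chrom not in genome_map:
                raise ParseError(
                    f"{path}: line {lineno}: contig {chrom!r} not in genome map"
                )
            mapq = 255
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    mapq = int(fields[4])
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-integer MAPQ {fields[4]!r}"
                    ) from None
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            mapqs.append(mapq)
    genome = [genome_map[c] for c in chroms]
    if not chroms:
        return pd.DataFrame(columns=FRAGMENT_COLUMNS).astype(
            {"start": np.int64, "end": np.int64, "mapq": np.int64}
        )
    return fragments_frame(chroms, starts, ends, genome, mapqs)


def write_fragments(df: pd.DataFrame, path) -> None:
    """Write fragments as BED5 (chrom, start, end, '.', MAPQ)."""
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t.\t{row.mapq}\n")


# ---------------------------------------------------------------------------
# bedGraph


def _check_sorted_disjoint(df: pd.DataFrame) -> None:
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping or unsorted intervals on {chrom}")


def write_bedgraph(track: pd.DataFrame, path) -> None:
    """Write a 4-column bedGraph. Intervals must be sorted and non-overlapping
    within each chromosome (bedGraph forbids overlap)."""
    _check_sorted_disjoint(track)
    with open(path, "w") as fh:
        for row in track.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value!r}\n")


def read_bedgraph(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns")
            try:
                rows.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: malformed bedGraph") from None
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return df.astype({"start": np.int64, "end": np.int64, "value": float})


# ---------------------------------------------------------------------------
# gene annotation


def _tss(start: int, end: int, strand: str) -> int:
    # + genes start transcription at `start`; - genes at the last base, end-1
    return start if strand == "+" else end - 1


def read_gene_annotation(path, fmt: str | None = None) -> pd.DataFrame:
    """Read gene models from BED6 or a minimal GTF (feature == 'gene' rows).

    Returns a DataFrame with columns gene_id, chrom, start, end, strand, tss.
    The TSS is the 5' end of the gene: ``start`` on the + strand, ``end - 1``
    on the - strand (half-open coordinates).
    """
    if fmt is None:
        fmt = "gtf" if str(path).endswith((".gtf", ".gff")) else "bed"
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fmt == "bed":
                if len(fields) < 6:
                    raise ParseError(
                        f"{path}: line {lineno}: BED6 with strand required"
                    )
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                gene_id, strand = fields[3], fields[5]
            else:
                if len(fields) < 9:
                    raise ParseError(f"{path}: line {lineno}: not a GTF row")
                if fields[2] != "gene":
                    continue
                chrom = fields[0]
                start, end = int(fields[3]) - 1, int(fields[4])  # GTF is 1-based
                strand = fields[6]
                gene_id = _gtf_gene_id(fields[8], path, lineno)
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path}: line {lineno}: strand must be + or -, got {strand!r}"
                )
            if start < 0 or start >= end:
                raise ParseError(f"{path}: line {lineno}: invalid gene interval")
            rows.append((gene_id, chrom, start, end, strand, _tss(start, end, strand)))
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"]
    )
    return df.astype({"start": np.int64, "end": np.int64, "tss": np.int64})


def _gtf_gene_id(attributes: str, path, lineno: int) -> str:
    for chunk in attributes.split(";"):
        chunk = chunk.strip()
        if chunk.startswith("gene_id"):
            return chunk.split(None, 1)[1].strip().strip('"')
    raise ParseError(f"{path}: line {lineno}: gene row lacks gene_id attribute")


# ---------------------------------------------------------------------------
# generic TSV helpers


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def frame_to_bedgraph_string(track: pd.DataFrame) -> str:
    buf = _stdio.StringIO()
    for row in track.itertuples(index=False):
        buf.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value!r}\n")
    return buf.getvalue()
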