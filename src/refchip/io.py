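"""Readers/writers for the text formats the pipeline touches and read
counting from coordinate-sorted alignments.

Formats: MACS2 narrowPeak (BED6+4) and BED6 peak files, tab-separated counts
matrices (header row = sample ids, first column = peak names), and the sample
sheet CSV (``sample_id,condition,replicate,alignment_path,peaks_path``).
"""

from __future__ import annotations

import csv
import warnings
from os import PathLike
from pathlib import Path
import numpy as np
import pandas as pd
import pysam

from .containers import CountsMatrix, GenomicInterval, PeakSet, SampleSheet

__all__ = [
    "read_narrowpeak",
    "read_bed",
    "write_bed",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_sample_sheet",
    "write_sample_sheet",
    "count_reads_in_peaks",
]


class PeakFileError(ValueError):
    """Raised for malformed peak files; carries the offending line number."""


def _parse_peak_line(line: str, lineno: int) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise PeakFileError(f"line {lineno}: expected >= 6 tab-separated columns, got {len(fields)}")
    chrom, start_s, end_s, name, score_s, strand = fields[:6]
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise PeakFileError(f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from exc
    if not 0 <= start < end:
        raise PeakFileError(f"line {lineno}: invalid interval [{start}, {end})")
    try:
        score = float(score_s) if score_s not in (".", "") else 0.0
    except ValueError as exc:
        raise PeakFileError(f"line {lineno}: non-numeric score {score_s!r}") from exc
    return GenomicInterval(chrom=chrom, start=start, end=end, name=name, score=score, strand=strand)


def read_narrowpeak(
    path: str | PathLike,
    species_tag: str = "",
    channel: str = "target",
) -> PeakSet:
    """Read a narrowPeak/BED6+ file into a sorted :class:`PeakSet`.

    Coordinates are taken verbatim (0-based half-open). Track/browser/comment
    lines are skipped. No chromosome filtering happens here.
    """
    intervals: list[GenomicInterval] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            intervals.append(_parse_peak_line(line, lineno))
    return PeakSet(intervals, channel=channel, species_tag=species_tag)


#: BED6 and narrowPeak share the first six columns; one reader serves both.
read_bed = read_narrowpeak


def write_bed(peaks: PeakSet, path: str | PathLike) -> None:
    """Write a PeakSet as BED6 (score as integer if exact, else float)."""
    with open(path, "w", encoding="utf-8") as handle:
        for iv in peaks:
            score = int(iv.score) if float(iv.score).is_integer() else iv.score
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


def read_counts_tsv(path: str | PathLike) -> CountsMatrix:
    """Read a peaks-x-samples counts TSV.

    Library totals, when present, are stored in a sidecar comment line
    ``#library_totals<TAB>v1<TAB>v2...`` written by :func:`write_counts_tsv`.
    """
    totals = None
    with open(path, encoding="utf-8") as handle:
        first = handle.readline()
        if first.startswith("#library_totals"):
            totals_fields = first.rstrip("\n").split("\t")[1:]
            frame = pd.read_csv(handle, sep="\t", index_col=0)
            totals = pd.Series([float(v) for v in totals_fields], index=frame.columns)
        else:
            handle.seek(0)
            frame = pd.read_csv(handle, sep="\t", index_col=0)
    values = frame.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: counts matrix contains non-numeric cells")
    # integer-valued columns come back as int64; keep whatever pandas inferred
    return CountsMatrix(frame, library_totals=totals)


def write_counts_tsv(matrix: CountsMatrix, path: str | PathLike) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        if matrix.library_totals is not None:
            vals = "\t".join(repr(float(v)) for v in matrix.library_totals)
            handle.write(f"#library_totals\t{vals}\n")
        matrix.counts.rename_axis("peak").to_csv(handle, sep="\t", lineterminator="\n")


def read_sample_sheet(path: str | PathLike) -> SampleSheet:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path: str | PathLike) -> None:
    sheet.frame.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)


def _five_prime(read: pysam.AlignedSegment) -> int:
    """Strand-aware 5' end of an aligned read (0-based reference position)."""
    return read.reference_end - 1 if read.is_reverse else read.reference_start


def count_reads_in_peaks(
    alignment: str | PathLike,
    peaks: PeakSet,
    min_mapq: int = 15,
    blacklist: PeakSet | None = None,
) -> np.ndarray:
    """Count reads per peak from a coordinate-sorted, indexed BAM/CRAM.

    A read is assigned to a peak when its strand-aware 5' end lies within
    ``[start, end)``; each read contributes at most once per peak (a read
    inside two overlapping peaks counts once in each). Reads with mapping
    quality below ``min_mapq``, unmapped/secondary/supplementary records, and
    reads whose 5' end falls in a blacklist interval are excluded.
    """
    if len(peaks) == 0:
        raise ValueError("peaks must be non-empty")
    path = Path(alignment)
    try:
        bam = pysam.AlignmentFile(str(path), require_index=True)
    except (FileNotFoundError, ValueError, OSError) as exc:
        raise IOError(f"cannot open indexed alignment {path}: {exc}") from exc

    black_by_chrom: dict[str, list[tuple[int, int]]] = {}
    if blacklist is not None:
        for iv in blacklist:
            black_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    counts = np.zeros(len(peaks), dtype=np.int64)
    header_chroms = set(bam.references)
    missing = sorted({iv.chrom for iv in peaks} - header_chroms)
    if missing:
        warnings.warn(
            f"chromosome(s) {missing} absent from alignment header; their peaks get count 0",
            stacklevel=2,
        )
    with bam:
        for i, iv in enumerate(peaks):
            if iv.chrom not in header_chroms:
                continue
            seen: set[str] = set()
            n = 0
            # fetch with slop so reverse reads whose 5' end (rightmost base)
            # is inside the peak are retrieved even when their leftmost
            # position is to the left of the peak start
            for read in bam.fetch(iv.chrom, max(0, iv.start - 1000), iv.end + 1000):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if read.mapping_quality < min_mapq:
                    continue
                pos = _five_prime(read)
                if not iv.start <= pos < iv.end:
                    continue
                if any(s <= pos < e for s, e in black_by_chrom.get(iv.chrom, ())):
                    continue
                if read.query_name in seen:
                    continue
                seen.add(read.query_name)
                n += 1
            counts[i] = n
    return counts
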