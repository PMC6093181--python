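"""Peak-set algebra: species partitioning of combined-genome peaks, the
control-reference distance filter, and consensus peak construction.

The control filter implements the reference-peak cleaning step of
parallel-factor normalization: control-factor peaks lying within a minimum
distance of any target-factor peak are discarded, because overlapping target
signal would make them respond to treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .containers import GenomicInterval, PeakSet

__all__ = [
    "PartitionRule",
    "partition_by_genome",
    "filter_control_peaks",
    "consensus_peaks",
]


@dataclass(frozen=True)
class PartitionRule:
    """Chromosome-prefix -> species mapping (e.g. ``{"dm3_": "Dm", "": "Hs"}``).

    At most one empty prefix is allowed; it is the default species that
    collects chromosomes matching no other prefix.
    """

    prefix_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.prefix_map:
            raise ValueError("prefix_map must be non-empty")
        tags = list(self.prefix_map.values())
        if len(set(self.prefix_map)) != len(self.prefix_map):
            raise ValueError("prefixes must be unique")
        if len(set(tags)) != len(tags):
            raise ValueError("species tags must be unique")

    def species_for(self, chrom: str) -> str | None:
        """Longest-prefix match; None when nothing (not even "") matches."""
        best: str | None = None
        for prefix in self.prefix_map:
            if chrom.startswith(prefix):
                if best is None or len(prefix) > len(best):
                    best = prefix
        return None if best is None else self.prefix_map[best]


def partition_by_genome(peaks: PeakSet, rule: PartitionRule) -> dict[str, PeakSet]:
    """Split combined-genome peaks into one PeakSet per species.

    Every species in the rule appears in the output (possibly empty). Peaks on
    chromosomes matching no prefix raise unless the rule has a default
    (empty-prefix) species.
    """
    buckets: dict[str, list[GenomicInterval]] = {tag: [] for tag in rule.prefix_map.values()}
    unmatched: set[str] = set()
    for iv in peaks:
        tag = rule.species_for(iv.chrom)
        if tag is None:
            unmatched.add(iv.chrom)
        else:
            buckets[tag].append(iv)
    if unmatched:
        raise ValueError(
            f"chromosomes match no prefix and the rule has no default species: {sorted(unmatched)}"
        )
    return {
        tag: PeakSet(ivs, channel=peaks.channel, species_tag=tag)
        for tag, ivs in buckets.items()
    }


def _min_gap_to_targets(
    iv: GenomicInterval, starts: np.ndarray, ends_cummax: np.ndarray
) -> int:
    """Minimum edge-to-edge gap from ``iv`` to target intervals on the same
    chromosome, given their starts (sorted) and the running maximum of their
    ends in start order. The rightmost end among left-neighbours and the first
    start at/after the interval give the two candidate gaps."""
    j = int(np.searchsorted(starts, iv.start))
    # overlap with a right neighbour starting inside [start, end) or a left
    # neighbour extending past start
    if j < starts.size and int(starts[j]) < iv.end:
        return 0
    if j > 0 and int(ends_cummax[j - 1]) > iv.start:
        return 0
    right = int(starts[j]) - iv.end if j < starts.size else None
    left = iv.start - int(ends_cummax[j - 1]) if j > 0 else None
    candidates = [g for g in (left, right) if g is not None]
    return max(min(candidates), 0)


def filter_control_peaks(
    control: PeakSet,
    target: PeakSet,
    min_distance: int = 500,
    anchor: str = "edge",
) -> PeakSet:
    """Keep control peaks farther than ``min_distance`` bp from every target peak.

    Distance is the edge-to-edge gap between half-open intervals (overlapping
    or abutting peaks have distance 0); ``anchor='midpoint'`` measures between
    interval midpoints instead. A control peak exactly ``min_distance`` away
    is removed ("within" is inclusive); peaks on chromosomes with no target
    peaks are retained. Idempotent, and anti-monotone in ``min_distance``.
    """
    if anchor not in ("edge", "midpoint"):
        raise ValueError("anchor must be 'edge' or 'midpoint'")
    targets_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, ivs in target.by_chrom().items():
        starts = np.array([t.start for t in ivs], dtype=np.int64)
        ends = np.array([t.end for t in ivs], dtype=np.int64)
        targets_by_chrom[chrom] = (starts, ends, np.maximum.accumulate(ends))

    kept: list[GenomicInterval] = []
    for iv in control:
        if iv.chrom not in targets_by_chrom:
            kept.append(iv)
            continue
        starts, ends, ends_cummax = targets_by_chrom[iv.chrom]
        if starts.size == 0:
            kept.append(iv)
            continue
        if anchor == "edge":
            gap = _min_gap_to_targets(iv, starts, ends_cummax)
        else:
            mid = (iv.start + iv.end) // 2
            gap = int(np.min(np.abs((starts + ends) // 2 - mid)))
        if gap > min_distance:
            kept.append(iv)
    return PeakSet(kept, channel=control.channel, species_tag=control.species_tag)


def _merge_intervals(ivs: Sequence[GenomicInterval]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping intervals of one chromosome into maximal runs."""
    merged: list[tuple[int, int]] = []
    for iv in sorted(ivs, key=lambda i: (i.start, i.end)):
        if merged and iv.start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], iv.end))
        else:
            merged.append((iv.start, iv.end))
    return merged


def consensus_peaks(
    peaksets: Sequence[PeakSet],
    min_occurrence: int,
    name_prefix: str = "consensus",
) -> PeakSet:
    """Bases covered by >= ``min_occurrence`` input sets, merged into maximal runs.

    Each input set contributes at most 1 to the occurrence count of a base
    (its intervals are merged first), so replicates with internally
    overlapping peaks do not double-count. Output peaks are named
    ``{name_prefix}_{k}`` in genomic order.
    """
    if not peaksets:
        raise ValueError("need at least one peak set")
    if not 1 <= min_occurrence <= len(peaksets):
        raise ValueError(
            f"min_occurrence must be in [1, {len(peaksets)}], got {min_occurrence}"
        )
    chroms = sorted({c for ps in peaksets for c in ps.chroms()})
    channel = peaksets[0].channel
    species = peaksets[0].species_tag
    out: list[GenomicInterval] = []
    k = 0
    for chrom in chroms:
        events: list[tuple[int, int]] = []  # (position, +1/-1)
        for ps in peaksets:
            for start, end in _merge_intervals(ps.by_chrom().get(chrom, [])):
                events.append((start, +1))
                events.append((end, -1))
        events.sort()
        depth = 0
        run_start: int | None = None
        i = 0
        while i < len(events):
            pos = events[i][0]
            # apply all deltas at this position together so abutting
            # intervals (one set's end == another's start) do not split a run
            while i < len(events) and events[i][0] == pos:
                depth += events[i][1]
                i += 1
            if run_start is None and depth >= min_occurrence:
                run_start = pos
            elif run_start is not None and depth < min_occurrence:
                k += 1
                out.append(GenomicInterval(chrom, run_start, pos, f"{name_prefix}_{k}"))
                run_start = None
    return PeakSet(out, channel=channel, species_tag=species)
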