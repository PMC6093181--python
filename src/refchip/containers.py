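"""Core in-memory containers shared by every stage of the pipeline.

All genomic coordinates are BED-style: 0-based, half-open ``[start, end)``.
Peak intensities live in a :class:`CountsMatrix` (peaks x samples, pandas
backed); experimental design lives in a :class:`SampleSheet`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "SampleSheet",
    "CountsMatrix",
    "CHANNELS",
]

#: Recognised factor channels: the antibody target under study, the unchanged
#: internal-control factor (e.g. CTCF or spike-in H2Av) and xenogeneic spike-in.
CHANNELS = ("target", "control", "spike_in")


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A named, scored genomic interval (0-based, half-open).

    ``chrom`` may carry a species prefix such as ``"dm3_"`` when peaks were
    called against a combined multi-species reference.
    """

    chrom: str
    start: int
    end: int
    name: str
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.name!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Edge-to-edge gap in bp to ``other``; 0 if they overlap or abut,
        ``None`` if they lie on different chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.start < other.end and other.start < self.end:
            return 0
        return max(other.start - self.end, self.start - other.end, 0)


class PeakSet:
    """An ordered collection of :class:`GenomicInterval` with channel metadata.

    Intervals are kept sorted by ``(chrom, start, end)``; names must be
    unique. ``channel`` records which antibody/factor the peaks belong to and
    ``species_tag`` the genome they live on (empty for the default species).
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        channel: str = "target",
        species_tag: str = "",
    ) -> None:
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        names = [iv.name for iv in ivs]
        if len(set(names)) != len(names):
            seen: set[str] = set()
            dup = next(n for n in names if n in seen or seen.add(n))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate peak name {dup!r} in PeakSet")
        if channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {channel!r}")
        self.intervals: list[GenomicInterval] = ivs
        self.channel = channel
        self.species_tag = species_tag

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return (
            self.intervals == other.intervals
            and self.channel == other.channel
            and self.species_tag == other.species_tag
        )

    def __repr__(self) -> str:
        return (
            f"PeakSet(n={len(self)}, channel={self.channel!r}, "
            f"species_tag={self.species_tag!r})"
        )

    @property
    def names(self) -> list[str]:
        return [iv.name for iv in self.intervals]

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def subset(self, names: Iterable[str]) -> "PeakSet":
        keep = set(names)
        missing = keep - set(self.names)
        if missing:
            raise KeyError(f"peaks not in set: {sorted(missing)[:5]}")
        return PeakSet(
            (iv for iv in self.intervals if iv.name in keep),
            channel=self.channel,
            species_tag=self.species_tag,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
            }
        )


class SampleSheet:
    """Sample -> condition/replicate assignments driving every contrast."""

    REQUIRED = ("sample_id", "condition", "replicate")
    COLUMNS = ("sample_id", "condition", "replicate", "alignment_path", "peaks_path")

    def __init__(self, frame: pd.DataFrame) -> None:
        frame = frame.copy()
        for col in self.REQUIRED:
            if col not in frame.columns:
                raise ValueError(f"sample sheet missing required column {col!r}")
        for col in ("alignment_path", "peaks_path"):
            if col not in frame.columns:
                frame[col] = ""
            frame[col] = frame[col].fillna("").astype(str)
        frame["sample_id"] = frame["sample_id"].astype(str)
        frame["condition"] = frame["condition"].astype(str)
        frame["replicate"] = frame["replicate"].astype(int)
        if (frame["replicate"] < 1).any():
            raise ValueError("replicate numbers must be positive integers")
        if frame["sample_id"].duplicated().any():
            dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_id(s): {dups}")
        self.frame = frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "SampleSheet":
        return cls(pd.DataFrame.from_records(records))

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def conditions(self) -> list[str]:
        return sorted(self.frame["condition"].unique())

    def samples_for(self, condition: str) -> list[str]:
        sel = self.frame.loc[self.frame["condition"] == condition, "sample_id"]
        if sel.empty:
            raise KeyError(f"no samples with condition {condition!r}")
        return sel.tolist()

    def check_contrast(self, contrast: tuple[str, str]) -> tuple[list[str], list[str]]:
        """Validate a (control_condition, treated_condition) pair and return
        the sample ids for each side."""
        if len(contrast) != 2 or contrast[0] == contrast[1]:
            raise ValueError(f"contrast must be two distinct conditions, got {contrast}")
        return self.samples_for(contrast[0]), self.samples_for(contrast[1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleSheet):
            return NotImplemented
        return self.frame.equals(other.frame)

    def __repr__(self) -> str:
        return f"SampleSheet(n_samples={len(self.frame)}, conditions={self.conditions})"


class CountsMatrix:
    """Non-negative read counts, peaks x samples.

    Counts are integers on ingest but may become non-integer after scaling
    (RPM, coefficient correction with ``rounding='none'``).
    ``library_totals`` optionally carries per-sample total (aligned) read
    counts for depth-based normalization baselines.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        library_totals: pd.Series | dict | None = None,
    ) -> None:
        counts = counts.copy()
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        if counts.index.duplicated().any():
            raise ValueError("duplicate peak names in counts matrix")
        if counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in counts matrix")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if values.size and (np.isnan(values.astype(float)).any()):
            raise ValueError("counts must not contain missing cells")
        if values.size and (values < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        if library_totals is not None:
            library_totals = pd.Series(library_totals, dtype=float)
            library_totals.index = library_totals.index.astype(str)
            missing = set(counts.columns) - set(library_totals.index)
            if missing:
                raise ValueError(f"library_totals missing samples: {sorted(missing)}")
            library_totals = library_totals.loc[counts.columns]
        self.library_totals = library_totals

    @classmethod
    def from_array(
        cls,
        values: np.ndarray,
        peak_names: Sequence[str],
        sample_ids: Sequence[str],
        library_totals: pd.Series | dict | None = None,
    ) -> "CountsMatrix":
        frame = pd.DataFrame(np.asarray(values), index=list(peak_names), columns=list(sample_ids))
        return cls(frame, library_totals=library_totals)

    @property
    def peak_names(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_peaks(self, names: Iterable[str]) -> "CountsMatrix":
        names = list(names)
        missing = set(names) - set(self.counts.index)
        if missing:
            raise KeyError(f"peaks not in matrix: {sorted(missing)[:5]}")
        return CountsMatrix(self.counts.loc[names], library_totals=self.library_totals)

    def copy(self) -> "CountsMatrix":
        return CountsMatrix(
            self.counts.copy(),
            library_totals=None if self.library_totals is None else self.library_totals.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountsMatrix):
            return NotImplemented
        same_counts = self.counts.equals(other.counts)
        if self.library_totals is None or other.library_totals is None:
            return same_counts and (self.library_totals is None) == (other.library_totals is None)
        return same_counts and self.library_totals.equals(other.library_totals)

    def __repr__(self) -> str:
        return f"CountsMatrix(peaks={self.shape[0]}, samples={self.shape[1]})"
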