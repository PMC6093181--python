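"""Synthetic parallel-factor / spike-in ChIP-seq experiments.

The generator emulates the statistical structure the normalization method
assumes: reference peaks (internal-control factor and xenogeneic spike-in)
whose biology does not change between conditions but whose counts carry a
global multiplicative efficiency bias in the treated libraries, and target
peaks of which a configurable fraction undergoes a true (by default
unidirectional loss) change — the regime of a degrader treatment where
genome-wide occupancy of the target factor collapses.

``competition_mode`` reproduces the known spike-in failure mode: when one
antibody is shared between the target and the spike-in species' homolog,
loss of the target frees antibody, inflating spike-in recovery in the
treated condition. Spike-in treated means are multiplied by
``1 + kappa * (1 - R)`` where ``R`` is the treated/control ratio of total
expected target signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .containers import CountsMatrix, GenomicInterval, PeakSet, SampleSheet

__all__ = ["SimulationConfig", "SimulatedExperiment", "generate_experiment", "generate_alignment_fixture"]


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a simulated two-condition parallel-factor experiment.

    Parameters
    ----------
    n_target_peaks, n_control_peaks, n_spikein_peaks : int
        Peaks per channel. Control peaks are numerous (CTCF-like), spike-in
        peaks fewer (a small xenogeneic genome).
    n_replicates : int
        Replicates per condition.
    true_treated_scaling : float
        Global efficiency multiplier applied to every treated library's
        expected counts (all channels); the quantity the normalization
        coefficient must recover as its reciprocal.
    fraction_changed : float
        Fraction of target peaks with a true condition effect.
    effect_mean_log2, effect_sd_log2 : float
        True effects are drawn as ``-|Normal(mean, sd)|`` in log2 units:
        unidirectional loss, mirroring a receptor-degrader treatment.
    mean_median, mean_sdlog : float
        Per-peak expected counts are lognormal with this median and
        log-scale (natural) standard deviation.
    dispersion : float
        NB dispersion alpha; ``var = mu + alpha * mu^2``.
    competition_mode : bool
        Enable the antibody-competition spike-in artefact.
    competition_kappa : float
        Strength of the artefact.
    seed : int
        Mandatory RNG seed; the run is a pure function of the config.
    """

    n_target_peaks: int = 10_000
    n_control_peaks: int = 50_000
    n_spikein_peaks: int = 2_000
    n_replicates: int = 3
    true_treated_scaling: float = 0.8
    fraction_changed: float = 0.5
    effect_mean_log2: float = 2.0
    effect_sd_log2: float = 0.5
    mean_median: float = 100.0
    mean_sdlog: float = 0.5
    dispersion: float = 0.05
    competition_mode: bool = False
    competition_kappa: float = 1.0
    seed: int | None = None
    peak_width: int = 400
    peak_spacing: int = 1_000
    spikein_prefix: str = "dm3_"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_target_peaks", "n_control_peaks", "n_spikein_peaks", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.fraction_changed <= 1.0:
            raise ValueError("fraction_changed must be in [0, 1]")
        for name in ("true_treated_scaling", "mean_median", "mean_sdlog", "dispersion"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimulatedExperiment:
    """Bundle returned by :func:`generate_experiment`."""

    counts: CountsMatrix
    peaks_target: PeakSet
    peaks_control: PeakSet
    peaks_spikein: PeakSet
    sheet: SampleSheet
    truth: pd.DataFrame  # peak (index), channel, true_log2fc
    config: SimulationConfig

    @property
    def control_peak_names(self) -> list[str]:
        return self.peaks_control.names

    @property
    def target_peak_names(self) -> list[str]:
        return self.peaks_target.names

    def channels(self) -> pd.Series:
        return self.truth["channel"]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB with var = mu + alpha mu^2 via the gamma-Poisson mixture."""
    shape = 1.0 / alpha
    lam = rng.gamma(shape, np.asarray(mean, dtype=float) * alpha)
    return rng.poisson(lam)


def _tiling_peaks(
    n: int, prefix: str, chrom: str, width: int, spacing: int, channel: str, species: str
) -> PeakSet:
    ivs = [
        GenomicInterval(chrom, 1_000 + i * spacing, 1_000 + i * spacing + width, f"{prefix}_{i + 1}")
        for i in range(n)
    ]
    return PeakSet(ivs, channel=channel, species_tag=species)


def generate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Draw a full synthetic experiment (counts, peaks, sheet, truth table).

    Expected counts: control condition ``mu_i``; treated condition
    ``s* . mu_i . 2**lfc_i`` where ``lfc_i`` is zero for control/spike-in
    peaks and for unchanged target peaks. Counts are NB draws around those
    means, independent across peaks and samples. Peak coordinates are valid,
    non-overlapping BED intervals on synthetic chromosomes (target on chr1,
    control on chr2, spike-in on a prefixed chromosome).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_t, n_c, n_s = cfg.n_target_peaks, cfg.n_control_peaks, cfg.n_spikein_peaks

    peaks_target = _tiling_peaks(n_t, "target", "chr1", cfg.peak_width, cfg.peak_spacing, "target", "")
    peaks_control = _tiling_peaks(n_c, "ctrl", "chr2", cfg.peak_width, cfg.peak_spacing, "control", "")
    peaks_spikein = _tiling_peaks(
        n_s, "spike", f"{cfg.spikein_prefix}chr2L", cfg.peak_width, cfg.peak_spacing, "spike_in", "Dm"
    )

    sdlog = cfg.mean_sdlog
    mu_t = cfg.mean_median * np.exp(rng.normal(0.0, sdlog, n_t))
    mu_c = cfg.mean_median * np.exp(rng.normal(0.0, sdlog, n_c))
    mu_s = cfg.mean_median * np.exp(rng.normal(0.0, sdlog, n_s))

    lfc_t = np.zeros(n_t)
    n_changed = int(round(cfg.fraction_changed * n_t))
    if n_changed:
        changed_idx = rng.choice(n_t, size=n_changed, replace=False)
        lfc_t[changed_idx] = -np.abs(
            rng.normal(cfg.effect_mean_log2, cfg.effect_sd_log2, n_changed)
        )

    s_star = cfg.true_treated_scaling
    treated_mu_t = mu_t * (2.0**lfc_t)
    spike_factor = 1.0
    if cfg.competition_mode:
        # relative target signal surviving treatment drives antibody release
        r = float(treated_mu_t.sum() / mu_t.sum())
        spike_factor = 1.0 + cfg.competition_kappa * (1.0 - r)

    names = peaks_target.names + peaks_control.names + peaks_spikein.names
    mu_all = np.concatenate([mu_t, mu_c, mu_s])
    trt_mu_all = np.concatenate([s_star * treated_mu_t, s_star * mu_c, s_star * spike_factor * mu_s])

    n_rep = cfg.n_replicates
    cols: dict[str, np.ndarray] = {}
    records = []
    for r_i in range(1, n_rep + 1):
        sid = f"ctrl_rep{r_i}"
        cols[sid] = _nb_draw(rng, mu_all, cfg.dispersion)
        records.append({"sample_id": sid, "condition": "control", "replicate": r_i})
    for r_i in range(1, n_rep + 1):
        sid = f"trt_rep{r_i}"
        cols[sid] = _nb_draw(rng, trt_mu_all, cfg.dispersion)
        records.append({"sample_id": sid, "condition": "treated", "replicate": r_i})

    counts = CountsMatrix(pd.DataFrame(cols, index=names))
    sheet = SampleSheet.from_records(records)
    truth = pd.DataFrame(
        {
            "channel": ["target"] * n_t + ["control"] * n_c + ["spike_in"] * n_s,
            "true_log2fc": np.concatenate([lfc_t, np.zeros(n_c), np.zeros(n_s)]),
        },
        index=pd.Index(names, name="peak"),
    )
    return SimulatedExperiment(
        counts=counts,
        peaks_target=peaks_target,
        peaks_control=peaks_control,
        peaks_spikein=peaks_spikein,
        sheet=sheet,
        truth=truth,
        config=cfg,
    )


def generate_alignment_fixture(
    peaks: PeakSet,
    peak_counts: Sequence[int] | np.ndarray,
    out_path: str | PathLike,
    read_length: int = 50,
    background_reads: int = 0,
    seed: int = 0,
    mapq: int = 60,
) -> Path:
    """Write a sorted, indexed BAM whose 5'-end-in-peak counts are exact.

    Per peak, exactly the requested number of single-end reads is emitted
    with strand drawn at random and the strand-aware 5' end uniform inside
    ``[start, end)``; reads longer than the remaining room keep their 5' end
    inside the peak regardless (the alignment may extend past the peak).
    ``background_reads`` reads per chromosome are placed with 5' ends outside
    every peak. Returns the BAM path (index written alongside).
    """
    counts = np.asarray(peak_counts, dtype=int)
    if counts.shape != (len(peaks),):
        raise ValueError("peak_counts must have one entry per peak")
    if (counts < 0).any():
        raise ValueError("peak_counts must be non-negative")
    rng = np.random.default_rng(seed)
    out_path = Path(out_path)

    chroms = peaks.chroms()
    by_chrom = peaks.by_chrom()
    chrom_len = {c: max(iv.end for iv in by_chrom[c]) + 10_000 for c in chroms}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": chrom_len[c]} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}

    reads: list[tuple[int, int, bool, str]] = []  # (tid, pos, is_reverse, name)
    serial = 0
    for iv, n in zip(peaks, counts):
        for _ in range(int(n)):
            serial += 1
            five = int(rng.integers(iv.start, iv.end))
            reverse = bool(rng.integers(0, 2)) and five >= read_length - 1
            pos = five - (read_length - 1) if reverse else five
            reads.append((tid[iv.chrom], pos, reverse, f"peak_read_{serial}"))
    for chrom in chroms:
        spans = [(iv.start, iv.end) for iv in by_chrom[chrom]]
        placed = 0
        while placed < background_reads:
            serial += 1
            five = int(rng.integers(0, chrom_len[chrom] - read_length))
            if any(s <= five < e for s, e in spans):
                continue
            reads.append((tid[chrom], five, False, f"bg_read_{serial}"))
            placed += 1

    reads.sort(key=lambda r: (r[0], r[1]))
    with pysam.AlignmentFile(str(out_path), "wb", header=header) as bam:
        for t, pos, reverse, name in reads:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = name
            a.query_sequence = "A" * read_length
            a.reference_id = t
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigarstring = f"{read_length}M"
            a.flag = 16 if reverse else 0
            bam.write(a)
    pysam.index(str(out_path))
    return out_path
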