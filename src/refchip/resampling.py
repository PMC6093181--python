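"""Subsampling stability of the normalization coefficient, and
cross-normalization of a single-factor experiment onto a parallel-factor one.

The stability analysis answers a design question: how many reference peaks
does the coefficient actually need?  Control peaks are subsampled without
replacement at a grid of fractions, the coefficient recomputed on each draw,
and the relative error versus the full-set coefficient summarised per
fraction.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CountsMatrix, SampleSheet
from .normalize import normalization_coefficient

__all__ = ["subsample_coefficient_stability", "cross_normalize"]


def subsample_coefficient_stability(
    matrix: CountsMatrix,
    control_peaks: Sequence[str],
    sheet: SampleSheet,
    contrast: tuple[str, str],
    fractions: Sequence[float],
    n_reps: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Stability report of the coefficient under control-peak subsampling.

    For each fraction ``f``, draws ``ceil(f * N)`` control peaks uniformly
    without replacement ``n_reps`` times, recomputes the coefficient on the
    draw and records ``rel_err = c_sub / c_full - 1``. One RNG stream per
    (fraction, repetition) is derived from the master seed, so results do not
    depend on evaluation order. Returns one row per fraction with columns
    ``fraction, n_peaks, n_reps, median_abs_rel_err, max_abs_rel_err``.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    control = list(control_peaks)
    n = len(control)
    sizes = {}
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"fractions must lie in (0, 1], got {f}")
        k = int(np.ceil(f * n))
        if k < 2:
            raise ValueError(f"fraction {f} yields {k} < 2 control peaks")
        sizes[f] = k

    c_full = normalization_coefficient(matrix, control, sheet, contrast).coefficient
    control_arr = np.array(control, dtype=object)
    rows = []
    for f in fractions:
        k = sizes[f]
        f_key = int(round(f * 1e9))  # stream keyed by fraction value, not position
        errs = np.empty(n_reps)
        for rep in range(n_reps):
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(f_key, rep)))
            idx = rng.choice(n, size=k, replace=False)
            c_sub = normalization_coefficient(
                matrix, control_arr[idx].tolist(), sheet, contrast
            ).coefficient
            errs[rep] = c_sub / c_full - 1.0
        rows.append(
            {
                "fraction": f,
                "n_peaks": k,
                "n_reps": n_reps,
                "median_abs_rel_err": float(np.median(np.abs(errs))),
                "max_abs_rel_err": float(np.max(np.abs(errs))),
            }
        )
    return pd.DataFrame(rows)


def cross_normalize(
    single_ma: pd.DataFrame,
    parallel_ma: pd.DataFrame,
    matched_peaks: Iterable[str] | Mapping[str, str],
) -> dict:
    """Transfer a parallel-factor normalization to a single-factor experiment.

    ``matched_peaks`` names consensus peaks present in both experiments'
    MA tables (or maps single-experiment names to parallel-experiment
    names); they must already be clear of the control factor's sites.  The
    per-peak discrepancy ``delta_i = M_single(i) - M_parallel(i)`` is
    summarised by its median, and the single experiment's treated condition
    is corrected by the multiplicative constant ``2**(-median delta)``; after
    applying it the median discrepancy is zero.

    Returns ``{"scale", "median_delta", "n_matched", "delta"}``.
    """
    if isinstance(matched_peaks, Mapping):
        pairs = list(matched_peaks.items())
    else:
        pairs = [(name, name) for name in matched_peaks]
    if len(pairs) < 2:
        raise ValueError("need >= 2 matched peaks")
    missing_s = [s for s, _ in pairs if s not in single_ma.index]
    missing_p = [p for _, p in pairs if p not in parallel_ma.index]
    if missing_s or missing_p:
        raise KeyError(
            f"matched peaks absent: single={missing_s[:5]}, parallel={missing_p[:5]}"
        )
    delta = pd.Series(
        {
            s: float(single_ma.at[s, "M"] - parallel_ma.at[p, "M"])
            for s, p in pairs
        },
        name="delta",
    )
    median_delta = float(delta.median())
    return {
        "scale": float(2.0 ** (-median_delta)),
        "median_delta": median_delta,
        "n_matched": len(pairs),
        "delta": delta,
    }
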