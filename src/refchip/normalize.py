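"""Normalization core: RPM baselines, control-peak size factors, the
regression normalization coefficient, MA transformation and control-anchored
log-fold-change correction.

The central idea: counts in reference peaks that are biologically unchanged
between conditions (parallel-factor CTCF peaks, or spike-in H2Av peaks)
isolate the systematic between-sample efficiency bias. Plotting the mean
treated count against the mean control count over those reference peaks and
fitting ``y = m * x`` through the origin, the absence of bias corresponds to
gradient 1. The normalization coefficient ``c = 1/m`` is the constant that,
multiplied into the treated condition's counts, restores gradient 1; it is
then applied unchanged to the target-factor counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import CountsMatrix, SampleSheet

__all__ = [
    "SizeFactors",
    "NormalizationResult",
    "normalize_rpm",
    "control_size_factors",
    "normalization_coefficient",
    "apply_coefficient",
    "ma_transform",
    "lfc_fit_correction",
    "RPMScaler",
    "ControlSizeFactorNormalizer",
    "RegressionNormalizer",
]

RPM_MODES = ("reads_in_peaks", "total_reads", "aligned_reads")


@dataclass(frozen=True)
class SizeFactors:
    """Per-sample positive scale factors, geometric mean 1 by convention."""

    factors: pd.Series
    method: str

    def __post_init__(self) -> None:
        vals = self.factors.to_numpy(dtype=float)
        if (vals <= 0).any():
            raise ValueError("size factors must be positive")
        gm = float(np.exp(np.mean(np.log(vals))))
        if abs(gm - 1.0) > 1e-12:
            raise ValueError(f"size factors must have geometric mean 1, got {gm}")

    def __getitem__(self, sample_id: str) -> float:
        return float(self.factors[sample_id])

    @classmethod
    def identity(cls, sample_ids: Sequence[str], method: str = "identity") -> "SizeFactors":
        return cls(pd.Series(1.0, index=list(sample_ids)), method=method)

    @classmethod
    def from_raw(cls, raw: pd.Series, method: str) -> "SizeFactors":
        """Rescale arbitrary positive per-sample scales to geometric mean 1."""
        vals = raw.to_numpy(dtype=float)
        if (vals <= 0).any() or np.isnan(vals).any():
            raise ValueError(f"cannot form size factors from {raw.to_dict()}")
        gm = np.exp(np.mean(np.log(vals)))
        return cls(raw / gm, method=method)


@dataclass(frozen=True)
class NormalizationResult:
    """Outcome of the through-origin regression on reference peaks.

    ``coefficient`` multiplies the treated condition's counts; it is the
    reciprocal of the fitted ``slope``. ``residual_se`` is the standard error
    of the through-origin fit residuals, a scale diagnostic for the fit.
    """

    coefficient: float
    slope: float
    n_control_peaks: int
    residual_se: float

    def __post_init__(self) -> None:
        if not self.coefficient > 0:
            raise ValueError("coefficient must be positive")
        if abs(self.coefficient * self.slope - 1.0) > 1e-9:
            raise ValueError("coefficient must equal 1/slope")


def normalize_rpm(matrix: CountsMatrix, mode: str = "reads_in_peaks") -> CountsMatrix:
    """Reads-per-million baseline: each column divided by its total, x 1e6.

    ``reads_in_peaks`` uses the column sums of the matrix itself;
    ``total_reads``/``aligned_reads`` use ``matrix.library_totals`` (whichever
    definition the user loaded there). Provided as the conventional baseline
    the reference-peak methods are compared against, not as a recommendation.
    """
    if mode not in RPM_MODES:
        raise ValueError(f"mode must be one of {RPM_MODES}, got {mode!r}")
    if mode == "reads_in_peaks":
        totals = matrix.counts.sum(axis=0).astype(float)
    else:
        if matrix.library_totals is None:
            raise ValueError(f"mode={mode!r} requires library_totals on the matrix")
        totals = matrix.library_totals.astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero/negative totals for sample(s) {bad}")
    scaled = matrix.counts / totals * 1e6
    return CountsMatrix(scaled, library_totals=matrix.library_totals)


def control_size_factors(
    matrix: CountsMatrix,
    control_peaks: Iterable[str],
    method: str = "median_ratio",
) -> SizeFactors:
    """Per-sample size factors estimated from control-peak counts only.

    ``sum``: factors proportional to each sample's total count over control
    peaks. ``median_ratio``: DESeq2-style — per control peak, the ratio of
    each sample's count to the peak's geometric mean across samples; the
    factor is the median ratio over control peaks with all-positive counts.
    Either way the factors are rescaled to geometric mean 1 and then apply to
    ALL peaks of the experiment.
    """
    names = list(control_peaks)
    if not names:
        raise ValueError("control peak subset must be non-empty")
    sub = matrix.subset_peaks(names).counts.to_numpy(dtype=float)
    samples = matrix.sample_ids
    if method == "sum":
        sums = sub.sum(axis=0)
        if (sums <= 0).any():
            bad = [s for s, v in zip(samples, sums) if v <= 0]
            raise ValueError(f"sample(s) with zero control-peak counts: {bad}")
        return SizeFactors.from_raw(pd.Series(sums, index=samples), method="sum")
    if method == "median_ratio":
        positive = (sub > 0).all(axis=1)
        if not positive.any():
            raise ValueError("median_ratio needs >=1 control peak with all-positive counts")
        sub = sub[positive]
        log_geomeans = np.mean(np.log(sub), axis=1)
        ratios = sub / np.exp(log_geomeans)[:, None]
        med = np.median(ratios, axis=0)
        if (med <= 0).any():
            bad = [s for s, v in zip(samples, med) if v <= 0]
            raise ValueError(f"zero median ratio for sample(s) {bad}")
        return SizeFactors.from_raw(pd.Series(med, index=samples), method="median_ratio")
    raise ValueError(f"method must be 'sum' or 'median_ratio', got {method!r}")


def _condition_means(
    matrix: CountsMatrix,
    sheet: SampleSheet,
    contrast: tuple[str, str],
    peak_names: Sequence[str] | None = None,
    size_factors: SizeFactors | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-peak mean (optionally size-factor-normalized) counts for the
    control-condition and treated-condition replicates of a contrast."""
    ctrl_samples, trt_samples = sheet.check_contrast(contrast)
    counts = matrix.counts if peak_names is None else matrix.subset_peaks(list(peak_names)).counts
    missing = (set(ctrl_samples) | set(trt_samples)) - set(matrix.sample_ids)
    if missing:
        raise KeyError(f"sheet samples absent from matrix: {sorted(missing)}")
    vals = counts.astype(float)
    if size_factors is not None:
        vals = vals / size_factors.factors[vals.columns]
    x = vals[ctrl_samples].mean(axis=1).to_numpy()
    y = vals[trt_samples].mean(axis=1).to_numpy()
    return x, y


def _through_origin_slope(x: np.ndarray, y: np.ndarray) -> float:
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValueError("all control-condition means are zero; cannot fit slope")
    return float(np.dot(x, y)) / sxx


def normalization_coefficient(
    matrix: CountsMatrix,
    control_peaks: Iterable[str],
    sheet: SampleSheet,
    contrast: tuple[str, str],
    fit_space: str = "linear",
    pseudocount: float = 0.5,
) -> NormalizationResult:
    """Estimate the between-condition normalization coefficient on reference peaks.

    For each control peak, ``x`` is the mean count over the control
    condition's replicates and ``y`` the mean over the treated condition's.
    The default fit is least squares through the origin in linear count space
    (``m = sum(x*y)/sum(x^2)``) as a single multiplicative bias cannot carry
    an intercept; ``fit_space='log'`` instead estimates the bias as the mean
    log2 ratio, ``m = 2**mean(log2((y+pc)/(x+pc)))``, which downweights
    high-count peaks. Returns ``c = 1/m``: multiplying the treated counts by
    ``c`` and refitting restores gradient 1 exactly (before any rounding).
    """
    names = list(control_peaks)
    if len(names) < 2:
        raise ValueError("need >= 2 control peaks to fit the coefficient")
    x, y = _condition_means(matrix, sheet, contrast, peak_names=names)
    if fit_space == "linear":
        m = _through_origin_slope(x, y)
    elif fit_space == "log":
        m = float(2.0 ** np.mean(np.log2((y + pseudocount) / (x + pseudocount))))
    else:
        raise ValueError("fit_space must be 'linear' or 'log'")
    if m <= 0:
        raise ValueError("fitted slope is not positive (all treated counts zero?)")
    resid = y - m * x
    residual_se = float(np.sqrt(np.sum(resid**2) / max(len(names) - 1, 1)))
    return NormalizationResult(
        coefficient=1.0 / m,
        slope=m,
        n_control_peaks=len(names),
        residual_se=residual_se,
    )


def _round_half_away(values: np.ndarray) -> np.ndarray:
    return np.sign(values) * np.floor(np.abs(values) + 0.5)


def apply_coefficient(
    matrix: CountsMatrix,
    result: NormalizationResult,
    treated_samples: Sequence[str],
    rounding: str = "none",
) -> CountsMatrix:
    """Multiply the treated samples' columns by the coefficient.

    ``rounding='nearest_int'`` rounds half away from zero to keep the matrix
    valid for integer count models; other columns are untouched.
    """
    missing = set(treated_samples) - set(matrix.sample_ids)
    if missing:
        raise KeyError(f"treated samples absent from matrix: {sorted(missing)}")
    if rounding not in ("none", "nearest_int"):
        raise ValueError("rounding must be 'none' or 'nearest_int'")
    out = matrix.counts.astype(float).copy()
    scaled = out[list(treated_samples)] * result.coefficient
    if rounding == "nearest_int":
        scaled = _round_half_away(scaled.to_numpy())
    out[list(treated_samples)] = scaled
    return CountsMatrix(out, library_totals=matrix.library_totals)


def ma_transform(
    matrix: CountsMatrix,
    factors: SizeFactors,
    sheet: SampleSheet,
    contrast: tuple[str, str],
    pseudocount: float = 0.5,
    peak_channels: Mapping[str, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Per-peak MA table: A = mean log2 intensity, M = log2 fold-change.

    Counts are first divided by the per-sample size factors, then averaged
    within condition.  ``A = log2((mean_ctrl + mean_trt)/2 + pc)`` and
    ``M = log2((mean_trt + pc)/(mean_ctrl + pc))``; the pseudocount keeps
    both finite at zero counts.  ``peak_channels`` labels each row (target /
    control / spike_in) for downstream channel-aware fits.
    """
    if not pseudocount > 0:
        raise ValueError("pseudocount must be positive")
    x, y = _condition_means(matrix, sheet, contrast, size_factors=factors)
    a = np.log2((x + y) / 2.0 + pseudocount)
    m = np.log2((y + pseudocount) / (x + pseudocount))
    table = pd.DataFrame({"A": a, "M": m}, index=matrix.counts.index)
    if peak_channels is None:
        table["channel"] = "target"
    else:
        chan = pd.Series(peak_channels)
        table["channel"] = chan.reindex(table.index).fillna("target")
    return table


def lfc_fit_correction(
    table: pd.DataFrame,
    control_channel: str = "control",
    fit: str = "linear",
) -> pd.DataFrame:
    """Anchor log2 fold-changes to the unchanged reference channel.

    Fits M on A by ordinary least squares (intercept + slope; or
    ``fit='constant'`` for an intercept-only fit) over rows of the control
    channel, then subtracts the fitted line from every row's M. After the
    correction the control rows' M has mean zero.
    """
    ctrl = table.loc[table["channel"] == control_channel]
    if len(ctrl) < 2:
        raise ValueError("need >= 2 control-channel rows for the fit")
    a_ctrl = ctrl["A"].to_numpy(dtype=float)
    m_ctrl = ctrl["M"].to_numpy(dtype=float)
    if fit == "linear":
        if np.ptp(a_ctrl) == 0:
            raise ValueError("control-channel A values have zero variance; use fit='constant'")
        design = np.column_stack([np.ones_like(a_ctrl), a_ctrl])
        (b0, b1), *_ = np.linalg.lstsq(design, m_ctrl, rcond=None)
    elif fit == "constant":
        b0, b1 = float(np.mean(m_ctrl)), 0.0
    else:
        raise ValueError("fit must be 'linear' or 'constant'")
    out = table.copy()
    out["M"] = table["M"] - (b0 + b1 * table["A"].to_numpy(dtype=float))
    return out


# --------------------------------------------------------------------------
# scikit-learn style estimators (thin stateful layers over the functions)
# --------------------------------------------------------------------------


def _as_counts(X: CountsMatrix | pd.DataFrame) -> CountsMatrix:
    return X if isinstance(X, CountsMatrix) else CountsMatrix(pd.DataFrame(X))


class RPMScaler(TransformerMixin, BaseEstimator):
    """Reads-per-million column scaling (sklearn transformer).

    Parameters
    ----------
    mode : {'reads_in_peaks', 'total_reads', 'aligned_reads'}
        Which per-sample total divides each column.
    """

    def __init__(self, mode: str = "reads_in_peaks"):
        self.mode = mode

    def fit(self, X: CountsMatrix | pd.DataFrame, y=None):
        matrix = _as_counts(X)
        if self.mode == "reads_in_peaks":
            self.totals_ = matrix.counts.sum(axis=0).astype(float)
        else:
            if matrix.library_totals is None:
                raise ValueError(f"mode={self.mode!r} requires library_totals")
            self.totals_ = matrix.library_totals.astype(float)
        self.n_features_in_ = matrix.shape[1]
        return self

    def transform(self, X: CountsMatrix | pd.DataFrame) -> CountsMatrix:
        return normalize_rpm(_as_counts(X), mode=self.mode)


class ControlSizeFactorNormalizer(TransformerMixin, BaseEstimator):
    """Size-factor normalization driven by control/reference peaks.

    ``fit`` estimates per-sample factors from the control-peak rows of the
    matrix; ``transform`` divides every column (all peaks) by its factor.

    Attributes
    ----------
    size_factors_ : pandas.Series
        Fitted per-sample factors, geometric mean 1.
    """

    def __init__(self, control_peaks: Sequence[str] = (), method: str = "median_ratio"):
        self.control_peaks = control_peaks
        self.method = method

    def fit(self, X: CountsMatrix | pd.DataFrame, y=None):
        matrix = _as_counts(X)
        result = control_size_factors(matrix, self.control_peaks, method=self.method)
        self.size_factors_ = result.factors
        self.result_ = result
        self.n_features_in_ = matrix.shape[1]
        return self

    def transform(self, X: CountsMatrix | pd.DataFrame) -> CountsMatrix:
        matrix = _as_counts(X)
        scaled = matrix.counts.astype(float) / self.size_factors_[matrix.counts.columns]
        return CountsMatrix(scaled, library_totals=matrix.library_totals)


class RegressionNormalizer(TransformerMixin, BaseEstimator):
    """Between-condition coefficient normalization (sklearn transformer).

    ``fit`` regresses treated on control replicate means over the reference
    peaks, through the origin; ``transform`` multiplies the treated samples'
    columns by the reciprocal slope.

    Attributes
    ----------
    slope_ : float
        Fitted through-origin gradient of treated vs control means.
    coefficient_ : float
        ``1/slope_``; the multiplier applied to the treated condition.
    n_control_peaks_ : int
    residual_se_ : float
    result_ : NormalizationResult
    """

    def __init__(
        self,
        control_peaks: Sequence[str] = (),
        sample_sheet: SampleSheet | None = None,
        contrast: tuple[str, str] = ("control", "treated"),
        fit_space: str = "linear",
        rounding: str = "none",
    ):
        self.control_peaks = control_peaks
        self.sample_sheet = sample_sheet
        self.contrast = contrast
        self.fit_space = fit_space
        self.rounding = rounding

    def fit(self, X: CountsMatrix | pd.DataFrame, y=None):
        if self.sample_sheet is None:
            raise ValueError("sample_sheet is required")
        matrix = _as_counts(X)
        result = normalization_coefficient(
            matrix,
            self.control_peaks,
            self.sample_sheet,
            self.contrast,
            fit_space=self.fit_space,
        )
        self.result_ = result
        self.slope_ = result.slope
        self.coefficient_ = result.coefficient
        self.n_control_peaks_ = result.n_control_peaks
        self.residual_se_ = result.residual_se
        self.n_features_in_ = matrix.shape[1]
        return self

    def transform(self, X: CountsMatrix | pd.DataFrame) -> CountsMatrix:
        matrix = _as_counts(X)
        treated = self.sample_sheet.samples_for(self.contrast[1])
        return apply_coefficient(matrix, self.result_, treated, rounding=self.rounding)
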