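"""Negative-binomial differential-binding test with externally supplied
(reference-peak-derived) size factors.

Model: counts ``K_ij ~ NB(mean = s_j * mu_{g(j)}, var = mean + alpha_i * mean^2)``
with a log link, a two-level condition factor and log size factors as
offsets. Dispersions are method-of-moments estimates stabilised by a
``a0/mu + a1`` mean-dispersion trend (the final dispersion is the maximum of
the per-peak estimate and the trend value, a deliberately conservative
choice). Significance is a two-sided Wald test on the condition log2
fold-change with Benjamini-Hochberg FDR control.

This is a compact, fully specified test in the spirit of DESeq2's GLM but
without empirical-Bayes shrinkage or outlier filtering: the normalization,
not the test machinery, is the point, and calibration is what the test suite
verifies.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .containers import CountsMatrix, SampleSheet
from .normalize import (
    SizeFactors,
    apply_coefficient,
    control_size_factors,
    normalization_coefficient,
)

__all__ = [
    "estimate_dispersions",
    "nb_wald_test",
    "bh_adjust",
    "differential_pipeline",
    "NBDifferentialTest",
]

NORMALIZATION_MODES = ("library_total", "control_size_factors", "coefficient")

LN2 = float(np.log(2.0))


def estimate_dispersions(
    matrix: CountsMatrix,
    factors: SizeFactors,
    sheet: SampleSheet,
    contrast: tuple[str, str] | None = None,
    alpha_min: float = 1e-8,
) -> pd.Series:
    """Per-peak NB dispersion from within-condition moments plus a trend floor.

    For each peak, ``alpha_hat = max((v - mu)/mu^2, alpha_min)`` with ``v``
    the replicate-variance of normalized counts pooled across conditions and
    ``mu`` the mean normalized count. A trend ``alpha_tr(mu) = a0/mu + a1``
    is fitted by least squares over peaks, and the final dispersion is
    ``max(alpha_hat, alpha_tr(mu))``.
    """
    conditions = list(contrast) if contrast is not None else sheet.conditions
    groups = [sheet.samples_for(c) for c in conditions]
    if not any(len(g) >= 2 for g in groups):
        raise ValueError(
            "no condition has >= 2 replicates; supply a user dispersion instead"
        )
    norm = matrix.counts.astype(float) / factors.factors[matrix.counts.columns]
    mu = norm[[s for g in groups for s in g]].mean(axis=1).to_numpy()

    num = np.zeros(matrix.shape[0])
    df = 0
    for g in groups:
        if len(g) >= 2:
            num += norm[g].var(axis=1, ddof=1).to_numpy() * (len(g) - 1)
            df += len(g) - 1
    v = num / df

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = np.where(mu > 0, (v - mu) / np.maximum(mu, 1e-300) ** 2, alpha_min)
    alpha_hat = np.maximum(alpha_hat, alpha_min)

    ok = mu > 0
    if ok.sum() >= 2 and np.ptp(1.0 / mu[ok]) > 0:
        design = np.column_stack([1.0 / mu[ok], np.ones(ok.sum())])
        (a0, a1), *_ = np.linalg.lstsq(design, alpha_hat[ok], rcond=None)
        with np.errstate(divide="ignore"):
            trend = np.where(mu > 0, a0 / np.maximum(mu, 1e-300) + a1, alpha_min)
        trend = np.maximum(trend, alpha_min)
    else:
        trend = np.full(matrix.shape[0], alpha_min)

    final = np.maximum(alpha_hat, trend)
    return pd.Series(final, index=matrix.counts.index, name="dispersion")


def _nb_group_fit(
    counts: np.ndarray, s: np.ndarray, alpha: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Newton fit of one group's mean on the log scale.

    ``counts``: peaks x samples of one condition; ``s``: that condition's
    size factors; ``alpha``: per-peak dispersions. Returns ``(log_mu, info,
    converged)`` where ``info`` is the Fisher information of ``log mu`` (the
    Wald variance is its reciprocal). Peaks whose group total is zero get
    ``log_mu = -inf`` and ``info = 0``.
    """
    total = counts.sum(axis=1)
    mu = np.maximum(counts.mean(axis=1) / s.mean(), 1e-8)
    eta = np.log(mu)
    alive = total > 0
    converged = np.zeros(counts.shape[0], dtype=bool)
    for _ in range(max_iter):
        active = alive & ~converged
        if not active.any():
            break
        m = np.exp(eta[active])[:, None] * s[None, :]
        denom = 1.0 + alpha[active][:, None] * m
        score = ((counts[active] - m) / denom).sum(axis=1)
        info = (m / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-300)
        step = np.clip(step, -10.0, 10.0)
        eta[active] = eta[active] + step
        newly = np.abs(step) < tol
        idx = np.flatnonzero(active)
        converged[idx[newly]] = True
    m = np.exp(eta)[:, None] * s[None, :]
    info = (m / (1.0 + alpha[:, None] * m)).sum(axis=1)
    eta = np.where(alive, eta, -np.inf)
    info = np.where(alive, info, 0.0)
    return eta, info, converged | ~alive


def nb_wald_test(
    matrix: CountsMatrix,
    factors: SizeFactors,
    sheet: SampleSheet,
    contrast: tuple[str, str],
    dispersions: pd.Series | float,
) -> pd.DataFrame:
    """Two-sided Wald test of the condition effect, peak by peak.

    Fits the two group means by Newton iteration (tolerance 1e-8, max 100
    iterations) and reports ``log2FC = (eta_trt - eta_ctrl)/ln 2`` with
    ``SE^2 = (1/I_ctrl + 1/I_trt)/ln(2)^2`` from the Fisher information.
    Peaks where one group's counts are all zero, or where Newton fails to
    converge, fall back to a moment estimate with a 0.5 pseudocount on the
    group means; all-zero peaks get ``log2FC = 0, p = 1``.
    """
    ctrl_samples, trt_samples = sheet.check_contrast(contrast)
    alpha = (
        pd.Series(float(dispersions), index=matrix.counts.index)
        if np.isscalar(dispersions)
        else pd.Series(dispersions).reindex(matrix.counts.index)
    )
    if alpha.isna().any() or (alpha <= 0).any():
        raise ValueError("dispersions must be positive and cover every peak")
    a = alpha.to_numpy(dtype=float)

    kc = matrix.counts[ctrl_samples].to_numpy(dtype=float)
    kt = matrix.counts[trt_samples].to_numpy(dtype=float)
    sc = factors.factors[ctrl_samples].to_numpy(dtype=float)
    st = factors.factors[trt_samples].to_numpy(dtype=float)

    eta_c, info_c, conv_c = _nb_group_fit(kc, sc, a)
    eta_t, info_t, conv_t = _nb_group_fit(kt, st, a)

    # moment fallback: pseudocount-protected group means of normalized counts
    nc = (kc / sc).mean(axis=1)
    nt = (kt / st).mean(axis=1)
    mom_beta = np.log2((nt + 0.5) / (nc + 0.5))
    mom_var = (
        (np.maximum(nc, 0.5) + a * np.maximum(nc, 0.5) ** 2) / (len(ctrl_samples) * np.maximum(nc, 0.5) ** 2)
        + (np.maximum(nt, 0.5) + a * np.maximum(nt, 0.5) ** 2) / (len(trt_samples) * np.maximum(nt, 0.5) ** 2)
    ) / LN2**2

    use_mle = conv_c & conv_t & np.isfinite(eta_c) & np.isfinite(eta_t)
    with np.errstate(invalid="ignore"):
        beta = np.where(use_mle, (eta_t - eta_c) / LN2, mom_beta)
    with np.errstate(divide="ignore"):
        var = np.where(
            use_mle,
            (1.0 / np.maximum(info_c, 1e-300) + 1.0 / np.maximum(info_t, 1e-300)) / LN2**2,
            mom_var,
        )
    se = np.sqrt(var)

    all_zero = (nc == 0) & (nt == 0)
    beta = np.where(all_zero, 0.0, beta)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.where(all_zero, 1.0, pvals)

    base_mean = (np.concatenate([kc / sc, kt / st], axis=1)).mean(axis=1)
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": beta,
            "SE": se,
            "stat": z,
            "pvalue": pvals,
            "dispersion": a,
        },
        index=matrix.counts.index,
    )


def bh_adjust(pvalues: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_pipeline(
    matrix: CountsMatrix,
    control_peaks: Iterable[str],
    sheet: SampleSheet,
    contrast: tuple[str, str],
    normalization_mode: str = "control_size_factors",
    size_factor_method: str = "median_ratio",
    alpha_min: float = 1e-8,
    dispersions: pd.Series | float | None = None,
) -> pd.DataFrame:
    """Reference-peak-normalized differential binding for the target peaks.

    The control peaks drive the normalization but are excluded from the
    tested set. Modes:

    - ``library_total``: size factors proportional to library totals (or to
      column sums when totals are absent) — the depth baseline.
    - ``control_size_factors``: size factors from the control-peak counts.
    - ``coefficient``: through-origin regression coefficient applied to the
      treated columns (nearest-int rounding), identity size factors after.

    Returns the Wald table for target peaks with a BH-adjusted ``FDR`` column.
    """
    if normalization_mode not in NORMALIZATION_MODES:
        raise ValueError(f"normalization_mode must be one of {NORMALIZATION_MODES}")
    control = list(control_peaks)
    targets = [n for n in matrix.peak_names if n not in set(control)]
    if not targets:
        return pd.DataFrame(
            columns=["baseMean", "log2FC", "SE", "stat", "pvalue", "dispersion", "FDR"]
        )

    work = matrix
    if normalization_mode == "library_total":
        totals = (
            work.library_totals
            if work.library_totals is not None
            else work.counts.sum(axis=0).astype(float)
        )
        factors = SizeFactors.from_raw(totals, method="library_total")
    elif normalization_mode == "control_size_factors":
        factors = control_size_factors(work, control, method=size_factor_method)
    else:  # coefficient
        result = normalization_coefficient(work, control, sheet, contrast)
        treated = sheet.samples_for(contrast[1])
        work = apply_coefficient(work, result, treated, rounding="nearest_int")
        factors = SizeFactors.identity(work.sample_ids, method="coefficient")

    tested = work.subset_peaks(targets)
    if dispersions is None:
        dispersions = estimate_dispersions(
            tested, factors, sheet, contrast=contrast, alpha_min=alpha_min
        )
    table = nb_wald_test(tested, factors, sheet, contrast, dispersions)
    table["FDR"] = bh_adjust(table["pvalue"].to_numpy())
    return table


class NBDifferentialTest(BaseEstimator):
    """Differential-binding estimator (sklearn interface).

    ``fit(X)`` runs the reference-peak normalization chosen by
    ``normalization_mode`` followed by the NB Wald test on the non-control
    peaks of ``X`` (a :class:`CountsMatrix` or peaks-x-samples DataFrame).

    Attributes
    ----------
    results_ : pandas.DataFrame
        Per-target-peak baseMean, log2FC, SE, stat, pvalue, dispersion, FDR.
    size_factors_ : pandas.Series or None
    coefficient_ : float or None
        Set when ``normalization_mode='coefficient'``.
    """

    def __init__(
        self,
        control_peaks: Sequence[str] = (),
        sample_sheet: SampleSheet | None = None,
        contrast: tuple[str, str] = ("control", "treated"),
        normalization_mode: str = "control_size_factors",
        size_factor_method: str = "median_ratio",
        alpha_min: float = 1e-8,
    ):
        self.control_peaks = control_peaks
        self.sample_sheet = sample_sheet
        self.contrast = contrast
        self.normalization_mode = normalization_mode
        self.size_factor_method = size_factor_method
        self.alpha_min = alpha_min

    def fit(self, X: CountsMatrix | pd.DataFrame, y=None):
        if self.sample_sheet is None:
            raise ValueError("sample_sheet is required")
        matrix = X if isinstance(X, CountsMatrix) else CountsMatrix(pd.DataFrame(X))
        self.coefficient_ = None
        self.size_factors_ = None
        if self.normalization_mode == "coefficient":
            result = normalization_coefficient(
                matrix, list(self.control_peaks), self.sample_sheet, self.contrast
            )
            self.coefficient_ = result.coefficient
        elif self.normalization_mode == "control_size_factors":
            self.size_factors_ = control_size_factors(
                matrix, list(self.control_peaks), method=self.size_factor_method
            ).factors
        self.results_ = differential_pipeline(
            matrix,
            list(self.control_peaks),
            self.sample_sheet,
            self.contrast,
            normalization_mode=self.normalization_mode,
            size_factor_method=self.size_factor_method,
            alpha_min=self.alpha_min,
        )
        self.n_features_in_ = matrix.shape[1]
        return self

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        """Rows of ``results_`` below the given FDR threshold."""
        return self.results_.loc[self.results_["FDR"] < fdr]
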