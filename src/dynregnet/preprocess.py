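"""Normalization, differential-expression selection and Fourier smoothing.

The stimulus-response design measures change from the unstimulated state,
so differential expression is tested per time point against the baseline
(first) time point with a two-sample equal-variance t-test; a gene is kept
when it is significant at ``min_sig_timepoints`` or more time points.
Time series are denoised by a truncated Fourier least-squares fit.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datatypes import ExpressionMatrix, ReplicatedExpression


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column (time point) to the same value distribution.

    Each column's sorted values are replaced by the rank-wise mean across
    columns; ranks within each column are preserved.  Idempotent.
    """
    values = matrix.values
    if values.shape[1] < 2:
        warnings.warn("single column: quantile normalization is a no-op")
        return ExpressionMatrix(values.copy(), list(matrix.gene_ids), matrix.timepoints)
    order = np.argsort(values, axis=0, kind="stable")
    ranked_means = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        out[order[:, j], j] = ranked_means
    return ExpressionMatrix(out, list(matrix.gene_ids), matrix.timepoints)


def loess_normalize(red, green, span: float = 0.4) -> np.ndarray:
    """Intensity-dependent correction of two-channel log-ratios.

    Computes M = log2(red/green) and A = 0.5*log2(red*green), fits a
    locally weighted regression of M on A, and returns the residuals.
    """
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    if red.shape != green.shape:
        raise ValueError("intensity vectors must have equal length")
    if np.any(red <= 0) or np.any(green <= 0):
        raise ValueError("intensities must be positive")
    m = np.log2(red / green)
    a = 0.5 * np.log2(red * green)
    trend = lowess(m, a, frac=span, return_sorted=False)
    return m - trend


def average_replicates(expr: ReplicatedExpression) -> ExpressionMatrix:
    """Arithmetic mean across the replicate axis."""
    return ExpressionMatrix(
        expr.values.mean(axis=2), list(expr.gene_ids), expr.timepoints
    )


def deg_pvalues(expr: ReplicatedExpression, baseline_index: int = 0) -> np.ndarray:
    """Per-gene, per-non-baseline-time-point t-test p-values vs baseline.

    Two-sample equal-variance t-test of the replicate values at each time
    point against the replicate values at ``baseline_index``.  Zero pooled
    variance: p = 1 when the group means agree (no evidence), p = 0 when
    they differ (infinitely strong evidence).
    Returns an array genes x (timepoints - 1).
    """
    values = expr.values
    n_genes, n_tp, n_rep = values.shape
    if n_rep < 2:
        raise ValueError("differential testing needs at least 2 replicates")
    if not 0 <= baseline_index < n_tp:
        raise ValueError("baseline_index out of range")
    baseline = values[:, baseline_index, :]
    other = [j for j in range(n_tp) if j != baseline_index]
    pvals = np.empty((n_genes, len(other)))
    for col, j in enumerate(other):
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(values[:, j, :], baseline, axis=1, equal_var=True)
        p = np.asarray(res.pvalue, dtype=float)
        degenerate = ~np.isfinite(p)
        if degenerate.any():
            same = np.isclose(values[:, j, :].mean(axis=1), baseline.mean(axis=1))
            p[degenerate & same] = 1.0
            p[degenerate & ~same] = 0.0
        pvals[:, col] = p
    return pvals


def select_degs(
    expr: ReplicatedExpression,
    baseline_index: int = 0,
    alpha: float = 0.05,
    min_sig_timepoints: int = 3,
) -> set[str]:
    """Genes significant (p < alpha) at >= min_sig_timepoints time points."""
    pvals = deg_pvalues(expr, baseline_index)
    n_sig = (pvals < alpha).sum(axis=1)
    return {g for g, k in zip(expr.gene_ids, n_sig) if k >= min_sig_timepoints}


def fourier_design(timepoints, n_harmonics: int, period: float) -> np.ndarray:
    t = np.asarray(timepoints, dtype=float)
    cols = [np.ones_like(t)]
    for h in range(1, n_harmonics + 1):
        w = 2.0 * np.pi * h * t / period
        cols.append(np.cos(w))
        cols.append(np.sin(w))
    return np.column_stack(cols)


def fourier_smooth(
    series,
    timepoints,
    n_harmonics: int = 3,
    period_factor: float = 2.0,
) -> np.ndarray:
    """Least-squares truncated Fourier fit evaluated at the input grid.

    The fundamental period is ``period_factor`` times the sampled span, so
    the fit is not forced to be periodic on the observation window.  With
    2H+1 == M the system is square and the fit interpolates the data.
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if y.shape[-1] != t.shape[0]:
        raise ValueError("series and timepoints lengths differ")
    m = t.shape[0]
    if 2 * n_harmonics + 1 > m:
        raise ValueError("underdetermined fit: need 2*n_harmonics + 1 <= len(series)")
    period = period_factor * (t[-1] - t[0])
    design = fourier_design(t, n_harmonics, period)
    coef, *_ = np.linalg.lstsq(design, np.atleast_2d(y).T, rcond=None)
    fitted = (design @ coef).T
    return fitted[0] if y.ndim == 1 else fitted


def smooth_matrix(
    matrix: ExpressionMatrix, n_harmonics: int = 3, period_factor: float = 2.0
) -> ExpressionMatrix:
    """Fourier-smooth every gene's profile."""
    fitted = fourier_smooth(
        matrix.values, matrix.timepoints, n_harmonics, period_factor
    )
    return ExpressionMatrix(fitted, list(matrix.gene_ids), matrix.timepoints)
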