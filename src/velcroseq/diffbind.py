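"""Precision-weighted linear models with empirical-Bayes variance shrinkage.

Per window, log-CPM values are modeled as intercept + condition with
observation weights derived from a fitted mean-variance trend (voom): the
square root of the per-window residual standard deviation (a quarter-root of
the variance) is smoothed against average log-count by lowess, each fitted
observation's predicted standard deviation is read off the trend, and the
weight is its inverse fourth power.  The per-window variances are then shrunk
toward a scaled inverse-chi-square prior whose parameters (d0, s0^2) are
estimated by moment matching on log s^2 (digamma/trigamma closed forms), and
moderated t-statistics are referred to a t distribution on d0 + d_g degrees
of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .normalize import NormalizationFactors, log_cpm
from .windows import CountMatrix


def make_design(matrix: CountMatrix, treatment: str | None = None) -> np.ndarray:
    """Two-column design: intercept and condition indicator (treatment = 1)."""
    ind = matrix.condition_indicator(treatment)
    return np.column_stack([np.ones_like(ind, dtype=float), ind.astype(float)])


@dataclass
class LinearFit:
    coef: np.ndarray          # per-window contrast coefficient (log2FC)
    sigma: np.ndarray         # residual sd per window
    df_residual: float
    unscaled_sd: np.ndarray   # sd of contrast coef per unit sigma
    amean: np.ndarray         # average log-CPM per window
    index: pd.Index


@dataclass
class DiffBindResult:
    table: pd.DataFrame       # logFC, AveExpr, t, P.Value, s, df_total
    d0: float
    s0_squared: float
    df_residual: float
    weights: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        p = self.table["P.Value"].to_numpy()
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p-values out of [0,1]")


def _ols_stats(y: np.ndarray, design: np.ndarray):
    """Row-wise OLS: coefficients, residual sd, fitted values."""
    pinv = np.linalg.pinv(design)
    beta = y @ pinv.T                       # (g, p)
    fitted = beta @ design.T
    resid = y - fitted
    df = y.shape[1] - np.linalg.matrix_rank(design)
    sigma = np.sqrt((resid ** 2).sum(axis=1) / df)
    return beta, sigma, fitted, df


def voom_weights(logcpm: pd.DataFrame, matrix: CountMatrix,
                 factors: NormalizationFactors | pd.Series | None,
                 design: np.ndarray, span: float = 0.5,
                 min_windows: int = 10) -> np.ndarray:
    """Observation weights from the fitted sqrt-sd versus log-count trend.

    Falls back to constant weights (with a warning) when there are too few
    windows to support the smoother.
    """
    y = logcpm.to_numpy(dtype=float)
    n_windows = y.shape[0]
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if n_windows < min_windows:
        warnings.warn("too few windows for a mean-variance trend; "
                      "using constant weights")
        return np.ones_like(y)
    if isinstance(factors, NormalizationFactors):
        f = factors.factors
    elif factors is None:
        f = pd.Series(1.0, index=matrix.counts.columns)
    else:
        f = factors
    eff = (matrix.library_size * f).to_numpy(dtype=float)
    beta, sigma, fitted, _df = _ols_stats(y, design)
    amean = y.mean(axis=1)
    # mean log2 count scale for the trend x-axis
    sx = amean + np.mean(np.log2(eff + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    ok = np.isfinite(sx) & np.isfinite(sy)
    smooth = lowess(sy[ok], sx[ok], frac=span, it=3, return_sorted=True)
    xs, ys = smooth[:, 0], smooth[:, 1]
    # each observation's fitted log2 count
    fitted_count = fitted + np.log2(eff + 1.0)[None, :] - np.log2(1e6)
    pred_sqrt_sd = np.interp(fitted_count, xs, ys)
    pred_sqrt_sd = np.clip(pred_sqrt_sd, 1e-6, None)
    w = pred_sqrt_sd ** -4.0
    if not np.all(np.isfinite(w)):
        raise RuntimeError("non-finite voom weights")
    return w


def fit_weighted_lm(logcpm: pd.DataFrame, weights: np.ndarray | None,
                    design: np.ndarray) -> LinearFit:
    """Weighted least squares per window; contrast = condition coefficient."""
    y = logcpm.to_numpy(dtype=float)
    g, n = y.shape
    p = design.shape[1]
    if np.linalg.matrix_rank(design) < p:
        raise ValueError("design matrix is rank deficient")
    if weights is None:
        weights = np.ones_like(y)
    w = np.asarray(weights, dtype=float)
    if w.ndim == 1:
        w = np.broadcast_to(w, y.shape)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    X = design
    # batched normal equations: A_g = X' W_g X, b_g = X' W_g y_g
    A = np.einsum("gi,ij,ik->gjk", w, X, X)
    b = np.einsum("gi,ij,gi->gj", w, X, y)
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    fitted = beta @ X.T
    resid = y - fitted
    df = n - p
    sigma2 = np.einsum("gi,gi->g", w, resid ** 2) / df
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    cov_unscaled = np.linalg.inv(A)
    unscaled_sd = np.sqrt(cov_unscaled[:, -1, -1])
    return LinearFit(coef=beta[:, -1], sigma=sigma, df_residual=float(df),
                     unscaled_sd=unscaled_sd, amean=y.mean(axis=1),
                     index=logcpm.index)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to observed variances.

    Returns (d0, s0^2); d0 = inf when the log-variances show no excess
    dispersion beyond sampling noise.
    """
    x = np.asarray(sigma2, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size < 2:
        raise ValueError("need at least two positive variances to fit a prior")
    z = np.log(x)
    if np.ptp(z) == 0.0:
        # all variances identical: degenerate prior concentrated on them
        return np.inf, float(x[0])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s02 = np.exp(emean)
    return float(d0), float(s02)


def ebayes_moderate(fit: LinearFit, moderate: bool = True) -> DiffBindResult:
    """Moderated t-statistics and two-sided p-values for the contrast.

    With ``moderate=False`` the prior is disabled (d0 = 0) and the classical
    t-statistic on the residual degrees of freedom is returned.
    """
    sigma2 = fit.sigma ** 2
    df = fit.df_residual
    if moderate:
        d0, s02 = fit_variance_prior(sigma2, df)
    else:
        d0, s02 = 0.0, float("nan")
    if np.isinf(d0):
        post_var = np.full_like(sigma2, s02)
        df_total = np.inf
    elif d0 == 0.0:
        post_var = sigma2
        df_total = df
    else:
        post_var = (d0 * s02 + df * sigma2) / (d0 + df)
        df_total = d0 + df
    post_sd = np.sqrt(post_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.coef / (fit.unscaled_sd * post_sd)
        # zero posterior sd: exact fits get +/- infinite t (p -> 0), and a
        # zero coefficient over zero sd is a flat window (t = 0)
        t = np.where(np.isfinite(t), t,
                     np.where(fit.coef == 0, 0.0, np.sign(fit.coef) * np.inf))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(np.where(np.isfinite(p), p, 0.0), 0.0, 1.0)
    table = pd.DataFrame({
        "logFC": fit.coef,
        "AveExpr": fit.amean,
        "t": t,
        "P.Value": p,
        "s": fit.sigma,
        "df.total": df_total,
    }, index=fit.index)
    return DiffBindResult(table=table, d0=float(d0), s0_squared=float(s02),
                          df_residual=df)


def run_diffbind(matrix: CountMatrix, factors: NormalizationFactors | None = None,
                 span: float = 0.5, moderate: bool = True,
                 treatment: str | None = None) -> DiffBindResult:
    """Convenience: log-CPM -> voom weights -> weighted LM -> moderation."""
    y = log_cpm(matrix, factors)
    design = make_design(matrix, treatment)
    w = voom_weights(y, matrix, factors, design, span=span)
    fit = fit_weighted_lm(y, w, design)
    res = ebayes_moderate(fit, moderate=moderate)
    res.weights = w
    return res
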