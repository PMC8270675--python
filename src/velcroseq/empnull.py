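"""Empirical-null decomposition and local false discovery rates.

The marginal density of the per-window moderated t-statistics (taken as
z-values) is fitted by Poisson regression of histogram bin counts on a
natural-cubic-spline basis of the bin midpoints.  A normal empirical null
N(delta0, sigma0^2) and the null proportion p0 are then estimated by
truncated-normal maximum likelihood on the central interval of z, and each
window receives the local fdr

    fdr(z) = min(1, p0 * f0(z) / f(z)),

the posterior probability of being null given z.  A window is flagged
enriched when fdr <= threshold and z lies on the right of the null mode
(gain-of-binding direction).

Defaults mirror the study's parameterization: 150 bins, spline with 25
degrees of freedom, no tail trimming, MLE normal null started at
(delta, sigma) = (-0.5, 1.0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import optimize, special, stats


@dataclass
class EmpiricalNullConfig:
    n_bins: int = 150
    spline_df: int = 25
    tail_trim_proportion: float = 0.0
    null_start: tuple[float, float] = (-0.5, 1.0)
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.n_bins < 10:
            raise ValueError("n_bins must be >= 10")
        if self.spline_df >= self.n_bins:
            raise ValueError("spline_df must be smaller than n_bins")
        if self.null_start[1] <= 0:
            raise ValueError("null start sigma must be positive")
        if not 0 <= self.tail_trim_proportion < 0.5:
            raise ValueError("tail_trim_proportion in [0, 0.5)")


@dataclass
class MarginalDensity:
    midpoints: np.ndarray
    bin_counts: np.ndarray
    density: np.ndarray          # f at midpoints, integrates to ~1
    bin_width: float
    n: int
    _design_info: object = field(repr=False, default=None)
    _params: np.ndarray = field(repr=False, default=None)

    def __call__(self, z: np.ndarray) -> np.ndarray:
        """Evaluate the fitted density at arbitrary z (clamped to bin range)."""
        z = np.clip(np.asarray(z, dtype=float),
                    self.midpoints[0], self.midpoints[-1])
        basis = patsy.build_design_matrices([self._design_info], {"x": z})[0]
        mu = np.exp(np.asarray(basis) @ self._params)
        f = mu / (self.n * self.bin_width)
        floor = max(self.density[self.density > 0].min(), 1e-300)
        return np.maximum(f, floor)


def fit_marginal_density(z: np.ndarray,
                         config: EmpiricalNullConfig | None = None) -> MarginalDensity:
    """Poisson-spline fit of the z histogram (Lindsey's method)."""
    config = config or EmpiricalNullConfig()
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    n = z.size
    if n < 200:
        warnings.warn(f"only {n} z-values; density fit may be unstable")
    lo, hi = z.min(), z.max()
    if config.tail_trim_proportion > 0:
        lo, hi = np.quantile(z, [config.tail_trim_proportion,
                                 1 - config.tail_trim_proportion])
    if hi <= lo:
        raise ValueError("degenerate z distribution: no spread to bin")
    edges = np.linspace(lo, hi, config.n_bins + 1)
    counts, _ = np.histogram(z, bins=edges)
    mid = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    design = patsy.dmatrix(f"cr(x, df={config.spline_df})", {"x": mid},
                           return_type="dataframe")
    X = np.asarray(design)
    # direct Poisson MLE by L-BFGS: the IRLS route oscillates when tail bins
    # are empty (log-link separation), L-BFGS does not
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Poisson(counts, X).fit(method="lbfgs", maxiter=2000, disp=0)
    fitted = np.exp(X @ res.params)
    deviance = 2.0 * np.sum(special.xlogy(counts, counts / np.maximum(fitted, 1e-300))
                            - (counts - fitted))
    if not res.mle_retvals.get("converged", False) or not np.all(np.isfinite(fitted)):
        raise RuntimeError(
            "Poisson spline fit did not converge "
            f"(deviance {deviance:.4g}, grad norm "
            f"{np.abs(res.mle_retvals.get('gopt', np.nan)).max():.3g})")
    density = fitted / (n * width)
    return MarginalDensity(midpoints=mid, bin_counts=counts, density=density,
                           bin_width=float(width), n=n,
                           _design_info=design.design_info, _params=res.params)


@dataclass
class EmpiricalNull:
    delta0: float
    sigma0: float
    p0: float
    central_interval: tuple[float, float]

    @property
    def nonnull_proportion(self) -> float:
        return 1.0 - self.p0

    def density(self, z: np.ndarray) -> np.ndarray:
        return stats.norm.pdf(z, loc=self.delta0, scale=self.sigma0)


def fit_empirical_null_mle(z: np.ndarray,
                           config: EmpiricalNullConfig | None = None,
                           seed: int = 0) -> EmpiricalNull:
    """Truncated-normal MLE of the null (delta0, sigma0) and proportion p0.

    The central interval is [delta_start - 2 sigma_start,
    delta_start + 2 sigma_start].  Let N0 of the N statistics fall inside it.
    We maximize over (delta, sigma, theta) the likelihood in which null
    statistics ~ N(delta, sigma^2) make up a fraction theta of all z in the
    interval; then p0 = theta / P_null(interval), capped at one.
    """
    config = config or EmpiricalNullConfig()
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    d_start, s_start = config.null_start
    a, b = d_start - 2.0 * s_start, d_start + 2.0 * s_start
    z0 = z[(z >= a) & (z <= b)]
    n, n0 = z.size, z0.size
    if n0 == 0:
        raise ValueError("no z-values in the central interval "
                         f"[{a:.3g}, {b:.3g}]")

    def negloglik(params: np.ndarray) -> float:
        delta, log_sigma, logit_theta = params
        sigma = np.exp(log_sigma)
        theta = 1.0 / (1.0 + np.exp(-logit_theta))
        pa = stats.norm.cdf((a - delta) / sigma)
        pb = stats.norm.cdf((b - delta) / sigma)
        mass = pb - pa
        if mass <= 1e-12:
            return 1e12
        ll = (n0 * np.log(theta) + (n - n0) * np.log1p(-theta)
              + np.sum(stats.norm.logpdf(z0, loc=delta, scale=sigma))
              - n0 * np.log(mass))
        return -ll

    rng = np.random.default_rng(seed)
    x0 = np.array([d_start, np.log(s_start),
                   np.log(max(n0 / n, 1e-3) / max(1 - n0 / n, 1e-3))])
    best = None
    for attempt in range(10):
        start = x0 if attempt == 0 else x0 + rng.normal(0, 0.3, size=3)
        res = optimize.minimize(negloglik, start, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8,
                                         "maxiter": 2000})
        if res.success and np.isfinite(res.fun):
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise RuntimeError("empirical-null MLE failed to converge "
                           "after 10 restarts")
    delta0 = float(best.x[0])
    sigma0 = float(np.exp(best.x[1]))
    theta = float(1.0 / (1.0 + np.exp(-best.x[2])))
    mass = stats.norm.cdf((b - delta0) / sigma0) - stats.norm.cdf((a - delta0) / sigma0)
    p0 = min(theta / mass, 1.0)
    return EmpiricalNull(delta0=delta0, sigma0=sigma0, p0=p0,
                         central_interval=(a, b))


@dataclass
class EmpiricalNullFit:
    z: np.ndarray
    marginal: MarginalDensity
    null: EmpiricalNull
    fdr: np.ndarray
    enriched: np.ndarray
    fdr_threshold: float
    index: pd.Index | None = None

    @property
    def nonnull_proportion(self) -> float:
        """Primary estimate of the non-null fraction, 1 - p0."""
        return self.null.nonnull_proportion

    @property
    def posterior_nonnull_mass(self) -> float:
        """Integrated posterior non-null mass, mean(1 - fdr)."""
        return float(np.mean(1.0 - self.fdr))

    @property
    def n_enriched(self) -> int:
        return int(self.enriched.sum())

    def table(self) -> pd.DataFrame:
        idx = self.index if self.index is not None else pd.RangeIndex(len(self.z))
        return pd.DataFrame({"z": self.z, "fdr": self.fdr,
                             "enriched": self.enriched}, index=idx)


def local_fdr(z: np.ndarray, marginal: MarginalDensity, null: EmpiricalNull,
              fdr_threshold: float = 0.05,
              index: pd.Index | None = None) -> EmpiricalNullFit:
    """Per-window local fdr and one-sided (z > delta0) enrichment flags."""
    z = np.asarray(z, dtype=float)
    f = marginal(z)
    f0 = null.density(z)
    fdr = np.minimum(1.0, null.p0 * f0 / f)
    enriched = (fdr <= fdr_threshold) & (z > null.delta0)
    return EmpiricalNullFit(z=z, marginal=marginal, null=null, fdr=fdr,
                            enriched=enriched, fdr_threshold=fdr_threshold,
                            index=index)


def fit_local_fdr(z: np.ndarray, config: EmpiricalNullConfig | None = None,
                  index: pd.Index | None = None, seed: int = 0) -> EmpiricalNullFit:
    """Marginal density + empirical null + per-window local fdr in one call."""
    config = config or EmpiricalNullConfig()
    marginal = fit_marginal_density(z, config)
    null = fit_empirical_null_mle(z, config, seed=seed)
    return local_fdr(z, marginal, null, fdr_threshold=config.fdr_threshold,
                     index=index)
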