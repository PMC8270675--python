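"""Trimmed-mean-of-M-values (TMM) normalization and log-CPM transform.

TMM estimates a relative composition correction factor per sample against a
reference sample: per-window log2 expression ratios (M) are doubly trimmed —
by the ratio itself and by absolute expression (A) — and averaged with
inverse-asymptotic-variance (delta-method) weights.  Factors are rescaled to
geometric mean one so that they encode composition, not depth; depth lives in
the library size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .windows import CountMatrix


@dataclass
class NormalizationFactors:
    factors: pd.Series           # geometric mean 1
    reference: str
    effective_library_size: pd.Series  # library_size * factor

    def __post_init__(self) -> None:
        log_gm = np.log(self.factors.to_numpy()).mean()
        if not np.isfinite(log_gm) or abs(log_gm) > 1e-10:
            raise ValueError("factors must be positive with geometric mean 1")


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """TMM log2 factor of `obs` against `ref` (library sizes given)."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        raise ValueError("no window with nonzero counts in both samples")
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    po, pr = o / n_obs, r / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.abs(m).max() < 1e-6:          # identical composition
        return 0.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    # rank on rounded values so exact ties stay tied despite float noise
    rm = rankdata(np.round(m, 9))
    ra = rankdata(np.round(a, 9))
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any():
        # heavily tied M: fall back to the M-trim alone, then to no trim
        keep2 = (rm >= lo_m) & (rm <= hi_m)
        if not keep2.any():
            keep2 = np.ones_like(keep2)
    return float(np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2]))


def tmm_factors(matrix: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05,
                reference: str | None = None) -> NormalizationFactors:
    """Compute TMM factors for every sample of a count matrix.

    The reference is the sample whose upper quartile of counts-per-million is
    closest to the mean upper quartile (overridable).  Windows with a zero in
    either the test or the reference sample are excluded from M/A.
    """
    if matrix.n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    counts = matrix.counts
    lib = matrix.library_size
    if (counts.sum(axis=0) == 0).any():
        bad = counts.columns[counts.sum(axis=0) == 0].tolist()
        raise ValueError(f"samples with all-zero counts: {bad}")
    if reference is None:
        cpm = counts.div(lib, axis=1) * 1e6
        uq = cpm.quantile(0.75, axis=0)
        reference = (uq - uq.mean()).abs().idxmin()
    ref_counts = counts[reference].to_numpy()
    n_ref = float(lib[reference])
    log_factors = {}
    for sample in counts.columns:
        if sample == reference:
            log_factors[sample] = 0.0
            continue
        try:
            log_factors[sample] = _tmm_pair(
                counts[sample].to_numpy(), ref_counts,
                float(lib[sample]), n_ref, trim_m, trim_a)
        except ValueError as err:
            raise ValueError(f"sample {sample!r}: {err}") from None
    f = pd.Series({s: 2.0 ** lf for s, lf in log_factors.items()})
    f = f[counts.columns]
    f /= np.exp(np.log(f.to_numpy()).mean())
    return NormalizationFactors(factors=f, reference=reference,
                                effective_library_size=lib * f)


def log_cpm(matrix: CountMatrix, factors: NormalizationFactors | pd.Series | None = None,
            prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million on effective library sizes.

    y_gi = log2( (K_gi + prior) / (N_i f_i + 1) * 1e6 )
    """
    if factors is None:
        f = pd.Series(1.0, index=matrix.counts.columns)
    elif isinstance(factors, NormalizationFactors):
        f = factors.factors
    else:
        f = factors
    eff = matrix.library_size * f + 1.0
    return np.log2((matrix.counts + prior_count).div(eff, axis=1) * 1e6)
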