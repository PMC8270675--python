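"""Region overrepresentation and gene-set enrichment for enriched windows.

Two questions are answered here: (i) are the ribosome-enriched windows
overrepresented in particular mRNA regions (5' UTR / ORF / 3' UTR)?  This is
tested with a Pearson chi-square statistic on the region x enriched
contingency table whose null distribution comes from permuting the enriched
flags across windows.  (ii) are particular gene sets overrepresented among
the genes carrying at least one enriched window?  This uses a one-sided
Fisher/hypergeometric test per term with an FDR estimated by permuting which
genes form the positive set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .windows import FIVE_UTR, ORF, THREE_UTR, REGION_PRIORITY

PRIMARY_LABEL = "PRIMARY_LABEL"
MULTI_LABEL = "MULTI_LABEL"


@dataclass
class RegionContingency:
    table: pd.DataFrame          # rows regions, columns [enriched, not_enriched]
    mode: str
    chi2: float
    n_permutations: int
    p_value: float
    fold: pd.Series              # per-region enriched-share fold vs overall
    note: str | None = None


def _chi2_stat(enriched_per_region: np.ndarray, region_totals: np.ndarray,
               k: int, n: int) -> np.ndarray:
    """Pearson chi-square of 3x2 tables parameterized by the enriched column."""
    mu = region_totals * (k / n)
    nu = region_totals - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = (enriched_per_region - mu) ** 2 * (1.0 / mu + 1.0 / nu)
    return np.nansum(contrib, axis=-1)


def region_chisq_permutation(labels, enriched, B: int = 100_000,
                             mode: str = PRIMARY_LABEL,
                             seed: int = 0) -> RegionContingency:
    """Permutation chi-square test of region versus enrichment independence.

    ``labels``: per-window primary region label (PRIMARY_LABEL mode) or an
    iterable of label sets (MULTI_LABEL mode, each window contributing to
    every region it overlaps).  ``enriched``: boolean per window.  The
    p-value is (1 + #{chi2_perm >= chi2_obs}) / (B + 1).
    """
    enriched = np.asarray(enriched, dtype=bool)
    n = enriched.size
    k = int(enriched.sum())
    regions = list(REGION_PRIORITY)
    if mode == PRIMARY_LABEL:
        lab = np.asarray(labels, dtype=object)
        if lab.size != n:
            raise ValueError("labels and flags differ in length")
        incidence = np.column_stack([(lab == r) for r in regions])
    elif mode == MULTI_LABEL:
        incidence = np.zeros((n, len(regions)), dtype=bool)
        for i, labset in enumerate(labels):
            for j, r in enumerate(regions):
                if r in labset:
                    incidence[i, j] = True
    else:
        raise ValueError(f"unknown mode {mode!r}")
    used = incidence.any(axis=1)
    incidence = incidence[used]
    flags = enriched[used]
    n_used = int(used.sum())
    region_totals = incidence.sum(axis=0)
    present = region_totals > 0
    if present.sum() < 2:
        raise ValueError("need at least two region classes present")
    obs_enriched = (incidence & flags[:, None]).sum(axis=0)
    table = pd.DataFrame({"enriched": obs_enriched,
                          "not_enriched": region_totals - obs_enriched},
                         index=regions)
    k_used = int(flags.sum())
    if k_used == 0 or k_used == n_used:
        return RegionContingency(table=table, mode=mode, chi2=0.0,
                                 n_permutations=B, p_value=1.0,
                                 fold=pd.Series(np.nan, index=regions),
                                 note="constant enrichment flags")
    inc = incidence[:, present].astype(np.int64)
    totals = region_totals[present].astype(float)
    obs = obs_enriched[present].astype(float)
    chi2_obs = float(_chi2_stat(obs, totals, k_used, n_used))
    rng = np.random.default_rng(seed)
    if mode == PRIMARY_LABEL:
        # permuting flags across windows == multivariate hypergeometric draw
        # of enriched counts per region
        perm = rng.multivariate_hypergeometric(region_totals[present].astype(int),
                                               k_used, size=B).astype(float)
    else:
        perm = np.empty((B, int(present.sum())))
        flag_pool = flags.copy()
        for bi in range(B):
            rng.shuffle(flag_pool)
            perm[bi] = flag_pool @ inc
    chi2_perm = _chi2_stat(perm, totals, k_used, n_used)
    p = (1.0 + float(np.sum(chi2_perm >= chi2_obs - 1e-12))) / (B + 1.0)
    overall_share = k_used / n_used
    with np.errstate(divide="ignore", invalid="ignore"):
        fold_vals = (obs_enriched / np.maximum(region_totals, 1)) / overall_share
    fold = pd.Series(np.where(region_totals > 0, fold_vals, np.nan), index=regions)
    return RegionContingency(table=table, mode=mode, chi2=chi2_obs,
                             n_permutations=B, p_value=p, fold=fold)


def gene_set_fisher(positive: set[str], background: set[str],
                    term_to_genes: dict[str, set[str]]) -> pd.DataFrame:
    """One-sided overrepresentation test per term.

    Term gene lists are intersected with the background before testing;
    expected = |positive| * |term| / |background| under the hypergeometric
    null.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background gene set")
    positive = set(positive) & background
    n_bg, n_pos = len(background), len(positive)
    rows = []
    for term, genes in term_to_genes.items():
        term_genes = set(genes) & background
        m = len(term_genes)
        obs = len(term_genes & positive)
        exp = n_pos * m / n_bg
        p = float(stats.hypergeom.sf(obs - 1, n_bg, m, n_pos)) if m else 1.0
        rows.append((term, obs, exp, obs / exp if exp > 0 else np.nan, p, m))
    df = pd.DataFrame(rows, columns=["term", "observed", "expected",
                                     "obs_exp_ratio", "p_value", "term_size"])
    return df.set_index("term")


def gene_set_permutation_fdr(results: pd.DataFrame, background: set[str],
                             term_to_genes: dict[str, set[str]],
                             positive_size: int, n_perm: int = 1000,
                             seed: int = 0) -> pd.Series:
    """Permutation FDR for the Fisher term p-values.

    Each permutation redraws a random positive set of the same size from the
    background and recomputes every term's p-value; the FDR of a term is the
    average permutation count of p-values at or below its own, divided by
    the observed count, capped at one.
    """
    if n_perm < 1:
        warnings.warn("n_perm < 1: returning observed p-values only (FDR NaN)")
        return pd.Series(np.nan, index=results.index, name="fdr")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives unstable FDR estimates")
    bg = sorted(background)
    n_bg = len(bg)
    gene_idx = {g: i for i, g in enumerate(bg)}
    terms = list(results.index)
    ind = np.zeros((n_bg, len(terms)), dtype=bool)
    for j, term in enumerate(terms):
        for g in term_to_genes.get(term, ()):  # restrict to background
            i = gene_idx.get(g)
            if i is not None:
                ind[i, j] = True
    term_sizes = ind.sum(axis=0)
    rng = np.random.default_rng(seed)
    p_obs = results["p_value"].to_numpy()
    order = np.sort(p_obs)
    n_obs_le = np.searchsorted(order, p_obs, side="right")
    counts_le = np.zeros_like(p_obs, dtype=float)
    for _ in range(n_perm):
        idx = rng.choice(n_bg, size=positive_size, replace=False)
        obs = ind[idx].sum(axis=0)
        p_perm = stats.hypergeom.sf(obs - 1, n_bg, term_sizes, positive_size)
        p_perm_sorted = np.sort(p_perm)
        counts_le += np.searchsorted(p_perm_sorted, p_obs, side="right")
    fdr = np.minimum(1.0, (counts_le / n_perm) / np.maximum(1, n_obs_le))
    return pd.Series(fdr, index=results.index, name="fdr")


def gene_set_enrichment(positive: set[str], background: set[str],
                        term_to_genes: dict[str, set[str]],
                        n_perm: int = 1000, seed: int = 0,
                        min_observed: int = 3, min_ratio: float = 2.0,
                        fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Fisher + permutation FDR + the reporting filter.

    ``reported`` marks terms meeting all of: observed/expected >= min_ratio,
    observed >= min_observed, FDR <= fdr_threshold.
    """
    res = gene_set_fisher(positive, background, term_to_genes)
    res["fdr"] = gene_set_permutation_fdr(
        res, background, term_to_genes,
        positive_size=len(set(positive) & set(background)),
        n_perm=n_perm, seed=seed)
    res["reported"] = ((res["obs_exp_ratio"] >= min_ratio)
                       & (res["observed"] >= min_observed)
                       & (res["fdr"] <= fdr_threshold))
    return res


def genes_with_enriched_region(window_table: pd.DataFrame, region: str,
                               fdr_threshold: float = 0.05) -> list[str]:
    """Genes with >= 1 enriched window overlapping the given region.

    ``window_table`` needs columns gene_ids (comma-joined or sets),
    region_labels (likewise) and either an ``enriched`` boolean or an
    ``fdr`` column (threshold applied).  Any-overlap rule: a window labelled
    both 5'UTR and ORF counts for either region filter.
    """
    if region not in REGION_PRIORITY:
        raise ValueError(f"unknown region {region!r}; "
                         f"expected one of {REGION_PRIORITY}")
    if "enriched" in window_table.columns:
        flagged = window_table["enriched"].astype(bool)
    elif "fdr" in window_table.columns:
        flagged = window_table["fdr"] <= fdr_threshold
    else:
        raise ValueError("window table needs an 'enriched' or 'fdr' column")
    genes: set[str] = set()
    for _, row in window_table.loc[flagged].iterrows():
        labels = row["region_labels"]
        if isinstance(labels, str):
            labels = set(labels.split(",")) if labels else set()
        if region not in labels:
            continue
        gids = row["gene_ids"]
        if isinstance(gids, str):
            gids = set(gids.split(",")) if gids else set()
        genes.update(g for g in gids if g)
    return sorted(genes)
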