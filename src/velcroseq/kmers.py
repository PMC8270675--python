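"""Reverse-complement k-mer complementarity between an expansion segment and mRNA windows.

Every distinct substring (4 <= k <= 8 by default) of the reverse complement
of the expansion-segment (ES) sequence is a candidate site of canonical
Watson-Crick pairing.  For each such k-mer we count its (overlapping)
occurrences in every 5' UTR window sequence, compare the count vectors of
ribosome-enriched versus all 5' UTR windows with a Wilcoxon rank-sum test,
estimate FDR across all k-mers jointly by Benjamini-Hochberg, and call a
k-mer significant when FDR <= 0.05 and the Hodges-Lehmann location-shift
estimate is positive (higher counts in the enriched group).  Significant
k-mers with k >= 5 are mapped back onto candidate 5' UTRs as occurrence
blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return normalize_seq(seq).translate(_COMPLEMENT)[::-1]


def enumerate_rc_kmers(es_sequence: str, k_min: int = 4,
                       k_max: int = 8) -> pd.DataFrame:
    """All distinct k-mers of reverse_complement(ES), with ES coordinates.

    A k-mer at offset j (0-based) of the reverse complement pairs with ES
    positions [L-j-k, L-j).  Duplicate substrings are reported once with all
    source offsets retained; k levels longer than the sequence are skipped;
    k-mers containing ambiguous bases are dropped with a warning.
    """
    es = normalize_seq(es_sequence)
    if not es:
        raise ValueError("empty ES sequence")
    bad = set(es) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters in ES sequence: {bad}")
    if len(es) < k_min:
        raise ValueError(f"ES sequence shorter than k_min={k_min}")
    rc = reverse_complement(es)
    L = len(es)
    seen: dict[str, dict] = {}
    n_ambiguous = 0
    order: list[str] = []
    for k in range(k_min, min(k_max, L) + 1):
        for j in range(L - k + 1):
            kmer = rc[j:j + k]
            if "N" in kmer:
                n_ambiguous += 1
                continue
            if kmer in seen:
                seen[kmer]["rc_offsets"].append(j)
            else:
                seen[kmer] = {"kmer": kmer, "k": k, "rc_offsets": [j],
                              "es_start": L - j - k, "es_end": L - j}
                order.append(kmer)
    if n_ambiguous:
        warnings.warn(f"skipped {n_ambiguous} k-mers containing ambiguous bases")
    return pd.DataFrame([seen[k] for k in order]).set_index("kmer")


def count_kmer_occurrences(kmer: str, window_sequence: str) -> int:
    """Number of (overlapping) exact occurrences of kmer in the sequence."""
    kmer = normalize_seq(kmer)
    seq = normalize_seq(window_sequence)
    count = 0
    pos = seq.find(kmer)
    while pos != -1:
        count += 1
        pos = seq.find(kmer, pos + 1)
    return count


_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def count_kmer_matrix(kmers: pd.DataFrame | list[str],
                      sequences: list[str]) -> np.ndarray:
    """Occurrence counts, k-mers x sequences, via rolling base-4 encoding."""
    kmer_list = list(kmers.index) if isinstance(kmers, pd.DataFrame) else list(kmers)
    ks = sorted({len(km) for km in kmer_list})
    out = np.zeros((len(kmer_list), len(sequences)), dtype=np.int64)
    encoded = []
    for seq in sequences:
        arr = _BASE_CODE[np.frombuffer(normalize_seq(seq).encode(), dtype=np.uint8)]
        encoded.append(arr)
    for k in ks:
        rows = [i for i, km in enumerate(kmer_list) if len(km) == k]
        codes = {}
        for i in rows:
            km = kmer_list[i]
            arr = _BASE_CODE[np.frombuffer(km.encode(), dtype=np.uint8)]
            codes[int(arr @ (4 ** np.arange(k - 1, -1, -1)))] = i
        mult = 4 ** np.arange(k - 1, -1, -1)
        for j, arr in enumerate(encoded):
            if arr.size < k:
                continue
            view = np.lib.stride_tricks.sliding_window_view(arr, k)
            valid = (view >= 0).all(axis=1)
            if not valid.any():
                continue
            window_codes = view[valid] @ mult
            uniq, cnt = np.unique(window_codes, return_counts=True)
            for code, c in zip(uniq, cnt):
                i = codes.get(int(code))
                if i is not None:
                    out[i, j] = c
    return out


def hodges_lehmann_shift(x: np.ndarray, y: np.ndarray) -> float:
    """Median of all pairwise differences x_i - y_j."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.median(x[:, None] - y[None, :]))


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for comb in combinations(range(len(pooled)), n1):
        s = ranks[list(comb)].sum()
        total += 1
        if abs(s - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    return count / total


def kmer_wilcoxon(enriched_counts, background_counts) -> tuple[float, float, float]:
    """Rank-sum test between enriched and background count vectors.

    Returns (statistic, two-sided p, Hodges-Lehmann shift enriched-background).
    Exact enumeration of all group assignments (midranks under ties) when
    both groups have <= 10 values; tie-corrected normal approximation with
    continuity correction otherwise.  All-equal input gives p = 1, shift = 0.
    """
    x = np.asarray(enriched_counts, dtype=float)
    y = np.asarray(background_counts, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both count vectors must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0, 0.0
    delta = hodges_lehmann_shift(x, y)
    u1 = float(stats.rankdata(pooled)[:x.size].sum() - x.size * (x.size + 1) / 2.0)
    if x.size <= 10 and y.size <= 10:
        return u1, _exact_ranksum_p(x, y), delta
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue), delta


def kmer_bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR across the whole k-mer family."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class KmerEnrichmentTable:
    table: pd.DataFrame           # per k-mer statistics
    enriched_counts: np.ndarray   # k-mers x enriched windows
    background_counts: np.ndarray  # k-mers x all 5'UTR windows
    overlapping_matches: bool = True

    def significant(self, k_min: int | None = None) -> pd.DataFrame:
        sig = self.table[self.table["significant"]]
        if k_min is not None:
            sig = sig[sig["k"] >= k_min]
        return sig


def kmer_enrichment(es_sequence: str, enriched_sequences: list[str],
                    background_sequences: list[str], k_min: int = 4,
                    k_max: int = 8, fdr_threshold: float = 0.05) -> KmerEnrichmentTable:
    """Full k-mer overrepresentation analysis.

    ``background_sequences`` should be all tested 5' UTR windows (the
    enriched ones are part of the background, matching the
    enriched-versus-all comparison).
    """
    kmers = enumerate_rc_kmers(es_sequence, k_min, k_max)
    if not enriched_sequences or not background_sequences:
        raise ValueError("need non-empty enriched and background sequence sets")
    enr = count_kmer_matrix(kmers, enriched_sequences)
    bg = count_kmer_matrix(kmers, background_sequences)
    n_e, n_b = enr.shape[1], bg.shape[1]
    stat = np.zeros(len(kmers))
    pvals = np.ones(len(kmers))
    shift = np.zeros(len(kmers))
    # vectorized asymptotic rank-sum where there is any signal
    pooled = np.concatenate([enr, bg], axis=1)
    varies = np.ptp(pooled, axis=1) > 0
    if varies.any():
        res = stats.mannwhitneyu(enr[varies], bg[varies], axis=1,
                                 alternative="two-sided", method="asymptotic",
                                 use_continuity=True)
        stat[varies] = res.statistic
        pvals[varies] = res.pvalue
        diffs = enr[varies][:, :, None] - bg[varies][:, None, :]
        shift[varies] = np.median(diffs.reshape(varies.sum(), -1), axis=1)
    fdr = kmer_bh_fdr(pvals)
    table = kmers.copy()
    table["n_enriched_windows"] = n_e
    table["n_background_windows"] = n_b
    table["statistic"] = stat
    table["p_value"] = pvals
    table["fdr"] = fdr
    table["location_shift"] = shift
    table["significant"] = (table["fdr"] <= fdr_threshold) & (table["location_shift"] > 0)
    return KmerEnrichmentTable(table=table, enriched_counts=enr,
                               background_counts=bg)


def map_kmers_to_utrs(table: KmerEnrichmentTable | pd.DataFrame,
                      utr_sequences: dict[str, str],
                      k_min_shown: int = 5) -> pd.DataFrame:
    """Occurrence blocks of significant k-mers (k >= k_min_shown) per 5' UTR.

    Returns BED-like records in UTR-local coordinates: (utr, start, end,
    kmer, k).  UTRs shorter than k simply yield no records.
    """
    tab = table.table if isinstance(table, KmerEnrichmentTable) else table
    sig = tab[tab["significant"] & (tab["k"] >= k_min_shown)]
    records = []
    for utr, seq in utr_sequences.items():
        seq_n = normalize_seq(seq)
        for kmer, row in sig.iterrows():
            pos = seq_n.find(kmer)
            while pos != -1:
                records.append((utr, pos, pos + int(row["k"]), kmer, int(row["k"])))
                pos = seq_n.find(kmer, pos + 1)
    return pd.DataFrame(records, columns=["utr", "start", "end", "kmer", "k"])
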