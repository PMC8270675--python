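"""Sliding genomic windows: construction, fragment counting, filtering, annotation.

The unit of analysis is a 200-nt genomic window advanced in 100-nt steps, so
that every position (beyond the first step) is covered by two windows.  A
sequenced fragment (the mate-pair union interval, or each spliced block of it)
increments every window it overlaps by at least one nucleotide, once per
window.  Windows are annotated with the mRNA regions (5' UTR, ORF, 3' UTR) of
any overlapping isoform.

Coordinates are 0-based half-open internally; GTF is read as 1-based
inclusive; bedGraph is written 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

FIVE_UTR = "FIVE_UTR"
ORF = "ORF"
THREE_UTR = "THREE_UTR"
REGION_PRIORITY = (FIVE_UTR, ORF, THREE_UTR)


@dataclass
class GenomicWindow:
    """A (possibly truncated) half-open window on a contig."""

    chrom: str
    start: int
    end: int
    gene_ids: set[str] = field(default_factory=set)
    region_labels: set[str] = field(default_factory=set)

    @property
    def window_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def primary_label(self) -> str | None:
        for label in REGION_PRIORITY:
            if label in self.region_labels:
                return label
        return None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window interval [{self.start}, {self.end})")


@dataclass
class CountMatrix:
    """Integer fragment counts over windows (rows) and samples (columns).

    ``samples`` carries per-sample metadata with at least a ``condition``
    column (two levels, e.g. WT / hES9S) and a ``replicate`` column.
    ``library_size`` defaults to the column sums and is deliberately *not*
    recomputed when rows are filtered.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    windows: list[GenomicWindow] | None = None
    library_size: pd.Series | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.library_size is None:
            self.library_size = counts.sum(axis=0).astype(float)
        self.library_size = self.library_size.reindex(counts.columns).astype(float)
        if self.windows is not None and len(self.windows) != counts.shape[0]:
            raise ValueError("windows list does not match count matrix rows")
        if not self.samples.index.equals(counts.columns):
            self.samples = self.samples.reindex(counts.columns)

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def condition_indicator(self, treatment: str | None = None) -> np.ndarray:
        """0/1 vector over samples; 1 marks the treatment condition.

        With ``treatment=None`` the condition level that is not ``WT`` is
        used (and with exactly two levels neither named WT, the
        lexicographically larger one).
        """
        cond = self.samples["condition"].astype(str)
        levels = sorted(cond.unique())
        if len(levels) != 2:
            raise ValueError(f"need exactly two conditions, got {levels}")
        if treatment is None:
            treatment = levels[1] if levels[0] == "WT" else (
                levels[0] if levels[1] == "WT" else levels[1]
            )
        if treatment not in levels:
            raise ValueError(f"condition {treatment!r} not among {levels}")
        return (cond == treatment).astype(int).to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        df = self.counts.copy()
        if self.windows is not None:
            meta = windows_to_frame(self.windows).set_index("window_id")
            df = pd.concat([meta.loc[df.index], df], axis=1)
        with open(path, "w") as fh:
            fh.write("# window count matrix; sample columns: "
                     + ", ".join(f"{s}={c}" for s, c in
                                 zip(self.samples.index, self.samples["condition"]))
                     + "\n")
            fh.write("# library_size: "
                     + ", ".join(f"{s}={int(v)}" for s, v in self.library_size.items())
                     + "\n")
            df.to_csv(fh, sep="\t", index_label="window_id")

    @classmethod
    def from_tsv(cls, path: str | Path, samples: pd.DataFrame) -> "CountMatrix":
        lib = None
        with open(path) as fh:
            header_lines = []
            while True:
                pos = fh.tell()
                line = fh.readline()
                if line.startswith("#"):
                    header_lines.append(line)
                else:
                    fh.seek(pos)
                    break
            df = pd.read_csv(fh, sep="\t", index_col="window_id")
        for line in header_lines:
            if line.startswith("# library_size:"):
                lib = pd.Series({
                    kv.split("=")[0].strip(): float(kv.split("=")[1])
                    for kv in line.split(":", 1)[1].split(",")
                })
        meta_cols = [c for c in ("chrom", "start", "end", "gene_ids",
                                 "region_labels", "primary_label") if c in df.columns]
        windows = None
        if {"chrom", "start", "end"} <= set(meta_cols):
            windows = []
            for wid, row in df[meta_cols].iterrows():
                w = GenomicWindow(row["chrom"], int(row["start"]), int(row["end"]))
                if "gene_ids" in meta_cols and isinstance(row["gene_ids"], str) and row["gene_ids"]:
                    w.gene_ids = set(row["gene_ids"].split(","))
                if "region_labels" in meta_cols and isinstance(row["region_labels"], str) and row["region_labels"]:
                    w.region_labels = set(row["region_labels"].split(","))
                windows.append(w)
        counts = df.drop(columns=meta_cols).astype(int)
        counts = counts[[c for c in samples.index if c in counts.columns]]
        return cls(counts=counts, samples=samples, windows=windows, library_size=lib)


def windows_to_frame(windows: Sequence[GenomicWindow]) -> pd.DataFrame:
    return pd.DataFrame({
        "window_id": [w.window_id for w in windows],
        "chrom": [w.chrom for w in windows],
        "start": [w.start for w in windows],
        "end": [w.end for w in windows],
        "gene_ids": [",".join(sorted(w.gene_ids)) for w in windows],
        "region_labels": [",".join(sorted(w.region_labels)) for w in windows],
        "primary_label": [w.primary_label or "NONE" for w in windows],
    })


def make_windows(contig_lengths: Mapping[str, int], width: int = 200,
                 step: int = 100, drop_partial: bool = False) -> list[GenomicWindow]:
    """Tile every contig with half-open windows starting at 0, step, 2*step, ...

    The last windows are truncated at the contig end (kept unless
    ``drop_partial``); exact-duplicate intervals are deduplicated.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    if step > width:
        raise ValueError("step must not exceed width")
    out: list[GenomicWindow] = []
    for chrom, length in contig_lengths.items():
        if length < 1:
            raise ValueError(f"contig {chrom!r} has non-positive length {length}")
        seen: set[tuple[int, int]] = set()
        for start in range(0, length, step):
            end = min(start + width, length)
            if drop_partial and end - start < width:
                continue
            if (start, end) in seen:
                continue
            seen.add((start, end))
            out.append(GenomicWindow(chrom, start, end))
    return out


def _window_lookup(windows: Sequence[GenomicWindow]):
    """Per-contig arrays of (start, end, row-index), sorted by start."""
    lookup: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append((w.start, w.end, i))
    for chrom, triples in by_chrom.items():
        triples.sort()
        arr = np.array(triples, dtype=np.int64)
        lookup[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
    return lookup


def overlapping_window_rows(lookup, chrom: str, start: int, end: int) -> np.ndarray:
    """Row indices of windows overlapping [start, end) by >= 1 nt."""
    if chrom not in lookup or end <= start:
        return np.empty(0, dtype=np.int64)
    starts, ends, rows = lookup[chrom]
    # windows sorted by start; candidates have window.start < end
    hi = np.searchsorted(starts, end, side="left")
    cand = slice(0, hi)
    mask = ends[cand] > start
    return rows[cand][mask]


def count_intervals(fragments: Iterable[tuple[str, int, int]],
                    windows: Sequence[GenomicWindow]) -> np.ndarray:
    """Count half-open fragment intervals into windows (one column)."""
    lookup = _window_lookup(windows)
    col = np.zeros(len(windows), dtype=np.int64)
    for chrom, start, end in fragments:
        rows = overlapping_window_rows(lookup, chrom, start, end)
        col[rows] += 1
    return col


def _blocks_counts(block_sets, windows, lookup) -> np.ndarray:
    """Count fragments given per-fragment lists of (chrom,start,end) blocks.

    A fragment increments each overlapped window once even when several of
    its blocks hit the same window.
    """
    col = np.zeros(len(windows), dtype=np.int64)
    for blocks in block_sets:
        rows: np.ndarray | set
        if len(blocks) == 1:
            chrom, s, e = blocks[0]
            rows = overlapping_window_rows(lookup, chrom, s, e)
        else:
            acc: set[int] = set()
            for chrom, s, e in blocks:
                acc.update(overlapping_window_rows(lookup, chrom, s, e).tolist())
            rows = np.fromiter(acc, dtype=np.int64) if acc else np.empty(0, np.int64)
        col[rows] += 1
    return col


def iter_fragments(path: str | Path, per_read: bool = False,
                   stats: dict | None = None):
    """Yield per-fragment block lists from a SAM/BAM file.

    Properly paired mates are merged into one fragment spanning the
    mate-pair union interval; everything else is its own fragment (spliced
    records contribute each aligned block).  Unmapped, secondary and
    supplementary records are skipped; the count of skipped records is
    written to ``stats['skipped']`` and reported as a warning by
    :func:`count_fragments`.
    """
    skipped = 0
    pending: dict[str, list[tuple[str, int, int]]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                skipped += 1
                continue
            blocks = [(rec.reference_name, s, e) for s, e in rec.get_blocks()]
            if not blocks:
                skipped += 1
                continue
            if per_read or not rec.is_paired or rec.mate_is_unmapped:
                yield blocks
                continue
            other = pending.pop(rec.query_name, None)
            if other is None:
                pending[rec.query_name] = blocks
            else:
                merged = other + blocks
                chroms = {c for c, _s, _e in merged}
                if len(chroms) == 1:
                    # mate-pair union interval: leftmost start to rightmost
                    # end, covering the unsequenced insert between mates
                    chrom = chroms.pop()
                    yield [(chrom, min(s for _c, s, _e in merged),
                            max(e for _c, _s, e in merged))]
                else:
                    yield merged
    # orphaned mates: count each on its own
    for blocks in pending.values():
        yield blocks
    if stats is not None:
        stats["skipped"] = skipped


def count_fragments(sam_paths: Mapping[str, str | Path],
                    windows: Sequence[GenomicWindow],
                    samples: pd.DataFrame | None = None,
                    per_read: bool = False) -> CountMatrix:
    """Count alignment fragments from one SAM/BAM per sample into windows."""
    lookup = _window_lookup(windows)
    cols = {}
    for sample, path in sam_paths.items():
        stats: dict = {}
        cols[sample] = _blocks_counts(
            iter_fragments(path, per_read=per_read, stats=stats),
            windows, lookup)
        if stats.get("skipped"):
            warnings.warn(f"{sample}: skipped {stats['skipped']} unmapped/"
                          "secondary/supplementary records")
    counts = pd.DataFrame(cols, index=[w.window_id for w in windows])
    if samples is None:
        samples = pd.DataFrame(index=counts.columns)
        samples["condition"] = "NA"
        samples["replicate"] = range(1, len(counts.columns) + 1)
    return CountMatrix(counts=counts, samples=samples, windows=list(windows))


def filter_low_count(matrix: CountMatrix, min_total: int = 30) -> CountMatrix:
    """Drop windows whose count total across all samples is below ``min_total``.

    The boundary follows the "< min_total discarded" rule: a row summing to
    exactly ``min_total`` is retained.  Library sizes stay at their pre-filter
    values.
    """
    if matrix.n_samples < 1:
        raise ValueError("matrix has no samples")
    keep = matrix.counts.sum(axis=1) >= min_total
    windows = None
    if matrix.windows is not None:
        windows = [w for w, k in zip(matrix.windows, keep) if k]
    return CountMatrix(counts=matrix.counts.loc[keep],
                       samples=matrix.samples,
                       windows=windows,
                       library_size=matrix.library_size.copy())


# ---------------------------------------------------------------------------
# GTF annotation


def read_gtf_regions(gtf_path: str | Path) -> pd.DataFrame:
    """Flatten a GTF into one row per regional feature.

    Returns columns (chrom, start, end, region, gene_id, transcript_id) with
    0-based half-open coordinates.  Generic ``UTR`` features are resolved to
    5' or 3' using the transcript strand and its CDS span; a transcript with
    CDS but no strand is rejected.
    """
    db = gffutils.create_db(str(gtf_path), ":memory:", force=True,
                            merge_strategy="create_unique",
                            keep_order=True, verbose=False,
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    rows = []
    tx_strand: dict[str, str] = {}
    tx_cds_span: dict[str, list[int]] = {}
    generic_utrs: list[tuple[str, int, int, str, str]] = []
    for feat_rec in db.all_features():
        chrom = feat_rec.seqid
        start, end = feat_rec.start - 1, feat_rec.end  # to 0-based half-open
        strand = feat_rec.strand
        gene = feat_rec.attributes.get("gene_id", [""])[0]
        tx = feat_rec.attributes.get("transcript_id", [""])[0]
        feat = feat_rec.featuretype.lower()
        if tx:
            tx_strand.setdefault(tx, strand)
        if feat == "cds":
            rows.append((chrom, start, end, ORF, gene, tx))
            span = tx_cds_span.setdefault(tx, [start, end])
            span[0] = min(span[0], start)
            span[1] = max(span[1], end)
        elif feat in ("five_prime_utr", "5utr"):
            rows.append((chrom, start, end, FIVE_UTR, gene, tx))
        elif feat in ("three_prime_utr", "3utr"):
            rows.append((chrom, start, end, THREE_UTR, gene, tx))
        elif feat == "utr":
            generic_utrs.append((chrom, start, end, gene, tx))
        elif feat == "gene":
            rows.append((chrom, start, end, "GENE", gene, tx))
    for tx, span in tx_cds_span.items():
        if tx_strand.get(tx, ".") not in ("+", "-"):
            raise ValueError(f"transcript {tx!r} has CDS but no strand")
    for chrom, start, end, gene, tx in generic_utrs:
        span = tx_cds_span.get(tx)
        if span is None:
            # no CDS on this transcript: cannot orient; skip with warning
            warnings.warn(f"generic UTR on CDS-less transcript {tx!r} skipped")
            continue
        strand = tx_strand[tx]
        before_cds = end <= span[0]
        if strand == "+":
            region = FIVE_UTR if before_cds else THREE_UTR
        else:
            region = THREE_UTR if before_cds else FIVE_UTR
        rows.append((chrom, start, end, region, gene, tx))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "region",
                                       "gene_id", "transcript_id"])


def annotate_windows(windows: Sequence[GenomicWindow],
                     gtf: str | Path | pd.DataFrame) -> list[GenomicWindow]:
    """Attach gene ids and region labels (any-isoform overlap) to windows.

    Mutates and returns the given windows.  ``gtf`` may be a path or the
    flattened frame from :func:`read_gtf_regions`.  A window gets every
    region label whose feature (from any isoform) overlaps it by >= 1 nt;
    the primary label follows the fixed priority 5'UTR > ORF > 3'UTR.
    """
    regions = gtf if isinstance(gtf, pd.DataFrame) else read_gtf_regions(gtf)
    trees: dict[str, IntervalTree] = {}
    gene_trees: dict[str, IntervalTree] = {}
    for row in regions.itertuples(index=False):
        if row.end <= row.start:
            continue
        if row.region == "GENE":
            gene_trees.setdefault(row.chrom, IntervalTree()).addi(
                row.start, row.end, row.gene_id)
        else:
            trees.setdefault(row.chrom, IntervalTree()).addi(
                row.start, row.end, (row.region, row.gene_id))
    have_gene_features = bool(gene_trees)
    for w in windows:
        w.gene_ids = set()
        w.region_labels = set()
        for iv in trees.get(w.chrom, IntervalTree()).overlap(w.start, w.end):
            region, gene = iv.data
            w.region_labels.add(region)
            if gene:
                w.gene_ids.add(gene)
        if have_gene_features:
            for iv in gene_trees.get(w.chrom, IntervalTree()).overlap(w.start, w.end):
                if iv.data:
                    w.gene_ids.add(iv.data)
    return list(windows)


def export_tracks(matrix: CountMatrix, factors: pd.Series,
                  out_dir: str | Path | None = None,
                  step: int | None = None) -> dict[str, pd.DataFrame]:
    """Per-sample normalized bedGraph tracks.

    Window counts are divided by the effective library size
    (library_size x TMM factor) and scaled to counts-per-million.  To keep
    bedGraph intervals sorted and non-overlapping, each window's value is
    written on its leading step-sized bin (the window's unique start bin
    under the regular tiling).
    """
    if matrix.windows is None:
        raise ValueError("matrix has no window coordinates")
    if (factors.reindex(matrix.counts.columns) <= 0).any():
        raise ValueError("normalization factors must be positive")
    if step is None:
        starts = sorted({w.start for w in matrix.windows})
        step = min((b - a for a, b in zip(starts, starts[1:])), default=100)
    out: dict[str, pd.DataFrame] = {}
    meta = [(w.chrom, w.start, min(w.start + step, w.end)) for w in matrix.windows]
    for sample in matrix.counts.columns:
        eff = matrix.library_size[sample] * factors[sample]
        values = matrix.counts[sample].to_numpy() / eff * 1e6
        df = pd.DataFrame(meta, columns=["chrom", "start", "end"])
        df["value"] = values
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        out[sample] = df
        if out_dir is not None:
            path = Path(out_dir) / f"{sample}.bedGraph"
            with open(path, "w") as fh:
                fh.write(f'track type=bedGraph name="{sample}"\n')
                df.to_csv(fh, sep="\t", header=False, index=False,
                          float_format="%.6g")
    return out
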