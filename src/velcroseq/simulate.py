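"""Synthetic VELCRO-IP style data with known ground truth.

Generates everything the pipeline consumes: a GENCODE-like gene annotation
(one gene per synthetic contig, contiguous 5' UTR / CDS / 3' UTR), a genome
FASTA, paired-end toy alignments, negative-binomial window counts for three
replicates each of two pulldown conditions (WT and hES9S), and 5' UTR
sequences with k-mers complementary to an expansion-segment sequence planted
in the truly enriched genes.

Two count modes exist:

* :func:`generate_counts` draws pure negative-binomial counts per window
  (marginals exactly NB) — the right input for testing the statistical
  stages at scale.
* :func:`generate_dataset` is fragments-first: it samples sequencing
  fragments per gene segment, derives the count matrix by counting those
  fragments with the same overlap rule as the counting module, and can emit
  the fragments as SAM.  Re-counting the SAM therefore reproduces the matrix
  exactly.

Defaults mirror the study's scale where it states one: three replicates per
condition, a planted non-null fraction of 0.157, and a median fragment
length of 246 nt.  The default ES sequence is synthetic (the real ES9S
sequence is not part of this package); supply your own via ``es_sequence``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import kmers as _kmers
from .windows import (CountMatrix, FIVE_UTR, GenomicWindow, ORF, THREE_UTR,
                      annotate_windows, count_intervals, make_windows,
                      windows_to_frame)

# Synthetic stand-in for an expansion-segment sequence (60 nt); not the
# biological ES9S.
SYNTHETIC_ES = ("GTTCGGAGACCTTAAGCAGCCATCATTTGGAGAAAGCGTAATAGCTCACTG"
                "GTCTTGTGG")


@dataclass
class SimulationConfig:
    """All knobs of the generator; identical seed + config => identical bytes."""

    seed: int
    n_genes: int = 300
    windows_per_gene: int = 8
    n_replicates_per_condition: int = 3
    planted_nonnull_fraction: float = 0.157
    planted_log2fc: float = 2.0
    lfc_mode: str = "constant"          # or "gamma"
    nb_dispersion: float = 0.1
    mean_log_expression: float = float(np.log(100.0))
    sd_log_expression: float = 0.7
    library_sizes: tuple[float, ...] | None = None
    composition_skew_fraction: float = 0.0
    utr5_length_range: tuple[int, int] = (200, 600)
    cds_length_range: tuple[int, int] = (600, 2400)
    utr3_length_range: tuple[int, int] = (200, 700)
    utr5_enrichment_bias: float = 1.0
    es_sequence: str = SYNTHETIC_ES
    planted_kmer: str | None = None
    planted_kmer_count_per_enriched_5utr: int = 3
    fragment_length_median: int = 246
    fragment_length_sd: float = 30.0
    window_width: int = 200
    window_step: int = 100
    strand_mode: str = "plus"           # or "random"

    def __post_init__(self) -> None:
        if not 0.0 <= self.planted_nonnull_fraction <= 1.0:
            raise ValueError("planted_nonnull_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.planted_log2fc <= 0:
            raise ValueError("planted_log2fc must be positive")
        if not 0.0 <= self.composition_skew_fraction <= 1.0:
            raise ValueError("composition_skew_fraction must be in [0, 1]")
        if self.library_sizes is not None:
            if len(self.library_sizes) != self.n_samples:
                raise ValueError(
                    f"library_sizes must have length {self.n_samples}")
            if any(s <= 0 for s in self.library_sizes):
                raise ValueError("library sizes must be positive")
        for rng_ in (self.utr5_length_range, self.cds_length_range,
                     self.utr3_length_range):
            if rng_[0] < 1 or rng_[1] < rng_[0]:
                raise ValueError(f"invalid length range {rng_}")
        if self.lfc_mode not in ("constant", "gamma"):
            raise ValueError("lfc_mode must be 'constant' or 'gamma'")
        if self.strand_mode not in ("plus", "random"):
            raise ValueError("strand_mode must be 'plus' or 'random'")

    @property
    def n_samples(self) -> int:
        return 2 * self.n_replicates_per_condition

    def sample_sheet(self) -> pd.DataFrame:
        names, cond, rep = [], [], []
        for c in ("WT", "hES9S"):
            for r in range(1, self.n_replicates_per_condition + 1):
                names.append(f"{c}_{r}")
                cond.append(c)
                rep.append(r)
        return pd.DataFrame({"condition": cond, "replicate": rep}, index=names)

    def relative_depths(self) -> np.ndarray:
        if self.library_sizes is None:
            return np.ones(self.n_samples)
        s = np.asarray(self.library_sizes, dtype=float)
        return s / s.mean()


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def _nb_draw(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-8:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = 1.0 / (1.0 + dispersion * mean)
    return rng.negative_binomial(n, p)


# ---------------------------------------------------------------------------
# Annotation + genome


@dataclass
class Annotation:
    genes: pd.DataFrame                 # gene_id, contig, strand, utr5/cds/utr3 lengths
    contig_lengths: dict[str, int]
    genome: dict[str, str]

    def regions_frame(self) -> pd.DataFrame:
        """Flattened regional features (same schema as read_gtf_regions)."""
        rows = []
        for g in self.genes.itertuples(index=False):
            L = g.utr5_len + g.cds_len + g.utr3_len
            if g.strand == "+":
                segs = [(0, g.utr5_len, FIVE_UTR),
                        (g.utr5_len, g.utr5_len + g.cds_len, ORF),
                        (g.utr5_len + g.cds_len, L, THREE_UTR)]
            else:
                segs = [(L - g.utr5_len, L, FIVE_UTR),
                        (g.utr3_len, L - g.utr5_len, ORF),
                        (0, g.utr3_len, THREE_UTR)]
            tx = f"{g.gene_id}.t1"
            for s, e, region in segs:
                rows.append((g.contig, s, e, region, g.gene_id, tx))
            rows.append((g.contig, 0, L, "GENE", g.gene_id, ""))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "region",
                                           "gene_id", "transcript_id"])

    def segment_frame(self) -> pd.DataFrame:
        """One row per (gene, region) segment with genomic coordinates."""
        df = self.regions_frame()
        return df[df["region"] != "GENE"].reset_index(drop=True)

    def utr5_interval(self, gene_id: str) -> tuple[str, int, int]:
        g = self.genes.set_index("gene_id").loc[gene_id]
        L = int(g["utr5_len"] + g["cds_len"] + g["utr3_len"])
        if g["strand"] == "+":
            return g["contig"], 0, int(g["utr5_len"])
        return g["contig"], L - int(g["utr5_len"]), L

    def to_gtf(self) -> str:
        lines = []
        feature_names = {FIVE_UTR: "five_prime_utr", ORF: "CDS",
                         THREE_UTR: "three_prime_utr"}
        segments = self.segment_frame()
        for g in self.genes.itertuples(index=False):
            tx = f"{g.gene_id}.t1"
            L = g.utr5_len + g.cds_len + g.utr3_len
            attrs_gene = f'gene_id "{g.gene_id}";'
            attrs_tx = f'gene_id "{g.gene_id}"; transcript_id "{tx}";'
            lines.append("\t".join([g.contig, "sim", "gene", "1", str(L), ".",
                                    g.strand, ".", attrs_gene]))
            lines.append("\t".join([g.contig, "sim", "transcript", "1", str(L),
                                    ".", g.strand, ".", attrs_tx]))
            lines.append("\t".join([g.contig, "sim", "exon", "1", str(L), ".",
                                    g.strand, ".", attrs_tx]))
            seg = segments[segments["gene_id"] == g.gene_id]
            for row in seg.itertuples(index=False):
                lines.append("\t".join([
                    row.chrom, "sim", feature_names[row.region],
                    str(row.start + 1), str(row.end), ".", g.strand, ".",
                    attrs_tx]))
        return "\n".join(lines) + "\n"

    def write_gtf(self, path: str | Path) -> None:
        Path(path).write_text(self.to_gtf())

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for contig in self.contig_lengths:
                fh.write(f">{contig}\n")
                seq = self.genome[contig]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")


def generate_annotation(config: SimulationConfig) -> Annotation:
    """One single-isoform gene per synthetic contig, contiguous regions."""
    rng = _rng(config, 1)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    rows = []
    genome: dict[str, str] = {}
    contig_lengths: dict[str, int] = {}
    for i in range(config.n_genes):
        gene_id = f"g{i + 1:04d}"
        contig = f"chr_{gene_id}"
        u5 = int(rng.integers(config.utr5_length_range[0],
                              config.utr5_length_range[1] + 1))
        cds = int(rng.integers(config.cds_length_range[0],
                               config.cds_length_range[1] + 1))
        u3 = int(rng.integers(config.utr3_length_range[0],
                              config.utr3_length_range[1] + 1))
        strand = "+"
        if config.strand_mode == "random":
            strand = "+" if rng.random() < 0.5 else "-"
        L = u5 + cds + u3
        if L < 1:
            raise ValueError("zero-length contig requested")
        seq = bases[rng.integers(0, 4, size=L)].tobytes().decode()
        rows.append((gene_id, contig, strand, u5, cds, u3))
        genome[contig] = seq
        contig_lengths[contig] = L
    genes = pd.DataFrame(rows, columns=["gene_id", "contig", "strand",
                                        "utr5_len", "cds_len", "utr3_len"])
    return Annotation(genes=genes, contig_lengths=contig_lengths, genome=genome)


# ---------------------------------------------------------------------------
# Truth containers


@dataclass
class SimulationTruth:
    windows: pd.DataFrame               # window_id, gene_id, region, enriched, true_log2fc
    segments: pd.DataFrame | None = None  # per (gene, region): enriched, true_log2fc
    planted_kmers: pd.DataFrame | None = None

    @property
    def enriched_fraction(self) -> float:
        return float(self.windows["enriched"].mean())


# ---------------------------------------------------------------------------
# Abstract (pure NB) count generator


def generate_counts(config: SimulationConfig) -> tuple[CountMatrix, SimulationTruth]:
    """Pure negative-binomial window counts with planted enrichment.

    Windows are abstract (grouped into genes, labelled by region with
    probabilities proportional to the mean region lengths); counts for
    window w in sample i are NB with mean mu_w * depth_i, times
    2^true_log2fc in hES9S samples when the window is enriched.
    """
    rng = _rng(config, 2)
    n_w = config.n_genes * config.windows_per_gene
    gene_ids = np.repeat([f"g{i + 1:04d}" for i in range(config.n_genes)],
                         config.windows_per_gene)
    window_ids = np.array([f"{g}:w{j % config.windows_per_gene:02d}"
                           for j, g in enumerate(gene_ids)])
    mean_lens = np.array([np.mean(config.utr5_length_range),
                          np.mean(config.cds_length_range),
                          np.mean(config.utr3_length_range)])
    region_probs = mean_lens / mean_lens.sum()
    regions = rng.choice([FIVE_UTR, ORF, THREE_UTR], size=n_w, p=region_probs)

    pi = config.planted_nonnull_fraction
    bias = np.where(regions == FIVE_UTR, config.utr5_enrichment_bias, 1.0)
    if pi > 0:
        scale = pi * n_w / bias.sum()
        p_enr = np.clip(scale * bias, 0.0, 1.0)
    else:
        p_enr = np.zeros(n_w)
    enriched = rng.random(n_w) < p_enr
    if config.lfc_mode == "constant":
        lfc = np.full(n_w, config.planted_log2fc)
    else:
        lfc = rng.gamma(4.0, config.planted_log2fc / 4.0, size=n_w)
    lfc = np.where(enriched, lfc, 0.0)

    mu = np.exp(rng.normal(config.mean_log_expression,
                           config.sd_log_expression, size=n_w))
    samples = config.sample_sheet()
    depths = config.relative_depths()
    treat = (samples["condition"] == "hES9S").to_numpy()
    skew = np.zeros(n_w, dtype=bool)
    if config.composition_skew_fraction > 0:
        skew = rng.random(n_w) < config.composition_skew_fraction
    counts = np.empty((n_w, config.n_samples), dtype=np.int64)
    for i in range(config.n_samples):
        m = mu * depths[i]
        if treat[i]:
            m = m * 2.0 ** lfc
        if i == config.n_samples - 1:    # skewed composition in last sample
            m = np.where(skew, m * 8.0, m)
        counts[:, i] = _nb_draw(rng, m, config.nb_dispersion)
    cm = CountMatrix(counts=pd.DataFrame(counts, index=window_ids,
                                         columns=samples.index),
                     samples=samples)
    truth = SimulationTruth(windows=pd.DataFrame({
        "window_id": window_ids, "gene_id": gene_ids, "region": regions,
        "enriched": enriched, "true_log2fc": lfc}).set_index("window_id"))
    return cm, truth


# ---------------------------------------------------------------------------
# Fragments-first dataset


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: Annotation
    windows: list[GenomicWindow]
    count_matrix: CountMatrix
    truth: SimulationTruth
    fragments: dict[str, list[tuple[str, int, int]]]
    utr5_sequences: dict[str, str] = field(default_factory=dict)


def _sample_fragment_length(rng, seg_len: int, config: SimulationConfig) -> int:
    for _ in range(20):
        ln = int(round(rng.normal(config.fragment_length_median,
                                  config.fragment_length_sd)))
        if 40 <= ln <= seg_len:
            return ln
    return min(seg_len, max(40, min(seg_len, config.fragment_length_median)))


def generate_dataset(config: SimulationConfig,
                     plant_kmers: bool | None = None) -> SimulatedDataset:
    """Fragments-first synthetic dataset with exact SAM round trip.

    Enrichment is planted per gene segment (5' UTR / ORF / 3' UTR block,
    with the configurable 5' UTR bias); fragments are placed uniformly
    within their segment, lengths around the configured median; the count
    matrix is obtained by counting the fragments over the sliding windows,
    so emitting them as SAM and re-counting reproduces it exactly.
    """
    annotation = generate_annotation(config)
    rng = _rng(config, 3)
    seg = annotation.segment_frame().copy()
    pi = config.planted_nonnull_fraction
    bias = np.where(seg["region"] == FIVE_UTR, config.utr5_enrichment_bias, 1.0)
    if pi > 0:
        scale = pi * len(seg) / bias.sum()
        p_enr = np.clip(scale * bias, 0.0, 1.0)
    else:
        p_enr = np.zeros(len(seg))
    seg["enriched"] = rng.random(len(seg)) < p_enr
    if config.lfc_mode == "constant":
        seg_lfc = np.full(len(seg), config.planted_log2fc)
    else:
        seg_lfc = rng.gamma(4.0, config.planted_log2fc / 4.0, size=len(seg))
    seg["true_log2fc"] = np.where(seg["enriched"], seg_lfc, 0.0)

    gene_expr = {g: float(np.exp(rng.normal(config.mean_log_expression,
                                            config.sd_log_expression)))
                 for g in annotation.genes["gene_id"]}
    gene_len = {g.gene_id: g.utr5_len + g.cds_len + g.utr3_len
                for g in annotation.genes.itertuples(index=False)}
    samples = config.sample_sheet()
    depths = config.relative_depths()
    treat = (samples["condition"] == "hES9S").to_numpy()

    fragments: dict[str, list[tuple[str, int, int]]] = {s: [] for s in samples.index}
    for si, sample in enumerate(samples.index):
        for row in seg.itertuples(index=False):
            seg_len = row.end - row.start
            mean = (gene_expr[row.gene_id] * seg_len / gene_len[row.gene_id]
                    * depths[si])
            if treat[si] and row.enriched:
                mean *= 2.0 ** row.true_log2fc
            n_frag = int(_nb_draw(rng, mean, config.nb_dispersion))
            for _ in range(n_frag):
                ln = _sample_fragment_length(rng, seg_len, config)
                start = row.start + int(rng.integers(0, seg_len - ln + 1))
                fragments[sample].append((row.chrom, start, start + ln))

    windows = make_windows(annotation.contig_lengths, config.window_width,
                           config.window_step)
    annotate_windows(windows, annotation.regions_frame())
    counts = {s: count_intervals(frs, windows) for s, frs in fragments.items()}
    cm = CountMatrix(counts=pd.DataFrame(counts,
                                         index=[w.window_id for w in windows]),
                     samples=samples, windows=windows)

    # window-level truth: enriched iff overlapping an enriched segment
    seg_enr = seg[seg["enriched"]]
    enr_by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for row in seg_enr.itertuples(index=False):
        enr_by_chrom.setdefault(row.chrom, []).append(
            (row.start, row.end, row.true_log2fc))
    win_rows = []
    for w in windows:
        hits = [lfc for s, e, lfc in enr_by_chrom.get(w.chrom, ())
                if s < w.end and e > w.start]
        enr = bool(hits)
        lfc = max(hits) if enr else 0.0
        win_rows.append((w.window_id, ",".join(sorted(w.gene_ids)),
                         w.primary_label or "NONE", enr, lfc))
    truth_windows = pd.DataFrame(
        win_rows, columns=["window_id", "gene_id", "region", "enriched",
                           "true_log2fc"]).set_index("window_id")
    truth = SimulationTruth(windows=truth_windows, segments=seg)
    ds = SimulatedDataset(config=config, annotation=annotation,
                          windows=windows, count_matrix=cm, truth=truth,
                          fragments=fragments)
    if plant_kmers is None:
        plant_kmers = config.planted_kmer_count_per_enriched_5utr > 0
    if plant_kmers:
        utr5, planted = generate_sequences_with_planted_kmers(
            config, annotation, truth)
        ds.utr5_sequences = utr5
        truth.planted_kmers = planted
    else:
        ds.utr5_sequences = {g: _extract_utr5(annotation, g)
                             for g in annotation.genes["gene_id"]}
    return ds


def _extract_utr5(annotation: Annotation, gene_id: str) -> str:
    contig, start, end = annotation.utr5_interval(gene_id)
    return annotation.genome[contig][start:end]


def default_planted_kmer(es_sequence: str, k: int = 6) -> str:
    """A deterministic k-mer from the middle of the ES reverse complement."""
    rc = _kmers.reverse_complement(es_sequence)
    if k > len(rc):
        raise ValueError("requested k-mer longer than the ES sequence")
    mid = (len(rc) - k) // 2
    return rc[mid:mid + k]


def generate_sequences_with_planted_kmers(
        config: SimulationConfig, annotation: Annotation,
        truth: SimulationTruth) -> tuple[dict[str, str], pd.DataFrame]:
    """Plant ES-complementary k-mers into the 5' UTRs of enriched genes.

    The planted k-mer (default: the central 6-mer of the ES reverse
    complement) is written at non-overlapping random positions of each
    enriched gene's 5' UTR, patching the genome in place; background 5' UTRs
    stay i.i.d. uniform.  Returns the per-gene 5' UTR sequences and the
    planted-position table (UTR-local and genomic coordinates).
    """
    kmer = config.planted_kmer or default_planted_kmer(config.es_sequence)
    if len(kmer) > len(config.es_sequence):
        raise ValueError("planted k-mer longer than the ES sequence")
    rc = _kmers.reverse_complement(config.es_sequence)
    if kmer not in rc:
        raise ValueError("planted k-mer is not a substring of the ES "
                         "reverse complement")
    rng = _rng(config, 4)
    k = len(kmer)
    count = config.planted_kmer_count_per_enriched_5utr
    if truth.segments is not None:
        enr_genes = set(truth.segments.loc[
            (truth.segments["region"] == FIVE_UTR)
            & truth.segments["enriched"], "gene_id"])
    else:
        enr_genes = set()
    records = []
    utr5_seqs: dict[str, str] = {}
    for g in annotation.genes.itertuples(index=False):
        contig, start, end = annotation.utr5_interval(g.gene_id)
        if g.gene_id in enr_genes and count > 0:
            utr_len = end - start
            positions: list[int] = []
            attempts = 0
            while len(positions) < count and attempts < 1000:
                attempts += 1
                pos = int(rng.integers(0, utr_len - k + 1))
                if all(abs(pos - p) >= k for p in positions):
                    positions.append(pos)
            if len(positions) < count:
                warnings.warn(f"could only plant {len(positions)} k-mers "
                              f"in {g.gene_id} 5'UTR")
            seq = list(annotation.genome[contig])
            for pos in sorted(positions):
                seq[start + pos:start + pos + k] = kmer
                records.append((g.gene_id, contig, pos, start + pos, kmer))
            annotation.genome[contig] = "".join(seq)
        utr5_seqs[g.gene_id] = annotation.genome[contig][start:end]
    planted = pd.DataFrame(records, columns=["gene_id", "contig", "utr_pos",
                                             "genomic_pos", "kmer"])
    return utr5_seqs, planted


# ---------------------------------------------------------------------------
# SAM emission


def generate_alignments(count_matrix: CountMatrix, annotation: Annotation,
                        out_dir: str | Path,
                        fragments: dict[str, list[tuple[str, int, int]]] | None = None,
                        read_length: int = 75,
                        seed: int = 0) -> dict[str, Path]:
    """Emit one SAM per sample as properly-paired ungapped fragments.

    With ``fragments`` (as produced by :func:`generate_dataset`) the emitted
    files re-count exactly to the matrix.  Without them, fragments are placed
    uniformly inside each counted window — adjacent windows overlap, so
    re-counting such files is approximate (each placed fragment may also hit
    a neighbouring window).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fragments is None:
        rng = np.random.default_rng(seed)
        if count_matrix.windows is None:
            raise ValueError("matrix without window coordinates; "
                             "pass explicit fragments")
        fragments = {}
        for sample in count_matrix.counts.columns:
            frs = []
            col = count_matrix.counts[sample]
            for w, c in zip(count_matrix.windows, col):
                for _ in range(int(c)):
                    ln = min(w.end - w.start,
                             int(rng.integers(40, 201)))
                    start = w.start + int(rng.integers(0, w.end - w.start - ln + 1))
                    frs.append((w.chrom, start, start + ln))
            fragments[sample] = frs
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in annotation.contig_lengths.items()],
    }
    tid = {c: i for i, c in enumerate(annotation.contig_lengths)}
    paths: dict[str, Path] = {}
    for sample, frs in fragments.items():
        path = out_dir / f"{sample}.sam"
        with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
            for fi, (contig, start, end) in enumerate(frs):
                ln = end - start
                if ln > annotation.contig_lengths[contig]:
                    raise ValueError("fragment longer than its contig")
                rl = min(read_length, ln)
                seq = annotation.genome[contig]
                for mate in (0, 1):
                    a = pysam.AlignedSegment()
                    a.query_name = f"{sample}.frag{fi}"
                    a.reference_id = tid[contig]
                    a.mapping_quality = 60
                    a.cigartuples = [(0, rl)]
                    if mate == 0:
                        a.reference_start = start
                        a.flag = 0x1 | 0x2 | 0x20 | 0x40
                        a.next_reference_start = end - rl
                        a.template_length = ln
                        a.query_sequence = seq[start:start + rl]
                    else:
                        a.reference_start = end - rl
                        a.flag = 0x1 | 0x2 | 0x10 | 0x80
                        a.next_reference_start = start
                        a.template_length = -ln
                        a.query_sequence = seq[end - rl:end]
                    a.next_reference_id = tid[contig]
                    a.query_qualities = pysam.qualitystring_to_array("I" * rl)
                    fh.write(a)
        paths[sample] = path
    return paths


# ---------------------------------------------------------------------------
# On-disk fixture


def write_dataset(ds: SimulatedDataset, out_dir: str | Path,
                  write_sam: bool = True) -> dict[str, object]:
    """Write a dataset to disk (GTF, FASTA, SAMs, counts, truth, manifest)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds.annotation.write_gtf(out_dir / "annotation.gtf")
    ds.annotation.write_fasta(out_dir / "genome.fa")
    ds.count_matrix.to_tsv(out_dir / "counts.tsv")
    ds.truth.windows.to_csv(out_dir / "truth_windows.tsv", sep="\t")
    if ds.truth.segments is not None:
        ds.truth.segments.to_csv(out_dir / "truth_segments.tsv", sep="\t",
                                 index=False)
    if ds.truth.planted_kmers is not None:
        ds.truth.planted_kmers.to_csv(out_dir / "truth_planted_kmers.tsv",
                                      sep="\t", index=False)
    with open(out_dir / "es.fa", "w") as fh:
        fh.write(">ES_synthetic\n" + ds.config.es_sequence + "\n")
    with open(out_dir / "utr5.fa", "w") as fh:
        for gene, seq in ds.utr5_sequences.items():
            fh.write(f">{gene}\n{seq}\n")
    ds.count_matrix.samples.to_csv(out_dir / "samples.tsv", sep="\t",
                                   index_label="sample")
    manifest: dict[str, object] = {
        "seed": ds.config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(ds.config).items()},
        "files": sorted(p.name for p in out_dir.iterdir()),
    }
    if write_sam:
        paths = generate_alignments(ds.count_matrix, ds.annotation,
                                    out_dir / "alignments",
                                    fragments=ds.fragments)
        manifest["alignments"] = {s: str(p) for s, p in paths.items()}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
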