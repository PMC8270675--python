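"""End-to-end orchestration: counts -> normalization -> moderated t ->
empirical-null local fdr -> region / gene-set / k-mer enrichment.

Each stage reads and writes plain files with documented schemas and can be
run standalone; :func:`run_pipeline` chains them and records every parameter,
seed and output checksum in a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .diffbind import DiffBindResult, run_diffbind
from .empnull import EmpiricalNullConfig, EmpiricalNullFit, fit_local_fdr
from .enrichment import (PRIMARY_LABEL, RegionContingency, gene_set_enrichment,
                         genes_with_enriched_region, region_chisq_permutation)
from .kmers import KmerEnrichmentTable, kmer_enrichment, map_kmers_to_utrs
from .normalize import NormalizationFactors, log_cpm, tmm_factors
from .windows import (FIVE_UTR, CountMatrix, annotate_windows, count_fragments,
                      filter_low_count, make_windows, windows_to_frame)

logger = logging.getLogger("velcro")


@dataclass
class RunConfig:
    """Everything one run needs; unset optional inputs skip their stage."""

    out_dir: str
    counts_tsv: str | None = None
    alignments: dict[str, str] | None = None     # sample -> SAM/BAM path
    sample_sheet: str | None = None              # TSV: sample, condition, replicate
    gtf: str | None = None
    genome_fasta: str | None = None
    es_fasta: str | None = None
    term_map: str | None = None                  # TSV term<TAB>gene
    window_width: int = 200
    window_step: int = 100
    min_total_count: int = 30
    voom_span: float = 0.5
    n_bins: int = 150
    spline_df: int = 25
    fdr_threshold: float = 0.05
    chisq_permutations: int = 100_000
    geneset_permutations: int = 1000
    kmer_min: int = 4
    kmer_max: int = 8
    seed: int = 0


def validate_config(config: RunConfig) -> list[str]:
    """Collect human-readable validation errors (empty list == valid)."""
    errors: list[str] = []
    if config.counts_tsv is None and not config.alignments:
        errors.append("either counts_tsv or alignments must be given")
    if config.alignments and config.gtf is None:
        errors.append("alignment input requires a GTF for annotation")
    for name, path in [("counts_tsv", config.counts_tsv), ("gtf", config.gtf),
                       ("genome_fasta", config.genome_fasta),
                       ("es_fasta", config.es_fasta),
                       ("term_map", config.term_map),
                       ("sample_sheet", config.sample_sheet)]:
        if path is not None and not Path(path).exists():
            errors.append(f"{name} path does not exist: {path}")
    for sample, path in (config.alignments or {}).items():
        if not Path(path).exists():
            errors.append(f"alignment for {sample} does not exist: {path}")
    if config.window_width < config.window_step or config.window_step < 1:
        errors.append("need window_width >= window_step >= 1")
    if config.n_bins < 10:
        errors.append("n_bins must be >= 10 for the empirical-null stage")
    if config.spline_df >= config.n_bins:
        errors.append("spline_df must be smaller than n_bins")
    if not 0 < config.fdr_threshold < 1:
        errors.append("fdr_threshold must be in (0, 1)")
    if not 0 <= config.kmer_min <= config.kmer_max:
        errors.append("need 0 <= kmer_min <= kmer_max")
    return errors


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    if "condition" not in df.columns:
        raise ValueError("sample sheet needs a 'condition' column")
    return df


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (term, gene) or GMT (term, description, genes...)."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if path and str(path).endswith(".gmt"):
                term, genes = parts[0], parts[2:]
            else:
                term, genes = parts[0], parts[1:2]
            terms.setdefault(term, set()).update(g for g in genes if g)
    return terms


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    matrix: CountMatrix
    factors: NormalizationFactors
    diffbind: DiffBindResult
    locfdr: EmpiricalNullFit
    window_table: pd.DataFrame
    region: RegionContingency | None = None
    geneset: pd.DataFrame | None = None
    kmers: KmerEnrichmentTable | None = None
    kmer_utr_map: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)

    @property
    def enriched_fraction_estimate(self) -> float:
        return self.locfdr.nonnull_proportion


def analyze_counts(matrix: CountMatrix, min_total: int = 30,
                   voom_span: float = 0.5,
                   null_config: EmpiricalNullConfig | None = None,
                   seed: int = 0) -> tuple[CountMatrix, NormalizationFactors,
                                           DiffBindResult, EmpiricalNullFit]:
    """The statistical core: filter -> TMM -> voom-limma -> local fdr."""
    filtered = filter_low_count(matrix, min_total)
    if filtered.n_windows == 0:
        raise RuntimeError("no windows pass the minimum-count filter")
    factors = tmm_factors(filtered)
    diffbind = run_diffbind(filtered, factors, span=voom_span)
    null_config = null_config or EmpiricalNullConfig()
    fit = fit_local_fdr(diffbind.table["t"].to_numpy(), null_config,
                        index=diffbind.table.index, seed=seed)
    return filtered, factors, diffbind, fit


def run_pipeline(config: RunConfig) -> PipelineResult:
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_outputs: dict[str, str] = {}
    warnings_log: list[str] = []

    def _record(name: str, path: Path) -> None:
        stage_outputs[name] = _sha256(path)

    samples = (read_sample_sheet(config.sample_sheet)
               if config.sample_sheet else None)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- quantification ---------------------------------------------
        if config.counts_tsv is not None:
            logger.info("stage=counts loading %s", config.counts_tsv)
            if samples is None:
                raise ValueError("counts input requires a sample sheet")
            matrix = CountMatrix.from_tsv(config.counts_tsv, samples)
            if (config.gtf is not None and matrix.windows is not None):
                annotate_windows(matrix.windows, config.gtf)
        else:
            logger.info("stage=count counting %d alignment files",
                        len(config.alignments))
            contig_lengths = _contig_lengths_from_alignments(config.alignments)
            windows = make_windows(contig_lengths, config.window_width,
                                   config.window_step)
            matrix = count_fragments(config.alignments, windows, samples)
            annotate_windows(matrix.windows, config.gtf)

        # --- statistics --------------------------------------------------
        null_config = EmpiricalNullConfig(
            n_bins=config.n_bins, spline_df=config.spline_df,
            fdr_threshold=config.fdr_threshold)
        filtered, factors, diffbind, fit = analyze_counts(
            matrix, config.min_total_count, config.voom_span, null_config,
            seed=config.seed)
        logger.info("stage=locfdr tested=%d enriched=%d nonnull=%.3f",
                    filtered.n_windows, fit.n_enriched, fit.nonnull_proportion)

        table = diffbind.table.copy()
        table["fdr"] = fit.fdr
        table["enriched"] = fit.enriched
        if filtered.windows is not None:
            meta = windows_to_frame(filtered.windows).set_index("window_id")
            table = meta.join(table, how="right")
        factors_df = pd.DataFrame({
            "library_size": filtered.library_size,
            "factor": factors.factors,
            "effective_library_size": factors.effective_library_size})
        factors_df.to_csv(out / "normalization.tsv", sep="\t",
                          index_label="sample")
        _record("normalization", out / "normalization.tsv")
        table.to_csv(out / "windows.tsv", sep="\t", index_label="window_id")
        _record("windows", out / "windows.tsv")
        null_report = pd.DataFrame([{
            "delta0": fit.null.delta0, "sigma0": fit.null.sigma0,
            "p0": fit.null.p0, "nonnull_fraction": fit.nonnull_proportion,
            "posterior_nonnull_mass": fit.posterior_nonnull_mass,
            "n_enriched": fit.n_enriched}])
        null_report.to_csv(out / "empirical_null.tsv", sep="\t", index=False)
        _record("empirical_null", out / "empirical_null.tsv")

        # --- region / gene-set enrichment --------------------------------
        region = geneset = None
        if "primary_label" in table.columns:
            labelled = table[table["primary_label"] != "NONE"]
            if labelled["enriched"].nunique() > 1 and len(labelled) > 1:
                region = region_chisq_permutation(
                    labelled["primary_label"].to_numpy(),
                    labelled["enriched"].to_numpy(),
                    B=config.chisq_permutations, mode=PRIMARY_LABEL,
                    seed=config.seed)
                region.table.assign(fold=region.fold).to_csv(
                    out / "region_contingency.tsv", sep="\t",
                    index_label="region")
                _record("region", out / "region_contingency.tsv")
            if config.term_map is not None:
                term_map = read_term_map(config.term_map)
                background = set(
                    g for gl in table["gene_ids"] if isinstance(gl, str) and gl
                    for g in gl.split(","))
                positive = set(
                    g for gl in table.loc[table["enriched"], "gene_ids"]
                    if isinstance(gl, str) and gl for g in gl.split(","))
                geneset = gene_set_enrichment(
                    positive, background, term_map,
                    n_perm=config.geneset_permutations, seed=config.seed,
                    fdr_threshold=config.fdr_threshold)
                geneset.to_csv(out / "geneset.tsv", sep="\t")
                _record("geneset", out / "geneset.tsv")

        # --- k-mer complementarity ---------------------------------------
        kmer_table = kmer_map = None
        if (config.es_fasta is not None and config.genome_fasta is not None
                and "region_labels" in table.columns):
            genome = read_fasta(config.genome_fasta)
            es = next(iter(read_fasta(config.es_fasta).values()))
            utr_mask = table["region_labels"].fillna("").str.contains(FIVE_UTR)
            utr_tab = table[utr_mask]
            seqs = [genome[r["chrom"]][int(r["start"]):int(r["end"])]
                    for _, r in utr_tab.iterrows()]
            enr_seqs = [s for s, e in zip(seqs, utr_tab["enriched"]) if e]
            if enr_seqs and seqs:
                kmer_table = kmer_enrichment(es, enr_seqs, seqs,
                                             config.kmer_min, config.kmer_max,
                                             config.fdr_threshold)
                kmer_table.table.to_csv(out / "kmers.tsv", sep="\t",
                                        index_label="kmer")
                _record("kmers", out / "kmers.tsv")
                enr_utrs = {wid: s for wid, s, e in
                            zip(utr_tab.index, seqs, utr_tab["enriched"]) if e}
                kmer_map = map_kmers_to_utrs(kmer_table, enr_utrs)
                kmer_map.to_csv(out / "kmer_utr_map.tsv", sep="\t", index=False)
                _record("kmer_utr_map", out / "kmer_utr_map.tsv")

        warnings_log = [str(w.message) for w in caught]

    manifest = {
        "tool_version": __version__,
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "outputs_sha256": stage_outputs,
        "warnings": warnings_log,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(matrix=filtered, factors=factors, diffbind=diffbind,
                          locfdr=fit, window_table=table, region=region,
                          geneset=geneset, kmers=kmer_table,
                          kmer_utr_map=kmer_map, manifest=manifest)


def _contig_lengths_from_alignments(alignments: dict[str, str]) -> dict[str, int]:
    import pysam
    lengths: dict[str, int] = {}
    for path in alignments.values():
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for sq in fh.header.get("SQ", []):
                lengths[sq["SN"]] = max(lengths.get(sq["SN"], 0), sq["LN"])
    if not lengths:
        raise ValueError("no @SQ contigs found in alignment headers")
    return lengths
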