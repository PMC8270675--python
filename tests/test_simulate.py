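"""Synthetic-data generator: determinism, schema, count model, round trips."""

import numpy as np
import pandas as pd
import pysam
import pytest

from velcroseq.kmers import count_kmer_occurrences, reverse_complement
from velcroseq.simulate import (SYNTHETIC_ES, SimulationConfig,
                                default_planted_kmer, generate_alignments,
                                generate_annotation, generate_counts,
                                generate_dataset,
                                generate_sequences_with_planted_kmers,
                                write_dataset)
from velcroseq.windows import FIVE_UTR, count_fragments, make_windows


class TestConfig:
    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, planted_nonnull_fraction=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, nb_dispersion=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, library_sizes=(1.0, 2.0))
        with pytest.raises(ValueError):
            SimulationConfig(seed=1,
                             library_sizes=(1, 1, 1, 1, 1, -2))


class TestGenerateAnnotation:
    def test_fixed_layout_coordinates(self):
        cfg = SimulationConfig(seed=1, n_genes=1,
                               utr5_length_range=(300, 300),
                               cds_length_range=(600, 600),
                               utr3_length_range=(300, 300))
        ann = generate_annotation(cfg)
        gtf = ann.to_gtf()
        assert len(ann.genome[ann.genes.iloc[0]["contig"]]) == 1200
        # CDS starts at 1-based position 301 for the plus-strand layout
        cds_lines = [l for l in gtf.splitlines() if "\tCDS\t" in l]
        assert cds_lines[0].split("\t")[3] == "301"
        assert cds_lines[0].split("\t")[4] == "900"

    def test_deterministic_gtf_bytes(self):
        cfg = SimulationConfig(seed=5, n_genes=100)
        g1 = generate_annotation(cfg).to_gtf()
        g2 = generate_annotation(cfg).to_gtf()
        assert g1 == g2

    def test_different_seeds_same_schema(self):
        a1 = generate_annotation(SimulationConfig(seed=1, n_genes=30))
        a2 = generate_annotation(SimulationConfig(seed=2, n_genes=30))
        assert not a1.genes.equals(a2.genes)
        for ann in (a1, a2):
            for line in ann.to_gtf().splitlines():
                f = line.split("\t")
                assert len(f) == 9
                assert int(f[3]) >= 1
                assert int(f[4]) <= len(ann.genome[f[0]])
                assert f[6] in "+-"

    def test_zero_length_layout_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, utr5_length_range=(0, 0))


class TestGenerateCounts:
    def test_no_planted_effect_fold_change_near_one(self):
        cfg = SimulationConfig(seed=2, n_genes=1000,
                               planted_nonnull_fraction=0.0)
        cm, truth = generate_counts(cfg)
        assert truth.windows["enriched"].sum() == 0
        treat = cm.counts.iloc[:, 3:].mean(axis=1)
        ctrl = cm.counts.iloc[:, :3].mean(axis=1)
        big = ctrl > 50
        ratio = (treat[big] + 1) / (ctrl[big] + 1)
        assert np.median(ratio) == pytest.approx(1.0, abs=0.05)

    def test_low_dispersion_fold_change_approaches_planted(self):
        cfg = SimulationConfig(seed=3, n_genes=1250, windows_per_gene=8,
                               planted_nonnull_fraction=0.5,
                               planted_log2fc=2.0, nb_dispersion=1e-3,
                               mean_log_expression=np.log(500.0))
        cm, truth = generate_counts(cfg)
        enr = truth.windows["enriched"].to_numpy()
        treat = cm.counts.iloc[:, 3:].mean(axis=1).to_numpy()
        ctrl = cm.counts.iloc[:, :3].mean(axis=1).to_numpy()
        fc = treat[enr] / ctrl[enr]
        assert np.median(fc) == pytest.approx(4.0, rel=0.05)

    def test_enriched_fraction_within_binomial_error(self):
        cfg = SimulationConfig(seed=4, n_genes=500, windows_per_gene=8,
                               planted_nonnull_fraction=0.157)
        _, truth = generate_counts(cfg)
        n = len(truth.windows)
        sd = np.sqrt(0.157 * (1 - 0.157) / n)
        assert abs(truth.enriched_fraction - 0.157) <= 3 * sd

    def test_nb_marginal_moments(self):
        # single-window mean/variance across 10^4 replicate draws
        cfg = SimulationConfig(seed=6, n_genes=1250, windows_per_gene=8,
                               planted_nonnull_fraction=0.0,
                               nb_dispersion=0.1, sd_log_expression=1e-9,
                               mean_log_expression=np.log(100.0))
        cm, _ = generate_counts(cfg)
        x = cm.counts.to_numpy().ravel().astype(float)   # 6e4 iid NB draws
        mean, var = x.mean(), x.var()
        assert mean == pytest.approx(100.0, rel=0.02)
        assert var == pytest.approx(100 + 0.1 * 100 ** 2, rel=0.05)

    def test_determinism(self):
        cfg = SimulationConfig(seed=11, n_genes=50)
        c1, t1 = generate_counts(cfg)
        c2, t2 = generate_counts(cfg)
        pd.testing.assert_frame_equal(c1.counts, c2.counts)
        pd.testing.assert_frame_equal(t1.windows, t2.windows)


class TestGenerateDatasetRoundTrip:
    def test_sam_recount_reproduces_matrix_exactly(self, tmp_path):
        ds = generate_dataset(SimulationConfig(seed=8, n_genes=12))
        paths = generate_alignments(ds.count_matrix, ds.annotation, tmp_path,
                                    fragments=ds.fragments)
        cm2 = count_fragments(paths, ds.windows, ds.count_matrix.samples)
        np.testing.assert_array_equal(cm2.counts.to_numpy(),
                                      ds.count_matrix.counts.to_numpy())

    def test_emitted_sam_is_valid(self, tmp_path):
        ds = generate_dataset(SimulationConfig(seed=9, n_genes=3))
        paths = generate_alignments(ds.count_matrix, ds.annotation, tmp_path,
                                    fragments=ds.fragments)
        for path in paths.values():
            with pysam.AlignmentFile(str(path)) as fh:
                n_pairs = 0
                for rec in fh:
                    assert rec.is_paired and rec.is_proper_pair
                    assert not rec.is_unmapped
                    n_pairs += 1
                assert n_pairs % 2 == 0

    def test_zero_count_window_has_no_overlapping_fragment(self):
        ds = generate_dataset(SimulationConfig(seed=10, n_genes=10))
        zero = ds.count_matrix.counts.sum(axis=1) == 0
        zero_windows = [w for w, z in zip(ds.windows, zero) if z]
        all_frags = [f for frs in ds.fragments.values() for f in frs]
        for w in zero_windows[:20]:
            for chrom, s, e in all_frags:
                assert not (chrom == w.chrom and s < w.end and e > w.start)

    def test_direct_mode_single_isolated_window(self, tmp_path):
        # contig of one window: 5 planted counts emit exactly 5 pairs
        # overlapping it
        from velcroseq.simulate import Annotation
        from velcroseq.windows import CountMatrix, GenomicWindow
        ann = Annotation(
            genes=pd.DataFrame([("gX", "cX", "+", 50, 100, 50)],
                               columns=["gene_id", "contig", "strand",
                                        "utr5_len", "cds_len", "utr3_len"]),
            contig_lengths={"cX": 200},
            genome={"cX": "A" * 200})
        windows = [GenomicWindow("cX", 0, 200)]
        samples = pd.DataFrame({"condition": ["WT"], "replicate": [1]},
                               index=["s1"])
        cm = CountMatrix(pd.DataFrame({"s1": [5]}, index=["cX:0-200"]),
                         samples, windows=windows)
        paths = generate_alignments(cm, ann, tmp_path, seed=0)
        cm2 = count_fragments(paths, windows, samples)
        assert cm2.counts.loc["cX:0-200", "s1"] == 5

    def test_truth_fraction_tracks_config(self):
        ds = generate_dataset(SimulationConfig(seed=12, n_genes=150,
                                               planted_nonnull_fraction=0.157))
        frac = ds.truth.windows["enriched"].mean()
        assert 0.05 < frac < 0.4   # segment planting inflates window fraction


class TestPlantedKmers:
    def test_planted_positions_index_the_kmer(self):
        cfg = SimulationConfig(seed=13, n_genes=60)
        ds = generate_dataset(cfg)
        planted = ds.truth.planted_kmers
        assert planted is not None and len(planted) > 0
        for rec in planted.itertuples(index=False):
            seq = ds.utr5_sequences[rec.gene_id]
            assert seq[rec.utr_pos:rec.utr_pos + len(rec.kmer)] == rec.kmer
            genome = ds.annotation.genome[rec.contig]
            assert genome[rec.genomic_pos:rec.genomic_pos + len(rec.kmer)] == rec.kmer

    def test_planted_count_met_in_every_enriched_utr(self):
        cfg = SimulationConfig(seed=14, n_genes=60,
                               planted_kmer_count_per_enriched_5utr=3)
        ds = generate_dataset(cfg)
        km = default_planted_kmer(cfg.es_sequence)
        enriched_genes = set(ds.truth.planted_kmers["gene_id"])
        for g in enriched_genes:
            assert count_kmer_occurrences(km, ds.utr5_sequences[g]) >= 3

    def test_planted_kmer_is_complementary_to_es(self):
        km = default_planted_kmer(SYNTHETIC_ES)
        assert km in reverse_complement(SYNTHETIC_ES)

    def test_overlong_kmer_rejected(self):
        cfg = SimulationConfig(seed=15, n_genes=5, es_sequence="ACGTACGT",
                               planted_kmer="ACGTACGTACGT")
        ann = generate_annotation(cfg)
        ds = generate_dataset(SimulationConfig(seed=15, n_genes=5),
                              plant_kmers=False)
        with pytest.raises(ValueError):
            generate_sequences_with_planted_kmers(cfg, ann, ds.truth)


class TestWriteDataset:
    def test_fixture_files_and_manifest(self, tmp_path):
        ds = generate_dataset(SimulationConfig(seed=16, n_genes=8))
        manifest = write_dataset(ds, tmp_path)
        for name in ("annotation.gtf", "genome.fa", "counts.tsv",
                     "truth_windows.tsv", "es.fa", "utr5.fa",
                     "manifest.json", "samples.tsv"):
            assert (tmp_path / name).exists()
        assert manifest["seed"] == 16
        assert len(manifest["alignments"]) == 6
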