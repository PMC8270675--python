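"""Window construction, fragment counting, filtering and GTF annotation."""

import numpy as np
import pandas as pd
import pysam
import pytest

from velcroseq.windows import (CountMatrix, FIVE_UTR, GenomicWindow, ORF,
                               THREE_UTR, annotate_windows, count_fragments,
                               count_intervals, export_tracks,
                               filter_low_count, make_windows,
                               read_gtf_regions)


def enumerate_windows_oracle(length, width=200, step=100):
    """Independent enumeration of expected (start, end) pairs."""
    out = []
    start = 0
    while start < length:
        iv = (start, min(start + width, length))
        if iv not in out:
            out.append(iv)
        start += step
    return out


class TestMakeWindows:
    def test_matches_enumeration_oracle_on_random_lengths(self):
        rng = np.random.default_rng(0)
        for length in rng.integers(1, 5000, size=50):
            length = int(length)
            got = [(w.start, w.end) for w in make_windows({"c": length})]
            assert got == enumerate_windows_oracle(length)

    @pytest.mark.parametrize("length,expected", [
        (400, [(0, 200), (100, 300), (200, 400), (300, 400)]),
        (50, [(0, 50)]),
        (200, [(0, 200), (100, 200)]),
    ])
    def test_spec_examples(self, length, expected):
        got = [(w.start, w.end) for w in make_windows({"c": length})]
        assert got == expected

    def test_rejects_bad_width_step(self):
        with pytest.raises(ValueError):
            make_windows({"c": 100}, width=0)
        with pytest.raises(ValueError):
            make_windows({"c": 100}, step=0)
        with pytest.raises(ValueError):
            make_windows({"c": 0})

    def test_drop_partial(self):
        got = [(w.start, w.end) for w in make_windows({"c": 450},
                                                      drop_partial=True)]
        assert got == [(0, 200), (100, 300), (200, 400)]

    def test_window_id_format(self):
        ids = [w.window_id for w in make_windows({"chr1": 250})]
        assert ids == ["chr1:0-200", "chr1:100-250", "chr1:200-250"]


def write_sam(path, contig_lengths, fragments, read_length=50):
    """Write properly-paired fragments to SAM for counting tests."""
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": c, "LN": l} for c, l in contig_lengths.items()]}
    tid = {c: i for i, c in enumerate(contig_lengths)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for i, (chrom, start, end) in enumerate(fragments):
            rl = min(read_length, end - start)
            for mate in (0, 1):
                a = pysam.AlignedSegment()
                a.query_name = f"frag{i}"
                a.reference_id = tid[chrom]
                a.next_reference_id = tid[chrom]
                a.mapping_quality = 60
                a.cigartuples = [(0, rl)]
                a.query_sequence = "A" * rl
                if mate == 0:
                    a.reference_start = start
                    a.flag = 0x1 | 0x2 | 0x20 | 0x40
                    a.next_reference_start = end - rl
                else:
                    a.reference_start = end - rl
                    a.flag = 0x1 | 0x2 | 0x10 | 0x80
                    a.next_reference_start = start
                fh.write(a)


def overlap_oracle(fragments, windows):
    """Brute-force interval-overlap counting."""
    col = np.zeros(len(windows), dtype=int)
    for chrom, s, e in fragments:
        for i, w in enumerate(windows):
            if w.chrom == chrom and s < w.end and e > w.start:
                col[i] += 1
    return col


class TestCountFragments:
    def test_random_fragments_match_overlap_oracle(self, tmp_path):
        rng = np.random.default_rng(1)
        lengths = {"c1": 4000, "c2": 1500}
        windows = make_windows(lengths)
        fragments = []
        for _ in range(1000):
            chrom = "c1" if rng.random() < 0.7 else "c2"
            L = lengths[chrom]
            s = int(rng.integers(0, L - 60))
            e = s + int(rng.integers(50, min(400, L - s)))
            fragments.append((chrom, s, min(e, L)))
        sam = tmp_path / "s.sam"
        write_sam(sam, lengths, fragments)
        cm = count_fragments({"s1": sam}, windows)
        np.testing.assert_array_equal(cm.counts["s1"].to_numpy(),
                                      overlap_oracle(fragments, windows))

    @pytest.mark.parametrize("frag,expected_hits", [
        ((150, 260), [(0, 200), (100, 300), (200, 400)]),
        ((200, 210), [(100, 300), (200, 400)]),   # half-open boundary
    ])
    def test_boundary_overlap(self, frag, expected_hits):
        windows = make_windows({"c": 400})
        col = count_intervals([("c", *frag)], windows)
        hit = [(w.start, w.end) for w, c in zip(windows, col) if c]
        assert hit == expected_hits

    def test_empty_sam_gives_zero_column(self, tmp_path):
        sam = tmp_path / "e.sam"
        write_sam(sam, {"c": 400}, [])
        cm = count_fragments({"s1": sam}, make_windows({"c": 400}))
        assert (cm.counts["s1"] == 0).all()

    def test_pair_counted_once_even_when_mates_share_window(self, tmp_path):
        sam = tmp_path / "p.sam"
        write_sam(sam, {"c": 400}, [("c", 10, 150)])
        cm = count_fragments({"s1": sam}, make_windows({"c": 400}))
        assert cm.counts["s1"].tolist() == [1, 1, 0, 0]

    def test_fragment_increment_bound(self):
        # contained fragment of length <= width overlaps at most
        # ceil(width/step) + 1 windows
        # away from the contig end (truncated trailing windows duplicate
        # coverage), a fragment [s, e) hits exactly the windows whose starts
        # (multiples of step) lie in the open interval (s - width, e)
        windows = make_windows({"c": 2000})
        rng = np.random.default_rng(2)
        for _ in range(200):
            s = int(rng.integers(0, 1600))
            e = s + int(rng.integers(1, 201))
            col = count_intervals([("c", s, e)], windows)
            n_starts = len([m for m in range(0, 2000, 100)
                            if s - 200 < m < e])
            assert col.sum() == n_starts
            assert col.sum() <= int(np.ceil((200 + (e - s)) / 100))


class TestFilterLowCount:
    def test_boundary_keeps_exactly_min_total(self, sample_sheet_3v3):
        counts = pd.DataFrame(
            [[4, 5, 5, 5, 5, 5],      # 29 -> dropped
             [5, 5, 5, 5, 5, 5],      # 30 -> kept
             [6, 5, 5, 5, 5, 5]],     # 31 -> kept
            index=["w29", "w30", "w31"], columns=sample_sheet_3v3.index)
        cm = CountMatrix(counts, sample_sheet_3v3)
        out = filter_low_count(cm, 30)
        assert out.counts.index.tolist() == ["w30", "w31"]

    def test_min_total_zero_is_identity(self, nb_matrix_factory):
        cm = nb_matrix_factory(3, n_windows=100)
        out = filter_low_count(cm, 0)
        assert out.counts.equals(cm.counts)

    def test_all_zero_matrix_gives_valid_empty(self, sample_sheet_3v3):
        counts = pd.DataFrame(0, index=["w1", "w2"],
                              columns=sample_sheet_3v3.index)
        out = filter_low_count(CountMatrix(counts, sample_sheet_3v3), 30)
        assert out.n_windows == 0

    def test_library_sizes_not_recomputed(self, nb_matrix_factory):
        cm = nb_matrix_factory(4, n_windows=500)
        out = filter_low_count(cm, 200)
        assert out.n_windows < cm.n_windows
        pd.testing.assert_series_equal(out.library_size, cm.library_size)


GTF_PLUS = """\
chr1\tx\tgene\t1\t1200\t.\t+\t.\tgene_id "gA";
chr1\tx\ttranscript\t1\t1200\t.\t+\t.\tgene_id "gA"; transcript_id "tA";
chr1\tx\tfive_prime_utr\t1\t300\t.\t+\t.\tgene_id "gA"; transcript_id "tA";
chr1\tx\tCDS\t301\t900\t.\t+\t.\tgene_id "gA"; transcript_id "tA";
chr1\tx\tthree_prime_utr\t901\t1200\t.\t+\t.\tgene_id "gA"; transcript_id "tA";
"""

# minus-strand transcript using generic UTR features: the UTR right of the
# CDS in genome coordinates is the 5' UTR
GTF_MINUS_GENERIC = """\
chr2\tx\tgene\t1\t900\t.\t-\t.\tgene_id "gB";
chr2\tx\ttranscript\t1\t900\t.\t-\t.\tgene_id "gB"; transcript_id "tB";
chr2\tx\tUTR\t1\t200\t.\t-\t.\tgene_id "gB"; transcript_id "tB";
chr2\tx\tCDS\t201\t700\t.\t-\t.\tgene_id "gB"; transcript_id "tB";
chr2\tx\tUTR\t701\t900\t.\t-\t.\tgene_id "gB"; transcript_id "tB";
"""


class TestAnnotateWindows:
    def test_window_inside_5utr(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(GTF_PLUS)
        w = GenomicWindow("chr1", 0, 200)
        annotate_windows([w], gtf)
        assert w.region_labels == {FIVE_UTR}
        assert w.gene_ids == {"gA"}
        assert w.primary_label == FIVE_UTR

    def test_window_straddling_utr_cds_junction(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(GTF_PLUS)
        w = GenomicWindow("chr1", 200, 400)   # 5'UTR ends at 300 (0-based)
        annotate_windows([w], gtf)
        assert w.region_labels == {FIVE_UTR, ORF}
        assert w.primary_label == FIVE_UTR

    def test_minus_strand_generic_utr_resolution(self, tmp_path):
        gtf = tmp_path / "b.gtf"
        gtf.write_text(GTF_MINUS_GENERIC)
        right = GenomicWindow("chr2", 750, 900)
        left = GenomicWindow("chr2", 0, 150)
        annotate_windows([right, left], gtf)
        assert right.region_labels == {FIVE_UTR}
        assert left.region_labels == {THREE_UTR}

    def test_cds_without_strand_rejected(self, tmp_path):
        gtf = tmp_path / "c.gtf"
        gtf.write_text('chr1\tx\tCDS\t1\t90\t.\t.\t.\tgene_id "g"; '
                       'transcript_id "t";\n')
        with pytest.raises(ValueError, match="t"):
            read_gtf_regions(gtf)

    def test_record_order_invariance(self, tmp_path):
        lines = GTF_PLUS.strip().split("\n")
        shuffled = [lines[i] for i in (4, 2, 0, 3, 1)]
        g1, g2 = tmp_path / "o1.gtf", tmp_path / "o2.gtf"
        g1.write_text(GTF_PLUS)
        g2.write_text("\n".join(shuffled) + "\n")
        w1 = make_windows({"chr1": 1200})
        w2 = make_windows({"chr1": 1200})
        annotate_windows(w1, g1)
        annotate_windows(w2, g2)
        for a, b in zip(w1, w2):
            assert a.region_labels == b.region_labels
            assert a.gene_ids == b.gene_ids


class TestExportTracks:
    def _matrix(self, sample_sheet_3v3, scale_last=1):
        windows = make_windows({"c": 600})
        rng = np.random.default_rng(5)
        base = rng.integers(10, 100, size=len(windows))
        counts = pd.DataFrame({s: base for s in sample_sheet_3v3.index},
                              index=[w.window_id for w in windows])
        counts[counts.columns[-1]] *= scale_last
        return CountMatrix(counts, sample_sheet_3v3, windows=windows)

    def test_identical_samples_identical_tracks(self, sample_sheet_3v3):
        cm = self._matrix(sample_sheet_3v3)
        f = pd.Series(1.0, index=cm.counts.columns)
        tracks = export_tracks(cm, f)
        first = tracks[cm.counts.columns[0]]
        for s in cm.counts.columns[1:]:
            pd.testing.assert_frame_equal(tracks[s], first)

    def test_doubling_library_size_halves_values(self, sample_sheet_3v3):
        cm = self._matrix(sample_sheet_3v3)
        f = pd.Series(1.0, index=cm.counts.columns)
        t1 = export_tracks(cm, f)
        cm2 = CountMatrix(cm.counts, cm.samples, windows=cm.windows,
                          library_size=cm.library_size * 2)
        t2 = export_tracks(cm2, f)
        s = cm.counts.columns[0]
        np.testing.assert_allclose(t2[s]["value"], t1[s]["value"] / 2)

    def test_bedgraph_syntax_and_totals(self, sample_sheet_3v3, tmp_path):
        cm = self._matrix(sample_sheet_3v3)
        f = pd.Series(1.0, index=cm.counts.columns)
        export_tracks(cm, f, tmp_path)
        s = cm.counts.columns[0]
        lines = (tmp_path / f"{s}.bedGraph").read_text().strip().split("\n")
        assert lines[0].startswith("track type=bedGraph")
        prev_end = {}
        total = 0.0
        for line in lines[1:]:
            chrom, start, end, value = line.split("\t")
            start, end, value = int(start), int(end), float(value)
            assert end > start
            assert start >= prev_end.get(chrom, 0)
            prev_end[chrom] = end
            total += value
        expected = (cm.counts[s] / cm.library_size[s] * 1e6).sum()
        assert total == pytest.approx(expected, rel=1e-6)

    def test_nonpositive_factor_rejected(self, sample_sheet_3v3):
        cm = self._matrix(sample_sheet_3v3)
        f = pd.Series(1.0, index=cm.counts.columns)
        f.iloc[0] = 0.0
        with pytest.raises(ValueError):
            export_tracks(cm, f)
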