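"""Format boundary: parsing, coordinate conversion, round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acetylseq import (GenomicInterval, ParseError, read_bed, read_bedgraph,
                       read_cx_report, read_expression_table, read_gene_models,
                       write_bed, write_bedgraph)
from acetylseq.formats_io import (ExpressionRecord, GeneModel,
                                  write_expression_table, write_gene_models)


class TestBed:
    @pytest.mark.parametrize("line,expected", [
        ("chr1\t100\t200",
         GenomicInterval("chr1", 100, 200)),
        ("chr1\t100\t200\tpk1\t7.5\t+",
         GenomicInterval("chr1", 100, 200, score=7.5, name="pk1", strand="+")),
        ("chr1\t0\t1\t.\t.\t-",
         GenomicInterval("chr1", 0, 1, strand="-")),
    ])
    def test_field_mapping(self, tmp_path, line, expected):
        p = tmp_path / "a.bed"
        p.write_text(line + "\n")
        assert read_bed(p) == [expected]

    @pytest.mark.parametrize("line,msg", [
        ("chr1\t200\t100", "start >= end at line 1"),
        ("chr1\tx\t100", "non-integer"),
        ("chr1\t100", "fewer than 3"),
    ])
    def test_malformed_lines(self, tmp_path, line, msg):
        p = tmp_path / "bad.bed"
        p.write_text(line + "\n")
        with pytest.raises(ParseError, match=msg):
            read_bed(p)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 10_000), st.integers(1, 500),
                              st.one_of(st.none(), st.floats(0, 100)),
                              st.sampled_from([None, "+", "-"])),
                    min_size=1, max_size=20))
    def test_round_trip_identity(self, tmp_path_factory, rows):
        ivs = [GenomicInterval("chr1", s, s + l, score=None if sc is None else round(sc, 3),
                               name=f"iv{i}", strand=std)
               for i, (s, l, sc, std) in enumerate(rows)]
        p = tmp_path_factory.mktemp("bed") / "rt.bed"
        write_bed(ivs, p)
        assert read_bed(p) == ivs


class TestGff:
    GFF = """##gff-version 3
chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=gA;biotype=protein_coding
chr1\tsrc\tmRNA\t1001\t2000\t.\t+\t.\tID=gA.1;Parent=gA
chr1\tsrc\texon\t1001\t1400\t.\t+\t.\tID=gA.1.e1;Parent=gA.1
chr1\tsrc\texon\t1601\t2000\t.\t+\t.\tID=gA.1.e2;Parent=gA.1
chr1\tsrc\tfive_prime_UTR\t1001\t1100\t.\t+\t.\tID=gA.1.u5;Parent=gA.1
chr1\tsrc\tthree_prime_UTR\t1901\t2000\t.\t+\t.\tID=gA.1.u3;Parent=gA.1
chr1\tsrc\tgene\t5001\t6000\t.\t-\t.\tID=gB
chr1\tsrc\tmRNA\t5001\t6000\t.\t-\t.\tID=gB.1;Parent=gB
chr1\tsrc\texon\t5001\t6000\t.\t-\t.\tID=gB.1.e1;Parent=gB.1
"""

    def test_coordinate_conversion_and_strand(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(self.GFF)
        genes = {g.gene_id: g for g in read_gene_models(p)}
        ga = genes["gA"]
        assert (ga.start, ga.end, ga.tss, ga.tes) == (1000, 2000, 1000, 1999)
        assert ga.exons == [(1000, 1400), (1600, 2000)]
        assert ga.utr5 == [(1000, 1100)] and ga.utr3 == [(1900, 2000)]
        gb = genes["gB"]
        assert gb.tss == 5999 and gb.strand == "-"

    def test_longest_mrna_wins_tie_by_file_order(self, tmp_path):
        gff = ("##gff-version 3\n"
               "chr1\ts\tgene\t101\t900\t.\t+\t.\tID=g\n"
               "chr1\ts\tmRNA\t101\t500\t.\t+\t.\tID=m_short;Parent=g\n"
               "chr1\ts\texon\t101\t500\t.\t+\t.\tID=e1;Parent=m_short\n"
               "chr1\ts\tmRNA\t101\t900\t.\t+\t.\tID=m_long_b;Parent=g\n"
               "chr1\ts\texon\t101\t900\t.\t+\t.\tID=e2;Parent=m_long_b\n"
               "chr1\ts\tmRNA\t101\t900\t.\t+\t.\tID=m_long_c;Parent=g\n"
               "chr1\ts\texon\t101\t450\t.\t+\t.\tID=e3;Parent=m_long_c\n")
        p = tmp_path / "t.gff3"
        p.write_text(gff)
        (g,) = read_gene_models(p)
        # both long mRNAs span 800 bp; the first in the file wins
        assert g.exons == [(100, 900)]

    def test_write_read_inverse_on_random_genes(self, tmp_path):
        rng = np.random.default_rng(0)
        genes = []
        pos = 100
        for i in range(50):
            start = pos + int(rng.integers(10, 500))
            end = start + int(rng.integers(200, 3000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"g{i:03d}", "chr1", strand, start, end))
            pos = end
        p = tmp_path / "rt.gff3"
        write_gene_models(genes, p)
        back = read_gene_models(p)
        assert [(g.gene_id, g.start, g.end, g.strand, g.tss) for g in back] == \
               [(g.gene_id, g.start, g.end, g.strand, g.tss) for g in genes]


class TestCxReport:
    def test_basic_conversion(self, tmp_path):
        p = tmp_path / "cx.txt"
        p.write_text("chr1\t101\t+\t3\t7\tCG\tCGA\n"
                     "chr1\t50\t-\t0\t0\tCHH\tCTT\n")
        table = read_cx_report(p)
        first = table[0]
        assert (first.pos, first.context, first.n_meth, first.n_total) == (100, "CG", 3, 10)
        assert table[1].n_total == 0  # kept; filtered downstream

    @pytest.mark.parametrize("line,msg", [
        ("chr1\t10\t+\t1\t1\tCXG\tCXG", "unknown context"),
        ("chr1\t10\t+\t-1\t1\tCG\tCGA", "negative count"),
    ])
    def test_parse_errors(self, tmp_path, line, msg):
        p = tmp_path / "bad.txt"
        p.write_text(line + "\n")
        with pytest.raises(ParseError, match=msg):
            read_cx_report(p)


class TestBedgraph:
    def test_library_size_is_value_times_length(self, tmp_path):
        p = tmp_path / "a.bg"
        p.write_text("chr1 0 100 2.0\n")
        track = read_bedgraph(p)
        assert track.library_size == pytest.approx(200.0)
        assert track.sum_range("chr1", 0, 100) == pytest.approx(200.0)

    def test_abutting_equal_steps_preserved(self, tmp_path):
        p = tmp_path / "b.bg"
        p.write_text("chr1\t0\t50\t1.0\nchr1\t50\t100\t1.0\n")
        track = read_bedgraph(p)
        assert len(list(track.steps("chr1"))) == 2

    def test_overlapping_steps_rejected(self, tmp_path):
        p = tmp_path / "c.bg"
        p.write_text("chr1\t0\t100\t1.0\nchr1\t50\t150\t1.0\n")
        with pytest.raises(ParseError, match="overlapping coverage"):
            read_bedgraph(p)

    def test_library_size_matches_bruteforce_and_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        lines, dense = [], np.zeros(5000)
        pos = 0
        while pos < 4500:
            ln = int(rng.integers(10, 200))
            v = float(np.round(rng.uniform(0, 5), 6))
            lines.append(f"chr9\t{pos}\t{pos + ln}\t{v:.6f}")
            dense[pos:pos + ln] = v
            pos += ln + int(rng.integers(0, 50))
        p = tmp_path / "d.bg"
        p.write_text("\n".join(lines) + "\n")
        track = read_bedgraph(p)
        assert track.library_size == pytest.approx(dense.sum(), rel=1e-12)
        # window sums agree with the dense array
        starts = rng.integers(0, 4000, size=50)
        ends = starts + rng.integers(1, 900, size=50)
        np.testing.assert_allclose(track.sums("chr9", starts, ends),
                                   [dense[s:e].sum() for s, e in zip(starts, ends)],
                                   rtol=1e-12)
        out = tmp_path / "rt.bg"
        write_bedgraph(track, out)
        assert out.read_text() == "\n".join(lines) + "\n"


def test_expression_table_round_trip(tmp_path):
    recs = [ExpressionRecord("gA", 0.0), ExpressionRecord("gB", 12.5)]
    p = tmp_path / "e.tsv"
    write_expression_table(recs, p)
    assert read_expression_table(p) == recs


def test_expression_table_requires_header(tmp_path):
    p = tmp_path / "noheader.tsv"
    p.write_text("gA\t1.0\n")
    with pytest.raises(ParseError, match="header"):
        read_expression_table(p)
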