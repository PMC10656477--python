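"""Interval arithmetic and on-disk format round-trips."""

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from elekit.intervals import GenomicInterval, IntervalIndex, overlap_query
from elekit.io import (CtssTable, MethylationRecord, ParseError,
                       family_of_subfamily, methylation_ratio, read_bed,
                       read_ctss, read_gff3_genes, read_te_table,
                       superfamily_of, write_bed, write_ctss,
                       write_gff3_genes)


class TestGenomicInterval:
    def test_rejects_inverted_and_empty(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1A", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1A", 100, 100)

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((100, 200), (199, 300), True),   # 1-bp overlap
            ((100, 200), (200, 300), False),  # half-open adjacency
            ((100, 200), (50, 100), False),
        ],
    )
    def test_half_open_overlap(self, a, b, expected):
        iv_a = GenomicInterval("chr1A", *a)
        iv_b = GenomicInterval("chr1A", *b)
        assert iv_a.overlaps(iv_b) is expected
        assert iv_b.overlaps(iv_a) is expected

    def test_cross_chromosome_never_overlaps(self):
        a = GenomicInterval("chr1A", 100, 200)
        b = GenomicInterval("chr1B", 100, 200)
        assert not a.overlaps(b)
        assert overlap_query(a, [b]) == []


@given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 60)),
                max_size=100))
def test_overlap_query_matches_all_pairs_scan(pairs):
    subjects = [GenomicInterval("c", s, s + w) for s, w in pairs]
    index = IntervalIndex(subjects)
    query = GenomicInterval("c", 200, 260)
    expected = sorted(
        (iv for iv in subjects if iv.start < query.end and query.start < iv.end),
        key=lambda iv: (iv.start, iv.end, iv.strand, iv.name),
    )
    assert overlap_query(query, index) == expected


class TestBed:
    def test_parse_and_roundtrip(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1A\t100\t200\tpk1\n")
        ivs = read_bed(p)
        assert ivs == [GenomicInterval("chr1A", 100, 200, ".", "pk1")]
        out = tmp_path / "b.bed"
        write_bed(ivs, out)
        assert read_bed(out)[0].start == 100

    def test_inverted_coordinates_name_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1A\t100\t200\nchr1A\t200\t100\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bed(p)

    def test_too_few_columns_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1A\t100\n")
        with pytest.raises(ParseError, match="line 1"):
            read_bed(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert read_bed(p) == []


class TestGff3:
    def _write(self, tmp_path, body):
        p = tmp_path / "g.gff3"
        p.write_text("##gff-version 3\n" + body)
        return p

    def test_plus_strand_tss_conversion(self, tmp_path):
        p = self._write(tmp_path, "\n".join([
            "chr1A\tx\tgene\t1001\t2000\t.\t+\t.\tID=g1",
            "chr1A\tx\tmRNA\t1001\t2000\t.\t+\t.\tID=m1;Parent=g1",
            "chr1A\tx\texon\t1001\t2000\t.\t+\t.\tParent=m1",
        ]) + "\n")
        (gene,) = read_gff3_genes(p)
        assert (gene.start, gene.end) == (1000, 2000)
        assert gene.tss == 1000

    def test_minus_strand_tss(self, tmp_path):
        p = self._write(tmp_path, "\n".join([
            "chr1A\tx\tgene\t1001\t2000\t.\t-\t.\tID=g1",
            "chr1A\tx\tmRNA\t1001\t2000\t.\t-\t.\tID=m1;Parent=g1",
            "chr1A\tx\texon\t1001\t2000\t.\t-\t.\tParent=m1",
        ]) + "\n")
        (gene,) = read_gff3_genes(p)
        assert gene.tss == 1999

    def test_end_before_start_rejected(self, tmp_path):
        p = self._write(tmp_path,
                        "chr1A\tx\tgene\t2000\t1001\t.\t+\t.\tID=g1\n")
        with pytest.raises(ValueError, match="end < start"):
            read_gff3_genes(p)

    def test_orphan_exon_is_parse_error(self, tmp_path):
        p = self._write(tmp_path,
                        "chr1A\tx\texon\t1\t10\t.\t+\t.\tParent=mX\n")
        with pytest.raises(ParseError, match="hierarchy"):
            read_gff3_genes(p)

    def test_write_read_roundtrip_is_identity(self, tmp_path):
        body = "\n".join([
            "chr1A\tx\tgene\t1001\t2400\t.\t-\t.\tID=g1",
            "chr1A\tx\tmRNA\t1001\t2400\t.\t-\t.\tID=m1;Parent=g1",
            "chr1A\tx\texon\t1001\t1700\t.\t-\t.\tParent=m1",
            "chr1A\tx\texon\t1901\t2400\t.\t-\t.\tParent=m1",
            "chr1A\tx\tfive_prime_UTR\t2201\t2400\t.\t-\t.\tParent=m1",
        ]) + "\n"
        genes = read_gff3_genes(self._write(tmp_path, body))
        out = tmp_path / "out.gff3"
        write_gff3_genes(genes, out)
        again = read_gff3_genes(out)
        assert [(g.gene_id, g.start, g.end, g.tss, g.exons, g.utr5)
                for g in genes] == \
               [(g.gene_id, g.start, g.end, g.tss, g.exons, g.utr5)
                for g in again]


class TestTeTable:
    HEADER = ("te_id\tchrom\tstart\tend\tstrand\tsuperfamily\tfamily\t"
              "subfamily\tfull_length\tltr5_start\tltr5_end\tltr3_start\t"
              "ltr3_end\n")

    def test_subfamily_family_resolution(self, tmp_path):
        assert family_of_subfamily("RLG_famc7.3") == "RLG_famc7"
        assert superfamily_of("RLG_famc7.3") == "RLG"
        p = tmp_path / "te.tsv"
        p.write_text(self.HEADER +
                     "te1\tchr1A\t100\t1300\t+\tRLG\tRLG_famc7\tRLG_famc7.3"
                     "\t1\t100\t300\t1100\t1300\n")
        (te,) = read_te_table(p)
        assert te.family == "RLG_famc7"
        assert te.full_length and te.ltr5.end == 300

    def test_non_ltr_without_sub_intervals(self, tmp_path):
        p = tmp_path / "te.tsv"
        p.write_text(self.HEADER +
                     "te1\tchr1A\t100\t900\t+\tDTC\tDTC_famc5\tDTC_famc5.1"
                     "\t0\t\t\t\t\n")
        (te,) = read_te_table(p)
        assert not te.full_length and te.ltr5 is None

    def test_ltr_outside_span_rejected(self, tmp_path):
        p = tmp_path / "te.tsv"
        p.write_text(self.HEADER +
                     "te1\tchr1A\t100\t1300\t+\tRLG\tRLG_famc7\tRLG_famc7.3"
                     "\t1\t100\t300\t1200\t1400\n")
        with pytest.raises(ValueError, match="outside element"):
            read_te_table(p)


class TestMethylation:
    @pytest.mark.parametrize("m, cov, expected", [
        (5, 10, 0.5),
        (1, 2, None),   # below the 3-read confidence floor
        (0, 3, 0.0),
    ])
    def test_ratio_with_coverage_mask(self, m, cov, expected):
        rec = MethylationRecord("chr1A", 10, "CG", m, cov)
        assert methylation_ratio(rec) == expected

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            MethylationRecord("chr1A", 10, "CG", 5, 4)


class TestCtssTable:
    def _table(self):
        return CtssTable(pd.DataFrame({
            "chrom": ["chr1A", "chr1A"], "pos": [10, 10],
            "strand": ["+", "-"],
            "embryo_rep1": [3, 1], "embryo_rep2": [2, 0],
        }))

    def test_strands_are_distinct_records(self):
        t = self._table()
        assert len(t.df) == 2
        assert t.tissues == ["embryo"]

    def test_duplicate_rows_rejected(self):
        df = self._table().df
        with pytest.raises(ValueError, match="duplicate"):
            CtssTable(pd.concat([df, df.iloc[[0]]], ignore_index=True))

    def test_roundtrip(self, tmp_path):
        t = self._table()
        p = tmp_path / "ctss.tsv"
        write_ctss(t, p)
        again = read_ctss(p)
        pd.testing.assert_frame_equal(
            t.sorted().df, again.df, check_dtype=False
        )
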