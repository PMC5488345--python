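"""Format boundary tests: rmsk/DGV parsing, coordinate conventions, reports."""

import pytest

from hml2scan.genome_io import (
    DictGenome,
    FastaGenome,
    RepeatRecord,
    VariantRecord,
    fetch_flanks,
    normalize_chrom,
    read_dgv,
    read_report,
    read_repeatmasker,
    write_dgv,
    write_report,
    write_repeatmasker,
)
from hml2scan.indel_scan import CandidateSite
from hml2scan.tsd_caller import TsdCall

RMSK_COLS_17 = ("0\t10000\t0\t0\t0\t{chrom}\t{start}\t{end}\t-1000\t{strand}"
                "\t{name}\tLTR\tERVK\t1\t968\t0\t1")


def _rmsk_line(chrom="chr7", start=16237346, end=16238314, strand="+",
               name="LTR5_Hs"):
    return RMSK_COLS_17.format(chrom=chrom, start=start, end=end,
                               strand=strand, name=name)


class TestReadRepeatmasker:
    def test_ucsc_row_is_zero_based_half_open(self, tmp_path):
        # the 1-based browser display chr7:16,237,347-16,238,314 is row
        # genoStart=16237346 in the table
        p = tmp_path / "rmsk.tsv"
        p.write_text(_rmsk_line() + "\n")
        (rec,) = read_repeatmasker(p)
        assert rec == RepeatRecord("chr7", 16237346, 16238314, "+",
                                   "LTR5_Hs", "LTR", "ERVK")

    def test_empty_file_and_header_skipping(self, tmp_path):
        p = tmp_path / "rmsk.tsv"
        p.write_text("")
        assert read_repeatmasker(p) == []
        p.write_text("# a header line\n\n" + _rmsk_line() + "\n")
        assert len(read_repeatmasker(p)) == 1

    def test_binless_dialect(self, tmp_path):
        p = tmp_path / "rmsk.tsv"
        p.write_text(_rmsk_line().split("\t", 1)[1] + "\n")  # drop bin column
        (rec,) = read_repeatmasker(p)
        assert (rec.start, rec.end, rec.rep_name) == (16237346, 16238314, "LTR5_Hs")

    def test_complement_strand_symbol(self, tmp_path):
        p = tmp_path / "rmsk.tsv"
        p.write_text(_rmsk_line(strand="C") + "\n")
        assert read_repeatmasker(p)[0].strand == "-"

    @pytest.mark.parametrize("line,msg", [
        (_rmsk_line(start=100, end=50), "start >= end"),
        (_rmsk_line(strand="?"), "strand"),
        (_rmsk_line().replace("16237346", "xyz"), "non-integer"),
        ("just\ttwo", "columns"),
    ])
    def test_malformed_rows_rejected_with_line_number(self, tmp_path, line, msg):
        p = tmp_path / "rmsk.tsv"
        p.write_text(line + "\n")
        with pytest.raises(ValueError, match="line 1"):
            read_repeatmasker(p)

    def test_order_preserving_and_idempotent(self, tmp_path):
        p = tmp_path / "rmsk.tsv"
        p.write_text(_rmsk_line(start=500, end=900) + "\n"
                     + _rmsk_line(start=100, end=200) + "\n")
        first = read_repeatmasker(p)
        assert [r.start for r in first] == [500, 100]
        assert read_repeatmasker(p) == first


DGV_HEADER = "variantaccession\tchr\tstart\tend\tvarianttype\tvariantsubtype\n"


class TestReadDgv:
    def test_one_based_inclusive_converted(self, tmp_path):
        p = tmp_path / "dgv.tsv"
        p.write_text(DGV_HEADER + "esv2662783\t7\t16237347\t16238564\tCNV\tdeletion\n")
        (rec,) = read_dgv(p)
        assert (rec.chrom, rec.start, rec.end) == ("chr7", 16237346, 16238564)
        assert rec.accession == "esv2662783"

    def test_nondeletion_subtypes_retained(self, tmp_path):
        p = tmp_path / "dgv.tsv"
        p.write_text(DGV_HEADER + "e1\t1\t10\t20\tCNV\tduplication\n")
        assert read_dgv(p)[0].var_subtype == "duplication"

    def test_prefixed_and_bare_chromosomes_agree(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        p1.write_text(DGV_HEADER + "e1\tchr7\t100\t200\tCNV\tloss\n")
        p2.write_text(DGV_HEADER + "e1\t7\t100\t200\tCNV\tloss\n")
        assert read_dgv(p1) == read_dgv(p2)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "dgv.tsv"
        p.write_text("variantaccession\tchr\tstart\tend\tvarianttype\n"
                     "e1\t1\t10\t20\tCNV\n")
        with pytest.raises(ValueError, match="variantsubtype"):
            read_dgv(p)

    def test_bad_coordinate_rejected_with_line(self, tmp_path):
        p = tmp_path / "dgv.tsv"
        p.write_text(DGV_HEADER + "e1\t1\tten\t20\tCNV\tloss\n")
        with pytest.raises(ValueError, match="line 2"):
            read_dgv(p)

    def test_round_trip_restores_one_based_numbers(self, tmp_path):
        src = tmp_path / "dgv.tsv"
        src.write_text(DGV_HEADER + "esv1\t7\t16237347\t16238564\tCNV\tdeletion\n"
                       + "esv2\tX\t55\t99\tCNV\tloss\n")
        records = read_dgv(src)
        out = tmp_path / "out.tsv"
        write_dgv(records, out)
        lines = out.read_text().splitlines()
        assert "esv1\t7\t16237347\t16238564\tCNV\tdeletion" in lines[1]
        assert "esv2\tX\t55\t99\tCNV\tloss" in lines[2]
        assert read_dgv(out) == records


class TestGenomeAccess:
    def test_fetch_uppercases_and_preserves_n(self):
        g = DictGenome({"1": "acgtnACGTN"})
        assert g.fetch("chr1", 0, 10) == "ACGTNACGTN"

    def test_fetch_bounds_checked(self):
        g = DictGenome({"chr1": "ACGT"})
        with pytest.raises(ValueError):
            g.fetch("chr1", 2, 9)
        with pytest.raises(KeyError):
            g.fetch("chr9", 0, 1)

    def test_fasta_matches_dict_backend(self, tmp_path):
        seq = "ACGTACGTAAccGGTT" * 10
        p = tmp_path / "g.fa"
        p.write_text(">chr1\n" + "\n".join(seq[i:i + 30] for i in range(0, len(seq), 30)) + "\n")
        fg = FastaGenome(p)
        dg = DictGenome({"chr1": seq})
        assert fg.chrom_lengths == dg.chrom_lengths
        assert fg.fetch("chr1", 5, 37) == dg.fetch("chr1", 5, 37)

    def test_flanks_simple_and_clipped(self):
        seq = "AAAAACCCCCGGGGGTTTTTACGTACGTAC"  # 30 bp
        g = DictGenome({"chr1": seq})
        left, right = fetch_flanks(g, "chr1", 10, 20, 5)
        assert (left, right) == (seq[5:10], seq[20:25])
        left, right = fetch_flanks(g, "chr1", 3, 20, 5)
        assert left == seq[0:3] and len(left) == 3
        with pytest.raises(KeyError):
            fetch_flanks(g, "chr5", 10, 20, 5)
        with pytest.raises(ValueError):
            fetch_flanks(g, "chr1", 10, 20, 0)

    def test_flank_concatenation_reconstructs_region(self):
        seq = "ACGTACGTGGTTCCAAACGTACGTGGAATT"
        g = DictGenome({"chr1": seq})
        start, end, w = 12, 18, 6
        left, right = fetch_flanks(g, "chr1", start, end, w)
        assert left + g.fetch("chr1", start, end) + right == seq[start - w:end + w]


class TestReports:
    CALL = TsdCall("chr7:1001-1968", "chr7", 250, (750, 1000), (1968, 2218),
                   2, 0.992, 0, 0, "solo_ltr")
    CAND = CandidateSite("chr7:1001-1968", "esv1;esv2", "chr7", 990, 1978,
                         988, 988, "preintegration_consistent", 10)

    def test_tsv_round_trip(self, tmp_path):
        for records, cls in [([self.CALL], TsdCall), ([self.CAND], CandidateSite)]:
            p = tmp_path / "r.tsv"
            write_report(records, p, "tsv", header_extra=["config_hash=abc"])
            assert read_report(p, cls) == records

    def test_empty_report_is_header_only(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_report([], p, "tsv")
        lines = p.read_text().splitlines()
        assert lines and all(l.startswith("#") for l in lines)

    def test_bed_two_lines_per_tsd_call(self, tmp_path):
        p = tmp_path / "r.bed"
        write_report([self.CALL], p, "bed")
        lines = p.read_text().splitlines()
        assert lines == [
            "chr7\t750\t1000\tchr7:1001-1968|TSD_L",
            "chr7\t1968\t2218\tchr7:1001-1968|TSD_R",
        ]

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_report([], tmp_path / "x", "vcf")


def test_normalize_chrom_dialects():
    assert normalize_chrom("7") == "chr7"
    assert normalize_chrom("chr7") == "chr7"
    assert normalize_chrom("X") == "chrX"
    with pytest.raises(ValueError):
        normalize_chrom("")


def test_rmsk_write_read_round_trip(tmp_path):
    recs = [RepeatRecord("chr1", 10, 900, "+", "LTR5_Hs", "LTR", "ERVK"),
            RepeatRecord("chr2", 5, 60, "-", "HERVK-int", "LTR", "ERVK")]
    p = tmp_path / "rm.tsv"
    write_repeatmasker(recs, p, {"chr1": 1000, "chr2": 100})
    assert read_repeatmasker(p) == recs
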