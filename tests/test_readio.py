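"""Read records, file round-trips, trimming, CH filter, region logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from decent.readio import (
    MethylRead,
    ReadSet,
    RegionTable,
    filter_ch,
    filter_reads_by_regions,
    load_reads,
    select_dmr_regions,
    trim_read,
    trim_reads,
    write_reads,
)


def _read(seq="ACGTACGTAC", meth=None, **kw):
    meth = meth if meth is not None else "." * len(seq)
    base = dict(chrom="chr1", start=100, strand="+", seq=seq, meth=meth)
    base.update(kw)
    return MethylRead(**base)


class TestMethylRead:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            _read(seq="ACGT", meth="..")

    def test_counts(self):
        r = _read(seq="CCCCC", meth="ZzHhx")
        assert r.n_methylated_cpg() == 1
        assert r.n_unmethylated_ch() == 2


class TestFileRoundTrip:
    @pytest.fixture()
    def readset(self):
        reads = [
            _read(read_id="r1", mate_id="f1", mate=1, label="embryonic"),
            _read(seq="CCGGA", meth="Zz.h.", start=500, strand="-", read_id="r2",
                  mate_id="f1", mate=2, label="maternal"),
            _read(read_id="r3"),
        ]
        return ReadSet(reads)

    @pytest.mark.parametrize("suffix", ["tsv", "sam", "bam"])
    def test_write_load_preserves_fields(self, readset, tmp_path, suffix):
        path = tmp_path / f"reads.{suffix}"
        write_reads(readset, path, chrom_lengths={"chr1": 10_000})
        back = load_reads(path)
        assert len(back) == len(readset)
        for a, b in zip(readset, back):
            assert (a.chrom, a.start, a.strand, a.seq, a.meth) == (
                b.chrom, b.start, b.strand, b.seq, b.meth)
            assert (a.label, a.read_id, a.mate_id, a.mate) == (
                b.label, b.read_id, b.mate_id, b.mate)

    def test_missing_tag_records_skipped_with_warning(self, tmp_path):
        import pysam

        path = tmp_path / "untagged.sam"
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 1000}]}
        with pysam.AlignmentFile(str(path), "w", header=header) as fh:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = "r0"
            a.query_sequence = "ACGT"
            a.reference_name = "chr1"
            a.reference_start = 10
            a.cigarstring = "4M"
            a.mapping_quality = 60
            fh.write(a)
        with pytest.warns(UserWarning, match="skipped 1"):
            rs = load_reads(path)
        assert len(rs) == 0
        assert rs.provenance["skipped_records"] == 1

    def test_malformed_tsv_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tstart\tstrand\tseq\tmeth\nchr1\tnotint\t+\tACGT\t....\n")
        with pytest.raises(ValueError, match=":2"):
            load_reads(path)

    def test_tsv_of_three_rows(self, tmp_path):
        path = tmp_path / "ok.tsv"
        path.write_text(
            "chrom\tstart\tstrand\tseq\tmeth\n"
            + "".join(f"chr1\t{i}\t+\tACGT\t....\n" for i in range(3))
        )
        assert len(load_reads(path)) == 3

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            load_reads("/nonexistent/reads.tsv")


class TestTrimRead:
    def test_143bp_to_66(self):
        r = _read(seq="A" * 143, meth="." * 143)
        out = trim_read(r)
        assert len(out.seq) == 66 and len(out.meth) == 66

    def test_70bp_dropped_71bp_kept(self):
        assert trim_read(_read(seq="A" * 70, meth="." * 70)) is None
        out = trim_read(_read(seq="A" * 71, meth="." * 71))
        assert len(out.seq) == 66

    def test_plus_strand_keeps_positions_5_to_70(self):
        seq = "".join("ACGT"[i % 4] for i in range(71))
        r = _read(seq=seq, meth="." * 71, start=1000, strand="+")
        out = trim_read(r)
        assert out.start == 1005
        assert out.seq == seq[5:71]

    def test_minus_strand_trims_from_right(self):
        seq = "".join("ACGT"[i % 4] for i in range(71))
        r = _read(seq=seq, meth="." * 71, start=1000, strand="-")
        out = trim_read(r)
        # 5' end of a minus-strand read is the right-hand end
        assert out.seq == seq[0:66]
        assert out.start == 1000

    def test_idempotent_on_66bp(self):
        r = _read(seq="A" * 71, meth="." * 71)
        once = trim_read(r)
        twice = trim_read(once, head_trim=0, target_len=66)
        assert once.seq == twice.seq and once.start == twice.start

    def test_trim_reads_counts_drops(self):
        rs = ReadSet([_read(seq="A" * 80, meth="." * 80), _read(seq="A" * 30, meth="." * 30)])
        out = trim_reads(rs)
        assert len(out) == 1
        assert out.provenance["n_dropped_short"] == 1


class TestFilterCH:
    @staticmethod
    def _pair(n_unmeth_ch_r2):
        meth2 = "h" * n_unmeth_ch_r2 + "H" * (5 - n_unmeth_ch_r2)
        r1 = _read(seq="CCCCC", meth="HHHHH", read_id="a1", mate_id="f", mate=1)
        r2 = _read(seq="CCCCC", meth=meth2, read_id="a2", mate_id="f", mate=2)
        return ReadSet([r1, r2])

    def test_r2_over_limit_removes_pair(self):
        out = filter_ch(self._pair(4))
        assert len(out) == 0
        assert out.provenance["n_removed_ch_filter"] == 2

    def test_exactly_three_retained(self):
        assert len(filter_ch(self._pair(3))) == 2

    def test_r1_never_removed_when_its_r2_passes(self):
        # R1 itself has many unmethylated CH, but the rule targets R2 reads
        r1 = _read(seq="CCCCC", meth="hhhhh", read_id="b1", mate_id="g", mate=1)
        r2 = _read(seq="CCCCC", meth="HHHHH", read_id="b2", mate_id="g", mate=2)
        out = filter_ch(ReadSet([r1, r2]))
        assert len(out) == 2

    def test_unpaired_read_rule_applied_directly(self):
        singleton = _read(seq="CCCCC", meth="hhhh.", read_id="s")
        out = filter_ch(ReadSet([singleton]))
        assert len(out) == 0

    def test_no_ch_calls_unchanged(self):
        rs = ReadSet([_read(), _read(start=5)])
        assert len(filter_ch(rs)) == 2


class TestSelectDmrRegions:
    @pytest.fixture()
    def cgi(self):
        return RegionTable(pd.DataFrame({
            "chrom": ["chr1", "chr2", "chr3", "chrX"],
            "start": [0, 0, 0, 0],
            "end": [1000, 1000, 1000, 1000],
            "cumulus": [0.85, 0.70, 0.90, 0.95],
            "TE": [0.15, 0.10, 0.25, 0.05],
            "ICM": [0.05, 0.05, 0.05, 0.05],
        }))

    def test_criteria(self, cgi):
        out = select_dmr_regions(cgi)
        # chr1 passes; chr2 fails cumulus>0.8; chr3 fails TE<0.2; chrX excluded
        assert out.table["chrom"].tolist() == ["chr1"]

    def test_missing_column_named(self, cgi):
        with pytest.raises(KeyError, match="oocyte"):
            select_dmr_regions(cgi, others=["oocyte"])


class TestFilterReadsByRegions:
    @pytest.fixture()
    def regions(self):
        return RegionTable(pd.DataFrame({
            "chrom": ["chr1", "chr1"],
            "start": [100, 500],
            "end": [200, 600],
        }))

    def test_inside_retained_abutting_rejected(self, regions):
        inside = _read(start=150, seq="ACGT", meth="....")
        abutting = _read(start=200, seq="ACGT", meth="....")  # start == region end
        out = filter_reads_by_regions(ReadSet([inside, abutting]), regions)
        assert len(out) == 1 and out.start[0] == 150

    def test_one_bp_overlap_retained(self, regions):
        r = _read(start=96, seq="ACGTA", meth=".....")  # covers 96..101, overlaps 100
        assert len(filter_reads_by_regions(ReadSet([r]), regions)) == 1

    def test_empty_region_table(self):
        rs = ReadSet([_read()])
        out = filter_reads_by_regions(rs, RegionTable(pd.DataFrame(columns=["chrom", "start", "end"])))
        assert len(out) == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        read_start=st.integers(0, 60),
        read_len=st.integers(1, 15),
        regions=st.lists(st.tuples(st.integers(0, 60), st.integers(1, 15)), min_size=1, max_size=4),
    )
    def test_matches_brute_force_overlap(self, read_start, read_len, regions):
        table = RegionTable(pd.DataFrame({
            "chrom": ["chr1"] * len(regions),
            "start": [s for s, _ in regions],
            "end": [s + l for s, l in regions],
        }))
        r = _read(start=read_start, seq="A" * read_len, meth="." * read_len)
        got = len(filter_reads_by_regions(ReadSet([r]), table)) == 1
        expected = any(
            any(s <= p < s + l for s, l in regions)
            for p in range(read_start, read_start + read_len)
        )
        assert got == expected
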