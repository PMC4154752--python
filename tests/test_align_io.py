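import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repeatproof.align_io import (
    AlignmentBlock,
    Feature,
    collect_read_alignments,
    read_coords,
    read_gff3,
    read_paf,
    read_tabular_alignments,
    write_gff3,
    write_paf,
    write_tabular_alignments,
)


def _paf_line(matches, blocklen, qs=0, qe=100, ts=0, te=100):
    return (
        f"q\t1000\t{qs}\t{qe}\t+\tr\t5000\t{ts}\t{te}\t{matches}\t{blocklen}\t60\n"
    )


class TestPaf:
    @pytest.mark.parametrize("matches,expected", [(100, 1.0), (95, 0.95)])
    def test_identity_is_matches_over_block_length(self, tmp_path, matches, expected):
        p = tmp_path / "a.paf"
        p.write_text(_paf_line(matches, 100))
        (block,) = read_paf(p)
        assert block.identity == pytest.approx(expected)
        assert (block.ref_start, block.ref_end) == (0, 100)

    def test_malformed_line_aborts_with_line_number(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text(_paf_line(100, 100) + "broken\tline\n" + _paf_line(90, 100))
        with pytest.raises(ValueError, match=":2"):
            read_paf(p)

    def test_round_trip(self, tmp_path):
        blocks = [
            AlignmentBlock("c1", 0, 500, "chr1", 100, 600, "+", 0.99),
            AlignmentBlock("c1", 550, 900, "chr2", 0, 350, "-", 1.0),
        ]
        p = tmp_path / "rt.paf"
        write_paf(blocks, p)
        again = read_paf(p)
        assert [
            (b.contig_id, b.contig_start, b.contig_end, b.ref_id, b.ref_start,
             b.ref_end, b.strand) for b in again
        ] == [
            (b.contig_id, b.contig_start, b.contig_end, b.ref_id, b.ref_start,
             b.ref_end, b.strand) for b in blocks
        ]
        for a, b in zip(again, blocks):
            assert a.identity == pytest.approx(b.identity, abs=1e-2)


class TestCoords:
    def test_forward_row_converted_to_half_open(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("1\t100\t1\t100\t100\t100\t100.00\tchr1\tctg1\n")
        (b,) = read_coords(p)
        assert (b.ref_start, b.ref_end) == (0, 100)
        assert (b.contig_start, b.contig_end) == (0, 100)
        assert b.identity == 1.0 and b.strand == "+"

    def test_reversed_reference_interval_sets_minus_strand(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("200\t101\t1\t100\t100\t100\t99.95\tchr1\tctg1\n")
        (b,) = read_coords(p)
        assert b.strand == "-"
        assert (b.ref_start, b.ref_end) == (100, 200)
        assert b.identity == pytest.approx(0.9995)


class TestSam:
    def _write(self, tmp_path, body):
        p = tmp_path / "t.sam"
        p.write_text("@HD\tVN:1.6\n@SQ\tSN:ref1\tLN:5000\n" + body)
        return p

    def test_perfect_alignment_is_single_match_run(self, tmp_path):
        p = self._write(
            tmp_path, "r1\t0\tref1\t101\t60\t1000M\t*\t0\t0\t" + "A" * 1000 + "\t*\tMD:Z:1000\n"
        )
        alns, skipped = collect_read_alignments(p)
        assert skipped == 0
        assert [(r.op, r.length, r.read_offset) for r in alns[0].ops] == [("M", 1000, 0)]
        assert alns[0].ref_start == 100

    def test_insertion_splits_runs_at_read_offset(self, tmp_path):
        p = self._write(
            tmp_path,
            "r2\t0\tref1\t1\t60\t10M2I988M\t*\t0\t0\t" + "A" * 1000 + "\t*\tMD:Z:998\n",
        )
        (aln,), _ = collect_read_alignments(p)
        assert [(r.op, r.length, r.read_offset) for r in aln.ops] == [
            ("M", 10, 0), ("I", 2, 10), ("M", 988, 12)
        ]

    def test_unmapped_records_are_skipped_and_counted(self, tmp_path):
        p = self._write(tmp_path, "r3\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\t*\n")
        alns, skipped = collect_read_alignments(p)
        assert alns == [] and skipped == 1

    def test_no_md_and_no_reference_is_an_error(self, tmp_path):
        p = self._write(tmp_path, "r4\t0\tref1\t1\t60\t4M\t*\t0\t0\tACGT\t*\n")
        with pytest.raises(ValueError, match="MD"):
            collect_read_alignments(p)


class TestTabular:
    def test_round_trip(self, tmp_path):
        from repeatproof.align_io import OpRun, ReadAlignment

        alns = [
            ReadAlignment("r1", "chr1", 10, "+", 60,
                          [OpRun("M", 50, 0), OpRun("D", 2, 49), OpRun("M", 30, 50)],
                          read_length=80),
            ReadAlignment("r2", "chr2", 99, "-", 17, [OpRun("M", 40, 0)], read_length=40),
        ]
        p = tmp_path / "aln.tsv"
        write_tabular_alignments(alns, p)
        again = read_tabular_alignments(p)
        assert again == alns


@st.composite
def features(draw):
    start = draw(st.integers(min_value=0, max_value=10**7))
    length = draw(st.integers(min_value=1, max_value=10**5))
    return Feature(
        feature_id=f"f{draw(st.integers(0, 999))}",
        ref_id="chr1",
        start=start,
        end=start + length,
        strand=draw(st.sampled_from("+-")),
        feature_type=draw(st.sampled_from(["gene", "TE"])),
    )


class TestCoordinateConventions:
    @settings(max_examples=50, derandomize=True)
    @given(st.lists(features(), min_size=1, max_size=8))
    def test_gff3_round_trip_preserves_half_open_coordinates(self, tmp_path_factory, feats):
        p = tmp_path_factory.mktemp("gff") / "x.gff3"
        write_gff3(feats, p)
        again = read_gff3(p)
        assert [(f.ref_id, f.start, f.end, f.strand) for f in again] == [
            (f.ref_id, f.start, f.end, f.strand) for f in feats
        ]

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 10**6), st.integers(1, 10**5),
                st.integers(0, 10**6), st.sampled_from("+-"),
            ),
            min_size=1, max_size=8,
        )
    )
    def test_paf_round_trip_preserves_blocks(self, tmp_path_factory, rows):
        blocks = [
            AlignmentBlock(f"c{i}", cs, cs + ln, "chr1", rs, rs + ln, strand, 1.0)
            for i, (cs, ln, rs, strand) in enumerate(rows)
        ]
        p = tmp_path_factory.mktemp("paf") / "x.paf"
        write_paf(blocks, p)
        again = read_paf(p)
        assert [
            (b.contig_id, b.contig_start, b.contig_end, b.ref_start, b.ref_end,
             b.strand, b.identity) for b in again
        ] == [
            (b.contig_id, b.contig_start, b.contig_end, b.ref_start, b.ref_end,
             b.strand, b.identity) for b in blocks
        ]


class TestGff3:
    def test_coordinates_survive_round_trip_as_half_open(self, tmp_path):
        feats = [
            Feature("g1", "chr1", 0, 100, "+", "gene"),
            Feature("te1", "chr1", 499, 1500, "-", "TE", family="roo", divergence=0.0086),
        ]
        p = tmp_path / "f.gff3"
        write_gff3(feats, p)
        # 1-based inclusive on disk
        lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert lines[0].split("\t")[3:5] == ["1", "100"]
        assert lines[1].split("\t")[3:5] == ["500", "1500"]
        again = read_gff3(p)
        assert [(f.start, f.end) for f in again] == [(0, 100), (499, 1500)]
        assert again[1].family == "roo"
        assert again[1].divergence == pytest.approx(0.0086)
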