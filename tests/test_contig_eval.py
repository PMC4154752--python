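import numpy as np
import pytest

from repeatproof.align_io import AlignmentBlock
from repeatproof.contig_eval import (
    assembly_size_metrics,
    detect_misassemblies,
    merge_end_overlaps,
    na_metrics,
    nx_metrics,
    per100kbp_errors,
    revcomp,
)
from repeatproof.placement import ContigPlacement


def nx_oracle(lengths, x, genome_size=None):
    """Independent cumulative scan over the descending-sorted lengths."""
    srt = sorted(lengths, reverse=True)
    denom = genome_size if genome_size is not None else sum(srt)
    need = x / 100 * denom
    acc = 0
    for rank, l in enumerate(srt, 1):
        acc += l
        if acc >= need:
            return l, rank
    return 0, len(srt)


class TestNxMetrics:
    def test_hand_computed_n50(self):
        out = nx_metrics([5, 4, 3, 2, 1], 50)
        assert (out["N"], out["L"]) == (4, 2)  # cumulative 9 >= 7.5

    def test_single_contig(self):
        out = nx_metrics([1234], 50)
        assert (out["N"], out["L"]) == (1234, 1)

    def test_hand_computed_ng50(self):
        out = nx_metrics([5, 4, 3, 2, 1], 50, genome_size=20)
        assert (out["N"], out["L"]) == (3, 3)  # cumulative 12 >= 10

    def test_unreached_threshold_flagged(self):
        out = nx_metrics([5, 4], 50, genome_size=1000)
        assert out == {"N": 0, "L": 2, "reached": False}

    def test_agrees_with_cumulative_scan_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            lengths = rng.integers(1, 10_000, size=int(rng.integers(1, 40))).tolist()
            x = float(rng.uniform(1, 100))
            gs = int(rng.integers(1, 2 * sum(lengths))) if rng.random() < 0.5 else None
            out = nx_metrics(lengths, x, gs)
            assert (out["N"], out["L"]) == nx_oracle(lengths, x, gs)

    def test_n_is_non_increasing_in_x(self):
        rng = np.random.default_rng(18)
        lengths = rng.integers(1, 10_000, size=30).tolist()
        ns = [nx_metrics(lengths, x)["N"] for x in range(1, 101)]
        assert ns == sorted(ns, reverse=True)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            nx_metrics([], 50)
        with pytest.raises(ValueError):
            nx_metrics([5, 0], 50)
        with pytest.raises(ValueError):
            nx_metrics([5], 0)


def _chain(*specs, cid="c"):
    """specs: (contig_start, contig_end, ref_id, ref_start, ref_end, strand)."""
    blocks = [
        AlignmentBlock(cid, cs, ce, rid, rs, re, strand)
        for cs, ce, rid, rs, re, strand in specs
    ]
    return ContigPlacement(contig_id=cid, blocks=blocks)


class TestMisassemblies:
    def test_colinear_chain_has_no_events(self):
        pl = _chain((0, 1000, "chr2L", 0, 1000, "+"),
                    (1000, 2000, "chr2L", 1005, 2005, "+"))
        events, pieces = detect_misassemblies(pl)
        assert events == []
        assert pieces == [2000]

    def test_reference_switch_is_translocation(self):
        pl = _chain((0, 1000, "chr2L", 0, 1000, "+"),
                    (1000, 2000, "chr3R", 0, 1000, "+"))
        events, pieces = detect_misassemblies(pl)
        assert [e.kind for e in events] == ["translocation"]
        assert pieces == [1000, 1000]

    def test_large_reference_jump_is_relocation(self):
        pl = _chain((0, 1000, "chr2L", 0, 1000, "+"),
                    (1000, 2000, "chr2L", 6000, 7000, "+"))
        events, _ = detect_misassemblies(pl, inconsistency_threshold=1000)
        assert [e.kind for e in events] == ["relocation"]
        assert events[0].inconsistency == 5000

    def test_strand_flip_is_inversion(self):
        pl = _chain((0, 1000, "chr2L", 0, 1000, "+"),
                    (1000, 2000, "chr2L", 1000, 2000, "-"))
        events, _ = detect_misassemblies(pl)
        assert [e.kind for e in events] == ["inversion"]

    def test_na50_never_exceeds_n50(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(1, 6))
            specs = []
            pos = 0
            for _ in range(n):
                ln = int(rng.integers(500, 5000))
                rs = int(rng.integers(0, 100_000))
                specs.append(
                    (pos, pos + ln, f"chr{int(rng.integers(1, 3))}", rs, rs + ln,
                     "+" if rng.random() < 0.7 else "-")
                )
                pos += ln + int(rng.integers(0, 100))
            pl = _chain(*specs)
            placements = {"c": pl}
            n50 = nx_metrics([sum(b.aligned_length for b in pl.blocks)], 50)["N"]
            na50 = na_metrics(placements, 50)["N"]
            assert na50 <= n50


class TestPer100kbp:
    def test_perfect_blocks_have_zero_rates(self):
        ref = {"chr1": "ACGT" * 25_000}
        contig = {"c": ref["chr1"]}
        pl = {"c": _chain((0, 100_000, "chr1", 0, 100_000, "+"))}
        out = per100kbp_errors(pl, contig, ref)
        assert out["mismatches_per_100kbp"] == 0.0
        assert out["short_indels_per_100kbp"] == 0.0
        assert out["long_indels_per_100kbp"] == 0.0

    def test_one_mismatch_in_100kbp(self):
        ref = {"chr1": "ACGT" * 25_000}
        seq = list(ref["chr1"])
        seq[50_000] = "A" if seq[50_000] != "A" else "C"
        pl = {"c": _chain((0, 100_000, "chr1", 0, 100_000, "+"))}
        out = per100kbp_errors(pl, {"c": "".join(seq)}, ref)
        assert out["mismatches_per_100kbp"] == pytest.approx(1.0)

    def test_long_deletion_classified_by_gap_run(self):
        rng = np.random.default_rng(4)
        base = "".join(rng.choice(list("ACGT"), size=200_000))
        ref = {"chr1": base}
        contig = {"c": base[:100_000] + base[100_007:]}  # one 7 bp deletion
        pl = {"c": _chain((0, 199_993, "chr1", 0, 200_000, "+"))}
        out = per100kbp_errors(pl, contig, ref)
        assert out["long_indels_per_100kbp"] == pytest.approx(0.5)
        assert out["short_indels_per_100kbp"] == 0.0

    def test_missing_sequence_rejected(self):
        pl = {"c": _chain((0, 1000, "chr1", 0, 1000, "+"))}
        with pytest.raises(ValueError):
            per100kbp_errors(pl, {}, {"chr1": "A" * 1000})


class TestMergeEndOverlaps:
    def _mk(self, rng, n):
        return "".join(rng.choice(list("ACGT"), size=n))

    def test_exact_overlap_merges_with_length_arithmetic(self):
        rng = np.random.default_rng(10)
        shared = self._mk(rng, 1200)
        a = self._mk(rng, 3800) + shared
        b = shared + self._mk(rng, 2800)
        merged, log = merge_end_overlaps({"a": a, "b": b}, min_overlap=1000)
        assert len(merged) == 1
        (seq,) = merged.values()
        assert len(seq) == 5000 + 4000 - 1200
        assert log[0]["overlap"] == 1200

    def test_short_overlap_is_not_merged(self):
        rng = np.random.default_rng(11)
        shared = self._mk(rng, 900)
        a = self._mk(rng, 4100) + shared
        b = shared + self._mk(rng, 3100)
        merged, log = merge_end_overlaps({"a": a, "b": b}, min_overlap=1000)
        assert set(merged) == {"a", "b"}
        assert log == []

    def test_no_overlaps_leaves_input_unchanged(self):
        rng = np.random.default_rng(12)
        contigs = {f"c{i}": self._mk(rng, 2000) for i in range(3)}
        merged, log = merge_end_overlaps(contigs)
        assert merged == contigs and log == []

    def test_reverse_complement_overlap_detected(self):
        rng = np.random.default_rng(13)
        shared = self._mk(rng, 1500)
        a = self._mk(rng, 2000) + shared
        b = revcomp(shared + self._mk(rng, 2500))
        merged, log = merge_end_overlaps({"a": a, "b": b}, min_overlap=1000)
        assert len(merged) == 1

    def test_total_sequence_conserved(self):
        rng = np.random.default_rng(14)
        shared1 = self._mk(rng, 1100)
        shared2 = self._mk(rng, 1300)
        contigs = {
            "a": self._mk(rng, 2000) + shared1,
            "b": shared1 + self._mk(rng, 1500) + shared2,
            "c": shared2 + self._mk(rng, 1800),
        }
        merged, log = merge_end_overlaps(contigs)
        total_in = sum(len(s) for s in contigs.values())
        total_out = sum(len(s) for s in merged.values())
        assert total_out == total_in - sum(m["overlap"] for m in log)


class TestAssemblyMetrics:
    def test_size_table(self):
        out = assembly_size_metrics([5000, 4000, 1000], genome_size=20_000)
        assert out["n_contigs"] == 3
        assert out["total_size"] == 10_000
        assert out["N50"] == 5000 and out["L50"] == 1  # cumulative 5000 >= 5000
        assert out["NG50"] == 1000 and out["LG50"] == 3
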