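"""Assembly size and correctness metrics.

Covers the standard contiguity statistics (N50/NG50/NA50 and their L
counterparts), per-100 kbp mismatch and indel rates from block realignment,
misassembly breakpoint detection between adjacent placed blocks, and exact
suffix--prefix supercontig merging of contigs whose ends overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from .align_io import AlignmentBlock
from .placement import ContigPlacement

_COMPL = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPL)[::-1]


# ---------------------------------------------------------------------------
# Nx / Lx


def nx_metrics(
    lengths: Sequence[int], x: float = 50, genome_size: int | None = None
) -> dict:
    """N(x) and L(x): the length of the contig at which the cumulative sorted
    length first reaches x% of the total (or of ``genome_size`` for NG), and
    its 1-based rank. If the threshold is never reached (NG on a small
    assembly), N=0 and L=len(lengths) with ``reached=False``.
    """
    if not lengths:
        raise ValueError("empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    if not 0 < x <= 100:
        raise ValueError(f"x must be in (0, 100], got {x}")
    srt = sorted(lengths, reverse=True)
    denom = genome_size if genome_size is not None else sum(srt)
    threshold = x / 100.0 * denom
    cum = 0
    for rank, l in enumerate(srt, 1):
        cum += l
        if cum >= threshold:
            return {"N": l, "L": rank, "reached": True}
    return {"N": 0, "L": len(srt), "reached": False}


def assembly_size_metrics(lengths: Sequence[int], genome_size: int | None = None) -> dict:
    srt = sorted(lengths, reverse=True)
    out = {
        "n_contigs": len(srt),
        "total_size": int(sum(srt)),
        "longest": int(srt[0]),
        "shortest": int(srt[-1]),
        "mean": float(np.mean(srt)),
        "median": float(np.median(srt)),
    }
    n50 = nx_metrics(srt, 50)
    out["N50"], out["L50"] = n50["N"], n50["L"]
    if genome_size is not None:
        ng50 = nx_metrics(srt, 50, genome_size)
        out["NG50"], out["LG50"] = ng50["N"], ng50["L"]
    return out


# ---------------------------------------------------------------------------
# Misassembly detection


@dataclass
class MisassemblyEvent:
    contig_id: str
    kind: str  # translocation | relocation | inversion
    left_block: AlignmentBlock
    right_block: AlignmentBlock
    inconsistency: int = 0


def detect_misassemblies(
    placement: ContigPlacement, inconsistency_threshold: int = 1000
) -> tuple[list[MisassemblyEvent], list[int]]:
    """Classify breakpoints between adjacent blocks of a contig's chain.

    Adjacent blocks on different references are a translocation; same
    reference but opposite strands an inversion; same reference and strand
    with reference order contradicting contig order, or with the reference
    gap differing from the contig gap by more than the threshold, a
    relocation. Also returns the aligned lengths of the chain pieces after
    breaking at every event — the inputs to NA50.
    """
    blocks = sorted(placement.blocks, key=lambda b: (b.contig_start, b.contig_end))
    events = []
    piece_lengths = []
    piece = 0
    for i, b in enumerate(blocks):
        piece += b.aligned_length
        if i + 1 >= len(blocks):
            break
        nxt = blocks[i + 1]
        kind = None
        inconsistency = 0
        if b.ref_id != nxt.ref_id:
            kind = "translocation"
        elif b.strand != nxt.strand:
            kind = "inversion"
        else:
            contig_gap = nxt.contig_start - b.contig_end
            if b.strand == "+":
                ref_gap = nxt.ref_start - b.ref_end
                wrong_order = nxt.ref_start < b.ref_start
            else:
                ref_gap = b.ref_start - nxt.ref_end
                wrong_order = nxt.ref_start > b.ref_start
            inconsistency = abs(ref_gap - contig_gap)
            if wrong_order or inconsistency > inconsistency_threshold:
                kind = "relocation"
        if kind is not None:
            events.append(
                MisassemblyEvent(
                    contig_id=placement.contig_id,
                    kind=kind,
                    left_block=b,
                    right_block=nxt,
                    inconsistency=inconsistency,
                )
            )
            piece_lengths.append(piece)
            piece = 0
    if piece > 0 or not blocks:
        if blocks:
            piece_lengths.append(piece)
    return events, piece_lengths


def na_metrics(
    placements: Mapping[str, ContigPlacement],
    x: float = 50,
    genome_size: int | None = None,
    inconsistency_threshold: int = 1000,
) -> dict:
    """NA(x)/LA(x): Nx over aligned chain pieces after misassembly breaking."""
    pieces = []
    for pl in placements.values():
        _, lens = detect_misassemblies(pl, inconsistency_threshold)
        pieces.extend(lens)
    if not pieces:
        return {"N": 0, "L": 0, "reached": False}
    return nx_metrics(pieces, x, genome_size)


# ---------------------------------------------------------------------------
# Per-100 kbp error rates by block realignment


def per100kbp_errors(
    placements: Mapping[str, ContigPlacement],
    contig_seqs: Mapping[str, str],
    ref_seqs: Mapping[str, str],
    short_indel_max: int = 5,
) -> dict:
    """Mismatches and indel events per 100 kbp of aligned sequence.

    Each selected block's contig and reference segments are globally
    realigned with edlib; because the unit-cost path can split one indel
    into several runs in repetitive context, clusters of non-identity
    columns are then re-aligned locally with affine gap penalties so that
    one indel is one consolidated gap run. An indel event is one gap run,
    classified short/long at ``short_indel_max``.
    """
    mismatches = 0
    short_indels = 0
    long_indels = 0
    aligned = 0
    for pl in placements.values():
        for b in pl.blocks:
            if b.contig_id not in contig_seqs or b.ref_id not in ref_seqs:
                raise ValueError(f"missing sequence for block {b.contig_id}/{b.ref_id}")
            if b.contig_end > len(contig_seqs[b.contig_id]) or b.ref_end > len(
                ref_seqs[b.ref_id]
            ):
                raise ValueError(f"block coordinates beyond sequence for {b.contig_id}")
            cseq = contig_seqs[b.contig_id][b.contig_start : b.contig_end].upper()
            rseq = ref_seqs[b.ref_id][b.ref_start : b.ref_end].upper()
            if b.strand == "-":
                cseq = revcomp(cseq)
            mm, si, li = _alignment_events(cseq, rseq, short_indel_max)
            mismatches += mm
            short_indels += si
            long_indels += li
            aligned += b.aligned_length
    scale = 1e5 / aligned if aligned else 0.0
    return {
        "mismatches_per_100kbp": mismatches * scale,
        "short_indels_per_100kbp": short_indels * scale,
        "long_indels_per_100kbp": long_indels * scale,
        "aligned_bases": aligned,
    }


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _alignment_events(
    cseq: str, rseq: str, short_indel_max: int, merge_window: int = 30
) -> tuple[int, int, int]:
    """Count (mismatch bases, short indel events, long indel events) between
    two near-identical sequences.

    edlib supplies the global edit path; runs of non-identity columns closer
    than ``merge_window`` are grouped and their substrings re-aligned with
    affine gap penalties, which consolidates split gap runs into single
    events.
    """
    res = edlib.align(cseq, rseq, task="path", mode="NW")
    runs = []
    q = t = 0
    for length, op in _parse_cigar(res["cigar"] or ""):
        runs.append((op, length, q, t))
        if op in "=XI":
            q += length
        if op in "=XD":
            t += length
    q_end, t_end = q, t

    mismatches = short_indels = long_indels = 0
    # group non-identity runs separated by < merge_window identity columns
    clusters: list[list[tuple[str, int, int, int]]] = []
    current: list[tuple[str, int, int, int]] = []
    for op, length, qo, to in runs:
        if op == "=":
            if length >= merge_window and current:
                clusters.append(current)
                current = []
        else:
            current.append((op, length, qo, to))
    if current:
        clusters.append(current)

    for cluster in clusters:
        if len(cluster) == 1:
            op, length, _, _ = cluster[0]
            if op == "X":
                mismatches += length
            elif length <= short_indel_max:
                short_indels += 1
            else:
                long_indels += 1
            continue
        # realign the dirty window (plus clean anchors) with affine gaps
        q0 = cluster[0][2]
        t0 = cluster[0][3]
        last_op, last_len, last_q, last_t = cluster[-1]
        q1 = last_q + (last_len if last_op in "=XI" else 0)
        t1 = last_t + (last_len if last_op in "=XD" else 0)
        q0a, t0a = max(0, q0 - 10), max(0, t0 - 10)
        q1a, t1a = min(q_end, q1 + 10), min(t_end, t1 + 10)
        sub_q, sub_t = cseq[q0a:q1a], rseq[t0a:t1a]
        if max(len(sub_q), len(sub_t)) > 5000:
            # pathological low-identity window: fall back to raw edlib runs
            for op, length, _, _ in cluster:
                if op == "X":
                    mismatches += length
                elif length <= short_indel_max:
                    short_indels += 1
                else:
                    long_indels += 1
            continue
        mm, si, li = _affine_events(sub_q, sub_t, short_indel_max)
        mismatches += mm
        short_indels += si
        long_indels += li
    return mismatches, short_indels, long_indels


def _get_refine_aligner():
    global _REFINE_ALIGNER
    try:
        return _REFINE_ALIGNER
    except NameError:
        from Bio import Align

        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1.0
        a.mismatch_score = -2.0
        a.open_gap_score = -6.0
        a.extend_gap_score = -0.2
        _REFINE_ALIGNER = a
        return a


def _affine_events(q: str, t: str, short_indel_max: int) -> tuple[int, int, int]:
    aln = _get_refine_aligner().align(t, q)[0]
    t_segs, q_segs = aln.aligned
    mismatches = 0
    short_indels = 0
    long_indels = 0

    def classify(gap_len):
        nonlocal short_indels, long_indels
        if gap_len <= 0:
            return
        if gap_len <= short_indel_max:
            short_indels += 1
        else:
            long_indels += 1

    prev_t_end = prev_q_end = None
    for (ts, te), (qs, qe) in zip(t_segs, q_segs):
        if prev_t_end is not None:
            classify(ts - prev_t_end)  # deletion from query
            classify(qs - prev_q_end)  # insertion in query
        mismatches += sum(1 for a, b in zip(t[ts:te], q[qs:qe]) if a != b)
        prev_t_end, prev_q_end = te, qe
    # global alignment end gaps
    if t_segs.size:
        classify(int(t_segs[0][0]))
        classify(int(q_segs[0][0]))
        classify(len(t) - int(t_segs[-1][1]))
        classify(len(q) - int(q_segs[-1][1]))
    return mismatches, short_indels, long_indels


# ---------------------------------------------------------------------------
# End-overlap supercontig merging


def merge_end_overlaps(
    contigs: Mapping[str, str], min_overlap: int = 1000, max_mismatch: int = 0
) -> tuple[dict[str, str], list[dict]]:
    """Merge contigs whose ends overlap (suffix of one equals prefix of another
    over >= min_overlap bases, allowing <= max_mismatch substitutions),
    keeping one copy of the overlap. Longest overlap first, ties by contig
    id; reverse-complement orientations are considered. Returns the merged
    set and a log of merges performed.
    """
    if not contigs:
        return {}, []
    seqs = dict(contigs)
    log = []
    while True:
        best = None  # (overlap, a, b, a_rc, b_rc)
        ids = sorted(seqs)
        for a in ids:
            for b in ids:
                if a == b:
                    continue
                for a_rc in (False, True):
                    sa = revcomp(seqs[a]) if a_rc else seqs[a]
                    for b_rc in (False, True):
                        sb = revcomp(seqs[b]) if b_rc else seqs[b]
                        ov = _longest_end_overlap(sa, sb, min_overlap, max_mismatch)
                        if ov and (best is None or ov > best[0]):
                            best = (ov, a, b, a_rc, b_rc)
        if best is None:
            break
        ov, a, b, a_rc, b_rc = best
        sa = revcomp(seqs[a]) if a_rc else seqs[a]
        sb = revcomp(seqs[b]) if b_rc else seqs[b]
        merged = sa + sb[ov:]
        new_id = f"{a}+{b}"
        del seqs[a]
        del seqs[b]
        seqs[new_id] = merged
        log.append(
            {"left": a, "right": b, "overlap": ov, "left_rc": a_rc, "right_rc": b_rc,
             "merged_id": new_id, "merged_length": len(merged)}
        )
    return seqs, log


def _longest_end_overlap(sa: str, sb: str, min_overlap: int, max_mismatch: int) -> int:
    """Longest k >= min_overlap with suffix_k(sa) matching prefix_k(sb)
    within max_mismatch substitutions; 0 if none."""
    kmax = min(len(sa), len(sb))
    for k in range(kmax, min_overlap - 1, -1):
        suf = sa[-k:]
        pre = sb[:k]
        if max_mismatch == 0:
            if suf == pre:
                return k
        else:
            mism = sum(1 for x, y in zip(suf, pre) if x != y)
            if mism <= max_mismatch:
                return k
    return 0
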