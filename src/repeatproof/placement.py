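"""Reduce raw alignment blocks to each contig's best placement.

This mirrors the "best mapping of each query contig" filtering step that
precedes every downstream assessment: for each contig the subset of local
alignments that maximizes identity-weighted aligned bases, subject to the
selected blocks not re-using contig sequence (overlaps beyond a small
jitter tolerance are forbidden). Reference overlaps between selected blocks
are allowed — a contig may legitimately align twice to a collapsed repeat.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .align_io import AlignmentBlock
from .intervals import complement, merge_intervals


@dataclass
class ContigPlacement:
    contig_id: str
    blocks: list[AlignmentBlock] = field(default_factory=list)

    @property
    def score(self) -> float:
        return sum(b.identity * b.aligned_length for b in self.blocks)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def _tie_key(blocks: Sequence[AlignmentBlock]) -> tuple:
    # fewer blocks first, then leftmost reference start, then ref_id
    if not blocks:
        return (0, 0, "")
    return (
        len(blocks),
        min(b.ref_start for b in blocks),
        tuple(sorted(b.ref_id for b in blocks)),
    )


def best_placement(
    blocks: Iterable[AlignmentBlock], overlap_tolerance: int = 50
) -> ContigPlacement:
    """Select the score-maximal chain of blocks for one contig.

    Weighted-interval-scheduling dynamic programming over blocks sorted by
    contig_end; two selected blocks may overlap on the contig by at most
    ``overlap_tolerance`` bases. Assumes blocks are longer than the
    tolerance (alignment-end jitter, not genuine duplication). Ties are
    broken toward fewer blocks, then the leftmost reference start, then
    lexicographic ref_id.
    """
    blocks = sorted(
        blocks, key=lambda b: (b.contig_end, b.contig_start, b.ref_start, b.ref_id)
    )
    if not blocks:
        return ContigPlacement(contig_id="", blocks=[])
    contig_ids = {b.contig_id for b in blocks}
    if len(contig_ids) != 1:
        raise ValueError(f"best_placement got blocks from several contigs: {contig_ids}")
    (contig_id,) = contig_ids

    n = len(blocks)
    ends = [b.contig_end for b in blocks]
    # best[i]: (score, tie_key, chain) over selections from blocks[0..i] that include block i
    best_score = [0.0] * n
    best_chain: list[list[AlignmentBlock]] = [[] for _ in range(n)]
    for i, b in enumerate(blocks):
        # predecessors must end at or before contig_start + tolerance
        limit = b.contig_start + overlap_tolerance
        j_hi = bisect_right(ends, limit, hi=i)
        cand_score = b.identity * b.aligned_length
        cand_chain = [b]
        for j in range(j_hi):
            s = best_score[j] + b.identity * b.aligned_length
            if s > cand_score + 1e-12 or (
                abs(s - cand_score) <= 1e-12
                and _tie_key(best_chain[j] + [b]) < _tie_key(cand_chain)
            ):
                cand_score = s
                cand_chain = best_chain[j] + [b]
        best_score[i] = cand_score
        best_chain[i] = cand_chain
    i_best = 0
    for i in range(1, n):
        if best_score[i] > best_score[i_best] + 1e-12 or (
            abs(best_score[i] - best_score[i_best]) <= 1e-12
            and _tie_key(best_chain[i]) < _tie_key(best_chain[i_best])
        ):
            i_best = i
    return ContigPlacement(contig_id=contig_id, blocks=best_chain[i_best])


def best_placement_bruteforce(
    blocks: Iterable[AlignmentBlock], overlap_tolerance: int = 50
) -> ContigPlacement:
    """Exhaustive-subset oracle for :func:`best_placement` (exponential; test use).

    A subset is valid iff every pair of its blocks overlaps by at most
    ``overlap_tolerance`` on the contig.
    """
    blocks = list(blocks)
    contig_id = blocks[0].contig_id if blocks else ""
    best: list[AlignmentBlock] = []
    best_s = 0.0
    for mask in range(1, 1 << len(blocks)):
        sub = [b for k, b in enumerate(blocks) if mask >> k & 1]
        ok = all(
            min(a.contig_end, b.contig_end) - max(a.contig_start, b.contig_start)
            <= overlap_tolerance
            for i, a in enumerate(sub)
            for b in sub[i + 1 :]
        )
        if not ok:
            continue
        s = sum(b.identity * b.aligned_length for b in sub)
        sub_sorted = sorted(sub, key=lambda b: b.contig_end)
        if s > best_s + 1e-12 or (
            abs(s - best_s) <= 1e-12 and _tie_key(sub_sorted) < _tie_key(best)
        ):
            best_s = s
            best = sub_sorted
    return ContigPlacement(contig_id=contig_id, blocks=best)


def place_all(
    blocks: Iterable[AlignmentBlock], overlap_tolerance: int = 50
) -> dict[str, ContigPlacement]:
    """Best placement for every contig present in ``blocks``."""
    per_contig: dict[str, list[AlignmentBlock]] = defaultdict(list)
    for b in blocks:
        per_contig[b.contig_id].append(b)
    return {
        cid: best_placement(bl, overlap_tolerance) for cid, bl in sorted(per_contig.items())
    }


def stringent_filter(
    placements: dict[str, ContigPlacement],
    min_identity: float = 0.99,
    min_len: int = 1000,
) -> tuple[dict[str, ContigPlacement], list[str]]:
    """High-stringency filter: keep blocks with identity >= min_identity and
    aligned length >= min_len; drop (and report) contigs left with nothing."""
    kept: dict[str, ContigPlacement] = {}
    dropped: list[str] = []
    for cid, pl in placements.items():
        blocks = [
            b
            for b in pl.blocks
            if b.identity >= min_identity and b.aligned_length >= min_len
        ]
        if blocks:
            kept[cid] = ContigPlacement(contig_id=cid, blocks=blocks)
        else:
            dropped.append(cid)
    return kept, dropped


def genome_fraction_and_duplication(
    placements: dict[str, ContigPlacement], ref_lengths: dict[str, int]
):
    """Genome fraction, duplication ratio and the per-reference summary table.

    genome_fraction = covered reference bases / total reference bases;
    duplication_ratio = total aligned block bases / covered reference bases.
    Per-reference gap counts include terminal uncovered intervals.
    """
    import pandas as pd

    per_ref_blocks: dict[str, list[AlignmentBlock]] = defaultdict(list)
    for pl in placements.values():
        for b in pl.blocks:
            if b.ref_id not in ref_lengths:
                raise ValueError(f"block references unknown sequence {b.ref_id}")
            if b.ref_end > ref_lengths[b.ref_id]:
                raise ValueError(
                    f"block [{b.ref_start},{b.ref_end}) beyond end of "
                    f"{b.ref_id} (length {ref_lengths[b.ref_id]})"
                )
            per_ref_blocks[b.ref_id].append(b)

    rows = []
    covered_total = 0
    aligned_total = 0
    for ref_id, L in sorted(ref_lengths.items()):
        blocks = per_ref_blocks.get(ref_id, [])
        ivs = [(b.ref_start, b.ref_end) for b in blocks]
        covered = sum(e - s for s, e in merge_intervals(ivs))
        gaps = complement(ivs, L)
        aligned = sum(b.aligned_length for b in blocks)
        covered_total += covered
        aligned_total += aligned
        rows.append(
            {
                "ref_id": ref_id,
                "length": L,
                "aligned_contigs": len({b.contig_id for b in blocks}),
                "alignment_gaps": len(gaps),
                "length_aligned": covered,
                "percent_aligned": 100.0 * covered / L if L else 0.0,
            }
        )
    total_ref = sum(ref_lengths.values())
    return {
        "genome_fraction": covered_total / total_ref if total_ref else 0.0,
        "duplication_ratio": aligned_total / covered_total if covered_total else 0.0,
        "per_ref": pd.DataFrame(rows),
    }
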