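"""Per-feature assembly assessment.

For every annotated gene or TE: are both of its boundaries present inside
aligned blocks of a single contig's best placement? If so, the feature span
is projected onto that contig, both subsequences are extracted, and a local
alignment yields percent identity and length ratio (assembled length /
reference length). A feature is perfectly assembled when identity and
length ratio are both exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from Bio import Align

from .align_io import AlignmentBlock, Feature
from .contig_eval import revcomp
from .placement import ContigPlacement
from .synthetic_data import GenomeBundle


@dataclass
class FeatureAssessment:
    feature_id: str
    feature_type: str
    contained: bool
    contig_id: str | None = None
    identity: float | None = None
    length_ratio: float | None = None
    perfect: bool = False
    partial: bool = False
    unassessable: bool = False


class ProjectionError(RuntimeError):
    """Feature claimed contained but its block arithmetic is inconsistent."""


def _make_aligner(
    match: float = 2.0, mismatch: float = -3.0, open_gap: float = -5.0,
    extend_gap: float = -2.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def _block_containing(blocks: list[AlignmentBlock], pos: int) -> AlignmentBlock | None:
    for b in blocks:
        if b.ref_start <= pos < b.ref_end:
            return b
    return None


def _project(b: AlignmentBlock, ref_pos: int) -> int:
    """Project a reference position onto contig coordinates through a block,
    assuming colinearity within the block (indel drift absorbed by the
    flank and the local alignment)."""
    if b.strand == "+":
        return b.contig_start + (ref_pos - b.ref_start)
    return b.contig_end - 1 - (ref_pos - b.ref_start)


def assess_feature(
    feature: Feature,
    placements: Mapping[str, ContigPlacement],
    ref_seqs: Mapping[str, str],
    contig_seqs: Mapping[str, str],
    flank: int = 100,
    aligner: Align.PairwiseAligner | None = None,
) -> FeatureAssessment:
    """Assess one feature against stringent-filtered placements."""
    if aligner is None:
        aligner = _make_aligner()
    start_pt, end_pt = feature.start, feature.end - 1
    best_contig = None
    best_score = -1.0
    for cid, pl in placements.items():
        on_ref = [b for b in pl.blocks if b.ref_id == feature.ref_id]
        b1 = _block_containing(on_ref, start_pt)
        b2 = _block_containing(on_ref, end_pt)
        if b1 is not None and b2 is not None and pl.score > best_score:
            best_contig = (cid, b1, b2)
            best_score = pl.score

    if best_contig is None:
        covered = 0
        end_hits = 0
        for pl in placements.values():
            for b in pl.blocks:
                if b.ref_id != feature.ref_id:
                    continue
                covered += max(
                    0, min(b.ref_end, feature.end) - max(b.ref_start, feature.start)
                )
                if b.ref_start <= start_pt < b.ref_end:
                    end_hits += 1
                if b.ref_start <= end_pt < b.ref_end:
                    end_hits += 1
        partial = end_hits >= 1 or covered >= 100
        return FeatureAssessment(
            feature_id=feature.feature_id, feature_type=feature.feature_type,
            contained=False, partial=partial,
        )

    cid, b1, b2 = best_contig
    cseq = contig_seqs[cid]
    p1 = _project(b1, start_pt)
    p2 = _project(b2, end_pt)
    lo, hi = (p1, p2) if p1 <= p2 else (p2, p1)
    lo = max(0, lo - flank)
    hi = min(len(cseq), hi + 1 + flank)
    if hi <= lo:
        return FeatureAssessment(
            feature_id=feature.feature_id, feature_type=feature.feature_type,
            contained=True, contig_id=cid, unassessable=True,
        )
    contig_segment = cseq[lo:hi]
    if b1.strand == "-":
        contig_segment = revcomp(contig_segment)
    ref_segment = ref_seqs[feature.ref_id][feature.start : feature.end]

    alns = aligner.align(ref_segment.upper(), contig_segment.upper())
    if len(alns) == 0:
        return FeatureAssessment(
            feature_id=feature.feature_id, feature_type=feature.feature_type,
            contained=True, contig_id=cid, identity=0.0, length_ratio=0.0,
        )
    aln = alns[0]
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    identity = counts.identities / columns if columns else 0.0
    ref_covered = sum(e - s for s, e in aln.aligned[0])
    length_ratio = ref_covered / feature.length
    perfect = identity == 1.0 and length_ratio == 1.0
    return FeatureAssessment(
        feature_id=feature.feature_id, feature_type=feature.feature_type,
        contained=True, contig_id=cid, identity=identity,
        length_ratio=length_ratio, perfect=perfect,
    )


def assess_all(
    genome: GenomeBundle,
    placements: Mapping[str, ContigPlacement],
    contig_seqs: Mapping[str, str],
    flank: int = 100,
):
    """Assess every annotated feature; returns (list of assessments, summary).

    The summary reports, per feature type, the fraction contained, perfect,
    and at >=99% identity — the latter both over the full feature length and
    over the aligned portion only.
    """
    aligner = _make_aligner()
    results = [
        assess_feature(f, placements, genome.sequences, contig_seqs, flank, aligner)
        for f in genome.features
    ]
    summary: dict[str, dict[str, float]] = {}
    for ftype in ("gene", "TE"):
        rs = [r for r in results if r.feature_type == ftype]
        if not rs:
            continue
        n = len(rs)
        contained = [r for r in rs if r.contained]
        summary[ftype] = {
            "n": n,
            "fraction_contained": len(contained) / n,
            "fraction_perfect": sum(r.perfect for r in rs) / n,
            "fraction_at_99_full_length": sum(
                1 for r in contained
                if r.identity is not None and r.identity >= 0.99
                and r.length_ratio is not None and r.length_ratio >= 1.0
            ) / n,
            "fraction_at_99_aligned": sum(
                1 for r in contained
                if r.identity is not None and r.identity >= 0.99
            ) / n,
            "fraction_partial": sum(r.partial for r in rs) / n,
        }
    return results, summary


def assessments_to_dataframe(results):
    import pandas as pd

    return pd.DataFrame([vars(r) for r in results])
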