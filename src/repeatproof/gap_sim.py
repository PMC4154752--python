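"""Coverage gaps and the coverage-gap-limited pseudo-assembly.

The pseudo-assembly asks: if assembly were limited only by where long reads
landed, what contigs could an overlap-layout assembler build? Reads whose
reference placements overlap by at least ``min_overlap`` (default 800 bp,
the assembler's merge requirement) are merged transitively; covered regions
shorter than ``min_len`` (default 1,000 bp) are discarded. Comparing the
gaps of this pseudo-assembly with the gaps of the real contig alignment
shows how much assembly failure is explained by coverage alone.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import complement, merge_intervals, overlap_length


@dataclass
class PseudoContig:
    ref_id: str
    start: int
    end: int
    supporting_read_count: int

    @property
    def length(self) -> int:
        return self.end - self.start


def pseudo_assemble(
    read_placements: Mapping[str, Sequence[tuple[int, int]]],
    min_overlap: int = 800,
    min_len: int = 1000,
) -> list[PseudoContig]:
    """Merge read placements into pseudo-contigs.

    Two reads join the same pseudo-contig iff their reference intervals
    overlap by >= min_overlap bases (transitively closed). Regions shorter
    than min_len are dropped. Both thresholds are inclusive ("at least").
    """
    out = []
    for ref_id in sorted(read_placements):
        ivs = sorted(read_placements[ref_id])
        for s, e in ivs:
            if e < s:
                raise ValueError(f"negative-length interval ({s}, {e}) on {ref_id}")
        # Sweep with a single active cluster. A read of length < min_overlap
        # can merge with nothing (its overlap with anything is below the
        # threshold), so it is an isolated singleton and must not interrupt
        # the active cluster. A long read merges iff some earlier read ends
        # at or beyond its start + min_overlap, i.e. the cluster's max end
        # does; once the cluster's max end falls below that, no later read
        # (starts only increase) can ever join it, so it is finalized.
        cur_start = cur_end = None
        cur_n = 0
        singles = []
        for s, e in ivs:
            if e - s < min_overlap:
                singles.append(PseudoContig(ref_id, s, e, 1))
                continue
            if cur_end is None:
                cur_start, cur_end, cur_n = s, e, 1
            elif cur_end - s >= min_overlap:
                cur_end = max(cur_end, e)
                cur_n += 1
            else:
                if cur_end - cur_start >= min_len:
                    out.append(PseudoContig(ref_id, cur_start, cur_end, cur_n))
                cur_start, cur_end, cur_n = s, e, 1
        if cur_end is not None and cur_end - cur_start >= min_len:
            out.append(PseudoContig(ref_id, cur_start, cur_end, cur_n))
        out.extend(p for p in singles if p.length >= min_len)
    out.sort(key=lambda p: (p.ref_id, p.start))
    return out


def pseudo_assemble_bruteforce(
    read_placements: Mapping[str, Sequence[tuple[int, int]]],
    min_overlap: int = 800,
    min_len: int = 1000,
) -> list[PseudoContig]:
    """O(n^2) pairwise-merge oracle (union-find over all read pairs)."""
    out = []
    for ref_id in sorted(read_placements):
        ivs = list(read_placements[ref_id])
        n = len(ivs)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if overlap_length(ivs[i], ivs[j]) >= min_overlap:
                    parent[find(i)] = find(j)
        groups = defaultdict(list)
        for i in range(n):
            groups[find(i)].append(ivs[i])
        for members in groups.values():
            s = min(m[0] for m in members)
            e = max(m[1] for m in members)
            if e - s >= min_len:
                out.append(PseudoContig(ref_id, s, e, len(members)))
    out.sort(key=lambda p: (p.ref_id, p.start))
    return out


def alignment_gaps(
    covered: Mapping[str, Sequence[tuple[int, int]]],
    ref_lengths: Mapping[str, int],
) -> list[tuple[str, int, int]]:
    """Complement of the covered intervals per scaffold, terminal gaps included."""
    gaps = []
    for ref_id, L in sorted(ref_lengths.items()):
        for s, e in complement(covered.get(ref_id, []), L):
            gaps.append((ref_id, s, e))
    return gaps


_VALID_CLASSES = {"TE", "satellite", "simple", "low_complexity"}


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def gap_content(
    gaps: Sequence[tuple[str, int, int]],
    sequences: Mapping[str, str],
    annotations: Sequence[tuple[str, int, int, str, str | None]] = (),
    other_gaps: Sequence[tuple[str, int, int]] | None = None,
) -> dict:
    """Characterize gap intervals: GC, repeat-class composition, TE-family counts.

    ``annotations`` rows are (ref_id, start, end, klass, family) with klass in
    {TE, satellite, simple, low_complexity}; family is set for TEs. Class
    fractions are computed independently per class (overlapping annotations
    may make them sum above 1). When ``other_gaps`` is given, the fraction of
    ``gaps`` intersecting >=1 interval of ``other_gaps`` is reported — e.g.
    assembly gaps explained by coverage gaps.
    """
    for row in annotations:
        if row[3] not in _VALID_CLASSES:
            raise ValueError(f"unknown annotation class {row[3]!r}")

    per_ref_gaps = defaultdict(list)
    for ref_id, s, e in gaps:
        per_ref_gaps[ref_id].append((s, e))

    gc_per_gap = []
    total_gap_bases = 0
    for ref_id, s, e in gaps:
        seq = sequences[ref_id][s:e] if ref_id in sequences else ""
        gc_per_gap.append(gc_fraction(seq))
        total_gap_bases += e - s

    class_bases = {k: 0 for k in _VALID_CLASSES}
    te_family_hits: dict[str, set] = defaultdict(set)
    per_ref_ann = defaultdict(list)
    for idx, (ref_id, s, e, klass, family) in enumerate(annotations):
        per_ref_ann[ref_id].append((s, e, klass, family, idx))
    for ref_id, givs in per_ref_gaps.items():
        merged_by_class: dict[str, list] = defaultdict(list)
        for s, e, klass, family, idx in per_ref_ann.get(ref_id, []):
            merged_by_class[klass].append((s, e))
            if klass == "TE":
                for gs, ge in givs:
                    if min(e, ge) - max(s, gs) > 0:
                        te_family_hits[family or "unknown"].add(idx)
                        break
        for klass, ivs in merged_by_class.items():
            merged = merge_intervals(ivs)
            for gs, ge in givs:
                for s, e in merged:
                    ov = min(e, ge) - max(s, gs)
                    if ov > 0:
                        class_bases[klass] += ov

    result = {
        "gc_per_gap": np.array(gc_per_gap),
        "mean_gc": float(np.mean(gc_per_gap)) if gc_per_gap else 0.0,
        "fraction_by_class": {
            k: class_bases[k] / total_gap_bases if total_gap_bases else 0.0
            for k in sorted(_VALID_CLASSES)
        },
        "te_family_gap_counts": {k: len(v) for k, v in sorted(te_family_hits.items())},
        "total_gap_bases": total_gap_bases,
        "n_gaps": len(gaps),
    }
    if other_gaps is not None:
        per_ref_other = defaultdict(list)
        for ref_id, s, e in other_gaps:
            per_ref_other[ref_id].append((s, e))
        n_explained = 0
        for ref_id, s, e in gaps:
            if any(
                min(e, oe) - max(s, os_) > 0 for os_, oe in per_ref_other.get(ref_id, [])
            ):
                n_explained += 1
        result["fraction_gaps_explained_by_coverage"] = (
            n_explained / len(gaps) if gaps else 0.0
        )
        result["n_gaps_explained"] = n_explained
    return result
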