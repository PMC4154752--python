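#!/usr/bin/env python
"""Coverage-gap pseudo-assembly and gap content.

Merges read placements that overlap by >=800 bp into pseudo-contigs
(dropping regions under 1 kbp), reports their size statistics, then
characterizes the gaps of the draft-contig alignment: GC content, TE
composition, per-family gap counts, and the fraction of assembly gaps
explained by coverage gaps.
"""

import argparse
import json
from pathlib import Path

from repeatproof.align_io import read_fasta, read_gff3, read_paf, read_tabular_alignments
from repeatproof.contig_eval import assembly_size_metrics
from repeatproof.gap_sim import alignment_gaps, gap_content, pseudo_assemble
from repeatproof.placement import place_all, stringent_filter


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("scratch/sim"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--min-overlap", type=int, default=800)
    ap.add_argument("--min-len", type=int, default=1000)
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)
    if not (args.data / "reads.alignments.tsv").exists():
        raise SystemExit(f"no simulation in {args.data}; run analysis/01_simulate.py")

    genome = read_fasta(args.data / "genome.fasta")
    ref_lengths = {k: len(v) for k, v in genome.items()}
    alns = read_tabular_alignments(args.data / "reads.alignments.tsv")
    placements = {}
    for a in alns:
        placements.setdefault(a.ref_id, []).append((a.ref_start, a.ref_end))

    pcs = pseudo_assemble(placements, args.min_overlap, args.min_len)
    lens = [p.length for p in pcs]
    pstats = assembly_size_metrics(lens) if lens else {}
    coverage_gaps = alignment_gaps(
        {r: [(p.start, p.end) for p in pcs if p.ref_id == r] for r in genome},
        ref_lengths,
    )

    contig_blocks = read_paf(args.data / "contigs.true.paf")
    filtered, _ = stringent_filter(place_all(contig_blocks))
    covered = {r: [] for r in genome}
    for pl in filtered.values():
        for b in pl.blocks:
            covered[b.ref_id].append((b.ref_start, b.ref_end))
    asm_gaps = alignment_gaps(covered, ref_lengths)

    tes = read_gff3(args.data / "tes.gff3")
    ann = [(t.ref_id, t.start, t.end, "TE", t.family) for t in tes]
    content = gap_content(asm_gaps, genome, ann, other_gaps=coverage_gaps)

    out = {
        "pseudo_assembly": {
            "n_pseudo_contigs": len(pcs),
            "total_length": sum(lens),
            "N50": pstats.get("N50", 0),
        },
        "n_assembly_gaps": content["n_gaps"],
        "gap_mean_gc": content["mean_gc"],
        "gap_fraction_by_class": content["fraction_by_class"],
        "te_family_gap_counts": content["te_family_gap_counts"],
        "fraction_gaps_explained_by_coverage": content[
            "fraction_gaps_explained_by_coverage"
        ],
    }
    with open(args.results / "03_gaps.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
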