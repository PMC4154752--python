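#!/usr/bin/env python
"""Assembly quality metrics for the draft contigs.

Best placement per contig, high-stringency filtering (>=99% identity,
>=1 kbp), genome fraction and duplication ratio, N50/NG50/NA50 with their
L counterparts, per-100 kbp mismatch and indel rates from block
realignment, misassembly breakpoints, and exact end-overlap supercontig
merging.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from repeatproof.align_io import read_fasta, read_paf
from repeatproof.contig_eval import (
    assembly_size_metrics,
    detect_misassemblies,
    merge_end_overlaps,
    na_metrics,
    per100kbp_errors,
)
from repeatproof.placement import (
    genome_fraction_and_duplication,
    place_all,
    stringent_filter,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("scratch/sim"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)
    if not (args.data / "contigs.fasta").exists():
        raise SystemExit(f"no simulation in {args.data}; run analysis/01_simulate.py")

    genome = read_fasta(args.data / "genome.fasta")
    contigs = read_fasta(args.data / "contigs.fasta")
    ref_lengths = {k: len(v) for k, v in genome.items()}
    genome_size = sum(ref_lengths.values())

    blocks = read_paf(args.data / "contigs.true.paf")
    placements, dropped = stringent_filter(place_all(blocks))
    gf = genome_fraction_and_duplication(placements, ref_lengths)
    gf["per_ref"].to_csv(args.results / "04_per_ref_alignment.tsv", sep="\t",
                         index=False)

    metrics = assembly_size_metrics(
        [len(s) for s in contigs.values()], genome_size=genome_size
    )
    na = na_metrics(placements, 50, genome_size)
    metrics["NA50"], metrics["LA50"] = na["N"], na["L"]
    metrics.update(per100kbp_errors(placements, contigs, genome))
    metrics["genome_fraction_percent"] = 100 * gf["genome_fraction"]
    metrics["duplication_ratio"] = gf["duplication_ratio"]
    metrics["contigs_dropped_by_filter"] = len(dropped)

    events = []
    for pl in placements.values():
        evs, _ = detect_misassemblies(pl)
        events.extend(
            {"contig_id": e.contig_id, "kind": e.kind,
             "inconsistency": e.inconsistency} for e in evs
        )
    metrics["n_misassembly_events"] = len(events)
    if events:
        pd.DataFrame(events).to_csv(
            args.results / "04_misassemblies.tsv", sep="\t", index=False
        )

    merged, log = merge_end_overlaps(contigs, min_overlap=1000)
    metrics["n_supercontig_merges"] = len(log)

    pd.Series(metrics).to_csv(args.results / "04_assembly_metrics.tsv", sep="\t",
                              header=False)
    print(json.dumps(metrics, indent=2, default=float))


if __name__ == "__main__":
    main()
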