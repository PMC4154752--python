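#!/usr/bin/env python
"""Per-feature assembly assessment of genes and TE copies.

For every annotated feature: are both boundaries inside aligned blocks of a
single contig's best placement, and if so, what identity and length ratio
does local alignment give? Compares the outcome against the simulator's
planted truth labels.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from repeatproof.align_io import read_fasta, read_gff3, read_paf
from repeatproof.feature_eval import assess_all, assessments_to_dataframe
from repeatproof.placement import place_all, stringent_filter
from repeatproof.synthetic_data import GenomeBundle


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("scratch/sim"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)
    if not (args.data / "contigs.fasta").exists():
        raise SystemExit(f"no simulation in {args.data}; run analysis/01_simulate.py")

    sequences = read_fasta(args.data / "genome.fasta")
    genome = GenomeBundle(
        sequences=sequences,
        genes=read_gff3(args.data / "genes.gff3"),
        tes=read_gff3(args.data / "tes.gff3"),
        families={},
        canonical={},
    )
    contigs = read_fasta(args.data / "contigs.fasta")
    placements, _ = stringent_filter(
        place_all(read_paf(args.data / "contigs.true.paf"))
    )

    results, summary = assess_all(genome, placements, contigs)
    df = assessments_to_dataframe(results)
    df.to_csv(args.results / "05_feature_assessments.tsv", sep="\t", index=False)

    truth = pd.read_csv(args.data / "truthset.tsv", sep="\t")
    merged = df.merge(truth, on="feature_id")
    agreement = (
        merged.assign(
            assessed=lambda d: d.perfect.map({True: "perfect", False: "other"}),
        )
        .groupby(["planted_status", "assessed"])
        .size()
        .unstack(fill_value=0)
    )
    print("assessment summary:")
    print(json.dumps(summary, indent=2, default=float))
    print("\nplanted status vs assessed-perfect:")
    print(agreement)
    with open(args.results / "05_feature_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)


if __name__ == "__main__":
    main()
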