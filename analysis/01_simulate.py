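#!/usr/bin/env python
"""Simulate the study system: an annotated toy genome with TE families of
contrasting length, copy number, divergence and tandem structure; synthetic
long-reads with the measured error and length profile plus residual
heterozygosity; and draft contigs with planted failures (coverage gaps
preferentially hitting long, low-divergence TE copies).

Writes FASTA/GFF3/VCF/PAF/TSV artifacts under --data (default scratch/sim)
for the downstream numbered steps, and a small summary under --results.
"""

import argparse
import json
from pathlib import Path

from repeatproof.synthetic_data import (
    ReadSimConfig,
    TEFamilySpec,
    generate_genome,
    simulate_contigs,
    simulate_het_sites,
    simulate_reads,
    te_failure_plan,
    write_simulation,
)

FAMILIES = [
    # long, young, tandem-prone (hard to assemble) vs short, old, dispersed
    TEFamilySpec("roo_like", 6000, 12, 0.005, gc_content=0.40, tandem_fraction=0.3),
    TEFamilySpec("copia_like", 4000, 10, 0.02, gc_content=0.42, tandem_fraction=0.2),
    TEFamilySpec("ine1_like", 600, 40, 0.08, gc_content=0.45),
]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--data", type=Path, default=Path("scratch/sim"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--scaffolds", type=int, default=2)
    ap.add_argument("--scaffold-length", type=int, default=300_000)
    ap.add_argument("--depth", type=float, default=8.0)
    ap.add_argument("--het", type=float, default=1.5e-3,
                    help="fraction of heterozygous sites (h*pi of the model)")
    args = ap.parse_args()

    genome = generate_genome(
        args.scaffolds, args.scaffold_length, FAMILIES, gene_density=10.0,
        seed=args.seed,
    )
    het = simulate_het_sites(genome, args.het, seed=args.seed + 2)
    reads = simulate_reads(
        genome,
        ReadSimConfig(target_depth=args.depth, seed=args.seed + 1,
                      gc_bias_strength=4.0),
        het_sites=het,
    )
    plan = te_failure_plan(genome, seed=args.seed + 17)
    plan.divergence_noise = 5e-5  # sparse substitutions in the draft contigs
    contigs = simulate_contigs(genome, plan)
    write_simulation(args.data, genome, reads, contigs, het_sites=het,
                     gap_truth=[tuple(g) for g in plan.gap_intervals])

    summary = {
        "seed": args.seed,
        "genome_bp": genome.total_length,
        "n_genes": len(genome.genes),
        "n_te_copies": len(genome.tes),
        "n_reads": len(reads.reads),
        "read_bases": reads.total_bases,
        "n_het_sites": len(het),
        "n_contigs": len(contigs.sequences),
        "planted_status_counts": contigs.truth.status_counts(),
    }
    args.results.mkdir(parents=True, exist_ok=True)
    with open(args.results / "01_simulation.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(json.dumps(summary, indent=2))
    print(f"artifacts in {args.data}")


if __name__ == "__main__":
    main()
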