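# repeatproof

How well does a draft genome assembly resolve genes and transposable
elements (TEs)? `repeatproof` implements an assembly-evaluation pipeline
for exactly that question, built around the kind of study where a repeat-rich
genome (the motivating case is *Drosophila melanogaster* assembled from
TruSeq synthetic long-reads) is compared against a trusted reference:

- **Read quality** — position-binned mismatch/insertion/deletion profiles,
  per-scaffold depth of coverage, and a heterozygosity-corrected error-rate
  estimator. Reads from an inbred line still carry segregating sites that
  masquerade as sequencing errors when mapped to the reference; the number
  of reference sites with at least one mismatch decomposes as

  ```
  M     = L (e + h·π)           M_SNP = L (e·p + h·π)
  ```

  where `L` is the aligned reference length, `e` the per-site error rate,
  `h` the residual heterozygosity, `π` the population pairwise diversity,
  `p` the fraction of sites that are known SNPs and `M_SNP` the mismatch
  sites overlapping known SNPs. Solving gives `e = (M − M_SNP)/(L(1−p))`
  and `h = (M/L − e)/π`; dividing `e` by the mean depth `c` converts
  site-level error to per-read-base error.
- **Contig placement** — the best placement of each contig on the reference
  (weighted-interval-scheduling dynamic programming over alignment blocks,
  maximizing identity-weighted aligned bases), the high-stringency filter
  (≥99% identity, ≥1 kbp), genome fraction and duplication ratio.
- **Assembly metrics** — N50/NG50/NA50 and L-counterparts, per-100 kbp
  mismatch and indel rates from block realignment, misassembly breakpoints
  (translocations, relocations, inversions), and exact suffix–prefix
  supercontig merging.
- **Pseudo-assembly** — the coverage-gap-limited assembly simulation: read
  placements merging when they overlap by ≥800 bp, covered regions under
  1 kbp dropped; its gaps show how much assembly failure coverage alone
  explains. Gap content is characterized by GC, repeat class and TE family.
- **Feature assessment** — per annotated gene/TE: are both boundaries
  inside aligned blocks of one contig's placement, and what identity and
  length ratio does local alignment give? "Perfect" means identity and
  length ratio both exactly 1.
- **TE success model** — a random-intercept logistic GLMM,
  `logit P(perfect) = Xβ + u_family`, `u ~ N(0, σ²)`, with standardized
  fixed effects for copy length, flank GC, divergence, high-identity copy
  count (<0.01 substitutions/base) and the divergence × high-identity
  interaction. Fitted by Laplace-approximated maximum likelihood (own
  implementation, validated against quadrature).
- **Coverage titration** — down-sampling reads to target depths and tracing
  NG(x) and feature recovery as a function of coverage.

A first-class synthetic-data generator (`repeatproof.synthetic_data`)
produces annotated toy genomes, reads and draft contigs with planted
failures and full ground truth, so every stage is testable end to end.

## Worked example

The error-decomposition solver on the study's printed euchromatic inputs
(M = 1,105,831 mismatch sites over L = 120,381,546 bp; h = 0.0550%;
π = 0.141; mean depth 31.81×):

```python
>>> from repeatproof.read_eval import HetSolveInput, solve_error_rates
>>> out = solve_error_rates(HetSolveInput(M=1_105_831, L=120_381_546,
...                                       pi=0.141, c=31.81, h=0.000550))
>>> print(f"{out['e_read'] * 100:.3g}% per base")
0.0286% per base
```

The raw rate M/(L·c) would be 0.0289% per base, inflated by
heterozygosity; the corrected 0.0286% per base is the read error alone.

## The analysis

Numbered drivers under `analysis/` run the study end to end on synthetic
data, writing tables to `results/` (simulation artifacts go to
`scratch/sim/`):

```bash
python analysis/01_simulate.py --seed 0     # genome + reads + draft contigs
python analysis/02_read_error_profile.py    # error profiles + corrected rate
python analysis/03_pseudo_assembly.py       # coverage-gap pseudo-assembly
python analysis/04_assembly_metrics.py      # N50 family, errors, misassemblies
python analysis/05_feature_assessment.py    # per-feature verdicts vs truth
python analysis/06_te_glmm.py               # TE success GLMM
python analysis/07_coverage_series.py       # NG(x) and recovery vs depth
```

On the default 600 kbp demo (seed 0), step 02 prints an uncorrected rate of
7.15e-4/base against a corrected 5.34e-4/base (configured mismatch rate
5.09e-4) — the correction removes the planted heterozygosity almost
exactly. Step 05 reports every planted `perfect` feature assessed perfect
and every planted `broken`/`diverged` feature assessed otherwise. Step 06,
on a larger 2.2 Mbp scenario where failures preferentially hit long,
low-divergence copies, prints

```
              coef      se        z       p
length      -1.6676  0.1657 -10.0657  0.0000
divergence   3.7042  0.7119   5.2035  0.0000
```

i.e. longer and less divergent TE copies are less likely to assemble
perfectly — the repeat-ambiguity signature. Step 07 shows NG50 rising from
~19 kbp at 2.5× to scaffold length by 10–20×, and gene/TE recovery
saturating toward 1.0, the characteristic coverage-response curve.

There is also a thin CLI over the same library:
`repeatproof simulate|place|run-all` (see `repeatproof --help`).

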