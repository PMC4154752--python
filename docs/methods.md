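# Methods

This note documents the models, conventions, parameter choices and known
limitations of `repeatproof`, in the order the pipeline runs.

## Coordinates and formats

Every internal coordinate is 0-based half-open on the forward strand;
GFF3 and NUCmer `show-coords` output (1-based inclusive) are converted at
the parse/write boundary in `align_io` and nowhere else. Reverse-strand
alignment blocks store their reference interval in forward orientation
plus a strand flag, so interval arithmetic is orientation-free. SAM/BAM is
read through pysam; mismatches are classified from the MD tag when present
or from a supplied reference otherwise (an error if neither is available).

## Synthetic-data generator

The generator emulates the study system — a repeat-rich inbred-line genome
sequenced with low-error synthetic long-reads — with full ground truth.

**Genome.** Background sequence with sinusoidal GC (mean 0.42, amplitude
0.08, period 100 kbp by default, matching a euchromatic GC level with
low-GC troughs). Each TE family has a random canonical sequence at its
specified GC; copies are planted as mutated, possibly 5′-truncated
(probability 0.25, retaining 40–95%) instances on random strands.
Per-copy divergence is Gamma-distributed (shape 2, mean = the family's
`mean_divergence`, CV ≈ 0.71) and substitutions are then binomial at that
rate: TE copies in real annotations span insertion ages, and this
within-family divergence variation is what makes the divergence effect in
the downstream GLMM identifiable at all rather than perfectly confounded
with the family intercept. A configured fraction of each family's copies
is placed as adjacent same-family tandem pairs (20 bp spacer). Genes are
annotation intervals over unique background, never overlapping TEs.
Packing beyond 80% of the genome raises an explicit error.

**Reads.** Lengths follow a two-component log-normal mixture truncated at
`min_length` (default 1,500 bp): a narrow component with median at the
modal length (default 8,500 bp, σ_log = 0.18) and a broad short component
(median ≈ 2,500 bp, σ_log = 0.45), with the long-component weight solved
numerically so the truncated mixture mean equals `mean_length` (default
4,400 bp; the weight comes out near 0.25). This reproduces the observed
left-skewed distribution — most reads short, a local maximum near 8.5 kbp
— without claiming a parametric form the data do not pin down. Per-base
error rates default to the measured values (mismatch 5.09e-4, insertion
1.66e-4, deletion 2.90e-4); mismatch probability is multiplied by
`start_mismatch_multiplier` over the first 100 sequenced bases, emulating
the start-elevated mismatch profile. Start positions are drawn
per-500 bp-window with weight `1/(1+exp(−k·(GC−0.35)))`, under-sampling
low-GC windows for `k > 0`. Residual heterozygosity is modeled as
biallelic sites at frequency 0.5 (pooled inbred line); an overlapping read
carries the alternate allele with probability 0.5, and such bases are
recorded as mismatches in the read's true alignment, exactly as a mapping
pipeline would see them. Every read records its true source interval and
operation-level alignment, so no mapper is needed downstream.

**Contigs.** Draft contigs are reference segments between planted gap
intervals. Tandem collapse removes the second copy of each tandem pair as
an internal deletion (the contig continues); relocations splice two
segments from different locations into one contig; divergence noise
substitutes contig bases at a configured rate. Every annotated feature
receives a truth label: `absent` (interval fully removed or collapsed),
`broken` (partially removed), `diverged` (≥1 noise substitution inside
it), else `perfect`. `te_failure_plan` builds a gap plan in which each TE
copy is hit with probability
`expit(logit(base) + lw·z_length − dw·z_divergence)` — long, low-divergence
copies fail preferentially, giving the GLMM a planted effect with known
signs.

**What the generator does not emulate:** chimeric reads, base-quality
structure, indel hotspots, segmental duplications, satellite arrays, and
real mapping ambiguity (true alignments are used instead of a mapper).
Passing tests therefore demonstrate correctness of the evaluation
machinery under the stated error model, not robustness to every artifact
of real data.

## Read evaluation

Error profiles bin events by distance from the read's 5′ end as sequenced
(bin width 100 bp). Conventions: aligned-base denominators count
match+mismatch bases; insertions contribute one event per inserted base at
their read offset; deletions one event per deleted base, binned at the
read offset immediately 5′ of the deletion. Depth of coverage counts only
match/mismatch-consuming operations (insertions add nothing; deletions
span but do not cover).

The heterozygosity correction counts reference *sites* with ≥1 mismatch
observation (M), not mismatch events — a site hit by several reads counts
once. The solver inverts `M = L(e + hπ)` and `M_SNP = L(ep + hπ)` (or uses
a known `h` directly) and converts site-level to read-level error by
dividing by mean depth `c`. This conversion ignores multi-hit sites and is
therefore conservative, slightly underestimating the error rate at high
depth; negative intermediates (h·π exceeding M/L) raise an inconsistency
error rather than clamping.

## Placement

`best_placement` maximizes Σ identity·aligned_length over subsets of one
contig's blocks that are non-overlapping in contig coordinates beyond a
50 bp tolerance (alignment-end jitter), by weighted-interval-scheduling
dynamic programming over blocks sorted by contig end; ties prefer fewer
blocks, then leftmost reference start, then lexicographic reference name.
Chain consistency is enforced only in contig coordinates — reference
overlaps are allowed, mirroring query-best filtering: a contig may
genuinely align twice into a collapsed repeat. The DP's predecessor rule
is exact when blocks are longer than the tolerance (then pairwise-overlap
validity equals consecutive-overlap validity in end order); blocks shorter
than 50 bp are below any stringent filter anyway. The exhaustive-subset
oracle used in tests checks the all-pairs predicate.

Genome fraction is covered reference bases over total reference bases;
duplication ratio is aligned block bases over covered bases. Per-reference
gap counts include terminal uncovered intervals (end gaps count).

## Pseudo-assembly and gaps

Two reads merge into one pseudo-contig iff their reference intervals
overlap by ≥ `min_overlap` (800 bp), transitively closed; covered regions
shorter than `min_len` (1,000 bp) are dropped. Both thresholds are
inclusive ("at least"). The sweep implementation exploits two facts: a
read shorter than the overlap threshold can merge with nothing, and a
cluster whose maximum end falls below `start + min_overlap` of the current
read can never gain members again; it is validated against an O(n²)
union-find oracle. Gap/annotation intersection requires ≥1 bp; repeat-class
fractions are computed independently per class and may sum above 1 where
annotations overlap.

## Assembly metrics

N(x) is the length of the contig at which the descending cumulative length
first reaches x% of the total (or of `genome_size` for NG); if the
threshold is unreachable the value is 0 and flagged. NA(x) is N(x) over
aligned chain pieces after breaking contigs at misassembly events.
Misassembly classification between adjacent placed blocks: different
reference → translocation; same reference, opposite strands → inversion;
same reference and strand with reference order contradicting contig order
or |reference gap − contig gap| > 1,000 bp → relocation (the 1 kbp
inconsistency threshold is the conventional one in reference-based
assembly evaluation).

Per-100 kbp error rates realign each block's contig and reference segments
globally with edlib. Because a unit-cost aligner may split one indel into
several runs at equal edit distance, clusters of non-identity columns
(within 30 columns of each other) are re-aligned with affine gap penalties
(match 1, mismatch −2, open −6, extend −0.2), which consolidates each
indel into one gap run; an indel event is one gap run, short vs long at
≤5 bp. Supercontig merging requires an exact (0-mismatch) suffix–prefix
overlap of ≥1,000 bp by default, considers both orientations, merges
longest-overlap-first, and logs every merge.

## Feature assessment

A feature is *contained* when both of its endpoints lie inside aligned
blocks belonging to the same contig's best placement — the two endpoints
may be in different blocks of that chain, tolerating internal alignment
breaks shorter than the feature. The feature span (±100 bp flank) is
projected onto the contig through the covering blocks assuming
within-block colinearity (indel drift is absorbed by the flank and the
aligner), and the reference feature sequence is locally aligned to the
extracted contig window with match +2, mismatch −3, gap open −5, gap
extend −2 (megablast-like defaults; configurable). Identity is
matches/alignment columns; length ratio is reference bases covered by the
single best local alignment over feature length (no HSP stitching —
conservative). Perfect requires both exactly 1. A non-contained feature is
*partial* if at least one endpoint or ≥100 bp of it is covered by any
block. The ≥99%-identity summary is reported both over the full feature
length (length ratio 1) and over the aligned portion, since the two
definitions genuinely differ.

## TE success GLMM

One row per assessed TE copy: `y = perfect`, with standardized fixed
effects for copy length, GC of the copy ±1 kbp flanks (truncated at
scaffold ends), divergence from the family canonical, the family's count
of high-identity copies (divergence < 0.01, strict), and the
divergence × high-copies interaction formed as the product of the two
standardized columns (not re-standardized itself). Family enters as a
random intercept.

The marginal likelihood integrates each family's intercept by the Laplace
approximation: per family `l(û) − û²/(2σ²) − ½·log(1 + σ²W)` with `û` the
conditional mode (inner Newton) and `W = Σ p(1−p)` at the mode. At σ = 0
this is exactly the logistic log-likelihood, so the parametrization
(β, σ ≥ 0) is smooth through the boundary. Optimization is L-BFGS-B from
fixed starting values (β = 0, σ = 1), gradient tolerance 1e-8; standard
errors come from the observed information (numerical Hessian of the
marginal log-likelihood). Complete separation is detected as a diverging
fixed effect and raised explicitly.

Validation is dual-route: against plain logistic regression with σ fixed
at 0, and against an adaptive 51-point Gauss–Hermite quadrature oracle
(centered and scaled at each family's conditional mode) for the marginal
log-likelihood. The Laplace approximation error on a 3-family, 12-
observation toy grows approximately as σ⁴ — measured ≈1.4e-5 at σ = 0.1,
≈5e-4 at σ = 0.25, ≈1e-3 at σ = 0.3, ≈1.4e-2 at σ = 0.7 — an inherent
property of the approximation at 4 observations per group, not an
implementation defect. The quadrature agreement test therefore evaluates
at σ = 0.25, where approximation error sits well below the 1e-3
comparison tolerance, so the check isolates implementation error (a wrong
mode, curvature or determinant term fails it by orders of magnitude);
the σ-growth above documents where the approximation itself degrades.
Parameter recovery is assessed over 20 replicates at n = 3,000 / 50
families (mean bias per standardized coefficient < 0.05; ≈95% coverage of
2-SE intervals), which is the statistically meaningful form of the claim —
a single-replicate "all six coefficients within 2 SE" check fails ~26% of
the time by construction.

Predicted-probability curves hold other covariates at 0 (the standardized
mean) and the random intercept at 0, recomputing the interaction along the
grid.

## Coverage titration

Reads are drawn uniformly without replacement until cumulative bases reach
`target_depth × genome_size` (the crossing read is kept, so totals
overshoot by less than one read length). Re-assembly at each depth is
replaced by the coverage-gap pseudo-assembly — the gap analysis itself
shows coverage explains most assembly breaks, which is what licenses the
surrogate — and a feature counts as recoverable when it lies entirely
inside one pseudo-contig (pseudo-contigs are reference segments, so
containment is exactly perfect reconstruction). Coverage is normalized to
the full synthetic genome length. The known caveat that very high coverage
can degrade overlap-layout assembly in practice is not modeled; the
surrogate saturates instead.

## Problem sizes and experiment design

The bundled analyses and tests run at desk scale, chosen so each planted
effect is detectable with comfortable margin rather than balanced on a
statistical knife edge:

- Truth-recovery runs use 2 × 150 kbp genomes with ~70 features across 20
  seeds; planted gap/collapse/noise labels must be recovered for every
  feature.
- The error-model experiment uses a 500 kbp genome at 6× with a planted
  heterozygous-site fraction of 1.5e-3. The study's own value (h·π ≈
  7.8e-5) is only resolvable against Poisson noise on M at the full
  120 Mbp reference; at desk scale the fraction is raised so the
  correction margin `f/(2c)` exceeds 5 standard deviations of M per run.
- The GLMM sign experiment uses 20 families × 28 copies (≈560 copies on
  2.2 Mbp) with length and divergence varied on crossed grids so they are
  uncorrelated by design, and planted failure weights (length 1.5,
  divergence 3.0 on standardized scales) sized by power analysis —
  divergence standard errors are inflated by its intrinsic collinearity
  with the high-identity copy count and the interaction, exactly as in
  real TE annotations.
- The coverage series uses a 2 Mbp genome across 2.5–34×, 10 seeds.

## Known limitations

- Feature projection assumes colinearity within each alignment block;
  blocks from a real aligner with large internal indels would project
  approximately (the flank plus local alignment absorbs small drift).
- The site→read error conversion divides by mean depth, ignoring
  depth heterogeneity and multi-hit sites (conservative).
- `best_placement` is exact for blocks longer than the overlap tolerance;
  sub-tolerance blocks are handled but not guaranteed optimal.
- The GLMM supports a single scalar random intercept per family; crossed
  or nested random effects and alternative links are out of scope.
- Supercontig merging is exact-overlap by default and greedy
  (longest-overlap-first) on ambiguous three-way overlaps, which are
  logged rather than resolved optimally.
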