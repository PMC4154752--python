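import numpy as np
import pytest

from repeatproof.contig_eval import revcomp
from repeatproof.synthetic_data import (
    FailurePlan,
    PackingError,
    ReadSimConfig,
    TEFamilySpec,
    generate_genome,
    simulate_contigs,
    simulate_het_sites,
    simulate_reads,
)


class TestGenerateGenome:
    def test_zero_divergence_copies_match_canonical_exactly(self):
        fam = TEFamilySpec("f", 800, 12, mean_divergence=0.0)
        g = generate_genome(1, 100_000, [fam], gene_density=0, seed=3,
                            truncation_prob=0.0)
        canon = g.canonical["f"]
        for te in g.tes:
            planted = g.sequences[te.ref_id][te.start : te.end]
            assert planted == canon or revcomp(planted) == canon

    def test_realized_substitutions_center_on_family_mean(self):
        # per-copy divergence is Gamma(shape 2) around the family mean, then
        # substitutions are binomial: E[subs] = n * mean_divergence, with
        # compound variance n*d*(1-d) + n^2 * d^2/2
        n, d, copies = 1000, 0.01, 50
        fam = TEFamilySpec("f", n, copies, mean_divergence=d)
        g = generate_genome(1, 300_000, [fam], gene_density=0, seed=5,
                            truncation_prob=0.0)
        subs = [g.te_info[t.feature_id].n_substitutions for t in g.tes]
        var = n * d * (1 - d) + n * n * d * d / 2
        se = np.sqrt(var / copies)
        assert abs(np.mean(subs) - n * d) <= 3 * se

    def test_family_divergence_converges_at_large_copy_number(self):
        n, d, copies = 300, 0.02, 500
        fam = TEFamilySpec("f", n, copies, mean_divergence=d)
        g = generate_genome(2, 600_000, [fam], gene_density=0, seed=6,
                            truncation_prob=0.0)
        divs = [t.divergence for t in g.tes]
        var = (d * (1 - d) / n) + d * d / 2  # compound variance of d_hat
        se = np.sqrt(var / copies)
        assert abs(np.mean(divs) - d) <= 3 * se

    def test_gene_count_and_te_exclusion(self):
        fam = TEFamilySpec("f", 500, 10, mean_divergence=0.05)
        g = generate_genome(2, 1_000_000, [fam], gene_density=10.0, seed=9)
        assert len(g.genes) == 20
        for gene in g.genes:
            for te in g.tes:
                if te.ref_id != gene.ref_id:
                    continue
                assert min(gene.end, te.end) - max(gene.start, te.start) <= 0

    def test_tandem_fraction_places_adjacent_pairs(self):
        fam = TEFamilySpec("f", 400, 20, mean_divergence=0.02, tandem_fraction=0.5)
        g = generate_genome(1, 200_000, [fam], gene_density=0, seed=11)
        pairs = {
            t.feature_id: g.te_info[t.feature_id].tandem_partner
            for t in g.tes
            if g.te_info[t.feature_id].tandem_partner
        }
        assert len(pairs) == 10  # 5 pairs
        by_id = {t.feature_id: t for t in g.tes}
        for fid, pid in pairs.items():
            a, b = by_id[fid], by_id[pid]
            assert a.ref_id == b.ref_id
            gap = max(a.start, b.start) - min(a.end, b.end)
            assert gap == 20

    def test_determinism(self):
        fam = TEFamilySpec("f", 500, 8, mean_divergence=0.03)
        g1 = generate_genome(2, 100_000, [fam], seed=21)
        g2 = generate_genome(2, 100_000, [fam], seed=21)
        assert g1.sequences == g2.sequences
        assert [(t.feature_id, t.start, t.end) for t in g1.tes] == [
            (t.feature_id, t.start, t.end) for t in g2.tes
        ]

    def test_infeasible_packing_raises(self):
        fam = TEFamilySpec("f", 10_000, 50, mean_divergence=0.0)
        with pytest.raises(PackingError):
            generate_genome(1, 100_000, [fam], seed=1)

    def test_invalid_family_spec(self):
        with pytest.raises(ValueError):
            TEFamilySpec("f", 10, 5, 0.01)
        with pytest.raises(ValueError):
            TEFamilySpec("f", 500, 5, 0.9)


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self, small_genome):
        cfg = ReadSimConfig(
            target_depth=0.5, seed=2, mismatch_rate=0, insertion_rate=0,
            deletion_rate=0, start_mismatch_multiplier=1.0,
        )
        rs = simulate_reads(small_genome, cfg)
        for r in rs.reads[:200]:
            segment = small_genome.sequences[r.ref_id][r.ref_start : r.ref_end]
            assert r.sequence == (segment if r.strand == "+" else revcomp(segment))

    def test_read_lengths_respect_minimum(self, small_genome, fast_read_config):
        rs = simulate_reads(small_genome, fast_read_config, emit_sequences=False)
        spans = [r.ref_end - r.ref_start for r in rs.reads]
        assert min(spans) >= fast_read_config.min_length

    def test_mismatch_count_follows_poisson_expectation(self, small_genome):
        cfg = ReadSimConfig(
            target_depth=8.0, seed=13, mismatch_rate=0.001, insertion_rate=0,
            deletion_rate=0, start_mismatch_multiplier=1.0,
        )
        rs = simulate_reads(small_genome, cfg, emit_sequences=False)
        n_mm = sum(
            run.length for r in rs.reads for run in r.alignment.ops if run.op == "X"
        )
        expected = 0.001 * rs.total_bases
        assert abs(n_mm - expected) <= 3 * np.sqrt(expected)

    def test_het_sites_appear_in_about_half_of_overlapping_reads(self, small_genome):
        sites = simulate_het_sites(small_genome, 2e-4, seed=3)
        cfg = ReadSimConfig(
            target_depth=6.0, seed=4, mismatch_rate=0, insertion_rate=0,
            deletion_rate=0, start_mismatch_multiplier=1.0,
        )
        rs = simulate_reads(small_genome, cfg, het_sites=sites, emit_sequences=False)
        site_set = {(r, p) for r, p, _ in sites}
        n_overlap = 0
        n_alt = 0
        for r in rs.reads:
            for ref, p, _ in sites:
                if r.ref_id == ref and r.ref_start <= p < r.ref_end:
                    n_overlap += 1
        for r in rs.reads:
            for op, s, e in r.alignment.iter_ref_ops():
                if op == "X":
                    for pos in range(s, e):
                        if (r.ref_id, pos) in site_set:
                            n_alt += 1
        assert n_overlap > 50
        frac = n_alt / n_overlap
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / n_overlap)

    def test_determinism_of_read_sets(self, small_genome):
        cfg = ReadSimConfig(target_depth=1.0, seed=6)
        r1 = simulate_reads(small_genome, cfg)
        r2 = simulate_reads(small_genome, cfg)
        assert [a.sequence for a in r1.reads] == [a.sequence for a in r2.reads]

    def test_too_short_genome_is_an_error(self):
        fam = TEFamilySpec("f", 100, 1, 0.0)
        tiny = generate_genome(1, 1000, [fam], gene_density=0, seed=1)
        with pytest.raises(ValueError, match="min_length"):
            simulate_reads(tiny, ReadSimConfig(target_depth=1.0, seed=1))


class TestSimulateContigs:
    def test_empty_plan_gives_one_perfect_contig_per_scaffold(self, small_genome):
        cs = simulate_contigs(small_genome, FailurePlan())
        assert len(cs.sequences) == len(small_genome.sequences)
        statuses = {r.planted_status for r in cs.truth.records.values()}
        assert statuses == {"perfect"}
        # contigs are byte-identical to their scaffolds
        assert sorted(cs.sequences.values()) == sorted(
            small_genome.sequences.values()
        )

    def test_gap_bisecting_a_gene_labels_it_broken(self, small_genome):
        gene = small_genome.genes[0]
        mid = (gene.start + gene.end) // 2
        plan = FailurePlan(gap_intervals=[(gene.ref_id, mid - 10, mid + 10)])
        cs = simulate_contigs(small_genome, plan)
        assert cs.truth.records[gene.feature_id].planted_status == "broken"
        flank_blocks = [
            b for b in cs.true_blocks
            if b.ref_id == gene.ref_id
            and min(b.ref_end, gene.end) - max(b.ref_start, gene.start) > 0
        ]
        assert len(flank_blocks) == 2

    def test_collapse_tandems_removes_one_copy_per_pair(self, small_genome):
        cs = simulate_contigs(small_genome, FailurePlan(collapse_tandems=True))
        partners = {
            fid: info.tandem_partner
            for fid, info in small_genome.te_info.items()
            if info.tandem_partner
        }
        n_pairs = len(partners) // 2
        counts = cs.truth.status_counts()
        assert counts.get("absent", 0) == n_pairs
        for fid, pid in partners.items():
            st = {cs.truth.records[fid].planted_status,
                  cs.truth.records[pid].planted_status}
            assert st == {"absent", "perfect"}

    def test_sequence_conservation_without_collapses(self, small_genome):
        plan = FailurePlan(gap_intervals=[("scaffold_1", 50_000, 60_000),
                                          ("scaffold_2", 10_000, 11_000)])
        cs = simulate_contigs(small_genome, plan)
        contig_total = sum(len(s) for s in cs.sequences.values())
        gap_total = 10_000 + 1_000
        assert contig_total + gap_total == small_genome.total_length

    def test_relocations_splice_two_segments(self, small_genome):
        plan = FailurePlan(
            gap_intervals=[("scaffold_1", 100_000, 101_000)], relocation_count=1,
            seed=5,
        )
        cs = simulate_contigs(small_genome, plan)
        assert len(cs.truth.misassemblies) == 1
        spliced = cs.truth.misassemblies[0]["contig_id"]
        refs = {b.ref_id for b in cs.true_blocks if b.contig_id == spliced}
        assert len([b for b in cs.true_blocks if b.contig_id == spliced]) >= 2

    def test_too_many_relocations_rejected(self, small_genome):
        with pytest.raises(ValueError, match="relocation_count"):
            simulate_contigs(small_genome, FailurePlan(relocation_count=50))

    def test_out_of_bounds_gap_rejected(self, small_genome):
        with pytest.raises(ValueError, match="bounds"):
            simulate_contigs(
                small_genome, FailurePlan(gap_intervals=[("scaffold_1", -5, 10)])
            )
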