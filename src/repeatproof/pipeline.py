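"""End-to-end orchestration: simulate -> place -> evaluate -> model.

A single RunConfig drives every stage with the standard thresholds
(stringent filter >=99% identity and >=1 kbp; pseudo-assembly merge >=800 bp
and minimum region 1 kbp; high-identity divergence < 0.01). Stages run in
dependency order; a stage failure aborts its dependents but not independent
stages, and the run report records per-stage status alongside every summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .contig_eval import assembly_size_metrics, na_metrics, per100kbp_errors
from .downsample import coverage_series
from .feature_eval import assess_all, assessments_to_dataframe
from .gap_sim import alignment_gaps, gap_content, pseudo_assemble
from .placement import genome_fraction_and_duplication, place_all, stringent_filter
from .read_eval import depth_of_coverage, profile_errors
from .synthetic_data import (
    te_failure_plan,
    FailurePlan,
    GenomeBundle,
    ReadSimConfig,
    TEFamilySpec,
    generate_genome,
    simulate_contigs,
    simulate_het_sites,
    simulate_reads,
)
from .te_glmm import build_design, fit_glmm


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/demo"
    # genome
    n_scaffolds: int = 2
    scaffold_length: int = 500_000
    gene_density: float = 10.0
    families: list[dict] = field(default_factory=lambda: [
        {"name": "roo_like", "canonical_length": 6000, "copy_number": 12,
         "mean_divergence": 0.005, "gc_content": 0.40, "tandem_fraction": 0.3},
        {"name": "ine1_like", "canonical_length": 600, "copy_number": 40,
         "mean_divergence": 0.08, "gc_content": 0.45, "tandem_fraction": 0.0},
        {"name": "copia_like", "canonical_length": 4000, "copy_number": 10,
         "mean_divergence": 0.02, "gc_content": 0.42, "tandem_fraction": 0.2},
    ])
    # reads
    read_config: dict = field(default_factory=dict)
    heterozygosity: float = 0.0005
    # contigs
    failure_plan: dict = field(default_factory=dict)
    # thresholds
    min_identity: float = 0.99
    min_len: int = 1000
    min_overlap: int = 800
    pseudo_min_len: int = 1000
    high_identity_div: float = 0.01
    mapq: int = 20
    coverage_depths: list[float] = field(default_factory=lambda: [2.5, 5.0, 10.0])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _default_failure_plan(genome: GenomeBundle, cfg: RunConfig) -> FailurePlan:
    """By default break TE copies with covariate-linked probability (long,
    low-divergence copies fail more often); explicit plan entries override."""
    raw = dict(cfg.failure_plan)
    if "gap_intervals" not in raw:
        raw["gap_intervals"] = te_failure_plan(
            genome, seed=cfg.seed + 17
        ).gap_intervals
    raw.setdefault("seed", cfg.seed + 29)
    raw["gap_intervals"] = [tuple(g) for g in raw["gap_intervals"]]
    return FailurePlan(**raw)


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write a machine-readable run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    def stage(name, fn, *deps):
        if any(report["stages"].get(d, {}).get("status") != "ok" for d in deps):
            report["stages"][name] = {"status": "skipped (failed dependency)"}
            return None
        try:
            result = fn()
            report["stages"][name] = {"status": "ok"}
            return result
        except Exception as exc:  # recorded, dependents skipped
            report["stages"][name] = {"status": f"error: {exc}"}
            return None

    # --- simulate
    def do_genome():
        fams = [TEFamilySpec(**f) for f in config.families]
        return generate_genome(
            config.n_scaffolds, config.scaffold_length, fams,
            gene_density=config.gene_density, seed=config.seed,
        )

    genome = stage("genome", do_genome)

    def do_reads():
        rc = ReadSimConfig(**{"seed": config.seed + 1, **config.read_config})
        het = simulate_het_sites(genome, config.heterozygosity, seed=config.seed + 2)
        return simulate_reads(genome, rc, het_sites=het), het

    reads_het = stage("reads", do_reads, "genome")
    reads, het = reads_het if reads_het else (None, None)

    contigs = stage(
        "contigs",
        lambda: simulate_contigs(genome, _default_failure_plan(genome, config)),
        "genome",
    )

    # --- read evaluation
    def do_read_eval():
        prof = profile_errors(reads.alignments, bin_width=100, mapq_min=0)
        track, means = depth_of_coverage(
            reads.alignments, genome.ref_lengths(), mapq_min=0
        )
        report["read_error_totals"] = prof.totals()
        report["coverage_means"] = {
            r.ref_id: r.mean_depth for r in means.itertuples()
        }
        report["genome_mean_depth"] = track.genome_mean()
        prof.to_dataframe().to_csv(out / "error_profile.tsv", sep="\t", index=False)
        return track

    track = stage("read_eval", do_read_eval, "reads")

    # --- placement and assembly metrics
    def do_place():
        placements = place_all(contigs.true_blocks)
        filtered, dropped = stringent_filter(
            placements, config.min_identity, config.min_len
        )
        gf = genome_fraction_and_duplication(filtered, genome.ref_lengths())
        report["genome_fraction"] = gf["genome_fraction"]
        report["duplication_ratio"] = gf["duplication_ratio"]
        report["n_contigs_dropped_by_filter"] = len(dropped)
        gf["per_ref"].to_csv(out / "per_ref_alignment.tsv", sep="\t", index=False)
        return filtered

    placements = stage("place", do_place, "contigs")

    def do_metrics():
        lens = [len(s) for s in contigs.sequences.values()]
        m = assembly_size_metrics(lens, genome_size=genome.total_length)
        na = na_metrics(placements, 50, genome.total_length)
        m["NA50"], m["LA50"] = na["N"], na["L"]
        errs = per100kbp_errors(placements, contigs.sequences, genome.sequences)
        m.update(errs)
        report["assembly_metrics"] = m
        return m

    stage("metrics", do_metrics, "place")

    # --- gaps
    def do_gaps():
        pcs = pseudo_assemble(
            reads.placements, config.min_overlap, config.pseudo_min_len
        )
        coverage_gaps = alignment_gaps(
            {r: [(p.start, p.end) for p in pcs if p.ref_id == r]
             for r in genome.sequences},
            genome.ref_lengths(),
        )
        covered = {
            r: [
                (b.ref_start, b.ref_end)
                for pl in placements.values()
                for b in pl.blocks
                if b.ref_id == r
            ]
            for r in genome.sequences
        }
        asm_gaps = alignment_gaps(covered, genome.ref_lengths())
        ann = [
            (t.ref_id, t.start, t.end, "TE", t.family) for t in genome.tes
        ]
        content = gap_content(
            asm_gaps, genome.sequences, ann, other_gaps=coverage_gaps
        )
        report["pseudo_assembly"] = {
            "n_pseudo_contigs": len(pcs),
            "total_length": int(sum(p.length for p in pcs)),
            "N50": assembly_size_metrics([p.length for p in pcs])["N50"] if pcs else 0,
        }
        report["gap_content"] = {
            "n_gaps": content["n_gaps"],
            "mean_gc": content["mean_gc"],
            "fraction_by_class": content["fraction_by_class"],
            "te_family_gap_counts": content["te_family_gap_counts"],
            "fraction_gaps_explained_by_coverage": content.get(
                "fraction_gaps_explained_by_coverage"
            ),
        }

    stage("gaps", do_gaps, "reads", "place")

    # --- feature assessment
    def do_assess():
        results, summary = assess_all(genome, placements, contigs.sequences)
        report["feature_summary"] = summary
        assessments_to_dataframe(results).to_csv(
            out / "feature_assessments.tsv", sep="\t", index=False
        )
        return results

    assessments = stage("assess", do_assess, "place")

    # --- GLMM
    def do_glmm():
        data = build_design(assessments, genome.tes, genome)
        fit = fit_glmm(data)
        report["glmm"] = {
            "coefficients": {
                c: {"coef": float(b), "se": float(s), "z": float(z), "p": float(p)}
                for c, b, s, z, p in zip(fit.columns, fit.beta, fit.se, fit.z, fit.p)
            },
            "sigma_family": fit.sigma_family,
            "loglik": fit.loglik,
        }
        fit.coefficient_table().to_csv(out / "glmm_coefficients.tsv", sep="\t")

    stage("glmm", do_glmm, "assess")

    # --- coverage series
    def do_series():
        rc = ReadSimConfig(**{"seed": config.seed + 1, **config.read_config})
        series = coverage_series(
            genome, rc, config.coverage_depths,
            config.min_overlap, config.pseudo_min_len, seed=config.seed + 3,
        )
        series.feature_recovery.to_csv(
            out / "coverage_series.tsv", sep="\t", index=False
        )
        report["coverage_series"] = series.feature_recovery.to_dict("records")

    stage("coverage_series", do_series, "genome")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
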