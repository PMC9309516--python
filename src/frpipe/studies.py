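"""Benchmark study conditions for validating the presence-calling rule.

Two canonical seeded communities exercise the pipeline's discrimination
behaviour end to end:

* :func:`recovery_community` — eight genomes: five genuinely planted
  members with abundant uniform coverage at low divergence (the cases the
  rule must accept), two decoy genomes that receive only cross-mapped
  secondary alignments from related members at high extra divergence (best
  -hit filtering must starve them of reads), and one "artifact" genome
  whose reads all pile into a single genome tenth (the coverage-uniformity
  statistic must reject it).
* :func:`host_depletion_community` — one microbial member plus a 15%
  host-plant read fraction at 2% divergence, for measuring depletion
  recall and precision against the generator's truth table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .host import deplete_host
from .io import annotate_alignments, contig_table_from_fasta
from .qc import trim_dataset
from .recruitment import best_hits, build_profiles, presence_table
from .synthetic import (
    CommunityDesign, GenomeSpec, Member, generate_genomes, manifest_from_specs,
    simulate_alignments, simulate_reads,
)

PLANTED = ["p1", "p2", "p3", "p4", "p5"]
DECOYS = ["d1", "d2"]
ARTIFACT = "a1"


def recovery_specs() -> list[GenomeSpec]:
    sizes = {
        "p1": (40_000,), "p2": (25_000, 15_000), "p3": (40_000,),
        "p4": (30_000, 10_000), "p5": (40_000,),
        "d1": (40_000,), "d2": (40_000,), "a1": (40_000,),
    }
    return [
        GenomeSpec(g, f"Species {g}", f"Genus_{g[0]}", "ClassX", sizes[g],
                   seed=100 + i)
        for i, g in enumerate(PLANTED + DECOYS + [ARTIFACT])
    ]


def recovery_design(seed: int, n_reads: int = 20_000) -> CommunityDesign:
    divergences = [0.0, 0.01, 0.02, 0.03, 0.05]
    members = [
        Member(g, 0.13, divergence=d,
               sister_id={"p1": "d1", "p2": "d2"}.get(g),
               sister_extra_divergence=0.2)
        for g, d in zip(PLANTED, divergences)
    ]
    members.append(Member(ARTIFACT, 0.09, divergence=0.01,
                          coverage_mode="single-region", region=2))
    return CommunityDesign(
        sample_id="recovery", members=members, n_reads=n_reads, seed=seed,
        unclassified_fraction=1.0 - 5 * 0.13 - 0.09,
    )


def run_recovery(seed: int, n_reads: int = 20_000) -> pd.DataFrame:
    """Simulate, trim, recruit and call the recovery community."""
    specs = recovery_specs()
    design = recovery_design(seed, n_reads)
    genomes = generate_genomes(specs)
    reads, truth = simulate_reads(design, genomes)
    trimmed, stats = trim_dataset(reads)
    aln = annotate_alignments(
        simulate_alignments(truth, trimmed, genomes, members=design.members,
                            seed=seed + 1)
    )
    best = best_hits(aln)
    manifest = manifest_from_specs(specs)
    profiles = build_profiles(best, manifest, contig_table_from_fasta(genomes))
    return presence_table(profiles, manifest, design.sample_id,
                          stats.n_reads_out)


def host_depletion_community(seed: int, n_reads: int = 20_000):
    specs = [GenomeSpec("m1", "Microbe unus", "Microbus", "ClassX",
                        (60_000,), seed=7)]
    host_specs = [GenomeSpec("plantA", "Plantus hostus", "Plantus",
                             "Viridiplantae", (80_000, 40_000), seed=8)]
    design = CommunityDesign(
        sample_id="hostbench",
        members=[Member("m1", 0.75, divergence=0.03)],
        host_fraction=0.15, unclassified_fraction=0.10,
        n_reads=n_reads, seed=seed, host_divergence=0.02,
    )
    return specs, host_specs, design


def run_host_depletion(seed: int, n_reads: int = 20_000) -> dict:
    """Deplete the benchmark sample; score against the truth table."""
    specs, host_specs, design = host_depletion_community(seed, n_reads)
    genomes = generate_genomes(specs)
    host = generate_genomes(host_specs)
    reads, truth = simulate_reads(design, genomes, host)
    aln = annotate_alignments(
        simulate_alignments(truth, reads, genomes, host, design.members,
                            seed=seed + 1)
    )
    host_aln = aln[aln["genome_id"].isin(host)]
    result = deplete_host(reads, host_aln)
    host_ids = set(truth.loc[truth["origin"] == "host", "read_id"])
    kept_ids = {r.read_id for r in result.kept}
    removed_ids = {r.read_id for r in reads} - kept_ids
    tp = len(removed_ids & host_ids)
    return {
        "n_reads": len(reads),
        "n_removed": result.n_removed,
        "removed_fraction": result.n_removed / len(reads),
        "sensitivity": tp / len(host_ids) if host_ids else float("nan"),
        "specificity": len(kept_ids - host_ids) / (len(reads) - len(host_ids)),
        "planted_host_fraction": len(host_ids) / len(reads),
    }
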