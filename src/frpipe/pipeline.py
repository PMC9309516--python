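"""Stage orchestration with provenance records.

``run_pipeline`` executes the stages of the reference-based species-calling
workflow in dependency order over a working directory laid out as::

    workdir/
      raw/<sample>.fastq            sequencer output (or synthetic)
      trimmed/<sample>.fastq        after quality trimming
      depleted/<sample>.fastq       after host-read removal
      db/manifest.tsv, contigs.tsv  recruitment database tables
      recruit/<sample>.best.tsv     per-read best hits
      calls/<sample>.presence.tsv   presence-call tables
      stats/…                       diversity / ordination outputs
      figures/…                     recruitment + composition plots

Each executed stage appends a provenance record (stage, config hash, input
digests, outputs) to ``workdir/provenance.json``. Deterministic stages are
byte-identical across reruns with the same inputs and seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .host import deplete_host
from .io import (
    read_alignments, read_fastq, read_manifest, write_fastq,
)
from .metrics import distance_matrix, diversity_table, pca, permanova
from .qc import trim_fastq
from .recruitment import best_hits, build_profiles, presence_table
from .report import frp_points, render_frp

STAGES = [
    "simulate", "trim", "deplete", "build-db", "recruit", "call",
    "diversity", "ordinate", "report",
]

#: which earlier stage produces each stage's input, for error messages.
_UPSTREAM = {
    "trim": ("raw", "simulate"),
    "deplete": ("trimmed", "trim"),
    "recruit": ("depleted", "deplete"),
    "call": ("recruit", "recruit"),
    "diversity": ("calls", "recruit/call"),
    "ordinate": ("calls", "recruit/call"),
    "report": ("calls", "recruit/call"),
}


class MissingStageInput(RuntimeError):
    def __init__(self, stage: str, path: Path, producer: str):
        super().__init__(
            f"stage {stage!r}: missing input {path}; run stage {producer!r} first"
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]


def _record(workdir: Path, stage: str, config: PipelineConfig,
            inputs: list[Path], outputs: list[Path]) -> None:
    prov_path = workdir / "provenance.json"
    records = json.loads(prov_path.read_text()) if prov_path.exists() else []
    records.append({
        "stage": stage,
        "version": __version__,
        "config_hash": _config_hash(config),
        "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
        "outputs": [str(p) for p in outputs],
    })
    prov_path.write_text(json.dumps(records, indent=1))


def _require(stage: str, path: Path) -> Path:
    if not path.exists():
        subdir, producer = _UPSTREAM.get(stage, ("?", "?"))
        raise MissingStageInput(stage, path, producer)
    return path


def _samples(workdir: Path, subdir: str) -> list[str]:
    return sorted(p.stem for p in (workdir / subdir).glob("*.fastq"))


def run_pipeline(
    config: PipelineConfig, workdir: str | Path, stages: list[str] | None = None
) -> dict[str, list[str]]:
    """Run the requested stages (default: all but ``simulate``).

    Returns a manifest of output paths per stage. The ``simulate`` stage is
    driven separately (see :mod:`frpipe.synthetic`) because it defines the
    inputs rather than consuming them; including it here runs the bundled
    demo community.
    """
    workdir = Path(workdir)
    stages = stages or [s for s in STAGES if s != "simulate"]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}; choose from {STAGES}")
    stages = [s for s in STAGES if s in stages]  # dependency order
    outputs: dict[str, list[str]] = {}
    for stage in stages:
        outputs[stage] = [str(p) for p in _run_stage(stage, config, workdir)]
    return outputs


def _run_stage(stage: str, config: PipelineConfig, workdir: Path) -> list[Path]:
    fn = {
        "simulate": _stage_simulate,
        "trim": _stage_trim,
        "deplete": _stage_deplete,
        "build-db": _stage_build_db,
        "recruit": _stage_recruit,
        "call": _stage_call,
        "diversity": _stage_diversity,
        "ordinate": _stage_ordinate,
        "report": _stage_report,
    }[stage]
    return fn(config, workdir)


# ---------------------------------------------------------------------------
# stages

def demo_specs():
    """The bundled demo community: a small mixed bacterial/fungal panel."""
    from .synthetic import CommunityDesign, GenomeSpec, Member

    specs = [
        GenomeSpec("ent_dem", "Enterobacter demoensis", "Enterobacter",
                   "Gammaproteobacteria", (60_000, 40_000), seed=11),
        GenomeSpec("pan_dem", "Pantoea demoensis", "Pantoea",
                   "Gammaproteobacteria", (80_000,), seed=12),
        GenomeSpec("leu_dem", "Leuconostoc demoensis", "Leuconostoc",
                   "Firmicutes", (50_000, 30_000), seed=13),
        GenomeSpec("art_dem", "Curtobacterium artifactum", "Curtobacterium",
                   "Actinobacteria", (70_000,), seed=14),
        GenomeSpec("dec_dem", "Pantoea decoyensis", "Pantoea",
                   "Gammaproteobacteria", (80_000,), seed=15),
    ]
    host = [GenomeSpec("host_dem", "Hostus plantus", "Hostus", "Viridiplantae",
                       (120_000,), seed=16)]
    design = CommunityDesign(
        sample_id="demo",
        members=[
            Member("ent_dem", 0.30, divergence=0.02, sister_id="dec_dem",
                   sister_extra_divergence=0.15),
            Member("pan_dem", 0.25, divergence=0.04),
            Member("leu_dem", 0.15, divergence=0.00),
            Member("art_dem", 0.10, divergence=0.01,
                   coverage_mode="single-region", region=3),
        ],
        host_fraction=0.10,
        unclassified_fraction=0.10,
        n_reads=20_000,
        seed=101,
    )
    return specs, host, design


def _stage_simulate(config: PipelineConfig, workdir: Path) -> list[Path]:
    from .synthetic import write_community

    specs, host, design = demo_specs()
    raw = workdir / "raw"
    paths = write_community(raw, specs, design, host)
    # the demo writes database tables straight into db/
    db = workdir / "db"
    db.mkdir(parents=True, exist_ok=True)
    for key in ("manifest", "contigs"):
        (db / paths[key].name).write_bytes(paths[key].read_bytes())
    out = list(paths.values()) + [db / "manifest.tsv", db / "contigs.tsv"]
    _record(workdir, "simulate", config, [], out)
    return out


def _stage_trim(config: PipelineConfig, workdir: Path) -> list[Path]:
    out_dir = workdir / "trimmed"
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs, rows = [], []
    raw_dir = workdir / "raw"
    _require("trim", raw_dir)
    for sample in _samples(workdir, "raw"):
        src = raw_dir / f"{sample}.fastq"
        dst = out_dir / f"{sample}.fastq"
        stats = trim_fastq(
            src, dst, window=config.trim_window, step=config.trim_step,
            min_mean_q=config.trim_min_mean_q, min_end_q=config.trim_min_end_q,
            min_len=config.trim_min_len,
        )
        rows.append({"Sample": sample, **stats.as_row()})
        outputs.append(dst)
        _record(workdir, "trim", config, [src], [dst])
    stats_path = out_dir / "trim_stats.tsv"
    pd.DataFrame(rows).to_csv(stats_path, sep="\t", index=False)
    outputs.append(stats_path)
    return outputs


def _stage_deplete(config: PipelineConfig, workdir: Path) -> list[Path]:
    out_dir = workdir / "depleted"
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs, rows = [], []
    for sample in _samples(workdir, "trimmed"):
        src = _require("deplete", workdir / "trimmed" / f"{sample}.fastq")
        aln_path = _require(
            "deplete", workdir / "raw" / f"{sample}.host_alignments.tsv"
        )
        host_aln = read_alignments(aln_path)
        result = deplete_host(
            read_fastq(src), host_aln,
            min_identity=config.host_min_identity,
            min_coverage=config.host_min_coverage,
        )
        dst = out_dir / f"{sample}.fastq"
        write_fastq(result.kept, dst)
        row = {"Sample": sample,
               "Number of MSRs aligned to plant genomes": result.n_removed}
        row.update({f"removed_{g}": n for g, n in result.per_genome_removed.items()})
        rows.append(row)
        outputs.append(dst)
        _record(workdir, "deplete", config, [src, aln_path], [dst])
    stats_path = out_dir / "depletion_stats.tsv"
    pd.DataFrame(rows).to_csv(stats_path, sep="\t", index=False)
    outputs.append(stats_path)
    return outputs


def _stage_build_db(config: PipelineConfig, workdir: Path) -> list[Path]:
    # database tables are produced by simulate (demo) or supplied by the
    # user; this stage validates them.
    db = workdir / "db"
    manifest_path = db / "manifest.tsv"
    if not manifest_path.exists():
        raise MissingStageInput("build-db", manifest_path, "simulate")
    read_manifest(manifest_path)
    _record(workdir, "build-db", config, [manifest_path], [manifest_path])
    return [manifest_path]


def _stage_recruit(config: PipelineConfig, workdir: Path) -> list[Path]:
    out_dir = workdir / "recruit"
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = []
    for sample in _samples(workdir, "depleted"):
        kept = _require("recruit", workdir / "depleted" / f"{sample}.fastq")
        aln_path = _require("recruit", workdir / "raw" / f"{sample}.alignments.tsv")
        aln = read_alignments(aln_path)
        kept_ids = {r.read_id for r in read_fastq(kept)}
        aln = aln[aln["qseqid"].isin(kept_ids)]
        best = best_hits(
            aln, min_identity=config.recruit_min_identity,
            min_coverage=config.recruit_min_coverage,
        )
        dst = out_dir / f"{sample}.best.tsv"
        best.to_csv(dst, sep="\t", index=False)
        outputs.append(dst)
        _record(workdir, "recruit", config, [kept, aln_path], [dst])
    return outputs


def _denominator(config: PipelineConfig, workdir: Path, sample: str) -> int:
    subdir = "trimmed" if config.abundance_denominator == "trimmed" else "depleted"
    path = _require("call", workdir / subdir / f"{sample}.fastq")
    return sum(1 for _ in read_fastq(path))


def _stage_call(config: PipelineConfig, workdir: Path) -> list[Path]:
    out_dir = workdir / "calls"
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(_require("call", workdir / "db" / "manifest.tsv"))
    contig_table = pd.read_csv(workdir / "db" / "contigs.tsv", sep="\t")
    outputs = []
    for best_path in sorted((workdir / "recruit").glob("*.best.tsv")):
        sample = best_path.name.removesuffix(".best.tsv")
        best = pd.read_csv(best_path, sep="\t")
        profiles = build_profiles(best, manifest, contig_table)
        total = _denominator(config, workdir, sample)
        table = presence_table(
            profiles, manifest, sample, total,
            min_reads=config.presence_min_reads, max_rsd=config.presence_max_rsd,
        )
        dst = out_dir / f"{sample}.presence.tsv"
        table.to_csv(dst, sep="\t", index=False)
        outputs.append(dst)
        _record(workdir, "call", config, [best_path], [dst])
    if not outputs:
        raise MissingStageInput("call", workdir / "recruit", "recruit")
    return outputs


def _abundance_matrix(workdir: Path) -> pd.DataFrame:
    frames = []
    for path in sorted((workdir / "calls").glob("*.presence.tsv")):
        frames.append(pd.read_csv(path, sep="\t"))
    if not frames:
        raise MissingStageInput("diversity", workdir / "calls", "recruit/call")
    calls = pd.concat(frames)
    wide = calls.pivot_table(index="sample_id", columns="species",
                             values="relative_abundance", fill_value=0.0)
    return wide


def _stage_diversity(config: PipelineConfig, workdir: Path) -> list[Path]:
    out_dir = workdir / "stats"
    out_dir.mkdir(parents=True, exist_ok=True)
    wide = _abundance_matrix(workdir)
    div_path = out_dir / "diversity.tsv"
    diversity_table(wide).to_csv(div_path, sep="\t", index=False)
    outputs = [div_path]
    if len(wide) >= 3:
        dm = distance_matrix(wide)
        res = permanova(dm, wide.index.str[:2], config.n_permutations, config.seed)
        pm_path = out_dir / "permanova.tsv"
        pd.DataFrame([{
            "pseudo_F": res.pseudo_F, "p_value": res.p_value,
            "n_permutations": res.n_permutations, "seed": res.seed,
        }]).to_csv(pm_path, sep="\t", index=False)
        outputs.append(pm_path)
    _record(workdir, "diversity", config, [], outputs)
    return outputs


def _stage_ordinate(config: PipelineConfig, workdir: Path) -> list[Path]:
    out_dir = workdir / "stats"
    out_dir.mkdir(parents=True, exist_ok=True)
    wide = _abundance_matrix(workdir)
    try:
        result = pca(wide, min_abundance=config.pca_min_abundance)
    except ValueError as exc:
        note = out_dir / "pca_skipped.txt"
        note.write_text(f"PCA skipped: {exc}\n")
        _record(workdir, "ordinate", config, [], [note])
        return [note]
    scores_path = out_dir / "pca_scores.tsv"
    loadings_path = out_dir / "pca_loadings.tsv"
    result.scores.to_csv(scores_path, sep="\t")
    result.loadings.to_csv(loadings_path, sep="\t")
    var_path = out_dir / "pca_variance.tsv"
    pd.DataFrame({
        "component": [f"PC{i+1}" for i in range(len(result.variance_explained))],
        "variance_explained": result.variance_explained,
    }).to_csv(var_path, sep="\t", index=False)
    outputs = [scores_path, loadings_path, var_path]
    _record(workdir, "ordinate", config, [], outputs)
    return outputs


def _stage_report(config: PipelineConfig, workdir: Path) -> list[Path]:
    out_dir = workdir / "figures"
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(_require("report", workdir / "db" / "manifest.tsv"))
    contig_table = pd.read_csv(workdir / "db" / "contigs.tsv", sep="\t")
    lengths = dict(zip(manifest["genome_id"], manifest["total_length"]))
    outputs = []
    for best_path in sorted((workdir / "recruit").glob("*.best.tsv")):
        sample = best_path.name.removesuffix(".best.tsv")
        best = pd.read_csv(best_path, sep="\t")
        profiles = build_profiles(best, manifest, contig_table)
        for genome_id, prof in profiles.items():
            pts = frp_points(best, genome_id, contig_table)
            res = render_frp(
                prof, pts, int(lengths[genome_id]),
                out_dir / f"{sample}.{genome_id}.frp.png",
            )
            outputs.extend(res.values())
    _record(workdir, "report", config, [], outputs)
    return outputs
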