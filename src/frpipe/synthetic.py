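"""Seeded synthetic communities: genomes, reads, truth and alignment tables.

The generator fabricates everything the pipeline consumes so that each
stage can be tested end to end without downloads: multi-contig reference
genomes with i.i.d. uniform base composition; shotgun reads drawn from
community members at a configured divergence (substitutions only, so the
alignment identity of a read is analytically 100·(L−m)/L for m planted
substitutions); host-plant contamination reads; "random" reads with no
source (emulating the no-hit fraction); Phred quality strings with a high
5' plateau and a linear 3' decay; and the matching best-hit alignment
table, optionally with decoy secondary hits against a designated sister
genome at extra divergence.

Base-call errors implied by the quality profile are off by default
(``error_rate = 0``); when enabled they substitute extra bases and are
absorbed into the truth table's substitution count, so recomputing identity
from the truth always reproduces the emitted alignment identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    OUTFMT6_COLUMNS, ReadRecord, write_alignments, write_fasta, write_fastq,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

TRUTH_COLUMNS = [
    "read_id", "origin", "source_contig", "source_start", "read_length",
    "n_substitutions",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Blueprint for one toy reference genome."""

    genome_id: str
    species: str
    genus: str
    taxon_class: str
    contig_lengths: tuple[int, ...]
    seed: int
    group_label: str = ""

    @property
    def total_length(self) -> int:
        return int(sum(self.contig_lengths))


@dataclass(frozen=True)
class Member:
    """One community member: which genome, how many reads, how divergent."""

    genome_id: str
    fraction: float
    divergence: float = 0.0          # substitutions per base vs. the reference
    coverage_mode: str = "uniform"   # "uniform" | "single-region"
    region: int = 0                  # which genome tenth for single-region
    sister_id: str | None = None     # decoy genome receiving secondary hits
    sister_extra_divergence: float = 0.05


@dataclass
class CommunityDesign:
    """Recipe for one sample's read set."""

    sample_id: str
    members: list[Member]
    n_reads: int
    seed: int
    host_fraction: float = 0.0
    unclassified_fraction: float = 0.0
    host_divergence: float = 0.02
    read_length_mean: int = 200
    read_length_sd: float = 20.0
    min_read_length: int = 60
    # two-segment Phred profile: plateau, then linear decay to the 3' end
    q_plateau: int = 32
    q_end: int = 22
    plateau_frac: float = 0.6
    q_jitter: float = 2.0
    error_rate: float = 0.0  # base-call substitution rate on top of divergence

    def __post_init__(self) -> None:
        total = sum(m.fraction for m in self.members)
        total += self.host_fraction + self.unclassified_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"design fractions sum to {total!r}, expected 1")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        for m in self.members:
            if not 0.0 <= m.divergence <= 0.4:
                raise ValueError(f"divergence {m.divergence} outside [0, 0.4]")
            if m.coverage_mode not in ("uniform", "single-region"):
                raise ValueError(f"unknown coverage_mode {m.coverage_mode!r}")


Genomes = dict[str, list[tuple[str, str]]]  # genome_id -> [(contig_id, seq)]


def generate_genome(spec: GenomeSpec) -> list[tuple[str, str]]:
    """Deterministic uniform-composition contigs for one genome spec."""
    if any(length <= 0 for length in spec.contig_lengths):
        raise ValueError(f"{spec.genome_id}: contig lengths must be positive")
    rng = np.random.default_rng(spec.seed)
    contigs = []
    for i, length in enumerate(spec.contig_lengths):
        seq = _BASES[rng.integers(0, 4, int(length))].tobytes().decode()
        contigs.append((f"{spec.genome_id}|c{i + 1}", seq))
    return contigs


def generate_genomes(specs: list[GenomeSpec]) -> Genomes:
    return {s.genome_id: generate_genome(s) for s in specs}


def manifest_from_specs(specs: list[GenomeSpec], source: str = "selected") -> pd.DataFrame:
    rows = [
        {
            "genome_id": s.genome_id, "species": s.species, "genus": s.genus,
            "taxon_class": s.taxon_class,
            "group_label": s.group_label or s.taxon_class,
            "total_length": s.total_length, "source": source,
        }
        for s in specs
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# read simulation

def _quality_string(length: int, design: CommunityDesign, rng) -> np.ndarray:
    plateau_len = int(round(design.plateau_frac * length))
    q = np.full(length, float(design.q_plateau))
    tail = length - plateau_len
    if tail > 0:
        q[plateau_len:] = np.linspace(design.q_plateau, design.q_end, tail)
    if design.q_jitter > 0:
        q += rng.normal(0.0, design.q_jitter, length)
    return np.clip(np.rint(q), 2, 41).astype(np.int64)


def _mutate(seq: np.ndarray, rate: float, rng) -> np.ndarray:
    """Substitute bases i.i.d. at ``rate``; always to a different base."""
    if rate <= 0:
        return seq
    hit = rng.random(seq.size) < rate
    n = int(hit.sum())
    if n == 0:
        return seq
    out = seq.copy()
    shift = rng.integers(1, 4, n)
    codes = np.searchsorted(_BASES, out[hit])
    out[hit] = _BASES[(codes + shift) % 4]
    return out


def _draw_position(contigs, length, rng, mode="uniform", region=0):
    """Pick (contig index, start) for a read of ``length`` bases.

    Uniform mode samples a start over the whole concatenated axis (contigs
    weighted by length). Single-region mode confines starts to one genome
    tenth of the concatenated axis; reads are clamped to the containing
    contig, so they never straddle contigs.
    """
    lengths = np.array([len(seq) for _, seq in contigs])
    offsets = np.concatenate(([0], np.cumsum(lengths)))
    total = int(offsets[-1])
    if mode == "single-region":
        width = total // 10
        lo, hi = region * width, (region + 1) * width
        pos = int(rng.integers(lo, max(lo + 1, hi - length)))
    else:
        pos = int(rng.integers(0, total))
    ci = int(np.searchsorted(offsets, pos, side="right") - 1)
    start = pos - int(offsets[ci])
    # clamp to contig end; shorten only if the contig itself is short
    start = max(0, min(start, int(lengths[ci]) - length))
    if start < 0:
        start = 0
    return ci, start


def simulate_reads(
    design: CommunityDesign, genomes: Genomes, host_genomes: Genomes | None = None
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Draw the sample's reads and the matching truth table.

    Returns (reads, truth) where truth has one row per read: origin
    (member genome_id, "host" or "random"), 0-based source coordinates and
    the exact substitution count separating the read from its source.
    """
    host_genomes = host_genomes or {}
    for m in design.members:
        if m.genome_id not in genomes:
            raise ValueError(f"member genome {m.genome_id!r} not provided")
    if design.host_fraction > 0 and not host_genomes:
        raise ValueError("host_fraction > 0 but no host genomes provided")

    rng = np.random.default_rng(design.seed)
    fractions = [m.fraction for m in design.members]
    fractions += [design.host_fraction, design.unclassified_fraction]
    counts = rng.multinomial(design.n_reads, np.asarray(fractions))

    host_list = list(host_genomes.items())
    host_weights = None
    if host_list:
        w = np.array([sum(len(s) for _, s in contigs) for _, contigs in host_list], float)
        host_weights = w / w.sum()

    reads: list[ReadRecord] = []
    truth_rows = []
    serial = 0

    def next_id() -> str:
        nonlocal serial
        rid = f"{design.sample_id}_r{serial:07d}"
        serial += 1
        return rid

    def emit(origin: str, contigs, divergence: float, mode="uniform", region=0):
        length = int(np.clip(
            rng.normal(design.read_length_mean, design.read_length_sd),
            design.min_read_length, None,
        ))
        ci, start = _draw_position(contigs, length, rng, mode, region)
        contig_id, seq = contigs[ci]
        length = min(length, len(seq) - start)
        source = np.frombuffer(seq[start : start + length].encode(), dtype="S1")
        mutated = _mutate(source, divergence, rng)
        if design.error_rate > 0:
            mutated = _mutate(mutated, design.error_rate, rng)
        n_subs = int((mutated != source).sum())
        rid = next_id()
        reads.append(ReadRecord(rid, mutated.tobytes().decode(),
                                _quality_string(length, design, rng)))
        truth_rows.append({
            "read_id": rid, "origin": origin, "source_contig": contig_id,
            "source_start": start, "read_length": length,
            "n_substitutions": n_subs,
        })

    for member, n in zip(design.members, counts[: len(design.members)]):
        contigs = genomes[member.genome_id]
        for _ in range(int(n)):
            emit(member.genome_id, contigs, member.divergence,
                 member.coverage_mode, member.region)

    for _ in range(int(counts[len(design.members)])):  # host reads
        hi = int(rng.choice(len(host_list), p=host_weights))
        emit("host", host_list[hi][1], design.host_divergence)

    for _ in range(int(counts[-1])):  # unclassified: no planted source
        length = int(np.clip(
            rng.normal(design.read_length_mean, design.read_length_sd),
            design.min_read_length, None,
        ))
        seq = _BASES[rng.integers(0, 4, length)].tobytes().decode()
        rid = next_id()
        reads.append(ReadRecord(rid, seq, _quality_string(length, design, rng)))
        truth_rows.append({
            "read_id": rid, "origin": "random", "source_contig": "",
            "source_start": -1, "read_length": length, "n_substitutions": 0,
        })

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return reads, truth


# ---------------------------------------------------------------------------
# alignment simulation

def _bitscore(length: int, mismatches: int) -> float:
    return max(0.0, 2.0 * (length - mismatches) - 3.0 * mismatches)


def simulate_alignments(
    truth: pd.DataFrame,
    reads: list[ReadRecord],
    genomes: Genomes,
    host_genomes: Genomes | None = None,
    members: list[Member] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit the extended outfmt-6 table implied by the truth table.

    Every genome- or host-origin read gets one primary record against its
    true source interval with identity 100·(L−m)/L; members with a
    ``sister_id`` also yield one decoy secondary record against the sister
    genome at extra divergence, always scoring below the primary. Random
    reads yield nothing.
    """
    host_genomes = host_genomes or {}
    members = members or []
    sister_of = {m.genome_id: m for m in members if m.sister_id}
    truth_by_id = truth.set_index("read_id")
    missing = [r.read_id for r in reads if r.read_id not in truth_by_id.index]
    if missing:
        raise ValueError(f"reads without truth rows: {missing[:3]}")

    rng = np.random.default_rng(seed)
    rows = []
    for read in reads:
        t = truth_by_id.loc[read.read_id]
        origin = t["origin"]
        if origin == "random":
            continue
        length = int(t["read_length"])
        m = int(t["n_substitutions"])
        pident = round(100.0 * (length - m) / length, 2)
        sstart = int(t["source_start"]) + 1
        rows.append({
            "qseqid": read.read_id, "sseqid": t["source_contig"],
            "pident": pident, "length": length, "mismatch": m, "gapopen": 0,
            "qstart": 1, "qend": length, "sstart": sstart,
            "send": sstart + length - 1, "evalue": 1e-30,
            "bitscore": _bitscore(length, m), "qlen": length,
        })
        member = sister_of.get(origin)
        if member is not None:
            sister_contigs = genomes.get(member.sister_id) or host_genomes.get(
                member.sister_id
            )
            if sister_contigs is None:
                raise ValueError(f"sister genome {member.sister_id!r} not provided")
            extra = int(rng.binomial(length - m, member.sister_extra_divergence))
            m2 = m + extra
            ci, start = _draw_position(sister_contigs, length, rng)
            contig_id, seq = sister_contigs[ci]
            length2 = min(length, len(seq) - start)
            rows.append({
                "qseqid": read.read_id, "sseqid": contig_id,
                "pident": round(100.0 * (length2 - m2) / length2, 2),
                "length": length2, "mismatch": m2, "gapopen": 0,
                "qstart": 1, "qend": length2, "sstart": start + 1,
                "send": start + length2, "evalue": 1e-10,
                "bitscore": _bitscore(length2, m2), "qlen": length,
            })
    return pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)


# ---------------------------------------------------------------------------
# on-disk bundle

def write_community(
    out_dir: str | Path,
    specs: list[GenomeSpec],
    design: CommunityDesign,
    host_specs: list[GenomeSpec] | None = None,
) -> dict[str, Path]:
    """Materialise a full synthetic sample under ``out_dir``.

    Writes genome FASTAs, the manifest + contig tables, the sample FASTQ,
    the truth TSV, and microbial/host alignment TSVs; returns the paths.
    """
    from .io import annotate_alignments, contig_table_from_fasta, write_manifest

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes = generate_genomes(specs)
    host_genomes = generate_genomes(host_specs or [])

    paths: dict[str, Path] = {}
    paths["genomes_fasta"] = out / "genomes.fasta"
    write_fasta([c for contigs in genomes.values() for c in contigs],
                paths["genomes_fasta"])
    if host_genomes:
        paths["host_fasta"] = out / "host_genomes.fasta"
        write_fasta([c for contigs in host_genomes.values() for c in contigs],
                    paths["host_fasta"])

    manifest = manifest_from_specs(specs)
    paths["manifest"] = out / "manifest.tsv"
    write_manifest(manifest, paths["manifest"])
    contig_table = contig_table_from_fasta(genomes)
    paths["contigs"] = out / "contigs.tsv"
    contig_table.to_csv(paths["contigs"], sep="\t", index=False)

    reads, truth = simulate_reads(design, genomes, host_genomes)
    paths["fastq"] = out / f"{design.sample_id}.fastq"
    write_fastq(reads, paths["fastq"])
    paths["truth"] = out / f"{design.sample_id}.truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)

    aln = simulate_alignments(truth, reads, genomes, host_genomes,
                              design.members, seed=design.seed + 1)
    micro_mask = aln["sseqid"].str.partition("|")[0].isin(genomes.keys())
    paths["alignments"] = out / f"{design.sample_id}.alignments.tsv"
    write_alignments(aln[micro_mask], paths["alignments"])
    paths["host_alignments"] = out / f"{design.sample_id}.host_alignments.tsv"
    write_alignments(aln[~micro_mask], paths["host_alignments"])
    return paths
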