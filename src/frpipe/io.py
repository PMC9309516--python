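"""File formats shared by the pipeline stages.

Reads and genomes travel as FASTQ/FASTA (Biopython); read-vs-genome
alignments travel as BLAST tabular (outfmt 6) TSV extended with a ``qlen``
column, so query coverage can be computed without the reads at hand.
Subject sequence ids follow the ``<genome_id>|<contig>`` convention, which
lets a single alignment table span a multi-genome database.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: column order of the extended BLAST tabular dialect used throughout.
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qlen",
]

MANIFEST_COLUMNS = [
    "genome_id", "species", "genus", "taxon_class", "group_label",
    "total_length", "source",
]


@dataclass
class ReadRecord:
    """One sequencing read: bases plus per-base Phred scores."""

    read_id: str
    bases: str
    qualities: np.ndarray  # integer Phred scores, same length as bases

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int64)
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-vs-genome local alignment (a row of the outfmt-6 table)."""

    read_id: str
    genome_id: str
    percent_identity: float
    alignment_length: int
    query_length: int
    subject_contig: str
    subject_start: int  # 1-based inclusive
    subject_end: int
    bit_score: float
    e_value: float

    @property
    def query_coverage(self) -> float:
        return min(100.0, 100.0 * self.alignment_length / self.query_length)


def split_subject_id(sseqid: str) -> tuple[str, str]:
    """Split ``genome|contig`` subject ids; bare ids map to themselves."""
    genome, _, contig = sseqid.partition("|")
    return genome, contig or sseqid


# ---------------------------------------------------------------------------
# FASTQ / FASTA

def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a Phred+33 FASTQ file."""
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        try:
            quals = rec.letter_annotations["phred_quality"]
        except KeyError as exc:  # pragma: no cover - SeqIO always sets it
            raise ValueError(f"FASTQ record {i} has no quality string") from exc
        yield ReadRecord(rec.id, str(rec.seq), np.asarray(quals))


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            rec = SeqRecord(Seq(r.bases), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = [int(q) for q in r.qualities]
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n


def write_fasta(contigs: Iterable[tuple[str, str]], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for cid, seq in contigs:
            SeqIO.write(SeqRecord(Seq(seq), id=cid, description=""), fh, "fasta")
            n += 1
    return n


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# Tabular

def read_alignments(path: str | Path) -> pd.DataFrame:
    """Load an extended outfmt-6 TSV, adding genome_id/contig/qcov columns."""
    df = pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS, comment="#")
    return annotate_alignments(df)


def annotate_alignments(df: pd.DataFrame) -> pd.DataFrame:
    """Derive genome_id, subject_contig and query coverage from raw columns."""
    df = df.copy()
    if df.empty:
        df["genome_id"] = pd.Series(dtype=str)
        df["subject_contig"] = pd.Series(dtype=str)
        df["qcov"] = pd.Series(dtype=float)
        return df
    parts = df["sseqid"].str.partition("|")
    df["genome_id"] = parts[0]
    df["subject_contig"] = df["sseqid"]
    df["qcov"] = np.minimum(100.0, 100.0 * df["length"] / df["qlen"])
    return df


def write_alignments(df: pd.DataFrame, path: str | Path) -> None:
    df[OUTFMT6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["genome_id"].duplicated().any():
        dupes = df.loc[df["genome_id"].duplicated(), "genome_id"].tolist()
        raise ValueError(f"duplicate genome_id in manifest: {dupes}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def contig_table_from_fasta(fastas: dict[str, list[tuple[str, str]]]) -> pd.DataFrame:
    """Build the (genome_id, contig_id, length) table, preserving file order.

    Contig order defines the concatenated [0, L) coordinate axis used for
    recruitment-plot sections, so it must be deterministic.
    """
    rows = []
    for genome_id, contigs in fastas.items():
        for cid, seq in contigs:
            rows.append({"genome_id": genome_id, "contig_id": cid, "length": len(seq)})
    return pd.DataFrame(rows, columns=["genome_id", "contig_id", "length"])


def contig_offsets(contig_table: pd.DataFrame) -> pd.DataFrame:
    """Add the concatenated-axis start offset of every contig."""
    df = contig_table.copy()
    df["offset"] = df.groupby("genome_id", sort=False)["length"].cumsum() - df["length"]
    return df
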