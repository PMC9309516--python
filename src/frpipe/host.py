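"""Host (plant) read depletion.

Surface-swab metagenomes of fruits and flowers carry reads from the host
plant itself. Before recruiting reads to microbial genomes, any read with at
least one alignment to a host genome at >= ``min_identity`` percent identity
and >= ``min_coverage`` percent query coverage is removed. Both thresholds
are inclusive. Several proxy host genomes may be supplied at once (e.g. two
related species standing in for an unsequenced host); a hit to any of them
removes the read, and removals are also tallied per host genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .io import ReadRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 60.0
DEFAULT_MIN_COVERAGE = 60.0


@dataclass
class DepletionResult:
    kept: list[ReadRecord]
    n_removed: int
    per_genome_removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def deplete_host(
    reads: Iterable[ReadRecord],
    host_alignments: pd.DataFrame,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> DepletionResult:
    """Partition reads into kept vs host-removed using alignment evidence.

    ``host_alignments`` is an annotated outfmt-6 frame (see
    :func:`frpipe.io.annotate_alignments`); alignments referencing reads not
    present in the input are logged and skipped.
    """
    reads = list(reads)
    read_ids = {r.read_id for r in reads}

    hits = host_alignments[
        (host_alignments["pident"] >= min_identity)
        & (host_alignments["qcov"] >= min_coverage)
    ]
    unknown = set(hits["qseqid"]) - read_ids
    if unknown:
        logger.warning(
            "%d host alignments reference unknown reads (e.g. %s); skipped",
            len(unknown), sorted(unknown)[:3],
        )
        hits = hits[hits["qseqid"].isin(read_ids)]

    removed_ids = set(hits["qseqid"])
    # A read aligning to several host genomes counts once per genome.
    per_genome = (
        hits.drop_duplicates(["qseqid", "genome_id"])
        .groupby("genome_id")["qseqid"].size().to_dict()
    )
    kept = [r for r in reads if r.read_id not in removed_ids]
    return DepletionResult(kept, len(removed_ids), per_genome)
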