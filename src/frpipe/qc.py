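"""Sliding-window quality trimming.

A read is scanned 5'→3' in windows of ``window`` bases advancing by ``step``
bases; it is truncated at the start of the first window whose mean Phred
score falls below ``min_mean_q``. A final partial window (fewer than
``window`` bases) is evaluated over the bases it covers, so a short
low-quality tail cannot hide behind the window size. Both ends are then
trimmed while the terminal base quality is below ``min_end_q``, and reads
shorter than ``min_len`` after trimming are dropped. Reads surviving this
procedure are the pipeline's working unit (quality-trimmed metagenomic
sequence reads, MSRs).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .io import ReadRecord, read_fastq, write_fastq

DEFAULT_WINDOW = 10
DEFAULT_STEP = 4
DEFAULT_MIN_MEAN_Q = 20
DEFAULT_MIN_END_Q = 20
DEFAULT_MIN_LEN = 50


@dataclass
class TrimStats:
    """Dataset-level trimming tallies."""

    n_reads_in: int = 0
    n_bases_in: int = 0
    n_reads_out: int = 0
    n_bases_out: int = 0

    def as_row(self) -> dict:
        return {
            "Total number of MSRs": self.n_reads_in,
            "Total number of bases": self.n_bases_in,
            "Total number of MSRs after trimming": self.n_reads_out,
            "Total number of bases after trimming": self.n_bases_out,
        }


def trim_read(
    read: ReadRecord,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_mean_q: float = DEFAULT_MIN_MEAN_Q,
    min_end_q: float = DEFAULT_MIN_END_Q,
    min_len: int = DEFAULT_MIN_LEN,
) -> ReadRecord | None:
    """Trim one read; returns None when the read is dropped."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if len(read) == 0:
        return None
    q = read.qualities

    # 1) window scan from the 5' end; truncate at the first failing window.
    end = len(q)
    for start in range(0, len(q), step):
        win = q[start : start + window]
        if win.size and win.mean() < min_mean_q:
            end = start
            break

    # 2) trim low-quality bases inward from both ends.
    lo, hi = 0, end
    while lo < hi and q[lo] < min_end_q:
        lo += 1
    while hi > lo and q[hi - 1] < min_end_q:
        hi -= 1

    if hi - lo < min_len:
        return None
    return ReadRecord(read.read_id, read.bases[lo:hi], q[lo:hi])


def trim_reads(
    reads: Iterable[ReadRecord], stats: TrimStats | None = None, **params
) -> Iterator[ReadRecord]:
    """Lazily trim a read stream, tallying into ``stats`` if given."""
    for read in reads:
        if stats is not None:
            stats.n_reads_in += 1
            stats.n_bases_in += len(read)
        out = trim_read(read, **params)
        if out is not None:
            if stats is not None:
                stats.n_reads_out += 1
                stats.n_bases_out += len(out)
            yield out


def trim_dataset(reads: Iterable[ReadRecord], **params) -> tuple[list[ReadRecord], TrimStats]:
    stats = TrimStats()
    out = list(trim_reads(reads, stats, **params))
    return out, stats


def trim_fastq(in_path: str | Path, out_path: str | Path, **params) -> TrimStats:
    """Trim a FASTQ file on disk, streaming record by record."""
    stats = TrimStats()
    write_fastq(trim_reads(read_fastq(in_path), stats, **params), out_path)
    return stats
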