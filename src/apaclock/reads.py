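"""Quality filtering and 5' poly(T) trimming of raw 3'-end tag reads.

WTTS-seq reads begin with the reverse complement of the poly(A) tail, so
a run of Ts (often interrupted by sequencing errors) precedes the genomic
sequence.  Reads are (1) kept only if at least ``min_fraction_at_quality``
of their bases reach ``min_quality``, (2) stripped of the 5' T-rich
prefix, and (3) kept only if at least ``min_length_after_trim`` bases
remain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import io as aio


@dataclass(frozen=True)
class ReadRecord:
    """A sequenced 3'-end read."""

    read_id: str
    seq: str
    quals: tuple[int, ...]
    sample_id: str = ""

    def __post_init__(self):
        if len(self.seq) != len(self.quals):
            raise ValueError(
                f"{self.read_id}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadFilterConfig:
    min_quality: int = 10
    min_fraction_at_quality: float = 0.5
    min_length_after_trim: int = 16
    t_window: int = 10
    t_fraction: float = 0.8

    def __post_init__(self):
        if not 0 < self.min_fraction_at_quality <= 1:
            raise ValueError("min_fraction_at_quality must be in (0, 1]")
        if self.min_length_after_trim < 1:
            raise ValueError("min_length_after_trim must be >= 1")
        if not 0 < self.t_fraction <= 1:
            raise ValueError("t_fraction must be in (0, 1]")


def quality_filter(read: ReadRecord, cfg: ReadFilterConfig = ReadFilterConfig()) -> bool:
    """Keep a read iff >= min_fraction_at_quality of bases score >= min_quality.

    Both comparisons are boundary-inclusive.  Empty reads are dropped.
    """
    n = len(read)
    if n == 0:
        return False
    good = sum(1 for q in read.quals if q >= cfg.min_quality)
    return good / n >= cfg.min_fraction_at_quality


def _trim_once(seq: str, cfg: ReadFilterConfig) -> int:
    """One pass of the trimming rule; returns the number of bases to cut.

    (a) removes a leading run of Ts, then (b) removes successive full
    t_window-sized windows whose T fraction >= t_fraction, stopping at the
    first window below threshold.
    """
    i = 0
    n = len(seq)
    while i < n and seq[i] == "T":
        i += 1
    while i + cfg.t_window <= n:
        window = seq[i:i + cfg.t_window]
        if window.count("T") / cfg.t_window >= cfg.t_fraction:
            i += cfg.t_window
        else:
            break
    return i


def trim_polyT_5prime(read: ReadRecord, cfg: ReadFilterConfig = ReadFilterConfig()) -> ReadRecord:
    """Remove the maximal 5' T / T-rich prefix.

    The run-then-window rule is iterated to a fixed point (window removal
    can expose a fresh leading T-run), which makes the operation
    idempotent.  Qualities are trimmed in lockstep.  A read that is
    entirely T-rich comes back empty and is caught by the length filter.
    """
    seq, quals = read.seq, read.quals
    while seq:
        cut = _trim_once(seq, cfg)
        if cut == 0:
            break
        seq, quals = seq[cut:], quals[cut:]
    return ReadRecord(read.read_id, seq, tuple(quals), read.sample_id)


def length_filter(read: ReadRecord, cfg: ReadFilterConfig = ReadFilterConfig()) -> bool:
    """Keep iff the trimmed read is at least min_length_after_trim bases."""
    return len(read) >= cfg.min_length_after_trim


@dataclass
class TrimStats:
    total: int = 0
    kept: int = 0
    dropped_quality: int = 0
    dropped_length: int = 0
    kept_ids: set[str] = field(default_factory=set)

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "kept": self.kept,
            "dropped_quality": self.dropped_quality,
            "dropped_length": self.dropped_length,
        }


def process_fastq(
    in_path: str | Path,
    out_path: str | Path,
    cfg: ReadFilterConfig = ReadFilterConfig(),
    sample_id: str = "",
    collect_ids: bool = False,
) -> TrimStats:
    """Filter + trim a FASTQ file; returns per-reason drop counts.

    Conservation: total == kept + dropped_quality + dropped_length.
    With ``collect_ids`` the surviving read ids are gathered in
    ``stats.kept_ids`` (used downstream to subset alignments).
    """
    stats = TrimStats()

    def _records():
        for rid, seq, qual in aio.read_fastq(in_path):
            stats.total += 1
            read = ReadRecord(rid, seq, tuple(aio.phred_to_scores(qual)), sample_id)
            if not quality_filter(read, cfg):
                stats.dropped_quality += 1
                continue
            trimmed = trim_polyT_5prime(read, cfg)
            if not length_filter(trimmed, cfg):
                stats.dropped_length += 1
                continue
            stats.kept += 1
            if collect_ids:
                stats.kept_ids.add(trimmed.read_id)
            yield (
                trimmed.read_id,
                trimmed.seq,
                "".join(chr(q + 33) for q in trimmed.quals),
            )

    aio.write_fastq(_records(), out_path)
    return stats


def kept_read_ids(
    in_path: str | Path, cfg: ReadFilterConfig = ReadFilterConfig()
) -> set[str]:
    """Ids of reads that survive quality, trim and length filters."""
    kept: set[str] = set()
    for rid, seq, qual in aio.read_fastq(in_path):
        read = ReadRecord(rid, seq, tuple(aio.phred_to_scores(qual)))
        if not quality_filter(read, cfg):
            continue
        if length_filter(trim_polyT_5prime(read, cfg), cfg):
            kept.add(rid)
    return kept
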