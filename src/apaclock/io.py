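"""Shared format readers and writers.

All genomic coordinates are held internally 1-based closed (SAM/GTF
convention).  BED input/output converts to and from 0-based half-open at
this boundary and nowhere else.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

DESIGN_COLUMNS = ["sample_id", "group", "zt_h", "replicate"]


@dataclass(frozen=True)
class DesignRow:
    sample_id: str
    group: str
    zt_h: float
    replicate: int


class DesignTable:
    """Sample sheet: one row per library.

    ``group`` labels the experimental condition (ZT2..ZT22, R0..R8,
    ZT8ctrl); ``zt_h`` is the zeitgeber time of tissue collection and
    ``replicate`` indexes the biological replicate within the group.
    (group, replicate) pairs must be unique.
    """

    def __init__(self, rows: Iterable[DesignRow]):
        self.rows = list(rows)
        seen = set()
        for r in self.rows:
            key = (r.group, r.replicate)
            if key in seen:
                raise ValueError(f"duplicate (group, replicate): {key}")
            seen.add(key)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.rows]

    def groups(self) -> dict[str, list[DesignRow]]:
        out: dict[str, list[DesignRow]] = {}
        for r in self.rows:
            out.setdefault(r.group, []).append(r)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.sample_id, r.group, r.zt_h, r.replicate) for r in self.rows],
            columns=DESIGN_COLUMNS,
        )

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other) -> bool:
        return isinstance(other, DesignTable) and self.rows == other.rows


def read_design(path: str | Path) -> DesignTable:
    df = pd.read_csv(path, sep="\t")
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return DesignTable(
        DesignRow(str(r.sample_id), str(r.group), float(r.zt_h), int(r.replicate))
        for r in df.itertuples()
    )


def write_design(design: DesignTable, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read id, sequence, quality string) from a Phred+33 FASTQ."""
    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def phred_to_scores(qual: str) -> list[int]:
    return [ord(c) - 33 for c in qual]


# ---------------------------------------------------------------------------
# BED6


BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED6; returns the raw 0-based half-open frame."""
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS,
                     dtype={"chrom": str, "name": str, "strand": str})
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        i = int(bad.idxmax())
        raise ValueError(f"{path}: line {i + 1}: strand must be + or -")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=BED_COLUMNS)


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT gene-set collection.

    Returns {term_id: (description, genes)}.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT needs >= 3 fields")
            term, desc, genes = parts[0], parts[1], parts[2:]
            sets[term] = (desc, frozenset(g for g in genes if g))
    return sets


# ---------------------------------------------------------------------------
# Config / provenance


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def stamp(path: str | Path, config: dict, seed: int | None = None) -> None:
    """Write a provenance side-car (<path>.prov.json) for an output file."""
    prov = {"config_hash": config_hash(config), "seed": seed}
    Path(str(path) + ".prov.json").write_text(json.dumps(prov) + "\n")
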