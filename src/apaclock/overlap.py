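"""Cross-reference of significant APA genes with APA-linked brain-disorder
susceptibility genes.

A curated table (one row per disorder-linked PAS, grouped into 24 h
cycling, 12 h cycling and differentially expressed categories) is loaded
and counted: unique genes per category, unique genes overall, and unique
PAS ids overall (a PAS listed under two categories counts once).
Matching of pipeline hits against the disorder gene list is by
case-insensitive symbol equality (rat/human orthography).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

CATEGORIES = ("cycle24", "cycle12", "de")

DISORDER_CODES = frozenset(
    {"ALS", "ADHD", "ASD", "ANX", "BIP", "DEP", "MDD", "SCZ", "PTSD",
     "PD", "AD"}
)
# published tables carry occasional orthography slips; normalize them
_CODE_ALIASES = {"SZC": "SCZ"}

_DISORDER_RE = re.compile(r"([A-Za-z]+)\s*\((\d+)\)")


@dataclass(frozen=True)
class DisorderEntry:
    category: str
    pas_id: int
    symbol: str
    disorders: tuple[tuple[str, int], ...]
    pass_per_gene: int
    is_major_pas: bool
    stats: tuple[float, ...] = ()
    comparison: str = ""

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def parse_disorders(text: str, lineno: int = 0) -> tuple[tuple[str, int], ...]:
    """Parse a 'SCZ(2), BIP(1)' style association list.

    Accepts comma- or period-separated entries and normalizes known
    orthography variants; an unknown code raises with the line number.
    """
    text = (text or "").strip()
    if not text:
        return ()
    out = []
    matched_spans = []
    for m in _DISORDER_RE.finditer(text):
        code = m.group(1).upper()
        code = _CODE_ALIASES.get(code, code)
        if code not in DISORDER_CODES:
            raise ValueError(
                f"line {lineno}: unknown disorder code {m.group(1)!r}"
            )
        out.append((code, int(m.group(2))))
        matched_spans.append(m.span())
    leftovers = _DISORDER_RE.sub("", text)
    if re.search(r"[A-Za-z0-9]", leftovers.replace(",", "").replace(".", "")
                 .replace(" ", "")):
        raise ValueError(f"line {lineno}: malformed disorders field {text!r}")
    return tuple(out)


def load_disorder_table(path: str | Path | None = None) -> list[DisorderEntry]:
    """Load a disorder-gene TSV; defaults to the packaged fixture.

    Expected columns: category, pas_id, symbol, disorders, pass_per_gene,
    major_pas, stat_a, stat_b, stat_c, comparison.  Duplicate
    (category, pas_id) pairs are a validation error.
    """
    if path is None:
        path = resources.files("apaclock.data") / "disorder_genes.tsv"
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    entries: list[DisorderEntry] = []
    seen: set[tuple[str, int]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pas_id = int(str(row.pas_id).replace(",", ""))
        key = (row.category, pas_id)
        if key in seen:
            raise ValueError(f"line {i}: duplicate (category, pas_id) {key}")
        seen.add(key)
        stats = tuple(
            float(v) for v in (row.stat_a, row.stat_b, row.stat_c) if v != ""
        )
        entries.append(
            DisorderEntry(
                category=row.category,
                pas_id=pas_id,
                symbol=row.symbol,
                disorders=parse_disorders(row.disorders, i),
                pass_per_gene=int(row.pass_per_gene),
                is_major_pas=row.major_pas.strip().lower() in ("1", "yes", "mpas"),
                stats=stats,
                comparison=getattr(row, "comparison", ""),
            )
        )
    return entries


@dataclass(frozen=True)
class OverlapSummary:
    per_category_apas: dict
    per_category_genes: dict
    total_unique_genes: int
    total_unique_pas: int


def overlap_counts(entries: Sequence[DisorderEntry]) -> OverlapSummary:
    """Category-wise APA-row and unique-gene counts, plus overall uniques.

    Gene symbols deduplicate within a category and (case-insensitively)
    across categories; PAS ids deduplicate across categories, so a site
    listed under both periods counts once overall.
    """
    apas: dict[str, int] = {c: 0 for c in CATEGORIES}
    genes: dict[str, set] = {c: set() for c in CATEGORIES}
    all_genes: set[str] = set()
    all_pas: set[int] = set()
    for e in entries:
        apas[e.category] += 1
        genes[e.category].add(e.symbol.upper())
        all_genes.add(e.symbol.upper())
        all_pas.add(e.pas_id)
    return OverlapSummary(
        per_category_apas=apas,
        per_category_genes={c: len(g) for c, g in genes.items()},
        total_unique_genes=len(all_genes),
        total_unique_pas=len(all_pas),
    )


def match_significant(
    sig_tables: Mapping[str, pd.DataFrame],
    pac_meta: pd.DataFrame,
    disorder_entries: Sequence[DisorderEntry],
) -> pd.DataFrame:
    """Intersect significant PAS tables with the disorder gene list.

    ``sig_tables`` maps a category label (cycle24/cycle12/de) to a table
    indexed by pas_id whose rows are the significant calls;
    ``pac_meta`` supplies gene_symbol per pas_id.  Matching is by
    uppercased symbol.  Returns a disorder-table-shaped frame.
    """
    by_symbol: dict[str, list[DisorderEntry]] = {}
    for e in disorder_entries:
        by_symbol.setdefault(e.symbol.upper(), []).append(e)
    rows = []
    for category, table in sig_tables.items():
        for pas_id in table.index:
            if pas_id not in pac_meta.index:
                continue
            symbol = str(pac_meta.loc[pas_id, "gene_symbol"])
            hits = by_symbol.get(symbol.upper(), [])
            if not hits:
                continue
            disorders = sorted(
                {d for e in hits for d in e.disorders}
            )
            rows.append(
                (category, pas_id, symbol,
                 ", ".join(f"{c}({n})" for c, n in disorders),
                 int(pac_meta.loc[pas_id].get("apas_per_gene", 0)))
            )
    return pd.DataFrame(
        rows,
        columns=["category", "pas_id", "symbol", "disorders", "pass_per_gene"],
    )
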