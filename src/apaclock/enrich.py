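"""Hypergeometric over-representation analysis (ORA) of APA gene sets.

Input gene sets (diurnal, ultradian, per-comparison DE — each restricted
to genes carrying >= 2 poly(A) sites) are tested against GMT gene-set
collections.  The universe is the reference genes annotated to at least
one term in the collection; ``expect`` is the overlap expected by
chance and ``ratio`` = overlap / expect, as over-representation tools
conventionally report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .rhythm import bh_adjust


@dataclass(frozen=True)
class OraConfig:
    min_term_size: int = 10
    max_term_size: int = 500
    fdr_threshold: float = 0.05


def ora(
    input_genes: set[str],
    reference_genes: set[str],
    gene_sets: Mapping[str, tuple[str, frozenset[str]]],
    cfg: OraConfig = OraConfig(),
    database: str = "",
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of one gene set.

    The universe is the intersection of ``reference_genes`` with genes
    annotated to >= 1 term; the input is intersected with the universe.
    p = P(X >= overlap) for X ~ Hypergeom(universe, term size, draws);
    FDR is BH across tested terms.  Terms outside the configured size
    bounds (after universe intersection) are skipped.
    """
    annotated = set()
    for _, genes in gene_sets.values():
        annotated |= genes
    universe = reference_genes & annotated
    draws = input_genes & universe
    n_u, n_d = len(universe), len(draws)
    rows = []
    for term, (desc, genes) in gene_sets.items():
        size = len(genes & universe)
        if size == 0 or not (cfg.min_term_size <= size <= cfg.max_term_size):
            continue
        overlap = len(genes & draws)
        expect = size * n_d / n_u
        ratio = overlap / expect if expect > 0 else 0.0
        p = float(stats.hypergeom.sf(overlap - 1, n_u, size, n_d))
        rows.append((term, desc, size, overlap, expect, ratio, p, database))
    out = pd.DataFrame(
        rows,
        columns=["term_id", "description", "size", "overlap", "expect",
                 "ratio", "p", "database"],
    )
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out


def significant_terms(result: pd.DataFrame,
                      cfg: OraConfig = OraConfig()) -> pd.DataFrame:
    return result[result["fdr"] <= cfg.fdr_threshold]


# ---------------------------------------------------------------------------
# Input-set construction


def build_input_sets(
    pac_meta: pd.DataFrame,
    rhythm24: pd.DataFrame | None = None,
    rhythm12: pd.DataFrame | None = None,
    de_tables: Mapping[str, pd.DataFrame] | None = None,
    phase_groups: Mapping[float, Sequence] | None = None,
    sig_p: float = 0.01,
    sig_lfc: float = 0.5,
) -> dict[str, set[str]]:
    """Named gene-symbol sets for ORA.

    Every set keeps only genes with >= 2 poly(A) sites (the APA rule) and
    deduplicates symbols.  ``pac_meta`` supplies gene_symbol and
    apas_per_gene per pas_id; rhythm tables supply the all-trials
    significance flag; DE tables the raw p and shrunken log2FC
    (|log2FC| applied two-sided).
    """
    multi = pac_meta[
        (pac_meta["apas_per_gene"] >= 2)
        & (pac_meta["gene_symbol"] != "intergenic")
    ]

    def genes_of(pas_ids) -> set[str]:
        ids = [p for p in pas_ids if p in multi.index]
        return set(multi.loc[ids, "gene_symbol"])

    sets: dict[str, set[str]] = {}
    if rhythm24 is not None:
        sets["diurnal"] = genes_of(rhythm24.index[rhythm24["significant"]])
    if rhythm12 is not None:
        sets["ultradian"] = genes_of(rhythm12.index[rhythm12["significant"]])
    if de_tables:
        for name, tab in de_tables.items():
            sig = tab[(tab["p"] < sig_p)
                      & (tab["log2fc_shrunken"].abs() > sig_lfc)]
            sets[f"de_{name}"] = genes_of(sig.index)
    if phase_groups:
        for center, pas_ids in phase_groups.items():
            sets[f"phase_ZT{center:g}"] = genes_of(pas_ids)
    for name, s in sets.items():
        if not s:
            warnings.warn(f"input set '{name}' is empty; ORA will be skipped")
    return sets
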