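"""Small reporting utilities over published summary numbers."""

from __future__ import annotations

from importlib import resources

import pandas as pd

# Headline tallies of the source sequencing study: total PAS clusters and
# how many were diurnal (24 h), ultradian (12 h) or sleep-deprivation DE.
STUDY_COUNTS = {
    "total_pacs": 31_757,
    "diurnal": 2_011,
    "ultradian": 1_502,
    "de": 831,
}


def printed_fraction(part: int, total: int) -> int:
    """Percentage of ``part`` in ``total``, rounded to the nearest integer."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * part / total)


def study_fractions(counts: dict[str, int] = STUDY_COUNTS) -> dict[str, int]:
    """Rounded percentages of diurnal/ultradian/DE clusters among all PACs."""
    total = counts["total_pacs"]
    return {
        k: printed_fraction(v, total)
        for k, v in counts.items()
        if k != "total_pacs"
    }


def load_published_enrichment() -> pd.DataFrame:
    """Packaged enrichment table with printed size/overlap/expect/ratio."""
    path = resources.files("apaclock.data") / "published_enrichment.tsv"
    return pd.read_csv(path, sep="\t")


def ratio_identity(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute ratio = overlap / expect and report the printed deviation."""
    out = table.copy()
    out["ratio_recomputed"] = out["overlap"] / out["expect"]
    out["ratio_error"] = (out["ratio_recomputed"] - out["ratio"]).abs()
    return out
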