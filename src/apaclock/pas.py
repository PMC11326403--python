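"""Poly(A)-site calling: 3'-end tag extraction, 25-nt clustering,
library-size-aware filtering, gene annotation and per-10^7 normalization.

A *tag* is a uniquely mapped read reduced to its 3'-most aligned genomic
base (rightmost for + strand, leftmost for -).  Tags within 25 nt of one
another (single-linkage chaining per chromosome and strand) form one
polyadenylation site cluster (PAC) whose *peak* is the modal endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from . import io as aio

# Region classes of the APA taxonomy: sites can fall in an internal exon,
# an intron, just past an internal exon, within / at the terminus of /
# distal to the longest documented 3'UTR, or outside any gene.
REGION_INTERNAL_EXON = "internal_exon"
REGION_INTRON = "intron"
REGION_POST_EXON = "post_exon"
REGION_UTR3_INTERNAL = "utr3_internal"
REGION_UTR3_TERMINAL = "utr3_terminal"
REGION_UTR3_DISTAL = "utr3_distal"
REGION_INTERGENIC = "intergenic"

REGION_CLASSES = (
    REGION_INTERNAL_EXON,
    REGION_INTRON,
    REGION_POST_EXON,
    REGION_UTR3_INTERNAL,
    REGION_UTR3_TERMINAL,
    REGION_UTR3_DISTAL,
    REGION_INTERGENIC,
)

DEFAULT_MITO_CHROMS = frozenset({"chrM", "MT", "chrMT", "M"})

TAG_COLUMNS = ["chrom", "strand", "end3", "sample_id"]


@dataclass(frozen=True)
class PacFilterConfig:
    """Library-size-aware PAC retention rule.

    A sample's read threshold is ``min_reads_small_lib`` when its library
    has fewer than ``libsize_threshold`` covered reads, otherwise
    ``min_reads_large_lib`` (a library of exactly the threshold counts as
    large).  A cluster is retained iff at least one replicate group has
    >= ``min_samples`` samples meeting their thresholds.
    """

    libsize_threshold: int = 1_700_000
    min_samples: int = 3
    min_reads_small_lib: int = 3
    min_reads_large_lib: int = 4
    group_size: int = 5

    def __post_init__(self):
        if self.min_samples > self.group_size:
            raise ValueError("min_samples must be <= group_size")


@dataclass(frozen=True)
class GeneAnnot:
    """Annotation of one gene: span, exons and the documented 3' end."""

    gene_id: str
    chrom: str
    strand: str
    start: int          # 1-based closed genomic span
    end: int
    exons: tuple[tuple[int, int], ...]   # 1-based closed, genomically sorted
    utr3_start: int     # first base of the longest documented 3'UTR
    tx_end3: int        # annotated transcript 3' terminus (strand-aware)


@dataclass
class PacSet:
    """Clustered poly(A) sites: interval metadata plus count matrices.

    ``meta`` is indexed by pas_id with columns chrom, strand, start, end,
    peak (and after annotation: gene_symbol, region_class, apas_per_gene).
    ``counts_raw`` / ``counts_norm`` share that index; columns are samples.
    """

    meta: pd.DataFrame
    counts_raw: pd.DataFrame
    counts_norm: pd.DataFrame | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.counts_raw.columns)

    def __len__(self) -> int:
        return len(self.meta)

    def subset(self, pas_ids) -> "PacSet":
        return PacSet(
            self.meta.loc[pas_ids].copy(),
            self.counts_raw.loc[pas_ids].copy(),
            None if self.counts_norm is None else self.counts_norm.loc[pas_ids].copy(),
        )

    def to_tsv(self, path: str | Path) -> None:
        parts = [self.meta, self.counts_raw.add_prefix("raw_")]
        if self.counts_norm is not None:
            parts.append(self.counts_norm.add_prefix("norm_"))
        out = pd.concat(parts, axis=1)
        out.index.name = "pas_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PacSet":
        df = pd.read_csv(path, sep="\t", index_col="pas_id")
        raw_cols = [c for c in df.columns if c.startswith("raw_")]
        norm_cols = [c for c in df.columns if c.startswith("norm_")]
        meta = df[[c for c in df.columns if c not in raw_cols + norm_cols]].copy()
        raw = df[raw_cols].rename(columns=lambda c: c[4:])
        norm = df[norm_cols].rename(columns=lambda c: c[5:]) if norm_cols else None
        return cls(meta, raw, norm)


# ---------------------------------------------------------------------------
# Tag extraction


def extract_tags_sam(
    path: str | Path, sample_id: str, uniquely_mapped_only: bool = True
) -> pd.DataFrame:
    """Extract 3'-end tags from a SAM file (header required).

    Unmapped, secondary and supplementary records are skipped.  With
    ``uniquely_mapped_only``, records with NH > 1 or MAPQ == 0 are dropped
    as multi-mappers.
    """
    rows = []
    skipped = {"unmapped": 0, "secondary": 0, "supplementary": 0, "multi": 0}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                skipped["unmapped"] += 1
                continue
            if rec.is_secondary:
                skipped["secondary"] += 1
                continue
            if rec.is_supplementary:
                skipped["supplementary"] += 1
                continue
            if uniquely_mapped_only:
                nh = rec.get_tag("NH") if rec.has_tag("NH") else 1
                if nh > 1 or rec.mapping_quality == 0:
                    skipped["multi"] += 1
                    continue
            strand = "-" if rec.is_reverse else "+"
            # pysam: reference_start 0-based, reference_end exclusive
            end3 = rec.reference_end if strand == "+" else rec.reference_start + 1
            rows.append((rec.reference_name, strand, int(end3), sample_id))
    df = pd.DataFrame(rows, columns=TAG_COLUMNS)
    df.attrs["skipped"] = skipped
    return df


def extract_tags_bed(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """Extract 3'-end tags from BED6 alignment spans.

    The 3' end is the interval's right edge for + strand records and the
    left edge for -; BED 0-based half-open converts to 1-based here.  The
    sample is taken from ``sample_id`` or, if None, from the prefix of the
    name field (``sample:...``).
    """
    bed = aio.read_bed(path)
    end3 = np.where(bed["strand"] == "+", bed["end"], bed["start"] + 1)
    if sample_id is None:
        sample = bed["name"].str.split(":", n=1).str[0]
    else:
        sample = sample_id
    return pd.DataFrame(
        {"chrom": bed["chrom"], "strand": bed["strand"],
         "end3": end3.astype(int), "sample_id": sample}
    )


def extract_tags(path: str | Path, sample_id: str, **kw) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".sam":
        return extract_tags_sam(path, sample_id, **kw)
    if path.suffix == ".bed":
        return extract_tags_bed(path, sample_id)
    raise ValueError(f"unsupported alignment format: {path.suffix}")


def library_sizes(tags: pd.DataFrame) -> dict[str, int]:
    """Covered-read total per sample."""
    return tags.groupby("sample_id").size().to_dict()


# ---------------------------------------------------------------------------
# Clustering


def cluster_pas(tags: pd.DataFrame, window: int = 25,
                samples: Sequence[str] | None = None) -> PacSet:
    """Single-linkage chaining of tag endpoints within ``window`` nt.

    Adjacent distinct endpoints <= window apart join one cluster (so a
    cluster may span more than ``window`` nt); adjacent clusters are
    separated by > window.  The peak is the modal endpoint; ties go to
    the 3'-most endpoint in transcription order (+: rightmost,
    -: leftmost).  Per-sample counts preserve tag multiplicity.
    """
    if samples is None:
        samples = sorted(tags["sample_id"].unique()) if len(tags) else []
    samples = list(samples)
    meta_rows = []
    count_rows = []
    if len(tags):
        grouped = tags.groupby(["chrom", "strand"], sort=True)
        for (chrom, strand), sub in grouped:
            counts = (
                sub.groupby(["end3", "sample_id"]).size().unstack(fill_value=0)
                .reindex(columns=samples, fill_value=0)
            )
            pos = counts.index.to_numpy()           # sorted unique endpoints
            breaks = np.flatnonzero(np.diff(pos) > window)
            cluster_id = np.zeros(len(pos), dtype=int)
            cluster_id[breaks + 1] = 1
            cluster_id = np.cumsum(cluster_id)
            totals = counts.sum(axis=1).to_numpy()
            for cid in range(cluster_id[-1] + 1):
                m = cluster_id == cid
                cpos, ctot = pos[m], totals[m]
                best = ctot == ctot.max()
                cand = cpos[best]
                peak = int(cand.max() if strand == "+" else cand.min())
                meta_rows.append(
                    (chrom, strand, int(cpos.min()), int(cpos.max()), peak)
                )
                count_rows.append(counts.loc[m].sum(axis=0).to_numpy())
    meta = pd.DataFrame(
        meta_rows, columns=["chrom", "strand", "start", "end", "peak"]
    )
    raw = pd.DataFrame(
        np.array(count_rows, dtype=int).reshape(len(meta), len(samples)),
        columns=samples,
    )
    # stable pas_id ordering by genomic position
    order = meta.sort_values(["chrom", "strand", "start"]).index
    meta = meta.loc[order].reset_index(drop=True)
    raw = raw.loc[order].reset_index(drop=True)
    meta.index.name = "pas_id"
    raw.index.name = "pas_id"
    return PacSet(meta, raw)


# ---------------------------------------------------------------------------
# Filtering


def filter_pacs(
    pacs: PacSet,
    library_sizes: Mapping[str, int],
    groups: Mapping[str, str],
    cfg: PacFilterConfig = PacFilterConfig(),
) -> PacSet:
    """Retain clusters supported in at least one replicate group.

    Per sample the read threshold depends on its own library size; a
    cluster is kept iff some condition group contains >= ``min_samples``
    samples at or above their thresholds.
    """
    samples = pacs.samples
    for s in samples:
        if s not in library_sizes:
            raise ValueError(f"no library size for sample {s}")
        if s not in groups:
            raise ValueError(f"sample {s} has no group assignment")
    thresholds = np.array(
        [
            cfg.min_reads_small_lib
            if library_sizes[s] < cfg.libsize_threshold
            else cfg.min_reads_large_lib
            for s in samples
        ]
    )
    qualifies = pacs.counts_raw.to_numpy() >= thresholds[None, :]
    group_labels = np.array([groups[s] for s in samples])
    keep = np.zeros(len(pacs), dtype=bool)
    for g in np.unique(group_labels):
        cols = group_labels == g
        keep |= qualifies[:, cols].sum(axis=1) >= cfg.min_samples
    kept_ids = pacs.meta.index[keep]
    return pacs.subset(kept_ids)


# ---------------------------------------------------------------------------
# Annotation


def _classify_peak(peak: int, gene: GeneAnnot, terminal_tol: int,
                   post_exon_tol: int) -> str:
    """Region class of a peak known to be assigned to ``gene``."""
    sign = 1 if gene.strand == "+" else -1
    # transcription-direction offset from the annotated 3' terminus:
    # positive = downstream of the gene
    past_end = sign * (peak - gene.tx_end3)
    if abs(past_end) <= terminal_tol:
        return REGION_UTR3_TERMINAL
    if past_end > 0:
        return REGION_UTR3_DISTAL
    # within the gene body; is it inside the longest documented 3'UTR?
    in_utr3 = sign * (peak - gene.utr3_start) >= 0
    if in_utr3:
        return REGION_UTR3_INTERNAL
    for (s, e) in gene.exons:
        if s <= peak <= e:
            return REGION_INTERNAL_EXON
    # intronic: just past an internal exon's 3' edge counts as post_exon
    for (s, e) in gene.exons:
        exon_3end = e if gene.strand == "+" else s
        offset = sign * (peak - exon_3end)
        if 0 < offset <= post_exon_tol:
            return REGION_POST_EXON
    return REGION_INTRON


def annotate_pacs(
    pacs: PacSet,
    genes: Sequence[GeneAnnot],
    extension: int = 5000,
    terminal_tol: int = 25,
    post_exon_tol: int = 25,
) -> PacSet:
    """Assign gene symbol, region class and APAs-per-gene to each cluster.

    A peak inside a same-strand gene span (or within ``extension`` nt
    downstream of its annotated 3' end) is assigned to that gene; when
    several genes qualify the one with the nearest 3' terminus wins.
    """
    by_chrom: dict[tuple[str, str], list[GeneAnnot]] = {}
    for g in genes:
        by_chrom.setdefault((g.chrom, g.strand), []).append(g)

    symbols, classes = [], []
    for pas_id, row in pacs.meta.iterrows():
        peak = int(row["peak"])
        cands = []
        for g in by_chrom.get((row["chrom"], row["strand"]), []):
            lo, hi = g.start, g.end
            if g.strand == "+":
                hi = max(hi, g.tx_end3 + extension)
            else:
                lo = min(lo, g.tx_end3 - extension)
            if lo <= peak <= hi:
                cands.append(g)
        if not cands:
            symbols.append(REGION_INTERGENIC)
            classes.append(REGION_INTERGENIC)
            continue
        gene = min(cands, key=lambda g: abs(peak - g.tx_end3))
        symbols.append(gene.gene_id)
        classes.append(_classify_peak(peak, gene, terminal_tol, post_exon_tol))

    meta = pacs.meta.copy()
    meta["gene_symbol"] = symbols
    meta["region_class"] = classes
    genic = meta["gene_symbol"] != REGION_INTERGENIC
    per_gene = meta.loc[genic].groupby("gene_symbol").size()
    meta["apas_per_gene"] = (
        meta["gene_symbol"].map(per_gene).fillna(0).astype(int)
    )
    return PacSet(meta, pacs.counts_raw.copy(),
                  None if pacs.counts_norm is None else pacs.counts_norm.copy())


def apa_spectrum(pacs: PacSet) -> tuple[pd.Series, float, float]:
    """Histogram of genic clusters by APAs-per-gene, plus >=2 / >=3 fractions.

    Returns (cluster counts per APA bin, fraction of genic clusters in
    genes with >= 2 APAs, fraction in genes with >= 3).
    """
    meta = pacs.meta
    genic = meta[meta["gene_symbol"] != REGION_INTERGENIC]
    hist = genic.groupby("apas_per_gene").size().sort_index()
    n = len(genic)
    if n == 0:
        return hist, 0.0, 0.0
    frac2 = float(genic["apas_per_gene"].ge(2).sum()) / n
    frac3 = float(genic["apas_per_gene"].ge(3).sum()) / n
    return hist, frac2, frac3


# ---------------------------------------------------------------------------
# Normalization


def normalize(
    pacs: PacSet,
    drop_mito: bool = True,
    mito_chroms: frozenset[str] = DEFAULT_MITO_CHROMS,
) -> PacSet:
    """Tags-per-10^7 normalization after mitochondrial cluster removal.

    Mitochondrial clusters are removed first and excluded from the
    denominators; each library column of ``counts_norm`` then sums to
    10^7.
    """
    meta, raw = pacs.meta, pacs.counts_raw
    if drop_mito:
        keep = ~meta["chrom"].isin(mito_chroms)
        meta, raw = meta.loc[keep].copy(), raw.loc[keep].copy()
    totals = raw.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"libraries with zero retained reads: {list(zero.index)}"
        )
    norm = raw / totals * 1e7
    return PacSet(meta, raw, norm)


# ---------------------------------------------------------------------------
# GTF annotation input


def read_gtf(path: str | Path) -> list[GeneAnnot]:
    """Read gene models from GTF (1-based closed, gene_id attributes).

    The documented 3' terminus is the most-3' transcript end; the 3'UTR
    begins one base past the most-3' CDS end.  Genes without CDS features
    get utr3_start = tx_end3 (no UTR distinguishable).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = sorted(
            (f.start, f.end) for f in db.children(g, featuretype="exon")
        )
        if not exons:
            exons = [(g.start, g.end)]
        cds = [(f.start, f.end) for f in db.children(g, featuretype="CDS")]
        if g.strand == "+":
            tx_end3 = max(e for _, e in exons)
            utr3_start = max(e for _, e in cds) + 1 if cds else tx_end3
        else:
            tx_end3 = min(s for s, _ in exons)
            utr3_start = min(s for s, _ in cds) - 1 if cds else tx_end3
        genes.append(
            GeneAnnot(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start,
                end=g.end,
                exons=tuple(exons),
                utr3_start=utr3_start,
                tx_end3=tx_end3,
            )
        )
    return genes
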