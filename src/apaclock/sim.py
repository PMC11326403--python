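"""Synthetic WTTS-seq study generator.

Emulates the study design the pipeline expects — 6 diurnal timepoints
(ZT2..ZT22, every 4 h) x 5 replicates, four sleep-deprivation recovery
groups (R0/R2/R4/R8) x 5 and a ZT8 undisturbed control x 5, 55 libraries
in all — over a small self-contained genome with known poly(A) sites,
rhythm parameters and sleep-deprivation effects, so that every
downstream stage can be tested against planted truth.

Counts are negative binomial with variance mu + phi*mu^2.  A rhythmic
site's expected count at collection time t is
``baseline * (1 + amplitude_rel * cos(2*pi*(t - phase_h)/period_h))``;
a differentially expressed site multiplies its baseline by
``2**de_log2fc`` in the treatment group only.  Reads carry a 5' T-stretch
artifact and a configurable fraction of quality-check failures; truth
alignments are emitted as BED so that alignment itself stays out of the
loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as aio
from . import pas as apas

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class SimGeneModel:
    """A synthetic gene with its planted poly(A) sites.

    ``pas_sites`` are (genomic coordinate, region class, baseline
    expression in expected tags/library), sorted 5'->3' in transcription
    order.  ``exons`` are half-open genomic intervals.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    pas_sites: tuple[tuple[int, str, float], ...]
    apa_count: int
    utr3_start: int = 0   # genomic coord of the first 3'UTR base
    tx_end3: int = 0      # annotated transcript 3' terminus

    def __post_init__(self):
        if self.apa_count != len(self.pas_sites) or self.apa_count < 1:
            raise ValueError("apa_count must equal |pas_sites| >= 1")


@dataclass(frozen=True)
class SimSignal:
    """Planted behaviour of one PAS: null, rhythmic or DE."""

    gene_id: str
    site_index: int
    kind: str = "null"               # null | rhythmic | de
    period_h: float | None = None
    phase_h: float = 0.0
    amplitude_rel: float = 0.0
    de_comparison: str | None = None  # treatment group label, e.g. "R0"
    de_log2fc: float = 0.0
    dispersion: float = 0.05

    def __post_init__(self):
        if self.kind == "rhythmic" and self.period_h is None:
            raise ValueError("rhythmic signal needs period_h")
        if self.kind == "de" and self.de_comparison is None:
            raise ValueError("de signal needs de_comparison")
        if self.kind == "null" and (self.amplitude_rel or self.de_log2fc):
            raise ValueError("null signal must have zero amplitude and lfc")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


@dataclass(frozen=True)
class SimDesign:
    """Study layout; the default reproduces the 55-library design."""

    diurnal_timepoints_h: tuple[float, ...] = (2, 6, 10, 14, 18, 22)
    sd_groups: tuple[tuple[str, float], ...] = (
        ("R0", 6.0), ("R2", 8.0), ("R4", 10.0), ("R8", 14.0)
    )
    control_groups: tuple[tuple[str, float], ...] = (("ZT8", 8.0),)
    replicates: int = 5
    reads_per_library: int = 50_000
    seed: int = 0

    def design_table(self) -> aio.DesignTable:
        rows = []
        for t in self.diurnal_timepoints_h:
            for r in range(1, self.replicates + 1):
                g = f"ZT{int(t)}"
                rows.append(aio.DesignRow(f"{g}_r{r}", g, float(t), r))
        for g, t in self.sd_groups + self.control_groups:
            for r in range(1, self.replicates + 1):
                rows.append(aio.DesignRow(f"{g}_r{r}", g, float(t), r))
        return aio.DesignTable(rows)


# Gene-level APA-count mixture: P(gene has k = 1..10 poly(A) sites).
DEFAULT_APA_MIXTURE = (
    0.55, 0.22, 0.10, 0.05, 0.03, 0.02, 0.01, 0.01, 0.005, 0.005
)


@dataclass(frozen=True)
class GenomeConfig:
    chrom: str = "chr1"
    apa_mixture: tuple[float, ...] = DEFAULT_APA_MIXTURE
    baseline_range: tuple[float, float] = (30.0, 3000.0)  # log-uniform
    min_pas_separation: int = 60
    intergenic_gap: tuple[int, int] = (6000, 12000)
    include_mito: bool = False
    mito_chrom: str = "chrM"


# region classes available for non-terminal extra sites, with weights
_EXTRA_CLASSES = (
    apas.REGION_UTR3_INTERNAL,
    apas.REGION_UTR3_DISTAL,
    apas.REGION_INTRON,
    apas.REGION_INTERNAL_EXON,
    apas.REGION_POST_EXON,
)
_EXTRA_WEIGHTS = (0.50, 0.15, 0.15, 0.10, 0.10)


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    g_start: int,
    cfg: GenomeConfig,
    apa_count: int,
) -> SimGeneModel:
    """Lay out one gene in transcription coordinates, then map to genome."""
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(2, 6))
    exon_lens = rng.integers(150, 600, size=n_exons)
    exon_lens[-1] = int(rng.integers(900, 1800))     # room for a 3'UTR
    intron_lens = rng.integers(600, 2000, size=n_exons - 1)

    # transcription-coordinate exon intervals [s, e) from 0
    tx_exons = []
    t = 0
    for i, L in enumerate(exon_lens):
        tx_exons.append((t, t + int(L)))
        if i < n_exons - 1:
            t += int(L) + int(intron_lens[i])
        else:
            t += int(L)
    tx_len = t
    utr3_len = int(rng.integers(400, min(900, exon_lens[-1] - 100)))
    tx_utr3_start = tx_exons[-1][1] - utr3_len     # transcription coord
    tx_end = tx_exons[-1][1] - 1                   # last transcribed base

    # place PAS sites in transcription coordinates
    positions: list[tuple[int, str]] = [(tx_end, apas.REGION_UTR3_TERMINAL)]
    classes = list(rng.choice(_EXTRA_CLASSES, size=apa_count - 1,
                              p=_EXTRA_WEIGHTS))
    sep = cfg.min_pas_separation
    for cls in classes:
        for _ in range(200):
            if cls == apas.REGION_UTR3_INTERNAL:
                p = int(rng.integers(tx_utr3_start + sep, tx_end - sep))
            elif cls == apas.REGION_UTR3_DISTAL:
                p = tx_end + int(rng.integers(100, 2000))
            elif cls == apas.REGION_INTRON:
                i = int(rng.integers(0, n_exons - 1))
                lo, hi = tx_exons[i][1] + 100, tx_exons[i + 1][0] - sep
                p = int(rng.integers(lo, hi))
            elif cls == apas.REGION_INTERNAL_EXON:
                i = int(rng.integers(0, n_exons - 1))
                lo, hi = tx_exons[i][0] + 10, tx_exons[i][1] - 10
                p = int(rng.integers(lo, hi))
            else:  # post_exon: just downstream of an internal exon
                i = int(rng.integers(0, n_exons - 1))
                p = tx_exons[i][1] - 1 + int(rng.integers(1, 20))
            if all(abs(p - q) >= sep for q, _ in positions):
                positions.append((p, cls))
                break
        else:
            # crowded gene: fall back to a spaced 3'UTR-internal site
            p = positions[-1][0] - sep
            positions.append((p, apas.REGION_UTR3_INTERNAL))
    positions.sort()

    # map transcription coords to genome
    span = tx_end + 2000 + 1  # allow distal sites inside the allocation
    if strand == "+":
        to_g = lambda tc: g_start + tc
        g_exons = tuple((g_start + s, g_start + e) for s, e in tx_exons)
    else:
        g_end = g_start + span - 1
        to_g = lambda tc: g_end - tc
        g_exons = tuple(
            sorted((g_end - (e - 1), g_end - s + 1) for s, e in tx_exons)
        )
    lo, hi = cfg.baseline_range
    baselines = np.exp(rng.uniform(np.log(lo), np.log(hi), size=apa_count))
    sites = tuple(
        (int(to_g(p)), cls, float(b))
        for (p, cls), b in zip(positions, baselines)
    )
    return SimGeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=g_exons,
        pas_sites=sites,
        apa_count=apa_count,
        utr3_start=int(to_g(tx_utr3_start)),
        tx_end3=int(to_g(tx_end)),
    )


def _gene_span(model: SimGeneModel) -> tuple[int, int]:
    coords = [c for iv in model.exons for c in iv] + \
             [p for p, _, _ in model.pas_sites]
    return min(coords), max(coords)


def simulate_genome(
    n_genes: int,
    seed: int,
    config: GenomeConfig = GenomeConfig(),
) -> tuple[str, str, list[SimGeneModel]]:
    """Generate (FASTA text, GTF text, gene models) for a synthetic genome.

    Each gene draws its poly(A)-site count from ``config.apa_mixture``
    (1..10 sites spanning the APA region taxonomy); identical seed and
    config give byte-identical output.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    models: list[SimGeneModel] = []
    cursor = int(rng.integers(*config.intergenic_gap))
    ks = rng.choice(np.arange(1, 11), size=n_genes,
                    p=np.asarray(config.apa_mixture))
    for i in range(n_genes):
        m = _build_gene(rng, f"gene{i + 1}", config.chrom, cursor, config,
                        int(ks[i]))
        models.append(m)
        lo, hi = _gene_span(m)
        cursor = hi + int(rng.integers(*config.intergenic_gap))
    chrom_len = cursor + 1000

    seqs = {config.chrom: _random_seq(rng, chrom_len)}
    if config.include_mito:
        mito = _build_gene(rng, "mito_gene1", config.mito_chrom, 2000,
                           config, 1)
        models.append(mito)
        seqs[config.mito_chrom] = _random_seq(rng, _gene_span(mito)[1] + 2000)

    fasta = "".join(
        f">{chrom}\n" + _wrap(seq) for chrom, seq in seqs.items()
    )
    gtf = _models_to_gtf(models)
    return fasta, gtf, models


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _wrap(seq: str, width: int = 70) -> str:
    return "\n".join(seq[i:i + width] for i in range(0, len(seq), width)) + "\n"


def _models_to_gtf(models: Sequence[SimGeneModel]) -> str:
    """GTF (1-based closed) with gene/transcript/exon/CDS features."""
    lines = []
    for m in models:
        lo, hi = m.exons[0][0], m.exons[-1][1] - 1
        attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1";'
        lines.append(
            f"{m.chrom}\tsim\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
            f'gene_id "{m.gene_id}";'
        )
        lines.append(
            f"{m.chrom}\tsim\ttranscript\t{lo}\t{hi}\t.\t{m.strand}\t.\t{attrs}"
        )
        for (s, e) in m.exons:       # half-open -> 1-based closed
            lines.append(
                f"{m.chrom}\tsim\texon\t{s}\t{e - 1}\t.\t{m.strand}\t.\t{attrs}"
            )
        # CDS: everything upstream of the 3'UTR within exons
        for (s, e) in m.exons:
            e1 = e - 1
            if m.strand == "+":
                cs, ce = s, min(e1, m.utr3_start - 1)
            else:
                cs, ce = max(s, m.utr3_start + 1), e1
            if cs <= ce:
                lines.append(
                    f"{m.chrom}\tsim\tCDS\t{cs}\t{ce}\t.\t{m.strand}\t0\t{attrs}"
                )
    return "\n".join(lines) + "\n"


def models_to_gene_annots(models: Sequence[SimGeneModel]) -> list[apas.GeneAnnot]:
    """Direct conversion of simulator truth to annotation records."""
    out = []
    for m in models:
        exons = tuple((s, e - 1) for s, e in m.exons)
        out.append(
            apas.GeneAnnot(
                gene_id=m.gene_id, chrom=m.chrom, strand=m.strand,
                start=exons[0][0], end=exons[-1][1], exons=exons,
                utr3_start=m.utr3_start, tx_end3=m.tx_end3,
            )
        )
    return out


def scale_baselines(models: Sequence[SimGeneModel],
                    total_per_library: float) -> list[SimGeneModel]:
    """Rescale baselines so expected tags/library sum to a target depth."""
    total = sum(b for m in models for _, _, b in m.pas_sites)
    f = total_per_library / total
    return [
        replace(
            m,
            pas_sites=tuple((p, c, b * f) for p, c, b in m.pas_sites),
        )
        for m in models
    ]


# ---------------------------------------------------------------------------
# Signal assignment


def assign_signals(
    models: Sequence[SimGeneModel],
    seed: int,
    frac_rhythmic24: float = 0.10,
    frac_rhythmic12: float = 0.05,
    frac_de: float = 0.05,
    amplitude_range: tuple[float, float] = (0.3, 0.8),
    de_log2fc_choices: Sequence[float] = (-1.5, -1.0, 1.0, 1.5),
    de_comparisons: Sequence[str] = ("R0", "R2", "R4", "R8"),
    dispersion: float = 0.05,
) -> list[SimSignal]:
    """Randomly plant rhythmic/DE behaviour on a fraction of all PASs."""
    rng = np.random.default_rng(seed)
    sites = [(m.gene_id, i) for m in models for i in range(m.apa_count)]
    out = []
    for gid, idx in sites:
        u = rng.random()
        if u < frac_rhythmic24:
            out.append(SimSignal(gid, idx, "rhythmic", period_h=24.0,
                                 phase_h=float(rng.uniform(0, 24)),
                                 amplitude_rel=float(rng.uniform(*amplitude_range)),
                                 dispersion=dispersion))
        elif u < frac_rhythmic24 + frac_rhythmic12:
            out.append(SimSignal(gid, idx, "rhythmic", period_h=12.0,
                                 phase_h=float(rng.uniform(0, 12)),
                                 amplitude_rel=float(rng.uniform(*amplitude_range)),
                                 dispersion=dispersion))
        elif u < frac_rhythmic24 + frac_rhythmic12 + frac_de:
            out.append(SimSignal(gid, idx, "de",
                                 de_comparison=str(rng.choice(de_comparisons)),
                                 de_log2fc=float(rng.choice(de_log2fc_choices)),
                                 dispersion=dispersion))
        else:
            out.append(SimSignal(gid, idx, "null", dispersion=dispersion))
    return out


# ---------------------------------------------------------------------------
# Counts


def pas_key(gene_id: str, site_index: int) -> str:
    return f"{gene_id}:{site_index}"


def simulate_counts(
    models: Sequence[SimGeneModel],
    signals: Sequence[SimSignal],
    design: SimDesign,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-library NB tag counts for every planted PAS.

    Returns (counts, truth): ``counts`` is PAS x library (index
    ``gene:site``); ``truth`` records each site's planted parameters.
    Negative expected means (amplitude_rel > 1) are clamped to 0 with a
    warning.
    """
    sig_map = {(s.gene_id, s.site_index): s for s in signals}
    for key in sig_map:
        gids = {m.gene_id: m for m in models}
        if key[0] not in gids or key[1] >= gids[key[0]].apa_count:
            raise ValueError(f"signal references unknown PAS {key}")
    table = design.design_table()
    rng = np.random.default_rng(design.seed)

    keys, truth_rows, mu_rows = [], [], []
    clamped = 0
    for m in models:
        for i, (coord, cls, baseline) in enumerate(m.pas_sites):
            s = sig_map.get((m.gene_id, i),
                            SimSignal(m.gene_id, i, "null"))
            mus = []
            for row in table.rows:
                mu = baseline
                if s.kind == "rhythmic":
                    mu *= 1.0 + s.amplitude_rel * np.cos(
                        2 * np.pi * (row.zt_h - s.phase_h) / s.period_h
                    )
                if s.kind == "de" and row.group == s.de_comparison:
                    mu *= 2.0 ** s.de_log2fc
                if mu < 0:
                    mu, clamped = 0.0, clamped + 1
                mus.append(mu)
            keys.append(pas_key(m.gene_id, i))
            mu_rows.append(mus)
            truth_rows.append(
                (pas_key(m.gene_id, i), m.gene_id, i, m.chrom, m.strand,
                 coord, cls, baseline, s.kind, s.period_h, s.phase_h,
                 s.amplitude_rel, s.de_comparison, s.de_log2fc, s.dispersion)
            )
    if clamped:
        warnings.warn(f"{clamped} expected means clamped to 0")

    mu = np.array(mu_rows)
    phi = np.array(
        [sig_map.get((m.gene_id, i), SimSignal(m.gene_id, i, "null")).dispersion
         for m in models for i in range(m.apa_count)]
    )[:, None]
    # NB via gamma-Poisson mixture: variance = mu + phi*mu^2
    shape = 1.0 / phi
    lam = np.where(mu > 0, rng.gamma(np.broadcast_to(shape, mu.shape),
                                     mu * phi), 0.0)
    counts = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=pd.Index(keys, name="pas"),
                             columns=table.sample_ids)
    truth = pd.DataFrame(
        truth_rows,
        columns=["pas", "gene_id", "site_index", "chrom", "strand", "coord",
                 "region_class", "baseline", "kind", "period_h", "phase_h",
                 "amplitude_rel", "de_comparison", "de_log2fc", "dispersion"],
    ).set_index("pas")
    return counts_df, truth


# ---------------------------------------------------------------------------
# Reads


@dataclass(frozen=True)
class ReadSimParams:
    """Sequencing-artifact knobs for read generation."""

    jitter: int = 5                  # max |3'-end offset| from the true PAS
    read_len: tuple[int, int] = (30, 60)
    t_stretch_max: int = 30          # 5' poly(T) artifact length, 0..max
    t_contamination: float = 0.1     # per-base chance a T is replaced
    fail_quality_fraction: float = 0.05
    max_read_len: int = 120
    qual_pass: tuple[int, int] = (15, 38)
    qual_fail: tuple[int, int] = (2, 10)


def simulate_reads(
    models: Sequence[SimGeneModel],
    counts: pd.DataFrame,
    params: ReadSimParams,
    seed: int,
    out_dir: str | Path,
    genome_fasta: str,
) -> dict[str, dict[str, Path]]:
    """Write per-library FASTQ + truth-alignment BED files.

    Each read's genomic 3' end lies within ``params.jitter`` nt of its
    true PAS; a 5' T-stretch with <= ``t_contamination`` non-T bases is
    prepended; a ``fail_quality_fraction`` of reads draw qualities that
    fail the Q10/50% rule.  The truth BED holds one (chrom, 3' end,
    strand, read id) record per read; read ids are prefixed with the
    sample id.  Returns {sample: {"fastq": path, "bed": path}}.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = _parse_fasta(genome_fasta)
    site_info = {}
    for m in models:
        for i, (coord, cls, _) in enumerate(m.pas_sites):
            site_info[pas_key(m.gene_id, i)] = (m.chrom, m.strand, coord)

    manifest: dict[str, dict[str, Path]] = {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(counts.columns))
    for lib_i, sample in enumerate(counts.columns):
        rng = np.random.default_rng(children[lib_i])
        fq_path = out_dir / f"{sample}.fastq"
        bed_path = out_dir / f"{sample}.bed"
        with open(fq_path, "w") as fq, open(bed_path, "w") as bed:
            serial = 0
            for key, n in counts[sample].items():
                n = int(n)
                if n == 0:
                    continue
                chrom, strand, coord = site_info[key]
                seq = genome[chrom]
                jit = rng.integers(-params.jitter, params.jitter + 1, size=n)
                lens = rng.integers(params.read_len[0], params.read_len[1] + 1,
                                    size=n)
                t_lens = rng.integers(0, params.t_stretch_max + 1, size=n) \
                    if params.t_stretch_max > 0 else np.zeros(n, dtype=int)
                fails = rng.random(n) < params.fail_quality_fraction
                for r in range(n):
                    end3 = int(np.clip(coord + jit[r], 1, len(seq)))
                    L = int(lens[r])
                    if strand == "+":
                        body = _revcomp(seq[max(0, end3 - L):end3])
                    else:
                        body = seq[end3 - 1:end3 - 1 + L]
                    prefix = _t_stretch(rng, int(t_lens[r]),
                                        params.t_contamination)
                    read = prefix + body
                    if len(read) > params.max_read_len:
                        read = read[len(read) - params.max_read_len:]
                    quals = _qualities(rng, len(read), bool(fails[r]), params)
                    serial += 1
                    rid = f"{sample}:{key}:{serial}"
                    fq.write(f"@{rid}\n{read}\n+\n{quals}\n")
                    bed.write(
                        f"{chrom}\t{end3 - 1}\t{end3}\t{rid}\t0\t{strand}\n"
                    )
        manifest[sample] = {"fastq": fq_path, "bed": bed_path}
    return manifest


def _t_stretch(rng: np.random.Generator, n: int, contamination: float) -> str:
    if n == 0:
        return ""
    bases = np.full(n, "T")
    bad = rng.random(n) < contamination
    if bad.any():
        bases[bad] = np.array(list("ACG"))[rng.integers(0, 3, size=bad.sum())]
    return "".join(bases)


def _qualities(rng: np.random.Generator, n: int, fail: bool,
               params: ReadSimParams) -> str:
    if n == 0:
        return ""
    if fail:
        q = rng.integers(*params.qual_fail, size=n)
        hi = rng.random(n) < 0.3     # a minority of good bases
        q[hi] = rng.integers(*params.qual_pass, size=int(hi.sum()))
    else:
        q = rng.integers(*params.qual_pass, size=n)
    return (q.astype(np.uint8) + 33).tobytes().decode("ascii")


def _parse_fasta(text: str) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    for line in text.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = []
        elif name is not None:
            seqs[name].append(line.strip())
    return {k: "".join(v) for k, v in seqs.items()}
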