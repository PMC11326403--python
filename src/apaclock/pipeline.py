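"""End-to-end pipeline: simulate -> trim -> call -> rhythm -> de ->
enrich -> overlap, with provenance stamping.

Intermediate stages communicate through files in the run directory, so
any stage can also be run alone from the CLI on existing outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import de as ade
from . import enrich as aenrich
from . import io as aio
from . import overlap as aoverlap
from . import pas as apas
from . import reads as areads
from . import rhythm as arhythm
from . import sim as asim


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline in one place."""

    n_genes: int = 20
    reads_per_library: int = 50_000
    seed: int = 0
    frac_rhythmic24: float = 0.15
    frac_rhythmic12: float = 0.10
    frac_de: float = 0.10
    genome: asim.GenomeConfig = field(
        default_factory=lambda: asim.GenomeConfig(include_mito=True)
    )
    read_params: asim.ReadSimParams = field(default_factory=asim.ReadSimParams)
    read_filter: areads.ReadFilterConfig = field(
        default_factory=areads.ReadFilterConfig
    )
    cluster_window: int = 25
    pac_filter: apas.PacFilterConfig = field(default_factory=apas.PacFilterConfig)
    rhythm24: arhythm.RhythmConfig = field(
        default_factory=lambda: arhythm.RhythmConfig(period_h=24.0)
    )
    rhythm12: arhythm.RhythmConfig = field(
        default_factory=lambda: arhythm.RhythmConfig(period_h=12.0)
    )
    de: ade.DEConfig = field(default_factory=ade.DEConfig)
    gmt_path: str | None = None
    disorder_table: str | None = None   # None -> packaged fixture

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    design: aio.DesignTable
    models: list
    truth: pd.DataFrame
    trim_stats: dict[str, areads.TrimStats]
    pacs: apas.PacSet
    rhythm24: pd.DataFrame
    rhythm12: pd.DataFrame
    de_tables: dict[str, pd.DataFrame]
    enrichment: dict[str, pd.DataFrame]
    overlap_report: pd.DataFrame
    out_dir: Path


def run_all(cfg: PipelineConfig, out_dir: str | Path,
            stages: tuple[str, ...] = ("simulate", "trim", "call", "rhythm",
                                       "de", "enrich", "overlap")
            ) -> PipelineResult:
    """Run the pipeline; every stage output lands under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    conf = cfg.as_dict()

    design = asim.SimDesign(
        reads_per_library=cfg.reads_per_library, seed=cfg.seed
    )
    table = design.design_table()
    aio.write_design(table, out_dir / "design.tsv")

    # --- simulate -----------------------------------------------------
    fasta, gtf, models = asim.simulate_genome(cfg.n_genes, cfg.seed,
                                              cfg.genome)
    models = asim.scale_baselines(models, cfg.reads_per_library)
    signals = asim.assign_signals(
        models, cfg.seed + 1,
        frac_rhythmic24=cfg.frac_rhythmic24,
        frac_rhythmic12=cfg.frac_rhythmic12,
        frac_de=cfg.frac_de,
    )
    counts, truth = asim.simulate_counts(models, signals, design)
    (out_dir / "genome.fa").write_text(fasta)
    (out_dir / "genes.gtf").write_text(gtf)
    truth.to_csv(out_dir / "truth.tsv", sep="\t")
    manifest = asim.simulate_reads(
        models, counts, cfg.read_params, cfg.seed + 2,
        out_dir / "reads", fasta,
    )
    aio.stamp(out_dir / "truth.tsv", conf, cfg.seed)

    # --- trim ---------------------------------------------------------
    trim_dir = out_dir / "trimmed"
    trim_dir.mkdir(exist_ok=True)
    trim_stats: dict[str, areads.TrimStats] = {}
    for sample, paths in manifest.items():
        st = areads.process_fastq(
            paths["fastq"], trim_dir / f"{sample}.trim.fastq",
            cfg.read_filter, sample_id=sample, collect_ids=True,
        )
        trim_stats[sample] = st
    pd.DataFrame(
        {s: st.as_dict() for s, st in trim_stats.items()}
    ).T.to_csv(out_dir / "trim_stats.tsv", sep="\t")

    # --- call ---------------------------------------------------------
    tag_frames = []
    for sample, paths in manifest.items():
        tags = apas.extract_tags_bed(paths["bed"], sample_id=sample)
        bed_names = aio.read_bed(paths["bed"])["name"]
        keep = bed_names.isin(trim_stats[sample].kept_ids).to_numpy()
        tag_frames.append(tags.loc[keep])
    all_tags = pd.concat(tag_frames, ignore_index=True)
    lib_sizes = apas.library_sizes(all_tags)
    groups = {r.sample_id: r.group for r in table.rows}
    pacs = apas.cluster_pas(all_tags, cfg.cluster_window,
                            samples=table.sample_ids)
    pacs = apas.filter_pacs(pacs, lib_sizes, groups, cfg.pac_filter)
    annots = apas.read_gtf(out_dir / "genes.gtf")
    pacs = apas.annotate_pacs(pacs, annots)
    pacs = apas.normalize(pacs, drop_mito=True)
    pacs.to_tsv(out_dir / "pacs.tsv")
    aio.stamp(out_dir / "pacs.tsv", conf, cfg.seed)

    # --- rhythm -------------------------------------------------------
    r24 = arhythm.run_trials(pacs.counts_norm, table, cfg.rhythm24)
    r12 = arhythm.run_trials(pacs.counts_norm, table, cfg.rhythm12)
    r24.to_csv(out_dir / "diurnal.tsv", sep="\t")
    r12.to_csv(out_dir / "ultradian.tsv", sep="\t")

    # --- de -----------------------------------------------------------
    de_tables = ade.run_comparisons(pacs.counts_raw, table, cfg.de)
    de_dir = out_dir / "de"
    de_dir.mkdir(exist_ok=True)
    for name, tab in de_tables.items():
        tab.to_csv(de_dir / f"{name}.tsv", sep="\t")

    # --- enrich -------------------------------------------------------
    enrichment: dict[str, pd.DataFrame] = {}
    if cfg.gmt_path:
        gene_sets = aio.read_gmt(cfg.gmt_path)
        input_sets = aenrich.build_input_sets(
            pacs.meta, r24, r12, de_tables,
            sig_p=cfg.de.sig_p, sig_lfc=cfg.de.sig_lfc,
        )
        universe = set(
            pacs.meta.loc[pacs.meta["gene_symbol"] != "intergenic",
                          "gene_symbol"]
        )
        for name, s in input_sets.items():
            if s:
                enrichment[name] = aenrich.ora(s, universe, gene_sets)
                enrichment[name].to_csv(out_dir / f"enrich_{name}.tsv",
                                        sep="\t", index=False)

    # --- overlap ------------------------------------------------------
    entries = aoverlap.load_disorder_table(cfg.disorder_table)
    sig_tables = {
        "cycle24": r24[r24["significant"]],
        "cycle12": r12[r12["significant"]],
        "de": pd.concat(
            [ade.significant_set(t, cfg.de) for t in de_tables.values()]
        ) if de_tables else pd.DataFrame(),
    }
    overlap_report = aoverlap.match_significant(sig_tables, pacs.meta, entries)
    overlap_report.to_csv(out_dir / "disorder_overlap.tsv", sep="\t",
                          index=False)

    return PipelineResult(
        design=table, models=models, truth=truth, trim_stats=trim_stats,
        pacs=pacs, rhythm24=r24, rhythm12=r12, de_tables=de_tables,
        enrichment=enrichment, overlap_report=overlap_report,
        out_dir=out_dir,
    )


def evaluate_recovery(
    truth: pd.DataFrame,
    pacs: apas.PacSet,
    min_expected: float = 30.0,
    tolerance: int = 25,
) -> dict[str, float]:
    """Fraction of adequately expressed planted PASs recovered as clusters.

    A planted site counts as recovered when a retained cluster on its
    chromosome and strand has a peak within ``tolerance`` nt.  Only
    sites with baseline >= ``min_expected`` expected tags/library enter
    the denominator; mitochondrial sites are excluded because the
    pipeline removes their clusters by design.
    """
    meta = pacs.meta
    eligible = truth[
        (truth["baseline"] >= min_expected)
        & ~truth["chrom"].isin(apas.DEFAULT_MITO_CHROMS)
    ]
    hits = 0
    for _, row in eligible.iterrows():
        m = meta[(meta["chrom"] == row["chrom"])
                 & (meta["strand"] == row["strand"])
                 & ((meta["peak"] - row["coord"]).abs() <= tolerance)]
        if len(m):
            hits += 1
    n = len(eligible)
    return {
        "n_eligible": float(n),
        "n_recovered": float(hits),
        "recovery": hits / n if n else float("nan"),
    }
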