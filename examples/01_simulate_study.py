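"""Generate a small synthetic 3'-end sequencing study.

Builds a compact genome with planted poly(A) sites, assigns rhythmic /
differentially expressed / null behaviour, and draws negative-binomial
tag counts for the 55-library design (6 diurnal timepoints x 5
replicates, 4 sleep-deprivation recovery groups x 5, one ZT8 control
x 5).
"""

from apaclock import sim

design = sim.SimDesign(reads_per_library=20_000, seed=42)
fasta, gtf, models = sim.simulate_genome(n_genes=10, seed=42)
models = sim.scale_baselines(models, design.reads_per_library)
signals = sim.assign_signals(models, seed=43)
counts, truth = sim.simulate_counts(models, signals, design)

print(f"genes: {len(models)}, planted PASs: {len(truth)}")
print(f"libraries: {len(counts.columns)} "
      f"(mean depth {counts.sum(axis=0).mean():.0f} tags)")
print("\nplanted signal kinds:")
print(truth["kind"].value_counts().to_string())
print("\nfirst planted sites (coordinate, region class, expected tags/lib):")
print(truth[["chrom", "strand", "coord", "region_class", "baseline"]]
      .head(5).to_string())
# 'baseline' is each site's expected tags per library before any rhythm
# or sleep-deprivation modulation; the truth table is the reference every
# downstream stage is checked against.
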