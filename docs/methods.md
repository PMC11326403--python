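# Methods

This note documents the models, numerical choices and known limitations
behind `apaclock`.  Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design and coordinate conventions

The default design is 55 libraries: six diurnal timepoints (ZT2–ZT22,
every 4 h) × 5 biological replicates, four sleep-deprivation recovery
groups (R0/R2/R4/R8, collected at ZT6/8/10/14) × 5, and a ZT8
undisturbed control × 5.  Coordinates are 1-based closed internally
(the SAM/GTF convention); BED input/output converts to 0-based
half-open only at the I/O boundary, and strand-aware "3' end" always
means the rightmost aligned base on + and the leftmost on −.

## Synthetic data generator

The generator emulates the statistical structure of a 3'-end tag
experiment, not its chemistry.

*Genome and genes.* A few-hundred-kb random genome holds genes laid out
in transcription coordinates (2–5 exons of 150–600 bp, the last
900–1800 bp with a 400–900 bp 3'UTR; introns 600–2000 bp) and mapped to
either strand.  Each gene draws its PAS count from a configurable
mixture over 1..10 (default P(1) = 0.55, P(≥2) = 0.45).  Every gene has
a site at the annotated 3' terminus; extra sites fall in the 3'UTR
(50 %), distal to it (15 %), in introns (15 %), internal exons (10 %)
or just past an internal exon (10 %), with a minimum pairwise spacing
of 60 nt so that 25-nt clustering is exercised but unambiguous.  An
optional chrM contig carries a mitochondrial gene to exercise the mito
filter.

*Counts.* Baseline expression per site is log-uniform (default 30–3000
expected tags/library, rescaled so library depth matches the
configuration).  A rhythmic site's expected count at collection time t
is baseline·(1 + a·cos(2π(t − φ)/T)); a DE site multiplies its baseline
by 2^lfc in the treatment group only; realized counts are negative
binomial via a gamma–Poisson mixture with variance μ + φμ² (default
φ = 0.05 — a typical biological-replicate dispersion for bulk counts).
Expected means that would go negative (a > 1) are clamped to zero with
a warning.

*Reads.* Each read's genomic 3' end is jittered uniformly within ±5 nt
of its site (modelling cleavage heterogeneity; small enough that 25-nt
clustering cannot split a site).  A 5' T-stretch of length 0–30 with
≤ 20 % (default 10 %) non-T contamination is prepended; a configurable
fraction of reads (default 5 %) draws qualities that fail the Q10/50 %
rule.  Truth alignments are emitted as BED (one record per read, named
by read id) so that alignment itself stays outside the pipeline; after
trimming, alignments are subset to surviving read ids.

*What it does not model:* sequencing-platform homopolymer errors,
internal priming on genomic A-stretches, RNA degradation, mapping
ambiguity.  Passing tests therefore demonstrate correctness of the
statistics and bookkeeping, not robustness to those artifacts.

## Read processing

Quality rule: keep iff ≥ 50 % of bases score ≥ Q10, both comparisons
boundary-inclusive.  Trimming removes a leading T-run, then successive
10-nt windows with ≥ 80 % T, stopping at the first window below
threshold; because a removed window can expose a fresh leading T-run,
the run-then-window step is iterated to a fixed point, which makes the
operation idempotent (a property the suite asserts).  A consequence is
that no trimmed read begins with T; reads shorter than 16 bp after
trimming are dropped.  "T-rich" has no standard definition; window
size and fraction are configurable.

## PAS clustering and filtering

"Within 25 nt of one another" is implemented as single-linkage
chaining per chromosome and strand: adjacent distinct endpoints ≤ 25 nt
apart join one cluster, so clusters may span more than 25 nt; clusters
are separated by > 25 nt.  The peak is the endpoint with the largest
read count; ties go to the 3'-most endpoint in transcription order.
The implementation is checked against a brute-force union-find oracle
on 1,000 random endpoint sets.

Retention takes each sample's own library size into account: samples in
libraries below 1.7 M covered reads need ≥ 3 reads, others ≥ 4 (a
library of exactly 1.7 M counts as large); a cluster survives iff at
least one 5-replicate group has ≥ 3 qualifying samples.  Both
thresholds, the split point and the quorum are configurable.

Annotation assigns a peak to a same-strand gene whose span (extended a
configurable 5 kb past the annotated 3' terminus) contains it, breaking
overlaps by nearest 3' terminus.  Region classes: within ±25 nt of the
terminus → `utr3_terminal`; past it → `utr3_distal`; inside the longest
documented 3'UTR → `utr3_internal`; inside an exon → `internal_exon`;
intronic within 25 nt downstream of an internal exon's 3' edge →
`post_exon`; other intronic → `intron`; otherwise `intergenic`.
Mitochondrial clusters are removed before normalization and excluded
from its denominators; normalized counts are tags per 10⁷ per library.

## Rhythm detection

Three detectors are combined per series:

- **Lomb–Scargle** at the single tested frequency 1/T.  The periodogram
  power is normalized by the sample variance; the null tail used is the
  exact finite-sample form P(Z > z) = (1 − 2z/(n−1))^((n−3)/2), whose
  large-n limit is the familiar exp(−z) tail.  The exact form matters
  at n = 6: it makes null p-values exactly uniform (asserted by a KS
  test) and lets a noiseless cosine reach p → 0 at the maximal power
  (n−1)/2.  Constant series return p = 1.
- **JTK-style concordance**: Kendall's τ-b between the series and
  cosine references peaking at each sampling time folded into one
  period (ZT2..ZT22 for 24 h; three distinct phases for 12 h).  For
  n ≤ 8 the p-value is the exact two-sided permutation tail (the null
  is enumerated over all n! permutations, with ties on either side
  handled by τ-b, and cached per reference/tie pattern); larger n uses
  the normal approximation.  The best phase maximizes τ; the p-value is
  Bonferroni-adjusted for the number of reference phases.
- **Cosinor**: OLS fit of m + a·cos(ωt) + b·sin(ωt), F-test of
  (a,b) = 0 against the intercept model; amplitude √(a²+b²) (half the
  fitted peak-to-trough), acrophase from atan2.

Fisher's method combines the p-values (−2Σln p ~ χ² with 2k df, p
floored at 1e-300); the phase is the −ln p-weighted circular mean of
the JTK and cosinor phases; the amplitude comes from the cosinor fit.
Fisher assumes independence across methods, which is false in practice
(all three see the same series); the combination is therefore
anti-conservative per trial, and the all-trials conjunction below is
what restores control.

*Trials.* The ensemble runs n_trials = 5 times; trial r uses replicate
r at every timepoint (deterministic rotation; a seeded random
without-replacement assignment is available).  BH adjustment is
computed within each trial across all PASs.  A PAS is significant iff
the raw integrated p < α in **every** trial — the median BH.Q is
reported but plays no part in the call, since a 6-point series rarely
reaches small adjusted values.  Reported phase is the circular mean
across trials; amplitude and relative amplitude (amplitude / series
mean) are arithmetic means.

*Power at this design.* A single trial carries 6 observations, which
bounds what any detector can do.  At amplitude_rel 0.5, baseline 500,
dispersion 0.05, a cosinor oracle handed the *true* NB variance has
single-trial power ≈ 0.95, hence all-five-trials power ≈ 0.79; the
implemented ensemble sits well below that (JTK's smallest attainable
p after Bonferroni is 1/60; the LS and cosinor tests spend their few
degrees of freedom estimating noise).  The 5-trial conjunction is thus
a high-specificity, moderate-sensitivity rule: planted nulls are
essentially never called (< 0.5 % in 1,000 series), recovered phases
are accurate (circular RMSE well under 1.5 h), but recovery of
moderate-amplitude rhythms is partial.  `scripts/acceptance.py`
measures and reports the actual rates.

Phase windows are [c − 2.5, c + 2.5) hours around each collection
time, modulo 24; with 4 h spacing adjacent windows overlap by 1 h and
a PAS in the overlap is reported in both.

## Differential expression

Size factors are DESeq-style median-of-ratios against the geometric
mean pseudo-reference over all-positive PASs, normalized to geometric
mean 1 (total-count fallback if no PAS is all-positive).

The optional confounder scrub centers log₂(normalized + 1) per PAS,
zeroes the first singular component, and restores row means, reporting
the variance fraction removed.  **Caveat:** the correction removes
whatever dominates sample-space variance.  On matrices where true
effects are weak and scattered this is library-level technical
variation; but if strong, same-signed effects concentrate in one group
they *become* the first component and are scrubbed (we measured
complete loss of ten planted lfc = 1.5 single-group effects among 400
nulls).  The correction is therefore a config switch
(`DEConfig.remove_pc1`), and analyses of strongly perturbed designs
should compare both settings.

Testing is a per-PAS NB GLM with log link and group indicator, fit by
a vectorized IRLS with a closed-form 2×2 solve.  Dispersion is pooled
per-group method-of-moments, shrunk halfway toward a fitted a + b/μ
trend and floored at 1e-8 — a deliberate simplification of empirical
Bayes machinery that is fully specified and adequate at 5 vs 5.  The
Wald statistic uses the unpenalized fit; the reported log2FC is a
ridge MAP refit with a normal prior on the fold change (scale 1.0
log2 units), which contracts toward zero relative to the MLE (asserted
for every PAS; identical groups give log2FC = 0, p = 1).  BH runs per
comparison.  Local FDR fits an empirical null N(μ₀, σ₀) to the central
half of the Wald z-scores (median, IQR/1.349), estimates π₀ from the
central mass, and returns clip(π₀f₀(z)/f(z), 0, 1) with a Gaussian
KDE for f.  The significance rule for downstream gene sets is raw
p < 0.01 and |log2FC| > 0.5 (two-sided, since down-regulation is as
meaningful as up-) in genes with ≥ 2 PASs.

## Enrichment and disorder overlap

ORA uses the hypergeometric upper tail with universe = reference genes
annotated to ≥ 1 term in the collection (the PAS-detected gene set is
the natural reference for this pipeline); expect = size ×
draws/universe, ratio = overlap/expect, BH across tested terms, term
size bounds 10–500 by default.  The exact tail is verified against
exhaustive enumeration on a 20-gene universe.

The disorder table (one row per disorder-linked PAS, in 24 h / 12 h /
DE categories) ships as a packaged TSV transcribed from its published
source, typos included; the parser normalizes case and known
orthography slips (e.g. SZC → SCZ) and accepts comma- or
period-separated association lists.  Counting deduplicates genes within
and across categories and PAS ids across categories.  Matching
pipeline hits to the table is by uppercased symbol equality — no
ortholog mapping — which mirrors how such cross-species overlaps are
usually reported and is a documented limitation.

## Problem sizes used by the validation suite

Oracle checks: 1,000 random endpoint sets (≤ 200 points) for
clustering; 100 six-point series against full 720-permutation JTK
nulls; 20 exhaustive hypergeometric configurations.  Parameter
recovery: 100 planted 24 h series plus 1,000 nulls through the 5-trial
scheme; 2,000 null and 1,000 mixed PASs through the NB Wald test.  The
end-to-end run uses 20 genes × 55 libraries × 50,000 reads/library and
is executed twice to demonstrate byte-identical outputs under a fixed
seed.
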