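# Methods

## Setting and data model

The package analyses a serial-sampling evolution experiment on a haploid
microbe: one clonal ancestor, two propagation lines at different
temperatures ("cold" stress and "hot" control), archived samples
re-sequenced along the way. The default layout is six cold samples
followed by four hot samples, with 102 generations elapsed in the cold
line and 181 in the hot line — the faster-growing control line passes
through more generations in the same wall-clock time.

Inputs are standard formats: a reference FASTA, gene models as GFF3 or
BED (full gene spans, UTRs and introns included), a multi-sample VCF of
haploid calls, and TSV side tables (sample series, gene→GO map, motif
table, DE flags, growth measurements). Internally all coordinates are
0-based half-open; VCF positions stay 1-based at the boundary. Genotypes
are collapsed to presence/absence: allele index 0 → 0, any non-reference
index → 1, `.` → missing. A site is genic when its POS falls inside at
least one gene span; InDels are assigned by POS alone (deterministic, and
insensitive to the deleted-span convention).

## Hard filters

Variants are filtered separately by type with OR-combined clauses
(GATK's recommended thresholds): SNPs fail on
`QD < 1.0 || FS > 30.0 || MQ < 45.0 || SOR > 9 || MQRankSum < -4.0 ||
ReadPosRankSum < -10.0`; InDels on
`QD < 1.0 || FS > 200.0 || MQ < 45.0 || MQRankSum < -6.5 ||
ReadPosRankSum < -10.0`. A clause whose annotation is absent is skipped;
a record with every clause skipped is reported `UNEVALUATED` rather than
silently passed. Tightening any threshold can only move records from
PASS to FAIL (a property-tested invariant).

## Trajectory classification

Each variant's calls form a binary pattern partitioned cold|hot. The
classifier is exact and rule-based:

* `Background` — all ones. Every sample disagrees with the reference, so
  the "variant" is a reference-assembly discrepancy; these are removed
  from trajectory percentages but tallied.
* `ColdFixed` — cold block matches `0^a 1^b` with `b ≥ 1` and the hot
  block is all zero (`HotFixed` symmetric). This formalizes "gained once
  and fixed in every subsequent sample, exclusively in one condition."
  When the fixed block is all ones (`a = 0`) the gain predates the first
  sampling point, so the condition in which it arose is unknowable; the
  class carries a `gain_time_ambiguous` flag instead of being dropped.
* `NoVariant` — all zero (cannot occur in a retained call set, handled
  for closure).
* `Unresolved` — any missing call. Missing data is not imputed: at the
  coverage typical of such experiments (hundreds-fold) missingness is
  rare, and imputing a 0 or 1 would bias fixation calls. Unresolved
  records are excluded from class percentages.
* `Random` — everything else, including mixed-condition patterns such as
  `011111|0011`: fixation must be exclusive to one condition.

For the 6|4 layout this yields exactly 6 ColdFixed, 4 HotFixed, 1
Background, 1 NoVariant and 1012 Random patterns among the 1024
possibilities; the test suite checks the classifier against an
independent brute-force reference over every pattern for layouts up to
12 samples.

Summaries use two denominators, mirroring how such results are reported:
the background share is a percentage of all filtered records, while the
ColdFixed/HotFixed/Random shares are percentages of the trajectory set
(non-background). Zero denominators yield `None`, never 0.

Mutation rates are `count / (L × G)` with all three inputs explicit. The
package attributes a trajectory variant to the condition of the first
sample carrying it (for a hot-attributed variant the cold block is
necessarily all zero). We deliberately expose the inputs rather than
bake in a convention, because published per-condition rates are
sensitive to the choice of count set, genome length and generation
number.

## Hotspots

Per-gene variant counts (a variant overlapping two genes increments
both) are Z-scored, `z = (c_g − mean)/sd`, and genes with `z` strictly
above 2.575 — the upper 0.5% point of a standard normal, i.e. the
two-sided 99th percentile — are flagged. Defaults: sample standard
deviation (`ddof=1`), background population = genes with at least one
variant; both are configurable (`ddof=0`, `include_zero=True`) since
either convention is defensible. With zero spread no hotspot is callable
and all Z are reported as 0 with a warning.

## Enrichment statistics

**Fisher's exact test** is computed by direct summation of hypergeometric
point masses over the support (log-gamma arithmetic); the two-sided
p-value sums every outcome whose mass does not exceed the observed one
within relative tolerance 1e-7. This stays exact and fast (~60 µs) even
for the large-margin tables the k-mer scan produces. The test suite pins
it against `scipy.stats.fisher_exact` and against an exact
integer-arithmetic enumeration oracle over all small tables.

**Benjamini–Hochberg** q-values come from
`statsmodels.stats.multitest.multipletests`, property-tested against the
hand step-up formula `q_(i) = min_{j≥i}(p_(j)·m/j)`. Significance means
`q ≤ α` with α = 0.05 by default.

**GO enrichment.** For each GO term: `a` = variant-bearing genes carrying
it, `b` = variant-free genes carrying it, `c`/`d` = the remaining
gene–GO associations of each gene set — the focal term against the
pooled background of all other terms. A gene counts once per term.
Terms seen fewer than twice among variant genes (`min_count=2`) are
excluded before testing, and BH runs over the tested family only.

**k-mer enrichment.** Every overlapping forward-strand window of the
intergenic sequences is one occurrence; an occurrence is "variant" when
its window covers at least one variant position; windows containing
non-ACGT characters are skipped. Within each k (1..10), each k-mer's
variant/non-variant occurrences are tested against the pooled counts of
all other k-mers of that length, with BH per k-family (a `global` scope
is available). Counting is forward-strand only: the headline CpG signal
(`CG`) is palindromic and therefore strand-invariant, which the suite
verifies. Significant k-mers are annotated against a user-supplied motif
table by IUPAC-aware substring matching; hits from k-mers shorter than 6
are flagged low-confidence, following the convention that partial motif
hits need length > 5 to count as potential regulatory-element evidence.

**DE overlap.** A single 2×2 Fisher test of variant-bearing ×
differentially-expressed over the DE-table's gene universe; variant genes
absent from that universe are dropped with a warning. The DE flags are
consumed as input — the expression model that produced them is out of
scope.

## Growth analysis

Each re-plating interval runs from a known inoculum (default ~1,000
cells) to an OD750 harvest reading; an OD-per-cell calibration converts
OD to cells and `Td = Δt·ln2 / ln(N_end/N_start)`. Intervals without net
growth are excluded and logged. Mean Td is the arithmetic mean of
interval values. Because "growth rate" is ambiguous, both conventions
are emitted: doublings per day (`1/Td`) and the exponential rate
(`ln2/Td` per day); published pairings of doubling time and rate do not
always fit either convention exactly, so the two are labelled rather
than reconciled.

Condition differences use the Wilcoxon rank-sum test (exact enumeration
for combined n ≤ 20 without ties; tie-corrected normal approximation
otherwise; complete ties return p = 1 since the tie-corrected variance
vanishes). Temporal trends use the Jonckheere–Terpstra test, written
in-house since neither scipy nor statsmodels ships it: the statistic
`J = Σ_{i<j} #{a ∈ g_i, b ∈ g_j : a < b} + ½·ties`, a normal
approximation with the standard tie-corrected variance, and — for pooled
n ≤ 12 or on request — exhaustive enumeration over all distinct group
assignments (seeded Monte-Carlo permutation when enumeration is
infeasible). Nonparametric tests are applied unconditionally; no
normality gate is implemented. OLS trends come from
`scipy.stats.linregress`.

## The simulator

`synthetic_data` generates everything the pipeline consumes, with the
ground truth ledgered:

* **Genome.** Default one 200 kb contig with 100 non-overlapping 1 kb
  genes (genic fraction 50%) — a scaled-down analogue of a highly
  streamlined ~14 Mb / ~6,800-gene microbial genome that keeps the
  roughly balanced genic/intergenic split. The scale keeps full runs in
  seconds while leaving >1,000 plantable sites per run. Background
  sequence is i.i.d. with configurable GC; CpG islands are carved into
  intergenic gaps (default 15% of intergenic bp) by a generator that
  emits a `CG` dinucleotide with probability 0.30 per step, giving
  island CG-density several-fold over background.
* **Variants.** Planted class counts default to Background:100,
  ColdFixed:23, HotFixed:18, Random:1000 — the magnitudes of the class
  structure the pipeline is designed to resolve. Fixed trajectories draw
  a uniform gain time within their block; Random trajectories are drawn
  uniformly from the eligible (non-fixed, non-background, non-zero)
  pattern set, which maximizes classifier coverage rather than imitating
  any particular gain/loss process. SNP fraction 0.48 (matching a
  filtered call set roughly half SNPs), InDels 1–6 bp. Alternatively,
  per-condition per-base per-generation rates can drive the counts
  (binomial draws over L×G trials, a configurable fraction fixing);
  realized counts recover the configured rate within binomial error.
  Placement options: uniform, region-restricted, one-variant-per-gene
  (for clean hotspot fixtures), a forced n-variant hotspot gene, and a
  CpG weighting that multiplies the sampling weight of intergenic CG
  positions (10× in tests) to emulate methylation-associated mutation
  pressure. INFO annotations are drawn well inside the pass region of
  the hard filters.
* **Growth.** Re-plating series (6 cold / 10 hot events) with interval
  length set by a fixed number of doublings per interval (17, so ~100
  cold and ~170 hot generations over the series), exponential growth at
  the condition's Td, multiplicative lognormal OD noise (σ = 0.05), and
  an optional linear Td drift (default −30% across the cold series,
  emulating gradual adaptation; 0 for hot). With zero noise the
  doubling-time estimator inverts the generator exactly.

What the simulator does **not** emulate: read-level data (no FASTQ,
coverage or sequencing-error model — the pipeline starts at called
variants), linkage between variants, selection dynamics (classes are
planted, not evolved), within-sample polymorphism (calls are clonal
presence/absence, not allele frequencies), and realistic gene length or
GO-term distributions. Passing recovery tests therefore demonstrates the
correctness of the analysis code on its defined contract, not the
biological fidelity of any upstream caller.

## Numerical and design notes

* Percentages are emitted with explicit denominators; undefined
  percentages are `None`, never 0.
* A hotspot tie at exactly z = 2.575 is not flagged (strict inequality).
* Fisher two-sided ties use a 1e-7 relative tolerance on point masses,
  the convention shared by the major implementations.
* BH for k-mers corrects within each k-length family by default since
  each family answers a separate question; a global scope is one flag
  away.
* Multi-allelic sites collapse to one presence/absence record (any
  alternate allele → 1), consistent with the binary haplotype coding.
* Exhaustive JT permutation uses distinct group assignments
  (multinomial, not n!), keeping small-sample p-values exact; Monte-Carlo
  fallbacks take an explicit seed (default 10⁴ permutations).
* Determinism: one config seed spawns independent child generators per
  stage (genome / variants / growth); identical configs produce
  byte-identical output files.

## Known limitations

* The classifier treats the sample series as the experiment's ordering;
  it does not model sampling noise within a time point (a single
  miscalled sample turns a fixed trajectory into Random — by design, as
  fixation is defined by exactness).
* GO enrichment performs no DAG propagation; terms are taken as
  annotated.
* The k-mer scan is forward-strand; non-palindromic k-mer results are
  strand-convention-dependent.
* `doubling_time` assumes a constant inoculum per interval and a linear
  OD-to-cell calibration over the measured range.
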