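# Methods

## Coordinate model

All internal coordinates are 0-based half-open (BED convention); VCF-style
1-based positions are converted at the I/O boundary. Interval collections
are sorted and disjoint with base-set semantics: adjacent (touching)
intervals merge in unions. Chromosome-name dialects (`chr1` vs `1`) are
preserved as read; mixing dialects within one comparison raises, because a
silent mismatch is the classic zero-overlap bug.

A panel keeps per-gene structure: overlapping targets of the *same* gene are
merged on load, while a base shared by two genes counts once in panel-level
totals and once per gene in per-gene statistics. Disease-gene tables that
list one gene under several conditions therefore never double-count panel
bases.

The evaluation region for concordance is built by padding every target by a
configurable `pad_bp` (default 8, capturing essential splice sites and
proximal intronic bases), union-merging, then intersecting with the
high-confidence track. Padding is applied before merging; the order only
matters for targets closer than twice the pad, and the padded-then-merged
convention is the one recorded here.

## Callability

A base is callable when its *qualifying depth* is ≥ `min_depth` (default 20,
inclusive: a base at exactly 20× is callable). Qualifying depth counts
aligned read bases with base quality ≥ 20 from mapped, primary,
non-supplementary reads with mapping quality ≥ 20. Duplicate-flagged reads
are excluded by default; post-processed alignments mark duplicates but
whether callability should count them is a policy choice, so it is
configurable (`exclude_duplicates`). Overlapping mate pairs double-count by
default (simple pileup semantics, which keeps the per-base oracle trivial);
`count_overlapping_mates_once` switches to fragment counting. Deletions
within reads contribute no qualifying base. Pileup extraction is delegated
to pysam's `count_coverage` with a read callback implementing the filters;
plain SAM or unindexed BAM input is sorted and indexed into a temporary
directory first.

Per-gene callability across samples is the mean of per-sample percentages
with a normal-approximation 95 % CI, mean ± 1.96·SD/√n (SD with ddof = 1),
truncated to [0, 100]; with n = 1 the CI collapses to the point value. The
normal approximation is the simplest defensible choice for a cross-sample
CI of a percentage and reproduces the degenerate `100 (100–100)` rows of
fully covered genes exactly. Gap regions are maximal runs of consecutive
sub-threshold bases within a gene's target intervals — a run cannot bridge a
break in the target, and a single callable base splits two runs. Reports
carry both BED coordinates and 1-based inclusive display coordinates.

Panel summaries report the qualifying mean depth over panel bases and the
percentage of bases at or above each auxiliary threshold (default 10× and
20×), with the same CI rule across samples. Mean depth computed from a
depth TSV is whatever the TSV contains; when the toolkit computes depth
itself it is qualifying depth, and a raw (unfiltered) mean can be obtained
by zeroing the quality thresholds.

Formatting follows validation-table convention: one decimal place, with
values that round to 100.0 printed as `100`.

## Concordance

Matching is exact on normalized (chrom, pos, ref, alt); genotype concordance
is not evaluated — allele-level matching is the minimal faithful reading of
comparing "variant calls" to a benchmark set. Normalization left-aligns and
parsimony-trims: remove the shared allele suffix (pulling in the preceding
reference base whenever an allele would empty, which simultaneously shifts
indels left through repeat tracts), then remove the shared prefix while both
alleles keep at least one base. The operation is idempotent and is verified
in tests against an independent string-diff oracle. Classification refuses
unnormalized input (when given a reference accessor) and multiallelic
records; split those upstream. MNPs are kept whole and classed as "other",
since callers emit decomposable records and no decomposition policy is
assumed. Filtered (non-PASS) query records are excluded by default — a
filtered record did not count as called — with `include_filtered` to
override.

TP/FP/FN are variant-site counts; TN is a base count: evaluation-region
bases occupied by no TP/FP/FN site of the class under consideration. Under
the default `span` occupancy a site occupies its reference footprint
(`len(ref)` bases — 1 for an SNV or insertion, 1 + deleted length for a
deletion); inserted bases exist only on the alternate haplotype and never
displace a reference-base TN. This footprint rule reproduces the class-wise
TN bookkeeping of published panel benchmarks exactly; a `one`-base-per-site
alternative is provided. MCC's numerator and radicand are computed in exact
integer arithmetic before a single floating square root, so no precision is
lost at TN ≈ 5·10⁵.

Ts/Tv counts A↔G and C↔T SNVs as transitions and everything else as
transversions; a zero transversion count raises an undefined-statistic
signal rather than returning a number, as do empty denominators in
sensitivity/precision and zero marginals in MCC.

Haplotype-aware matching (vcfeval/hap.py-style local replay) is **not**
implemented; complex representation differences that normalization cannot
reconcile will score as FP+FN pairs. This is a recorded limitation.

## Sample QC

The IQR screen excludes samples with total reads strictly above
Q3 + 1.5·IQR or strictly below Q1 − 1.5·IQR, with quartiles by linear
interpolation between order statistics (the common spreadsheet default; the
estimator is not specified by convention, so the simulator plants outliers
far enough from the fences that tests are estimator-robust). With IQR = 0
the fences collapse to the common value and the strict inequalities exclude
nothing. Re-running the screen on the kept subset can exclude further
samples — the rule is deliberately not idempotent, and this is asserted as a
property, not "fixed". Threshold inclusion excludes samples strictly below
the minimum percentage, so a sample exactly at the boundary is kept.

## Synthetic data

The simulator emulates the features of capture-panel data the analysis
modules are sensitive to, with every generated quantity recorded in a
`SimulationTruth` oracle.

- **Reference and panel:** genes of exons with exactly controlled GC content
  (round(gc·length) G/C bases), separated by intronic/flanking sequence at
  45 % GC; 15-base adenine homopolymer runs are embedded (with a non-A
  anchor base) so call-set simulation can place deletions in the hardest
  context for short-read indel calling.
- **Depth:** per-base negative binomial around mean_depth × gc_factor ×
  mappability. Capture data are overdispersed relative to Poisson, hence
  the negative binomial; the dispersion (size) parameter defaults to 8,
  giving SD ≈ 37 at 100× — visibly noisy but far from gap-inducing. GC
  dropout is a step penalty (default 0.15) outside a [0.25, 0.65] GC
  window rather than a fitted dome: the phenomenon is a known dropout of
  high-GC and low-mappability exons, and the step keeps analytic
  expectations exact. Exons engineered with mappability ≈ 0.02 have mean
  depth ≈ 2, where the negative-binomial upper tail beyond 20× is
  negligible, so they are guaranteed whole-exon gaps (the titin-like
  dropout pattern).
- **Aligned reads:** plain SAM over the panel with per-read mapping quality,
  per-base qualities, duplicate flags and occasional deletion CIGARs; the
  intended qualifying depth is computed directly from the emitted read set
  and is the oracle for the pileup path.
- **Call sets:** sites are placed with enough clearance that spans never
  overlap, making ledger-derived confusion counts exact. SNV alternates are
  drawn with transition odds 3.5 (the coding-region Ts/Tv regime); indels
  are 1–10 bp and constructed normalized-by-construction (the last
  removed/inserted base differs from the anchor, so neither trimming nor
  left-shifting applies). The benchmark preset reproduces the published
  evaluation composition: a 522,763 bp region, 245 shared SNVs, 4 shared
  1-bp indels (three deletions, one insertion), one missed deletion placed
  immediately before a homopolymer run, and — in the NextSeq-like variant —
  one marginal false-positive SNV annotated QD = 2.1.
- **Cohort statistics:** baseline read counts from a narrow lognormal
  (σ_log = 0.08) truncated at ±1.5 σ_log, so the baseline has bounded
  support safely inside the Tukey fences; planted outliers are multiplied
  by 3.0 (inflation) or 0.2 (deflation). Generation verifies with an
  independently implemented quartile oracle that exactly the planted
  samples breach the fences, with ≥ 10 % of the IQR to spare, and raises
  otherwise — so a cohort that could make "exactly k excluded" ambiguous is
  never emitted. Small cohorts (≲ 20) may be rejected because the sampled
  IQR is too noisy to guarantee the margin; use larger cohorts.

Determinism: every generator draws from `numpy.random.default_rng` seeded
from the configuration seed (sub-generators use distinct `SeedSequence`
streams), and outputs are byte-identical for a fixed seed and config.

What the simulator does **not** model: read-sequence errors (no FASTQ, no
base-error or alignment-artifact models), probe thermodynamics, library
complexity, genotypes, and truth-set representation ambiguity beyond what
normalization handles. Passing tests therefore demonstrate the statistical
machinery is correct on data matching its assumptions — not that a real
assay will achieve any particular callability or concordance, which depend
on wet-lab performance the toolkit only measures.

## Problem sizes

The test suite and the acceptance script run at desk scale by design: a
five-gene, ~2.5 kb default panel; 10 kb randomized profiles for per-base
oracle checks; 100 randomized seeds for the concordance oracle; one ~523 kb
contig for the benchmark-shaped evaluation; 252-sample cohorts; 2,000 SNVs
for Ts/Tv recovery. These sizes make every check exact or tightly bounded
while keeping the whole suite in seconds.

## Known limitations

- Exact allele matching only (no haplotype-aware comparison).
- Gene structure comes from BED labels; no transcript models, no liftover.
- The CI is a normal approximation; with very few samples a t-based or
  bootstrap interval would be wider.
- The depth TSV path trusts its input to already be qualifying depth.
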