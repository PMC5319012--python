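# Methods

## Problem and model

A cassette exon (or, more generally, any meta-exon) can be included or
skipped in mature transcripts. RNA-seq measures this two ways: reads
spanning splice junctions, and read coverage along the exon body.
`aseview` tests both signals independently per gene, per unordered pair
of sample conditions, and per meta-exon, and reports candidates backed
by either or both.

**Coordinates.** Everything internal is 0-based half-open; GTF
(1-based inclusive) and STAR `SJ.out.tab` (1-based intron first/last
base) convert at the I/O boundary. A junction is identified by its
intron `(chrom, donor_end, acceptor_start)`, where `donor_end` is the
half-open end of the upstream exon — so STAR's intron `1001..2000`
becomes `[1000, 2000)`. The "donor"/"acceptor" field names follow the
plus-strand genomic-left/right convention; strand is consulted only
where it matters (alternative donor vs acceptor labels, sense/antisense
overlap classes).

**Meta-exons** merge transitively overlapping exons into the interval
from the minimum member start to the maximum member end. Book-ended
exons (`[0,100)` and `[100,200)`) share zero bases and are kept apart,
so "overlap" always means at least one common base. After isoform
pre-selection, one *exon group* per meta-exon of the selected isoforms
is the unit of ratio testing.

## PSI path

Per sample, `PSI = incl / (incl + excl)` on size-factor-adjusted
junction counts; the value is undefined (not zero) when the denominator
is zero, and undefined samples are excluded from means and tests rather
than imputed — a zero-denominator PSI carries no information. Inclusion
is measured from a **single junction** abutting the meta-exon
(acceptor at its start or donor at its end): terminal exons only ever
have one supporting junction, and exons connected to multiple neighbors
would otherwise contribute imbalanced neighboring-junction counts.
Exclusion junctions must span the meta-exon strictly (the intron
contains it and is larger than it).

All inclusion × exclusion combinations are scored; the pair with the
largest absolute difference in condition mean PSI wins. Ties break on
larger total adjusted count, then lexicographically smallest junction
coordinates, making the choice deterministic. When the winning pair
involves a junction absent from the annotation, the best pair among
fully annotated junctions is reported alongside, so users can judge
whether the call depends on a novel junction. Novel junctions can also
be materialized for display as *incomplete isoforms*: two exon stubs of
`flank` bases (default 50; any positive value works, since the isoform
is only a reduced representation) ending at the donor and starting at
the acceptor, clipped to the gene span.

The p-value is a Welch (unequal-variance) two-sample t-test on the
per-sample PSI values between the two conditions, undefined with fewer
than two defined samples in either group. When both groups are exactly
constant the t statistic is undefined; we define p = 1 for equal means
and p = 0 otherwise, which keeps degenerate noise-free fixtures
well-behaved.

## Coverage-ratio path

With `m_c(p)` the mean adjusted coverage of condition `c` at base `p`,
the ratio `r(p) = m_A(p) / (m_A(p) + m_B(p))` is ~0.5 wherever the two
conditions express the locus equally, regardless of absolute coverage
level. The test compares the defined per-base ratios over the target
exon group against the per-group mean ratios of the remaining groups
(one value per group) with the same Welch t-test; `delta_ratio` is the
absolute difference of the two sample means. The comparison is
inherently two-condition; multi-condition projects iterate over all
unordered condition pairs. The result is flagged untestable with fewer
than two remaining groups or fewer than two defined target bases.

Because the background sample has one value per group (typically a
handful), its degrees of freedom are small; in practice this makes the
test conservative for constitutive targets (their background includes
the deviating cassette group, inflating background variance), which is
the desired direction for error control.

## Isoform pre-selection

A transcript is kept iff every one of its exons has, in at least one
condition, at least `min_frac` (default 0.7) of bases with mean
adjusted coverage ≥ `min_depth` (default 5). Requiring only one
condition keeps condition-specific isoforms; requiring every exon
removes isoforms with unexpressed exons that would dilute the exon
groups. If all transcripts fail, the best-scoring one is retained so
the gene always has a scaffold.

## Normalization

Size factors use the median-of-ratios estimator on per-meta-exon
coverage sums: reference = per-region geometric mean across samples
(regions with any zero excluded), factor = median ratio to the
reference, then rescaled to geometric mean 1 so factors are
identifiable. Counts and coverage are divided by the factor.
Externally supplied factors (e.g. from a DEXSeq analysis) are accepted
via the project file and used verbatim. Whether the summaries come from
whole-genome bins or gene regions was a genuinely open choice; we use
the meta-exons of the annotated genes at hand, which suffices for the
estimator's median to be taken over dozens of regions in any realistic
annotation.

## Thresholds and ranking

Defaults: p ≤ 0.05 and effect ≥ 0.1 (for ΔΨ and delta-ratio alike),
`min_depth` 5, `min_frac` 0.7 — all CLI-overridable. The 0.1 effect
floor reflects that inclusion changes below ~15% are generally weak,
marginal calls. Candidates are sorted by their smallest p-value; no
multiple-testing correction is applied to the ranking (a
Benjamini-Hochberg column is emitted for information only). Only
exon-skipping candidates supported by *both* paths are highlighted on
the meta-exon track: other event classes are more prone to false
positives when unexpressed isoforms are in play.

Event classes: `exon_skipping` when the two junctions share their
outer anchor, the inclusion lands on the target, and the exclusion
skips exactly the target meta-exon; `alt_donor` / `alt_acceptor` when
the junctions share exactly one splice site (donor side oriented by
strand); `other` otherwise.

## Tissue specificity

The per-feature score is the tau index,
`tau = sum_i (1 - x_i / x_max) / (n - 1)`, on non-negative per-tissue
expression: 0 for uniform, 1 for one-hot, scale-invariant, undefined
for all-zero features. Tau was chosen as the standard specificity index
with exactly this 0–1 semantics; it is a declared formula of this
package, and scores on external atlases (e.g. GTEx) depend on that
atlas's processing.

## Synthetic data

The simulator emulates the pipeline's inputs with controlled truth: a
gene of `n_exons` equal exons (default 5 × 150 bp, 300 bp introns) with
one internal cassette exon, an inclusion isoform and a skipping
isoform, optionally an overlapping antisense transcript. Per sample
with library factor `l`: junction totals `N ~ Poisson(depth·l)`
(default depth 200, matching a well-covered gene in a standard bulk
library), inclusion counts `~ Binomial(N, PSI)` with exclusion the
complement of the upstream draw (the downstream inclusion junction
draws independently), constitutive junctions draw their own totals, and
exonic coverage is Poisson around `depth·l` (cassette: `depth·PSI·l`).
The `binomial` noise mode fixes totals at their means for noise-free
expectations. Defaults — 3 samples per condition, PSI 0.8 vs 0.3 —
are the study conditions used throughout the tests and the acceptance
script. All draws flow through one `numpy.random.default_rng(seed)`.

What the simulator does **not** emulate: read-length effects and
junction-overhang filters, positional coverage bias, mapping ambiguity,
overdispersion beyond Poisson, partially included (alternative 5'/3')
exons, and expression of off-target genes. Passing tests therefore show
correctness of the statistical machinery under the stated generative
model, not performance on real libraries.

## Plotting

Quartile bands use linear-interpolation percentiles (pinned so vector
output is reproducible). Introns are compressed to a fixed 60-unit plot
width by default (exonic bases are 1 unit each); `to_scale` is
available. Undefined ratio bases render as gaps, not zeros. SVG output
is byte-stable for identical inputs: the matplotlib hash salt is pinned
and timestamps suppressed.

## Numerical and scale choices

Simulation-based checks use 500 seeds for PSI recovery, 200 for
ratio-test calibration and 100 for null control — enough for the rates
being asserted to have standard errors well under the margins tested,
while the whole suite stays interactive (seconds). Junctions with zero
counts in every sample are dropped at merge since they cannot affect
any PSI. Junction files with undefined strand get their strand from the
matching annotated intron, or from the unique gene span containing
them; junctions matching no gene keep undefined strand and act only as
novel junctions.

## Known limitations

* Intron retention is not called (the exclusion/inclusion pair logic
  has no junction evidence for retention).
* The PSI estimate from the argmax pair is slightly optimistic under
  noise (selection bias of a maximum); at the default depth this bias
  is an order of magnitude below the 0.1 effect threshold.
* The ratio-test background treats groups as exchangeable; genes with
  several true events in one condition pair weaken the background.
* Exon groups are equated with meta-exons of the selected isoforms;
  finer exonic-part granularity (DEXSeq-style counting bins) is not
  modeled.
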