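# Methods

This note documents the models, conventions and numerical choices behind
`trfbin`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinates and annotation parsing

All internal coordinates are 0-based half-open on the forward genomic
strand; GTF output is 1-based inclusive. tRNAscan-SE tabular rows are
1-based inclusive with begin > end encoding the minus strand; both the
classic 9-column and the note-extended 10-column dialects are accepted,
with the pseudogene flag read from the note column. The table carries no
gene identifier, so the sequence name is used as `gene_id` when it
annotates a single tRNA (the common case for per-locus annotations) and
`<name>.trna<N>` otherwise.

The exclusion filter removes pseudogenes, selenocysteine tRNAs and
intron-containing tRNAs before binning. This keeps every retained gene's
annotated span equal to its mature sequence, so no intron splicing is
modeled downstream.

## Clover-leaf landmarks

With a secondary-structure string (tRNAscan `>`/`<` or dot-bracket), the
D-, anticodon- and T-loops are the unpaired runs enclosed between an
opening and a closing arm, in 5′→3′ order; spacers and the variable
region sit between a closing and an opening arm and are ignored. Without
a structure string, canonical geometry is assumed: 7-bp acceptor stem,
D-loop at mature positions 14–21, a 7-nt anticodon loop at 33–39
(anticodon at 34–36), T-loop at 54–60 (1-based). A consistency check
requires the anticodon inside the inferred anticodon loop. The mature 3′
end is taken as annotated; the post-transcriptionally added CCA is not
modeled, and the discriminator base is treated as mature, so the 3-Pre
bin starts immediately after the annotated 3′ end.

## Bin construction

Seven bins of width *w* (default 15 nt) are anchored per gene: the Pre
bins flush against the mature boundaries on the precursor side, the
5tRF/3tRF bins flush on the mature side, and the loop bins centered on
the loop midpoints with odd remainders shifted one base toward 5′. A Pre
bin is emitted only when at least *w* nt of flank are available (default
search flank 30 nt per side — precursor leaders and trailers are short,
and 30 nt accommodates any sweep size up to 30); a loop bin only when it
fits inside the mature span. All anchoring is strand-aware. One bin per
structural landmark (rather than tiled windows) keeps at most one bin
per region label per gene, which is what makes "a tRF" synonymous with
"a labeled bin".

## Read assignment and counting

Alignments are consumed from SAM/BAM; only primary mapped records are
counted. Each read is assigned to at most one bin: the bin with maximal
overlap of the aligned span, requiring at least 10 nt of overlap (a
majority of a 15-nt bin), ties broken by smaller bin start then
lexicographic bin id, and, by default, restricted to same-strand bins.
There is no fractional counting; the published per-bin counting semantics
are not specified at the overlap-rule level, so this rule is a documented
choice. Library sizes record mapped primary reads per sample (assigned
totals are kept alongside).

The bundled exact-match mapper exists so synthetic fixtures need no
external aligner: a read is located by exact substring search on both
strands, a unique hit produces one alignment, and ambiguous (multi-hit)
reads are discarded and counted rather than assigned arbitrarily —
ambiguity across near-identical isoacceptor copies must not produce
double counts. It is not a general-purpose aligner.

## Expression filter, normalization and testing

A bin is *expressed* with strictly more than 100 reads in at least 3
samples. TMM normalization follows the standard definition: reference =
sample whose upper-quartile count fraction is closest to the mean of
those fractions; bins zero in either member of a pair are dropped; 30 %
two-sided trim on M, 5 % on A (by rank); factor = 2 to the
precision-weighted mean of the surviving M with inverse asymptotic
binomial variance weights; factors rescaled to geometric mean 1. The
implementation is checked in the tests against an independently coded
direct-formula oracle.

Differential abundance uses a two-sided Fisher exact test on counts
pooled within each group, against library sizes pooled after TMM scaling
(rounded to integers; a flag switches to raw library sizes). The log2
fold change uses pooled count fractions with a +0.5 continuity offset to
avoid infinities at zero. Benjamini–Hochberg q-values are computed across
bins per contrast, but the headline significance gate is the raw
p < 0.05, with q reported alongside. Replicates are pooled within groups;
no dispersion estimation or GLM design matrices are implemented.

**Known limitation — overdispersion.** A pooled-count exact test is exact
only under count-sampling (binomial/Poisson-like) noise. When counts are
biologically overdispersed between replicates, pooled Fisher tests are
anticonservative: at pooled counts in the thousands, a dispersion of 0.1
makes the null rejection rate far exceed the nominal level. The
differential-recovery and bin-size-sweep checks in the test suite are
therefore run in the sampling-noise regime (dispersion 10⁻⁶, i.e.
technical-replicate-like variability); passing them demonstrates that the
binning/counting/normalization/testing chain recovers planted effects,
not that pooled Fisher testing is calibrated for biologically variable
replicates. For the latter, a dispersion-aware count model would be
required and is out of scope.

Sex-bias classification is deliberately non-statistical: a tRF is
"Female biased" iff its count is strictly higher in the female library of
every strain, "Male biased" for the mirror pattern, otherwise
"inconsistent". Cross-strain means per sex are reported as plain
(unnormalized) means of the values given; the classification itself is
invariant to any positive per-strain depth factor applied to both sexes.

## Multivariate stage

Mutual information between two profiles is estimated from the Spearman
rank correlation ρ under a Gaussian-copula model: raw
MI = −½ ln(1 − ρ²), reported on the normalized scale
1 − exp(−2 MI) = ρ², which lies in [0, 1], equals 1 on the diagonal and
is invariant under strictly monotone transforms. The estimator uses
average ranks (no discretization); |ρ| is clipped at 1 − 10⁻¹² before the
logarithm. Constant profiles have undefined correlation and raise.

PCA centers bins across samples and decomposes the centered matrix by
SVD; the sign of each component is fixed so its loading vector sums to a
non-negative value. Hierarchical clustering uses Ward linkage on
Euclidean distances (the pipeline passes log2(CPM + 1) profiles; counts
span several orders of magnitude). Trees serialize to Newick with merge
heights halved so leaf-to-leaf path distance equals the cophenetic
distance; leaf names are single-quoted because bin ids contain ':'. Two
trees over the same leaves (male vs female clusterings) are compared by
Pearson correlation of cophenetic distances and by the fraction of leaf
pairs with concordant co-membership at k = 2..4 cuts; the tanglegram
itself is exported as the two Newick files plus these statistics, with no
graphical rendering.

## Synthetic data generator

The generator emulates a genome-wide tRF profiling experiment. Defaults
are the study conditions of a five-strain sex comparison: 984 tRNA genes
with 109 exclusion-flagged (≈60 % pseudogene, 20 % SeC, 20 % intron, the
intron set drawn from Tyr/Ile/Leu isotypes), one female and one male
library per strain, and a 16-tRF source plan (4 female-biased, 12
male-biased) at published-scale mean counts.

Each gene is a random mature sequence of 72–76 nt carrying the canonical
geometry exactly (anticodon placed at 34–36; a matching structure string
is emitted). A 71-nt mature cannot host the canonical T-loop at 54–60
plus a full 3′ acceptor arm, so 72 nt is the lower bound. Genes sit on
individual contigs on random strands with 30-nt flanks; a configurable
near-edge fraction receives a short flank to exercise Pre-bin dropping.
Unless the duplicate-isoacceptor stress flag is set, sequences are
re-drawn until every k-mer at the minimum read length is unique
genome-wide (strand-collapsed), so the exact-match mapper is unambiguous.

Counts per (source tRF, sample) are negative binomial with the RNA-seq
parameterization (variance = μ + φμ²; default φ = 0.1, the conventional
scale for bulk RNA-seq-like overdispersion). Reads are exact genomic
subsequences: the 5′ end uniform within ±2 nt of the bin's
transcriptional start, length uniform in 15–21 nt but truncated so the 3′
end also stays within 2 nt of the bin end. Keeping both fragment ends
near the bin boundaries models imprecise biogenesis while guaranteeing
that the source bin retains maximal overlap under the assignment rule —
adjacent anchor bins can overlap by up to 9 nt, so an unbounded 21-nt
fragment from a 15-nt bin would otherwise be credited to a neighbor.
Background reads are Poisson-distributed uniform genomic fragments on
random strands. Every emission is recorded in a truth table, giving the
exact-recovery identity tested in the suite (background 0 ⇒ count matrix
equals drawn counts).

What the generator does **not** model: sequencing errors, adapters,
quality-score variation, CCA tailing, tRNA halves (30–35 nt), intron
splicing, or mechanistic treatment effects (treatments are abundance
shifts only). Passing tests on this generator therefore demonstrate
pipeline correctness — coordinate arithmetic, assignment, normalization,
statistics — not robustness to alignment artifacts or base-call noise in
real libraries.

## Problem sizes used in the checks

The acceptance-level checks run at sizes chosen to exercise the published
inventory arithmetic at full scale (984 genes / 109 flagged / 875
retained; 875 × 7 = 6,125 bins) while keeping simulation-based checks
compact: differential recovery uses 16 source tRFs (4 differential at
4-fold, mean ≥ 500; 12 null) with 3 replicates per group over 20 seeds;
the bin-size sweep uses 10 genes with precursor-derived differential
fragments. The sweep fixture uses precursor (3-Pre/5-Pre) tRFs — which
also dominate the expressed set in real data — because their reads are
captured whole at every bin size the 30-nt flank accommodates and are
cleanly lost when the bin exceeds the flank, so the 15-nt optimum follows
from the smallest-window tie-break rather than from fragile tie/split
behavior of re-centered loop bins.

## Error handling conventions

Invalid configuration (overlapping contrast groups, missing paths,
duplicate sample ids, zero library sizes) raises `ValidationError`; parse
problems name the offending line; a sample sharing no nonzero bins with
the TMM reference raises `DegenerateSampleError`; a simulation plan
naming an unconstructed bin raises `PlanError`. The CLI maps validation
errors to exit code 1 and runtime errors to 2.
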