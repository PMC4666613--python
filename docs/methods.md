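# Methods

This note records the models, conventions and numerical choices the
package implements, what the synthetic-data generator does and does
not emulate, and the known limitations of the simplified components.

## Coordinates and formats

All internal coordinates are 0-based half-open; strand `.` means
unstranded and is treated as `+` wherever an orientation is needed
(peak sets are typically unstranded).  The single place a conversion
happens is the SAM boundary, where 1-based positions become 0-based
starts.  A SAM mapping quality of 255 ("unavailable") is mapped to 0
so that the MAPQ > 20 uniqueness filter fails safe.  Overlap between
half-open intervals requires at least `min_bp` (default 1) shared
bases; adjacent intervals do not overlap.

## Consensus quantification

Reads are placed on the consensus library by exact k-mer seeding
(non-overlapping seeds of `seed_k` = 16 bp, so any read with fewer
mismatches than seeds retains an exact seed) followed by ungapped
extension under a mismatch budget (default 5).  This is a surrogate
for a production short-read aligner: no gaps, no base qualities, no
scoring matrix.  Ties across classes are resolved deterministically
to the lexicographically smallest class id at mapq 0; a unique best
placement gets mapq 42; otherwise mapq = min(42, 7·gap) where gap is
the best-vs-second-best mismatch difference.  Multi-mapped (mapq 0)
reads still count toward their assigned class for quantification —
consensus-level counts are family aggregates, where best-hit
assignment is the convention — while the MAPQ filter is reserved for
genomic element profiles, where uniqueness matters.

RPKM uses the *total* number of reads in the library (mapped or not)
as its denominator; SAM inputs should therefore include unmapped
records, or the caller should pass the known total.  Fold enrichment
is the RPKM ratio ChIP/Input with a pseudo-RPKM of 0.01 added to both
terms to guard zero-control classes (negligible against the
expression floor).  The tissue-expression filter (RPKM > 10) is
applied to the *control* (Input) library: Input approximates the
tissue's sequence abundance independent of the immunoprecipitation.
Whether the ratio is computed on RPKM or raw counts is irrelevant
when both libraries are sequenced to the same depth; RPKM is used so
unequal depths are handled.

Because the ChIP library's size includes the excess reads pulled into
enriched classes, the fold-change expectation for a class planted at
factor e is e·S/Σ where Σ > S grows with the total enriched fraction
of the genome.  With the generator defaults (repeats ≈ 3% of the toy
genome, a single 7-fold class) this renormalization shifts the
expectation by under 4%, well inside the counting-noise band the
recovery tests use; in a real genome the shift is smaller still.

## Peak landscape

Peak position is the interval midpoint (the summit surrogate
available in BED3); classification is an exclusive, promoter-first
partition: promoter if the midpoint is within ±2 kb of any TSS, else
intragenic if inside any gene span, else intergenic.  Profiles count
each read once, in the bin containing its midpoint, and report reads
per base so bins of different genomic width are comparable.  Metagene
and element profiles scale the body to a fixed number of bins
(default 100) with fixed 50 bp flank bins and reverse minus-strand
regions before averaging.  Anchored matrices use a ±3 kb window at
50 bp bins; a read midpoint exactly on the anchor falls in bin
n_bins/2.  Row clustering normalizes each row by its own maximum
(zero rows untouched) so shape rather than total signal drives the
clusters, then runs Euclidean k-means with 100 restarts at a fixed
seed; K is a user parameter (default 2 for element heat plots:
bound vs unbound).  Display order is (cluster, descending row sum).
Subsampling for depth matching is uniform without replacement and
deterministic per seed.

## Motif scanning and E-values

A degenerate IUPAC consensus matches a window when every position's
base belongs to the code's set; reverse-strand hits are reported at
forward-strand offsets.  PWM scoring adds a pseudocount of 0.01 per
cell (then renormalizes) before taking log₂ odds against the
background (uniform by default), and integerizes scores at 0.01 bits.
The null distribution of the integerized window score is computed
exactly by convolving per-position score distributions; scanning uses
the same integer matrix, so per-position p-values P(score ≥ s) are
exact for the integerized score (enumeration-verified for width 8).
Coarsening to 0.01 bits changes tail probabilities by far less than
any threshold in use.

The per-sequence p-value treats the m scanned positions (both
strands) as independent draws: p_seq = 1 − (1 − p_best)^m, the
single-motif case of a MAST-style combined p-value; the E-value is
p_seq times the number of sequences searched and sequences with
E < 10 are flagged.  Limitation: only the best hit enters p_seq, so a
sequence with four strong sites and one with a single equally strong
site have the same p_best and are separated only by their scan sizes
m.  In particular a chance perfect consensus match in a short
background sequence can out-rank the multi-site class; combining the
top-k hit p-values (QFAST) would resolve this but is out of scope.
Tandem detection is separate and explicit: the largest run of
same-strand hits with start-to-start gaps ≤ 30 bp (the gap default is
exposed; field data suggests tandem arrays are tightly spaced), with
a flag for whether the run lies wholly within the 5' quarter of the
sequence (fraction exposed).  Cluster-wise motif enrichment uses the
exact two-sided Fisher/hypergeometric p with a Haldane-corrected
(+0.5 per cell on zeros) odds ratio.

## Two-group differential test

The test is a deliberate simplification of negative-binomial models
(DESeq-style): pooling counts across replicates, the feature's pooled
count n splits between the groups Binomial(n, π) under the null with
π the het share of the summed library sizes; the two-sided p-value
sums all outcome probabilities no larger than the observed one
("minlike").  The pmf is evaluated on a window of ±20 standard
deviations around the mean (always extended to contain the observed
count); truncated mass is below 1e-20.  The test is exact for pure
counting noise but has no dispersion parameter, so it is
anticonservative under biological replicate variability — output
headers carry this caveat, and results on real replicated data should
be read as liberal.  Fold changes are ratios of group-mean per-million
rates with a pseudo-rate of 0.5; the default direction is het/wt (up-
regulation in mutants reads as fold > 1), with wt/het available.
Benjamini–Hochberg adjustment is the standard step-up
q_(i) = min_{j≥i} p_(j)·m/j capped at 1.

The null-calibration study (in the acceptance suite and script) draws
per-feature means log-uniformly over 500–5000 expected counts per
sample (wt n = 3, het n = 4, equal library sizes, Poisson noise).
The lower edge is set by the test's own discreteness: the exact
test's size converges to the nominal level from below and is within
a 3-SE band of 0.05 (at 100,000 feature-tests) only once pooled
counts exceed a few thousand, so the calibration uses well-expressed
features — which is also where a count-based test is scientifically
trusted.  This validates the test's exactness, not its robustness to
overdispersion, which the simulation deliberately omits.

## Synthetic-data generator

The generator is the package's test bed and defines the conditions
the pipeline is validated under: 6 repeat classes of 400–800 bp, one
class (`LTR01`) carrying 4 tandem copies of the Myb-like consensus
`AACTGYCW` in its 5' quarter (spacers 0–12 bp, so the array reads as
tandem under the 30 bp gap rule); 10 genomic copies per class at 2%
per-base divergence, separated by 20 kb random flanks (repeats ≈ 3%
of the genome, keeping the ChIP renormalization bias small, as in a
real genome); 8 genes, the first with its TSS inside a motif-bearing
instance to emulate an element acting as an alternative promoter;
ChIP enrichment 7 on the motif class; RNA het/wt multiplier 1.33 on
the motif class only (only elements with the binding sites respond to
regulator dosage); 100,000 single-end, error-free 50 bp reads per
library.  Reads are drawn by segment weights over valid start
positions, so in-class read counts are exactly binomial with known
expectation — the oracle the recovery tests use.  Every stream
derives from one master seed (identical config + seed gives
byte-identical outputs).

What the generator does **not** emulate, and what passing tests
therefore do not show: sequencing errors and quality strings,
paired-end structure, indels, LTR/internal-region architecture of
real ERVK elements, non-uniform genomic background (GC bias,
mappability), overdispersed biological replicates, and peak-caller
behaviour (peaks are emitted from truth, not called from signal).
Recovery of planted parameters demonstrates the correctness of the
analysis arithmetic, not robustness to these real-data features.

## Degenerate inputs and tie-breaks

Empty alignment sets give zero tracks/matrices; zero-length gene
spans are skipped with a log line; fraction-bound 0 yields only
promoter peaks; features with zero pooled count get p = 1; zero rows
in clustering are left unnormalized; equal-fold classes keep a stable
(mergesort) order; E-value ties order by sequence id.
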