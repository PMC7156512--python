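# Methods

This note records the models and procedures implemented in `loopevo`, the
parameters that matter, the numerical conventions, and what the synthetic
fixture does and does not establish about real data.

## Coordinates and input conventions

All internal coordinates are 0-based, half-open (BED convention); summits
are absolute 0-based positions. narrowPeak summits come from the column-10
offset; broadPeak records carry no summit, so the interval midpoint stands
in for it. Merging peaks follows `bedtools merge` defaults (distance 0,
book-ended intervals merge); the merged summit is the centroid of
constituent summits rounded half-to-even (a declared convention — the
centroid's rounding is otherwise undefined), and the merged signal is the
maximum, so the "strongest peak" selection downstream remains conservative.
UCSC chains are parsed to absolute block pairs on the + strand of both
genomes; minus-strand query coordinates are reflected through `qSize`
(reflection is an involution, which the tests exercise). Loops are
intrachromosomal by definition here; interchromosomal BEDPE records are
skipped with a logged count.

## Cross-species mapping

A feature intersecting several chains is mapped through the single chain
whose aligned blocks cover the most of its bases (ties: higher chain score,
then lower chain id), and the mapped interval spans the images of its
aligned bases within that chain only — the liftOver "longest subalignment"
convention. Any aligned base (≥ 1 bp) makes a feature mappable; no minimum
aligned fraction is imposed, but `mapped_fraction` is reported so callers
can impose one. Summits are propagated only when the summit base itself is
aligned. Gain/loss labels are sequence-level parsimony: mappable to the
target genome ⇒ orthologous; otherwise mappable to ≥ 1 outgroup ⇒ lost on
the target branch; otherwise gained on the query branch. "Present in an
outgroup" means chain-mappability of the locus, not occupancy. Labeling
without outgroups is an error, not a default.

## CTCF landscape

Union sets are built per reference genome from native peaks plus peaks
mapped in from the other species; occupancy labels use ≥ 1 bp interval
overlap between mapped and native peaks. Peaks that fail to cross-map are
retained as species-specific, non-orthologous records, so the union
partitions exactly into shared / query-specific / target-specific with no
double counting.

A TE is associated with a CTCF site when the repeat comes within ±50 bp of
the peak summit; among several candidates the repeat containing the summit
wins, then the nearest edge, then the longest interval. The
simple/low-complexity/structural-RNA repeat families are excluded at load
time — they are not transposons.

The random-background expectation places, per trial, N intervals with
exactly the TE-derived size multiset uniformly over the genome (chromosome
drawn proportional to length; nothing masked — the simplest null consistent
with the procedure; a per-record chromosome pin is available) and reports
the median overlap count over 1000 trials plus observed/median fold. When
the median is 0 the mean is the fallback denominator; 0/0 is reported as a
missing-fold flag rather than a number.

## Motif scanning

Scores are plain log-odds against background base frequencies (uniform 0.25
by default; configurable — "equilibrium frequencies" admits several
readings and uniform is the reproducible one). Both strands are scored at
every offset; per offset the better strand is reported, '+' on ties.
Windows containing any N are unscored rather than given an arbitrary
penalty. Hits require score strictly above the threshold (0 by default);
a log-odds of 1 is treated as the theoretical binding threshold when
interpreting window maxima. Anchor orientation takes each anchor's best
positive-scoring hit within ±50 bp of the peak summit; left-anchor '+' with
right-anchor '−' is convergent (inward-pointing).

## TE enrichment statistics

*Binomial*: for every TE type with ≥ 1 bound copy, p = P[X ≥ n_bound] for
X ~ Binomial(n_copies, r) with r the genome-wide fraction of TE copies
carrying a CTCF summit, computed per cell type. Bonferroni multiplies by
the number of *tested* types. Significance requires all three of:
adjusted p ≤ 1e-4, n_bound ≥ 25, and binding rate ≥ 1% within the type.

*Permutation*: TE type labels are shuffled within six TSS-distance bins
(default edges 0, 1 kb, 5 kb, 10 kb, 50 kb, 500 kb, ∞; configurable — six
bins are prescribed, the edges are this package's choice), so each bin's
label multiset is preserved exactly and insertion biases relative to genes
survive the shuffle. The empirical p uses the add-one estimator
(1 + #{perm ≥ obs}) / (B + 1), which can never be 0. Two consequences are
worth stating plainly:

1. **Power floor.** After Bonferroni over m types the smallest attainable
   adjusted p is m/(B+1); clearing the 1e-4 gate therefore requires
   B ≥ m·10^4 − 1. Recovery runs on the 12-type fixture use B = 150,000
   (floor 8×10^−5); the default B = 10,000 matches common practice but
   cannot, by construction, certify significance at this gate for m ≥ 2.
2. **Conservatism.** On tied count data the add-one p is discrete and
   super-uniform (P(p ≤ α) ≤ α). Calibration is therefore diagnosed with
   tie-randomized ranks (n_gt + U·(n_eq + 1))/(B + 1), which are exactly
   uniform under exchangeability (`randomized_calibration_p`); the reported
   p is separately checked to be valid, never anti-conservative.

*Motif-words*: normalized counts follow
nocc = occ · (Σocc · L / 10^6)^(−1) with the scale factor exactly as
written; species-specificity requires nocc ≥ 8 in the specific species and
odds ratio ≥ 2 in magnitude (the two-fold boundary counts). Words absent in
one species keep an infinite log-odds-ratio sentinel — no pseudocount is
injected into the definition. Per-type Fisher tests compare
specific/shared word counts in a TE type against all other bound words
(one-sided, Bonferroni, significance at 1e-40).

*Ages*: age = (d/100)/r. Defaults r = 2.2e-9 substitutions/base/year
(mammalian consensus) for the query genome and 2.4e-9 for the target,
derived as 2.2e-9 × 1.091 = 2.4002e-9 ≈ 2.4e-9 — the "9.1% faster rodent
clock" reading; the alternative reading (dividing by 0.091) is off by an
order of magnitude and is not used. Consensus divergence is an average
conformation, so individual ages are inexact; distributions are the
intended use.

## Loop conservation

Loops without a CTCF peak at both anchors are dropped; each surviving
anchor is replaced by its strongest overlapping peak (signal ties: leftmost
peak), carrying the summit. Classification maps both anchors at their
trimmed coordinates (no extension); the optional `flank` symmetrically
extends the *mapped* anchors before overlap testing. Class C requires one
single target loop whose two anchors account for the two mapped query
anchors, and C takes precedence over B2 whenever such a coherent loop
exists. For B2, "different loops" is implemented as "no single target loop
matches both anchors", with no additional disjointness constraint on the
two loops. Enlarging the flank is monotone: classes can only move toward
more conserved (B1→B2→C, N1B→N1A), which the acceptance suite checks
against a brute-force enumerator. Within-species comparisons run the same
classifier over identity chains, so non-orthologous classes cannot occur
between cells of one genome.

For cell/species-specific loop classes, a TE insertion counts toward the
TE-derived total only when it overlaps an anchor unique to the query cell:
the non-matching anchor for B1/N1A, any anchor lacking a same-loop match
for B2/N1B, and any anchor for C/B0/N0.

A loop corresponds to a whole TAD when its anchors overlap the ±10 kb
windows around the TAD's X and Y boundary coordinates of the same cell;
a single-boundary variant is available behind `boundary_only`. Group
contrasts (loop strength by class, TE age by class, etc.) use Wilcoxon
rank-sum over all group pairs, one- or two-sided as requested.

## Expression analysis

Anchor-to-gene distances are measured from the anchor midpoint to the
nearest TSS (one furthest-5′ TSS per gene; equidistant ties go to the
smaller coordinate) — note the deliberate asymmetry with TE association,
which uses the peak summit. Promoter/enhancer roles come from per-sample
min–max-scaled maximal H3K4me3/H3K4me1 signal with thresholds defaulting
to 0.5/0.5 (the source thresholds are not published; these are explicit and
configurable). ΔTPM = |TPM(q) − TPM(t)| for the proximal-anchor gene of
loops passing the ≤ 1 kb / ≥ 3 kb distance filters; conserved means class
C, variable means every other class; the test is the one-sided rank-sum
(independent samples, not signed-rank), variable > conserved, within each
TE status; one observation per loop by default with a gene-deduplication
option. Signal profiles average track values over even-length windows
centered on anchor summits, optionally flipping records whose right half
carries more signal and dividing by the mean profile of 1000 seeded random
windows; chromosome-edge records contribute only their covered columns.

## The synthetic fixture

The generator builds the chain first — alternating aligned blocks and
one-sided gaps per chromosome — and then places features relative to that
alignment, so every loop's intended conservation class holds by
construction (the generator re-classifies its own output and raises on any
mismatch). Defaults: two genomes × 2 chromosomes × 2 Mb; 12 TE types, 2 of
them CTCF-enriched at 10× the 2% null binding rate (200 vs 150 copies);
300 query-cell loops with class mix C 25%, B2 10%, B1 15%, B0 15%,
N1A 10%, N1B 15%, N0 10%; loop anchors are 200-bp peaks with a planted
20-bp motif ('+' on left anchors, '−' on right, so planted loops are
convergent); ~30% of loops carry a TE over the counting anchor; each
planted gene sits ≤ 1 kb from its loop's left anchor and ≥ 3 kb from the
right. TE divergences are age × rate × 100, so age recovery is exact by
construction. Expression: base TPM uniform 30–80, per-cell noise SD 5, and
a +20 TPM shift in the target cell for genes of variable loops.

With independent per-cell noise the observable ΔTPM contrast is not the
raw shift Δ but the folded-normal contrast E|Δ + ε| − E|ε| with
ε ~ N(0, √2·5) (≈ 14.4 for Δ = 20); the manifest stores this analytic
value and recovery is asserted against it within two standard errors.

Sequence content is i.i.d. uniform outside planted motifs. The fixture
therefore does *not* emulate real base composition, CpG decay, repeat
nesting, alignment error, ChIP-seq noise, or Hi-C contact noise: passing
tests establish correctness of the statistics and bookkeeping on planted
ground truth, not performance on real genomes. The null calibration table
draws per-type copy numbers log-uniformly (100–2000), mirroring the wide
abundance spread of real repeat annotations.

## Problem sizes and numerics

The default test and acceptance runs use the 2×2 Mb fixture (≈ 2000 TE
copies, 300 + ~200 loops, ~800 peaks per genome), 1000 background trials,
1000-permutation calibration over 20 seeds, and 150,000-permutation
recovery runs — sizes chosen so the full suite completes in a couple of
minutes while keeping every Monte-Carlo check comfortably powered. Binomial
tails use the regularized incomplete beta (scipy) and are verified against
60-digit Decimal summation to < 1e-9 relative error. All stochastic
components take explicit seeds and are bit-reproducible; fixture generation
is byte-identical for identical (config, seed).

## Known limitations

Raw ChIA-PET read processing, reciprocal-best chain construction, Hi-C
matrix processing and TAD calling are out of scope — their outputs are
consumed as inputs. The published CTCF position weight matrix is not
redistributed; `PWM.from_file` accepts MEME-minimal or tab log-odds
matrices, and the package's own deterministic CTCF-like matrix
(`default_ctcf_pwm`) serves fixtures and examples. The gain/loss labeler is
hard-configured for the two-ingroup/outgroups topology rather than
arbitrary trees. FIMO-style p-value calibration and dinucleotide
backgrounds are intentionally absent: downstream analyses consume raw
log-odds.
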