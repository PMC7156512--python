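# loopevo

Comparative analysis of transposable-element (TE)-derived CTCF binding and
chromatin-loop conservation across cell types and species.

Many mammalian chromatin loops are anchored by convergent CTCF motifs, and a
sizeable share of CTCF-binding sites sits inside TE insertions that carried a
CTCF motif into the genome. `loopevo` implements the statistics needed to ask,
for any pair of cells or genomes: which TE families distributed CTCF sites,
how old those insertions are, which loops are conserved between cells and
species, and whether loop turnover tracks gene-expression change. It is aimed
at regulatory-genomics researchers working from standard file formats
(narrowPeak/broadPeak, RepeatMasker BED, BEDPE loop calls, UCSC chains,
FASTA, bedGraph/wiggle signal, TPM tables).

## What it computes

**Cross-species mapping** (`loopevo.crossmap`). Features are lifted through
UCSC chain files with liftOver semantics: a peak spanning several chains is
mapped through the single chain covering most of its bases, and the mapped
interval spans the images of its aligned bases only. A parsimony labeler
classifies each site as *orthologous*, *lost* on the target branch, or
*gained* on the query branch, using outgroup mappability.

**TE enrichment** (`loopevo.enrichment`). For each TE type with at least one
CTCF-bound copy, an upper-tail binomial test against the genome-wide binding
rate, and a permutation test that shuffles TE type labels within six
TSS-distance bins (preserving insertion biases) with the add-one empirical
p-value (1 + #{perm ≥ obs}) / (B + 1). A type is significantly enriched only
if Bonferroni-adjusted p ≤ 1e-4, ≥ 25 bound copies, and binding rate ≥ 1%.

**Motif-word statistics** (`loopevo.enrichment`, `loopevo.motif`). PWM
log-odds scanning of both strands in overlapping 20-bp windows; distinct
bound 20-mers ("motif-words") are normalized per species,

    nocc_ij = occ_ij · (Σ_i occ_ij · L / 10^6)^(−1),

compared by log odds ratio ln(nocc_i(query)/nocc_i(target)), called
species-specific at nocc ≥ 8 and |OR| ≥ 2, and tested per TE type by
one-sided Fisher exact tests (threshold 1e-40).

**TE ages** — age = (d / 100) / r with percent divergence d from the
RepeatMasker consensus and a substitution clock r (2.2e-9 /base/year for the
human-like genome; 2.4e-9 for the rodent-like genome, i.e. the mammalian rate
times the 9.1% rodent excess).

**Loop conservation** (`loopevo.loops`). Loops are kept only when both
anchors carry a CTCF peak, trimmed to their strongest peak, and classified
against a target loop set into seven classes: C (both anchors map onto the
two anchors of one target loop), B2 (both overlap target anchors of
different loops), B1 (one overlap), B0 (none), and N1A/N1B/N0 when one or
both anchors lie in non-orthologous sequence. Within-species comparisons use
identity chains, so N-classes arise only between genomes.

**Expression** (`loopevo.expression`). Anchors are annotated with their
nearest TSS; enhancer–promoter loops (one anchor ≤ 1 kb, the other ≥ 3 kb
from a TSS) contribute ΔTPM_i = |TPM_i(q) − TPM_i(t)| for the
promoter-proximal gene, contrasted between conserved (class C) and variable
loops with a one-sided rank-sum test, separately for TE-derived and native
loops.

**Synthetic truth** (`loopevo.simulate`). A fully planted two-genome fixture
(chains first, features placed relative to aligned blocks and gaps) with
known enriched TE types, conservation classes, ages and expression effects,
so every stage is testable without downloads.

## Worked example

```python
import collections
import loopevo as le
from loopevo.enrichment import binomial_enrichment, genome_wide_binding_rate, estimate_age

fx = le.generate("fixture/", seed=42)

# 1. classify every query-cell loop against the target cell across species
classes = le.classify_all(fx.query_loops, fx.target_loops, fx.chains_ab, flank=0)
counts = collections.Counter(c.label for c in classes.values())
print("loop conservation classes:", dict(sorted(counts.items())))

# 2. which TE types carry more CTCF peaks than the genome-wide rate predicts?
bound, copies = {}, {}
summits = {(p.interval.chrom, p.summit) for p in fx.query_peaks}
for te in fx.repeats:
    copies[te.te_type] = copies.get(te.te_type, 0) + 1
    if any(te.interval.contains(s) for c, s in summits if c == te.interval.chrom):
        bound[te.te_type] = bound.get(te.te_type, 0) + 1
rate = genome_wide_binding_rate(bound, copies)
for r in binomial_enrichment(bound, copies, rate):
    if r.significant:
        print(f"{r.te_type}: {r.n_bound}/{r.n_copies} bound "
              f"(null rate {rate:.3f}), adjusted p = {r.p_adjusted:.3g}")

# 3. age of a TE family from its divergence
d = fx.truth.te_types["TE01"]["pct_divergence"]
print(f"TE01 divergence {d:.2f}% -> {estimate_age(d, rate=2.2e-9)/1e6:.0f} My")
```

prints

```
loop conservation classes: {'B0': 45, 'B1': 45, 'B2': 30, 'C': 75, 'N0': 30, 'N1A': 30, 'N1B': 45}
TE01: 93/248 bound (null rate 0.105), adjusted p = 2.63e-28
TE02: 91/242 bound (null rate 0.105), adjusted p = 8.1e-28
TE01 divergence 2.20% -> 10 My
```

The recovered class counts equal the planted mix exactly (75 of 300 loops
fully conserved, i.e. the 25% planted rate), and the two TE types planted
with tenfold CTCF binding — and only those — pass the three-criteria
significance gate.

A `loopevo` console command wraps the common shell workflows
(`loopevo simulate-fixture`, `merge-peaks`, `map`, `scan`, `enrich`, `age`,
`classify`); see `loopevo --help`.

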