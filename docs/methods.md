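# Methods

This note documents the models, parameter choices and numerical conventions
behind `pgclnc`, and what the synthetic-data experiments do and do not show.

## Coordinates and formats

All internal coordinates are 0-based half-open; GTF's 1-based inclusive
convention is converted only at the I/O boundary, so interval lengths are
always `end - start`. FASTQ qualities are Phred+33 only and anything else is
rejected rather than silently misdecoded. Matrices are TSV with a `#unit=`
header line tagging counts vs FPKM; duplicate feature ids are an error
because the correlation steps join on them.

## Read filtering

Three rules, all strict inequalities, reasons assigned in the fixed order
adapter → quality → N:

| rule | threshold | default |
|---|---|---|
| adapter-polluted bases | more than `max_adapter_bases` | 5 |
| bases below `quality_floor` (Phred) | more than `max_low_quality_fraction` | Q19 / 0.15 |
| N bases | more than `max_n_fraction` | 0.05 |

"Bases below 19 accounting for more than 15%" is read as: the fraction of
bases with Phred < 19 strictly exceeds 0.15 — the boundary case (exactly 15%)
is kept, matching the "more than" phrasing of every rule. N bases contribute
to the low-quality fraction only through their recorded quality score, which
keeps the three rules independent and independently testable.

Adapter pollution is overlap-based: reads are scanned 3′-end-first against
the adapter's 5′ end (the read-through geometry of short-insert Smart-seq2
libraries), accepting the longest overlap of ≥ 6 nt with ≥ 90% identity;
full internal exact copies of the adapter also count, each base once. The
original study's Perl filter is not published, so this overlap definition is
this package's documented stand-in. The default adapter is the TruSeq read-1
prefix; it is a parameter, not an assumption.

## FPKM

`FPKM = counts * 1e9 / (spliced_length * library_size)` with the library
size taken as the within-matrix column sum, since no alignment stage exists
in this pipeline; callers may pass external mapped-fragment totals. All-zero
libraries yield all-zero columns rather than dividing by zero. Correlations
for target prediction are computed on linear FPKM with Pearson's r by
default (Spearman by option); a constant vector raises an error rather than
returning a silent zero.

## lncRNA discovery

Known matching uses a k-mer-seeded (k = 11) gapped local alignment
(match +2 / mismatch −3 / gap open −5 / extend −2, via Biopython's
`PairwiseAligner`) and calls a candidate known at identity ≥ 0.95 over
≥ 0.90 of the candidate length.

The coding filter is a transparent three-rule conjunction replacing opaque
external predictors while preserving the "must survive several independent
predictors" structure; a transcript is non-coding only if all three pass:

- longest complete ATG→stop ORF over the three forward frames < 300 nt
  (ORFs are scanned on the sense strand only — transcripts are stranded);
- ORF coverage (ORF length / spliced length) < 0.35;
- hexamer score < 0, where the score is the mean log-ratio of hexamer
  frequencies under a coding model vs a uniform background. The coding table
  is estimated once from a long pseudo-CDS drawn from a fixed, skewed codon
  usage (seeded, deterministic); both tables are pseudocounted. The
  thresholds follow common coding-potential-calculator practice and are all
  configuration-exposed.

Positional classes are assigned with precedence sense > intronic >
antisense > intergenic: same-strand exonic overlap beats containment in a
same-strand intron, which beats opposite-strand gene-body overlap. The
precedence is this package's tie rule; same-strand evidence is the stronger
signal. Category percentages are rounded half-up to one decimal and computed
against the externally supplied total rather than the category sum, so
published tallies whose categories sum above their total remain checkable.

## Target prediction

Cis: closest-boundary gap between the lncRNA span and the gene body ≤ 10 kb
(overlap counts as distance 0) on the same chromosome, and r strictly
greater than 0.9. The correlation gate applies to both cis and trans
targets; the threshold's strictness follows "larger than".

Trans: a complementarity hit is a local alignment of the lncRNA against the
reverse-complemented mRNA scoring at least (match score × min_len ×
min_identity), defaults 20 nt and 0.8; the duplex is then folded over the
best hit's spans ± 10 nt, and the pair is emitted when ΔG ≤ −20 kcal/mol and
r > 0.9. The −20 kcal/mol cutoff is a common interaction-screening default —
the study states none — and is configuration-exposed. Whether the published
0.9 threshold for trans pairs refers to expression correlation or an
alignment statistic is ambiguous in the source; it is implemented as
expression correlation, consistently with the cis rule.

### Duplex energy model

The minimum-free-energy intermolecular duplex is computed by dynamic
programming over base pairs (i, j) with i ascending on strand A and j
descending on strand B (antiparallel geometry), with no intramolecular
structure:

E = initiation (4.09 kcal/mol)
  + Σ stack energies over consecutive pairs
  + Σ loop penalties for bulges/interior loops (size-dependent, with an
    asymmetry term for interior loops, log-extrapolated beyond the table,
    total loop size capped at 30 nt).

The shipped parameter table contains the standard nearest-neighbor
Watson–Crick stack free energies at 37 °C plus package-chosen values for
G·U-containing stacks and the loop tables; it is deliberately a reduced,
self-consistent set (users may substitute a full Turner table in the same
format). The DP is exact against whatever table it is given, which is what
the tests verify: an exhaustive enumerator over every legal duplex structure
must agree with the DP on all seeded inputs up to 8 nt, and a hand-summed
helix energy must match term by term. Accessibility/opening energies and
intramolecular competition are out of scope, so absolute energies are not
comparable to RNAplex output — only the model's own optimum is claimed.

## Downstream statistics

ΔΔCt uses the arithmetic mean of the two reference Cts (equivalent to the
geometric mean of reference expression, the standard dual-reference
convention; the combination rule is not stated in the source). The control
group's mean ΔCt is the centering point, so its mean fold is 1 by
construction. The phenotype mean is computed among affected embryos by
default — consistent with pairing a ~26% affected rate with a mean near 5 —
with an all-embryo switch; a group with no affected embryos reports mean 0
with an explicit flag. The t-test is pooled-variance Student's t; ANOVA is
the classical between/within decomposition; the all-identical degenerate
case returns (0, 1) for both. The significance threshold defaults to 0.05;
the source's printed "p < 0.5" is treated as a typographical error for 0.05,
as its own figure captions mark significance at p < 0.05.

## Synthetic data: what it emulates and what it does not

The generator plants ground truth by construction rather than by labelling:

- **Genome/annotation**: one chromosome; genes in 20 kb slots separated by
  45 kb gaps (2–6 exons of 250–400 nt, introns 1–2 kb, random strand), whose
  spliced sequence is one long ORF drawn from the skewed codon model — so
  every mRNA fails the coding filter. Each lncRNA is built to satisfy its
  class definition exactly: sense lncRNAs share 30 exonic bases with their
  host's last exon; intronic lncRNAs sit strictly inside a first intron on
  the same strand; antisense lncRNAs sit inside a first intron on the
  opposite strand; intergenic lncRNAs sit mid-gap, ≥ 20 kb from every gene
  body. lncRNA sequences are redrawn until they pass the coding filter.
- **Planted pairs**: sense and intronic lncRNAs are cis-planted with their
  hosts; intergenic lncRNAs are trans-planted by embedding a 30-nt perfect
  reverse complement of their target mRNA. Three decoy kinds are planted:
  antisense lncRNAs are near their host but uncorrelated; one intergenic
  lncRNA carries a complement without correlation and a correlation without
  complement. Correct behaviour is recovering every planted pair and no
  decoy.
- **Expression**: negative-binomial counts around a log-normal latent
  (variance = μ + noise·μ²), pair members sharing one latent per cell, with
  per-cell depth factors; lncRNA baselines are scaled to 0.2× mRNA levels so
  the class contrast of real data (lower lncRNA expression) is reproduced.
  The study profiled 3 cells per group; the generator defaults to 10 cells
  because a 0.9 correlation threshold at n = 3 is nearly vacuous, while n =
  3 remains supported.
- **Reads**: 100 nt single-end (the 15%/5% fraction rules then land on
  integer base counts), each defective read violating exactly one rule —
  8 adapter bases at the 3′ end, 16 bases below Q19, or 6 Ns — and clean
  reads redrawn until they violate none.
- **qPCR/phenotypes**: target Ct shifted by −log2(planted fold) around
  stable references; phenotype groups hit the planted affected fraction and
  mean exactly in exact mode, or via Bernoulli/shifted-Poisson draws.

What passing on this data does **not** show: the generator has no sequencing
error profile, no UMI/duplication structure, no paired ends, no ambiguous
multi-class loci, no alignment/assembly noise, and its expression model is a
clean shared-latent construction — real single-cell data would lower the
pair correlations and blur the class geometry. The recovery results certify
the correctness of the rules' implementation, not their biological
sensitivity on real libraries. Dataset-level published totals (e.g. hundreds
of lncRNAs, the 1352-pair catalogue) require the deposited sequencing data
and are deliberately out of scope.

## Problem sizes and determinism

The default analysis and the acceptance script use 50 genes, 12 lncRNAs
(three per class), 10 cells and 1000 reads — sizes chosen so every stage,
including the duplex oracle comparisons, completes in seconds while every
rule is still exercised at least three times. All generators are pure
functions of (configuration, seed); the pipeline derives per-stage
substreams from its single seed, and re-running a config reproduces
byte-identical artifacts (the manifest's config hash covers analysis
parameters, not output paths).
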