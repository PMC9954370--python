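# pgclnc

Long non-coding RNAs (lncRNAs) — transcripts longer than 200 nt with limited
protein-coding potential — are emerging regulators of germline development,
but profiling them in zebrafish primordial germ cells (PGCs) is hard: only a
handful of cells can be collected per embryo, so the analysis must run on
Smart-seq2-style single-cell libraries. `pgclnc` implements that analysis as
a tested, reusable pipeline: read quality filtering, FPKM quantification,
known/novel lncRNA identification with positional classification, cis/trans
lncRNA–mRNA target prediction (including an RNA–RNA duplex minimum-free-energy
folder), regulation-network assembly, and the downstream qPCR and phenotype
statistics. A first-class synthetic-data module generates every input with
planted ground truth, so the whole pipeline is verifiable end to end without
any sequencing download.

## The computations at the core

- **Read QC.** A read is discarded when it has more than 5 adapter-polluted
  bases (longest 3′-read / 5′-adapter overlap ≥ 6 nt at ≥ 90% identity, plus
  internal exact adapter copies), when more than 15% of bases fall below
  Phred Q19, or when more than 5% of bases are N.
- **FPKM.** FPKM_ij = counts_ij · 10⁹ / (length_i · total_j), with length_i
  the spliced transcript length and total_j the library's column sum.
- **lncRNA discovery.** Candidates matching a known-lncRNA reference (local
  alignment, identity ≥ 0.95 over ≥ 0.90 of the candidate) are *known*;
  remaining candidates ≥ 200 nt are *novel* if they survive a three-rule
  coding filter (longest ORF < 300 nt, ORF coverage < 0.35, hexamer
  log-likelihood ratio < 0), mirroring the convention of requiring several
  independent coding-potential predictors to agree. Each lncRNA gets exactly
  one positional class — sense, intronic, antisense, or intergenic — by
  overlap geometry against protein-coding annotation, with precedence
  sense > intronic > antisense > intergenic.
- **Target prediction.** *Cis*: protein-coding genes within a 10 kb window of
  the lncRNA locus whose expression correlates with it at Pearson r > 0.9
  (strict). *Trans*: lncRNA–mRNA pairs with a complementarity hit (local
  alignment of the lncRNA against the reverse-complemented mRNA), a predicted
  duplex ΔG ≤ −20 kcal/mol over the hit, and the same correlation gate. The
  duplex ΔG is a nearest-neighbor dynamic program (initiation + stack
  energies + bulge/interior-loop penalties, intermolecular pairs only) that
  is exact against its shipped parameter table; an exhaustive enumerator
  cross-checks it on small inputs.
- **Statistics.** Relative qPCR expression by 2^−ΔΔCt against the mean of the
  *ef1a*/*rpl13a* reference Cts; phenotype scoring as the percentage of
  embryos with ≥ 1 mislocalized PGC and the mean mislocalized count among
  affected embryos; Student's t (pooled variance) and one-way ANOVA;
  hypergeometric term enrichment with Benjamini–Hochberg adjustment.

## Worked example

The numbered scripts under `analysis/` run the study end to end on synthetic
data (50 genes, 12 lncRNAs, 10 cells, 1000 reads) and write their tables
under `results/`. Running them in order prints, among other things:

```
$ python analysis/02_read_qc.py
kept 700/1000; rejected 100 adapter / 100 quality / 100 N
label agreement with planted defects: 1.000

$ python analysis/04_discover_lncrnas.py
discovered 12 lncRNAs (2 known, 10 novel)
positional class accuracy vs planted truth: 1.000
published tallies recomputed: {'sense': 66.6, 'intergenic': 26.8, 'antisense': 10.2, 'intronic': 0.2}

$ python analysis/05_predict_targets.py
cis: 6 found / 6 planted; precision 1.00, recall 1.00
trans: 2 found / 2 planted; precision 1.00, recall 1.00
decoys emitted: none

$ python analysis/07_qpcr_phenotypes.py
           n_replicates  fold   sd
group
conASO                3  1.00  0.0
lnc304ASO             3  0.25  0.0
```

Reading the numbers: every planted read defect is rejected for exactly its
planted reason; all 12 lncRNAs are classified into their constructed
positional class; the four published category tallies (301/121/46/1 of 452
novel lncRNAs) reproduce the printed percentages under half-up rounding; the
cis and trans rules recover exactly the planted pairs while the planted
decoys (near-but-uncorrelated, complementary-but-uncorrelated,
correlated-but-non-complementary) are all rejected; and the ΔΔCt method
recovers the planted 4-fold knockdown exactly.

The same stages are available as a CLI (`pgclnc qc|quant|discover|targets|
network|qpcr|phenotype|run|simulate`) and as one orchestrated call,
`pgclnc.pipeline.run_pipeline`, which writes a manifest with per-stage record
counts and planted-truth recovery scores.

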