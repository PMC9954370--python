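"""Generate the synthetic study inputs with planted ground truth.

Writes a genome, GTF annotation, transcript/known-lncRNA FASTA, a noise-free
single-cell count matrix (10 cells), 1000 single-end reads with planted QC
defects, a qPCR Ct table with a planted 4-fold knockdown, grouped phenotype
counts, and the truth sidecar, all under results/data/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pgclnc import simulate
from pgclnc.formats import write_fastq, write_matrix
from pgclnc.pipeline import stage_seed

SEED = 20230672 % (2**31 - 1)
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    synth = simulate.generate_genome_annotation(
        n_genes=50, n_lnc_per_class=3, seed=stage_seed(SEED, "genome")
    )
    paths = synth.write(OUT)
    truth = synth.truth

    counts = simulate.generate_expression(
        truth, n_samples=10, noise=0.0, seed=stage_seed(SEED, "expression")
    )
    write_matrix(counts, OUT / "counts.tsv")

    reads, read_truth = simulate.generate_reads(
        synth.transcript_sequences(), counts, defect_rates=(0.1, 0.1, 0.1),
        seed=stage_seed(SEED, "reads"), n_reads=1000,
    )
    truth.planted_read_defects = read_truth.planted_read_defects
    write_fastq(reads, OUT / "reads.fastq")

    ct, qpcr_truth = simulate.generate_qpcr(
        ["conASO", "lnc304ASO"], {"conASO": 1.0, "lnc304ASO": 0.25},
        seed=stage_seed(SEED, "qpcr"),
    )
    truth.planted_fold_changes = qpcr_truth.planted_fold_changes
    ct.to_csv(OUT / "qpcr_ct.csv", index=False)

    pheno, pheno_truth = simulate.generate_phenotypes(
        {"conASO": (128, 0.05, 1.0), "lnc304ASO": (128, 0.2656, 4.88)},
        seed=stage_seed(SEED, "phenotype"), exact=True,
    )
    truth.planted_phenotype_effects = pheno_truth.planted_phenotype_effects
    pheno.to_csv(OUT / "phenotypes.csv", index=False)
    truth.to_json(OUT / "truth.json")

    print(f"genome: {len(synth.genome['chr1']):,} bp; "
          f"{len(synth.genes)} genes, {len(synth.lncrnas)} lncRNAs")
    print(f"planted: {len(truth.planted_cis_pairs)} cis pairs, "
          f"{len(truth.planted_trans_pairs)} trans pairs, "
          f"{len(truth.decoy_pairs)} decoys")
    print(f"wrote {len(paths) + 4} files under {OUT}")


if __name__ == "__main__":
    main()
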