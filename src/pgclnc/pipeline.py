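"""End-to-end orchestration: qc -> quant -> discover -> targets -> network -> stats.

A single config (YAML round-trippable) carries every stage threshold and the
run seed. In synthetic mode the pipeline first generates all inputs with
planted truth, then runs every stage and scores recovery (positional-class
accuracy, cis/trans precision and recall) into the run manifest. Per-stage
randomness flows from the one seed through fixed named offsets, so re-running
the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import read_qc, simulate
from .discovery import discover_lncrnas
from .expression import fpkm
from .formats import (
    parse_annotation,
    parse_sequences,
    read_matrix,
    write_fastq,
    write_matrix,
)
from .stats import ddct_fold_change, one_way_anova, phenotype_summary
from .targets import (
    build_network,
    cis_targets,
    network_summary,
    trans_targets,
    write_pairs_tsv,
)

logger = logging.getLogger("pgclnc")

# fixed per-stage offsets for seed substreams
_STAGE_OFFSETS = {"genome": 11, "expression": 23, "reads": 37, "qpcr": 41, "phenotype": 53}


def stage_seed(seed: int, stage: str) -> int:
    return (seed * 1009 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class SyntheticConfig:
    n_genes: int = 12
    n_lnc_per_class: int = 3
    n_known: int = 2
    n_samples: int = 10
    r_target: float = 0.98
    expression_noise: float = 0.0
    defect_rates: tuple[float, float, float] = (0.1, 0.1, 0.1)
    n_reads: int = 1000
    qpcr_groups: dict[str, float] = field(
        default_factory=lambda: {"conASO": 1.0, "lnc304ASO": 0.25}
    )
    qpcr_noise_sd: float = 0.0
    phenotype_groups: dict[str, tuple[int, float, float]] = field(
        default_factory=lambda: {"conASO": (40, 0.05, 1.0), "lnc304ASO": (40, 0.25, 5.0)}
    )
    phenotype_exact: bool = True


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "pipeline_out"
    synthetic: bool = True
    synthetic_config: SyntheticConfig = field(default_factory=SyntheticConfig)
    # real-input paths (used when synthetic is False)
    fastq: str | None = None
    counts: str | None = None
    annotation: str | None = None
    transcripts_fasta: str | None = None
    known_fasta: str | None = None
    # stage thresholds
    max_adapter_bases: int = 5
    quality_floor: int = 19
    max_low_quality_fraction: float = 0.15
    max_n_fraction: float = 0.05
    adapter_sequence: str = read_qc.TRUSEQ_ADAPTER
    min_lnc_length: int = 200
    orf_max_nt: int = 300
    orf_max_coverage: float = 0.35
    hexamer_max: float = 0.0
    window_bp: int = 10_000
    r_min: float = 0.9
    correlation_method: str = "pearson"
    energy_max: float = -20.0
    align_min_len: int = 20
    align_min_identity: float = 0.8
    qpcr_target: str = "lnc304"
    qpcr_control: str = "conASO"
    mean_among_affected: bool = True

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sc_raw = raw.pop("synthetic_config", {})
        if "defect_rates" in sc_raw:
            sc_raw["defect_rates"] = tuple(sc_raw["defect_rates"])
        if "phenotype_groups" in sc_raw:
            sc_raw["phenotype_groups"] = {
                k: tuple(v) for k, v in sc_raw["phenotype_groups"].items()
            }
        return cls(synthetic_config=SyntheticConfig(**sc_raw), **raw)

    def config_hash(self) -> str:
        # hash of the analysis parameters; output location is not provenance
        payload = asdict(self)
        payload.pop("outdir")
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _qc_thresholds(config: PipelineConfig) -> read_qc.QcThresholds:
    return read_qc.QcThresholds(
        max_adapter_bases=config.max_adapter_bases,
        quality_floor=config.quality_floor,
        max_low_quality_fraction=config.max_low_quality_fraction,
        max_n_fraction=config.max_n_fraction,
        adapter_sequence=config.adapter_sequence,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "stages": {}}
    truth: simulate.SyntheticTruth | None = None

    if config.synthetic:
        sc = config.synthetic_config
        logger.info("stage simulate: generating synthetic inputs")
        synth = simulate.generate_genome_annotation(
            n_genes=sc.n_genes,
            n_lnc_per_class=sc.n_lnc_per_class,
            seed=stage_seed(config.seed, "genome"),
            n_known=sc.n_known,
        )
        paths = synth.write(outdir / "data")
        truth = synth.truth
        counts = simulate.generate_expression(
            truth,
            n_samples=sc.n_samples,
            r_target=sc.r_target,
            noise=sc.expression_noise,
            seed=stage_seed(config.seed, "expression"),
        )
        write_matrix(counts, outdir / "data" / "counts.tsv")
        seqs = synth.transcript_sequences()
        reads, read_truth = simulate.generate_reads(
            seqs,
            counts,
            defect_rates=sc.defect_rates,
            adapter_seq=config.adapter_sequence,
            seed=stage_seed(config.seed, "reads"),
            n_reads=sc.n_reads,
        )
        truth.planted_read_defects = read_truth.planted_read_defects
        write_fastq(reads, outdir / "data" / "reads.fastq")
        ct_table, qpcr_truth = simulate.generate_qpcr(
            list(sc.qpcr_groups),
            sc.qpcr_groups,
            seed=stage_seed(config.seed, "qpcr"),
            noise_sd=sc.qpcr_noise_sd,
            target_gene=config.qpcr_target,
            control_group=config.qpcr_control,
        )
        truth.planted_fold_changes = qpcr_truth.planted_fold_changes
        ct_table.to_csv(outdir / "data" / "qpcr_ct.csv", index=False)
        pheno_table, pheno_truth = simulate.generate_phenotypes(
            sc.phenotype_groups,
            seed=stage_seed(config.seed, "phenotype"),
            exact=sc.phenotype_exact,
        )
        truth.planted_phenotype_effects = pheno_truth.planted_phenotype_effects
        pheno_table.to_csv(outdir / "data" / "phenotypes.csv", index=False)
        truth.to_json(outdir / "data" / "truth.json")
        annotation = synth.transcripts
        manifest["stages"]["simulate"] = {
            "n_genes": len(synth.genes),
            "n_lncrnas": len(synth.lncrnas),
            "n_reads": len(reads),
        }
    else:
        for name in ("fastq", "counts", "annotation", "transcripts_fasta", "known_fasta"):
            path = getattr(config, name)
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"pipeline stage inputs: missing {name} ({path})")
        reads = parse_sequences(config.fastq, "fastq")
        counts = read_matrix(config.counts)
        annotation = parse_annotation(config.annotation)
        seqs = {r.id: r.sequence for r in parse_sequences(config.transcripts_fasta, "fasta")}

    # ---- qc ----
    logger.info("stage qc: filtering %d reads", len(reads))
    kept, rejected, report = read_qc.filter_reads(reads, _qc_thresholds(config))
    write_fastq(kept, outdir / "clean_reads.fastq")
    (outdir / "qc_report.json").write_text(json.dumps(report.as_dict(), indent=1))
    manifest["stages"]["qc"] = report.as_dict()

    # ---- quant ----
    lengths = {t.transcript_id: t.spliced_length for t in annotation}
    fpkm_matrix = fpkm(counts, lengths)
    write_matrix(fpkm_matrix, outdir / "fpkm.tsv")
    manifest["stages"]["quant"] = {
        "n_features": len(fpkm_matrix.feature_ids),
        "n_samples": len(fpkm_matrix.sample_ids),
    }

    # ---- discover ----
    coding = [t for t in annotation if t.biotype == "protein_coding"]
    candidates = [t for t in annotation if t.biotype != "protein_coding"]
    if config.synthetic:
        reference = synth.known_reference
    else:
        reference = parse_sequences(config.known_fasta, "fasta")
    records = discover_lncrnas(
        candidates,
        seqs,
        reference,
        coding,
        min_length=config.min_lnc_length,
        orf_max_nt=config.orf_max_nt,
        orf_max_coverage=config.orf_max_coverage,
        hexamer_max=config.hexamer_max,
    )
    rows = [
        "\t".join(
            [
                r.transcript.transcript_id,
                r.status,
                r.positional_class or "",
                str(r.coding.longest_orf_nt if r.coding else ""),
                f"{r.coding.orf_coverage:.4f}" if r.coding else "",
                f"{r.coding.hexamer_score:.4f}" if r.coding else "",
            ]
        )
        for r in records
    ]
    (outdir / "lncrna.tsv").write_text(
        "transcript_id\tstatus\tclass\tlongest_orf_nt\torf_coverage\thexamer_score\n"
        + "\n".join(rows)
        + ("\n" if rows else "")
    )
    manifest["stages"]["discover"] = {
        "n_known": sum(1 for r in records if r.status == "known"),
        "n_novel": sum(1 for r in records if r.status == "novel"),
    }

    # ---- targets ----
    lnc_models = {r.transcript.transcript_id: r.transcript for r in records}
    lnc_loci = {tid: t.span for tid, t in lnc_models.items()}
    gene_loci = {t.gene_id: t.span for t in coding}
    cis = cis_targets(
        lnc_loci,
        gene_loci,
        fpkm_matrix,
        window_bp=config.window_bp,
        r_min=config.r_min,
        method=config.correlation_method,
    )
    lnc_seqs = {tid: seqs[tid] for tid in lnc_models}
    mrna_seqs = {t.gene_id: seqs[t.transcript_id] for t in coding}
    trans = trans_targets(
        lnc_seqs,
        mrna_seqs,
        fpkm_matrix,
        energy_max=config.energy_max,
        r_min=config.r_min,
        method=config.correlation_method,
        min_len=config.align_min_len,
        min_identity=config.align_min_identity,
    )
    pairs = cis + trans
    write_pairs_tsv(pairs, outdir / "target_pairs.tsv")
    manifest["stages"]["targets"] = {"n_cis": len(cis), "n_trans": len(trans)}

    # ---- network ----
    net = build_network(pairs)
    import networkx as nx

    nx.write_gml(net, outdir / "network.gml")
    manifest["stages"]["network"] = network_summary(net)

    # ---- stats ----
    if config.synthetic:
        folds = ddct_fold_change(ct_table, config.qpcr_target, config.qpcr_control)
        folds.to_csv(outdir / "qpcr_folds.csv", float_format="%.6g")
        summary = phenotype_summary(pheno_table, among_affected=config.mean_among_affected)
        groups = [
            sub["mislocalized_count"].to_numpy(dtype=float)
            for _, sub in pheno_table.groupby("group", sort=False)
        ]
        F, p = one_way_anova(groups)
        summary["anova_F"] = F
        summary["anova_p"] = p
        summary.to_csv(outdir / "phenotype_summary.csv", float_format="%.6g")
        manifest["stages"]["stats"] = {
            "folds": {g: float(folds.loc[g, "fold"]) for g in folds.index},
            "anova_F": F,
            "anova_p": p,
        }

    if truth is not None:
        manifest["recovery"] = score_recovery(records, cis, trans, truth)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _precision_recall(found: set, planted: set) -> dict[str, float]:
    tp = len(found & planted)
    precision = tp / len(found) if found else 1.0
    recall = tp / len(planted) if planted else 1.0
    return {"precision": precision, "recall": recall, "n_found": len(found), "n_planted": len(planted)}


def score_recovery(records, cis, trans, truth: simulate.SyntheticTruth) -> dict:
    """Compare discovered classes and predicted pairs with the planted truth."""
    classes = {
        r.transcript.transcript_id: r.positional_class for r in records
    }
    n_correct = sum(
        1 for lnc, cls in truth.planted_class.items() if classes.get(lnc) == cls
    )
    cis_found = {(p.lnc_id, p.gene_id) for p in cis}
    trans_found = {(p.lnc_id, p.gene_id) for p in trans}
    decoys_emitted = [
        (lnc, gene, kind)
        for lnc, gene, kind in truth.decoy_pairs
        if (lnc, gene) in cis_found | trans_found
    ]
    return {
        "class_accuracy": n_correct / len(truth.planted_class) if truth.planted_class else 1.0,
        "n_lnc_discovered": len(classes),
        "cis": _precision_recall(cis_found, set(map(tuple, truth.planted_cis_pairs))),
        "trans": _precision_recall(trans_found, set(map(tuple, truth.planted_trans_pairs))),
        "n_decoys_planted": len(truth.decoy_pairs),
        "decoys_emitted": decoys_emitted,
    }
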