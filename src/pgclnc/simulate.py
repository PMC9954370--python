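"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study's data shapes: a genome with annotated
protein-coding genes and lncRNAs constructed to satisfy one positional class
each; Smart-seq2-like single-cell count matrices where planted lncRNA-mRNA
pairs share a latent log-normal signal (expected Pearson r above the 0.9
prediction threshold) and decoys are independent; single-end reads where each
defective read violates exactly one QC rule by construction; Ct tables with
planted fold changes around stable reference genes; and grouped per-embryo
mislocalized-PGC counts. Every generator is a pure function of its
configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import read_qc
from .discovery import classify_coding_potential, classify_position, random_coding_sequence
from .formats import (
    ExpressionMatrix,
    GenomicInterval,
    SequenceRecord,
    TranscriptModel,
    extract_transcript_sequences,
    reverse_complement,
    write_annotation,
    write_fasta,
)

# Chromosome layout: each gene occupies a 20 kb slot followed by a 45 kb gap,
# so mid-gap lncRNAs sit >= 20 kb from every gene body (the intergenic rule).
GENE_SLOT = 20_000
GENE_GAP = 45_000
CHROM_MARGIN = 25_000
CHROM = "chr1"

SENSE_OVERLAP = 30  # exonic bases shared by a sense lncRNA and its host
TRANS_MATCH_LEN = 30  # embedded reverse-complement block for trans pairs

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SizingError(ValueError):
    """Requested features do not fit the generated chromosome/gene set."""


@dataclass
class SyntheticTruth:
    """Planted ground truth shared across generators."""

    planted_class: dict[str, str] = field(default_factory=dict)
    planted_cis_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_trans_pairs: list[tuple[str, str]] = field(default_factory=list)
    decoy_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    known_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    lnc_ids: list[str] = field(default_factory=list)
    planted_read_defects: dict[str, str] = field(default_factory=dict)
    planted_fold_changes: dict[str, float] = field(default_factory=dict)
    planted_phenotype_effects: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        truth = cls()
        for key, value in raw.items():
            if key.endswith("_pairs"):
                value = [tuple(v) for v in value]
            if key == "planted_phenotype_effects":
                value = {k: tuple(v) for k, v in value.items()}
            setattr(truth, key, value)
        return truth


@dataclass
class SyntheticGenome:
    genome: dict[str, str]
    genes: list[TranscriptModel]
    lncrnas: list[TranscriptModel]
    known_reference: list[SequenceRecord]
    truth: SyntheticTruth

    @property
    def transcripts(self) -> list[TranscriptModel]:
        return self.genes + self.lncrnas

    def transcript_sequences(self) -> dict[str, str]:
        return extract_transcript_sequences(self.genome, self.transcripts)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "annotation.gtf",
            "transcripts": outdir / "transcripts.fa",
            "known_reference": outdir / "known_lncrna.fa",
            "truth": outdir / "truth.json",
        }
        write_fasta(
            [SequenceRecord(id=c, sequence=s) for c, s in self.genome.items()],
            paths["genome"],
        )
        write_annotation(self.transcripts, paths["annotation"])
        seqs = self.transcript_sequences()
        write_fasta(
            [SequenceRecord(id=t, sequence=s) for t, s in seqs.items()],
            paths["transcripts"],
        )
        write_fasta(self.known_reference, paths["known_reference"])
        self.truth.to_json(paths["truth"])
        return paths


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _write_seq(chrom: bytearray, start: int, seq: str, strand: str) -> None:
    if strand == "-":
        seq = reverse_complement(seq)
    chrom[start : start + len(seq)] = seq.encode()


def _make_gene(
    rng: np.random.Generator, gene_index: int, base: int
) -> tuple[TranscriptModel, str]:
    """A protein-coding gene whose spliced sequence is one long ORF."""
    n_exons = int(rng.integers(2, 7))
    exon_lens = [int(rng.integers(250, 401)) for _ in range(n_exons)]
    # keep the spliced length a codon multiple so the whole transcript is CDS
    total = sum(exon_lens)
    exon_lens[-1] -= total % 3
    intron_lens = [int(rng.integers(1000, 2001)) for _ in range(n_exons - 1)]
    strand = "+" if rng.random() < 0.5 else "-"
    exons = []
    pos = base
    for k, length in enumerate(exon_lens):
        exons.append(GenomicInterval(CHROM, pos, pos + length, strand))
        pos += length
        if k < n_exons - 1:
            pos += intron_lens[k]
    gene_id = f"gene{gene_index:04d}"
    model = TranscriptModel(
        transcript_id=gene_id, gene_id=gene_id, biotype="protein_coding", exons=exons
    )
    spliced = random_coding_sequence(model.spliced_length // 3, rng)
    return model, spliced


def _spliced_pieces(model: TranscriptModel, spliced: str) -> list[tuple[GenomicInterval, str]]:
    """Pair each exon with its slice of the 5'->3' spliced sequence."""
    order = model.exons if model.strand == "+" else list(reversed(model.exons))
    pieces = []
    offset = 0
    for exon in order:
        pieces.append((exon, spliced[offset : offset + len(exon)]))
        offset += len(exon)
    return pieces


def _noncoding_sequence(
    rng: np.random.Generator,
    length: int,
    embed: tuple[int, str] | None = None,
    max_tries: int = 80,
) -> str:
    """Random sequence passing the three-rule coding filter.

    `embed` plants a fixed block (position, sequence) kept across redraws.
    """
    for _ in range(max_tries):
        seq = _random_dna(rng, length)
        if embed is not None:
            pos, block = embed
            seq = seq[:pos] + block + seq[pos + len(block) :]
        if classify_coding_potential(seq).is_noncoding:
            return seq
    raise RuntimeError("could not draw a filter-passing non-coding sequence")


def generate_genome_annotation(
    n_genes: int = 12,
    n_lnc_per_class: int = 3,
    seed: int = 1,
    n_known: int = 2,
) -> SyntheticGenome:
    """Genome, annotation and lncRNAs satisfying each positional class exactly.

    Also plants cis pairs (sense and intronic lncRNAs with their host genes),
    trans pairs (intergenic lncRNAs carrying an embedded reverse complement of
    a distal mRNA window), and two decoys: a complement-without-correlation
    pair and a correlation-without-complement pair (both on the last
    intergenic lncRNA, when more than one exists).
    """
    if n_genes < 4:
        raise SizingError("need at least 4 genes")
    if n_lnc_per_class < 0:
        raise SizingError("n_lnc_per_class must be >= 0")
    k = n_lnc_per_class
    n_trans = max(k - 1, min(k, 1))
    if n_genes < 3 * k + n_trans:
        raise SizingError(
            f"{n_genes} genes cannot host {k} lncRNAs per class; "
            f"need at least {3 * k + n_trans}"
        )
    rng = np.random.default_rng(seed)
    chrom_len = 2 * CHROM_MARGIN + n_genes * (GENE_SLOT + GENE_GAP)
    chrom = bytearray(_random_dna(rng, chrom_len).encode())

    genes: list[TranscriptModel] = []
    gene_seqs: dict[str, str] = {}
    for g in range(n_genes):
        base = CHROM_MARGIN + g * (GENE_SLOT + GENE_GAP)
        model, spliced = _make_gene(rng, g, base)
        for exon, piece in _spliced_pieces(model, spliced):
            _write_seq(chrom, exon.start, piece, model.strand)
        genes.append(model)
        gene_seqs[model.gene_id] = spliced

    truth = SyntheticTruth(gene_ids=[g.gene_id for g in genes])
    lncrnas: list[TranscriptModel] = []
    genome_view = {CHROM: chrom.decode()}

    def add_lnc(lnc_id: str, interval: GenomicInterval, cls: str) -> TranscriptModel:
        model = TranscriptModel(
            transcript_id=lnc_id, gene_id=lnc_id, biotype="lncRNA", exons=[interval]
        )
        lncrnas.append(model)
        truth.planted_class[lnc_id] = cls
        truth.lnc_ids.append(lnc_id)
        return model

    # sense: shares SENSE_OVERLAP exonic bases with the host's 3'-most genomic
    # exon and extends beyond the gene body, same strand
    for i in range(k):
        host = genes[i]
        length = int(rng.integers(300, 601))
        last_exon = host.exons[-1]
        start = last_exon.end - SENSE_OVERLAP
        interval = GenomicInterval(CHROM, start, start + length, host.strand)
        lnc_id = f"lnc_sense{i:02d}"
        # only the part outside the exon is freely writable; redraw it until
        # the extracted transcript passes the coding filter
        for _ in range(80):
            tail = _random_dna(rng, length - SENSE_OVERLAP)
            chrom[last_exon.end : last_exon.end + len(tail)] = tail.encode()
            seq = chrom[interval.start : interval.end].decode()
            if host.strand == "-":
                seq = reverse_complement(seq)
            if classify_coding_potential(seq).is_noncoding:
                break
        else:
            raise RuntimeError("could not draw a filter-passing sense lncRNA")
        add_lnc(lnc_id, interval, "sense")
        truth.planted_cis_pairs.append((lnc_id, host.gene_id))

    # intronic: fully inside the host's first intron, same strand
    for i in range(k):
        host = genes[k + i]
        intron = host.introns()[0]
        length = int(rng.integers(300, min(601, len(intron) - 100)))
        start = intron.start + 50
        interval = GenomicInterval(CHROM, start, start + length, host.strand)
        seq = _noncoding_sequence(rng, length)
        _write_seq(chrom, start, seq, host.strand)
        lnc_id = f"lnc_intronic{i:02d}"
        add_lnc(lnc_id, interval, "intronic")
        truth.planted_cis_pairs.append((lnc_id, host.gene_id))

    # antisense: inside the host's first intron on the opposite strand, so the
    # only relationship to any gene is opposite-strand gene-body overlap;
    # left uncorrelated, making it the near-but-independent cis decoy
    for i in range(k):
        host = genes[2 * k + i]
        intron = host.introns()[0]
        length = int(rng.integers(300, min(601, len(intron) - 100)))
        start = intron.start + 50
        strand = "-" if host.strand == "+" else "+"
        interval = GenomicInterval(CHROM, start, start + length, strand)
        seq = _noncoding_sequence(rng, length)
        _write_seq(chrom, start, seq, strand)
        lnc_id = f"lnc_antisense{i:02d}"
        add_lnc(lnc_id, interval, "antisense")
        truth.decoy_pairs.append((lnc_id, host.gene_id, "proximity_only"))

    # intergenic: mid-gap, >= 20 kb from every gene body
    trans_gene_ids = [genes[3 * k + t].gene_id for t in range(n_trans)]
    for i in range(k):
        gap_index = i  # gap between gene i and gene i+1
        gap_start = CHROM_MARGIN + gap_index * (GENE_SLOT + GENE_GAP) + GENE_SLOT
        length = int(rng.integers(300, 601))
        start = gap_start + GENE_GAP // 2
        interval = GenomicInterval(CHROM, start, start + length, "+")
        lnc_id = f"lnc_intergenic{i:02d}"
        embed = None
        if i < n_trans:
            target = trans_gene_ids[i]
            window = gene_seqs[target][200 : 200 + TRANS_MATCH_LEN]
            embed = (100, reverse_complement(window))
            truth.planted_trans_pairs.append((lnc_id, target))
        elif k >= 2 and i == k - 1:
            # decoys: perfect complement to one gene without correlation, and
            # correlation with another gene without complementarity
            comp_gene = genes[(3 * k + n_trans) % n_genes].gene_id
            corr_gene = genes[(3 * k + n_trans + 1) % n_genes].gene_id
            window = gene_seqs[comp_gene][200 : 200 + TRANS_MATCH_LEN]
            embed = (100, reverse_complement(window))
            truth.decoy_pairs.append((lnc_id, comp_gene, "complement_only"))
            truth.decoy_pairs.append((lnc_id, corr_gene, "correlation_only"))
        seq = _noncoding_sequence(rng, length, embed=embed)
        _write_seq(chrom, start, seq, "+")
        add_lnc(lnc_id, interval, "intergenic")

    genome_view = {CHROM: chrom.decode()}
    result = SyntheticGenome(
        genome=genome_view,
        genes=genes,
        lncrnas=lncrnas,
        known_reference=[],
        truth=truth,
    )

    # known-lncRNA reference: slightly mutated copies of the first n_known
    # lncRNAs plus unrelated decoy entries
    seqs = result.transcript_sequences()
    reference: list[SequenceRecord] = []
    for idx, lnc in enumerate(lncrnas[:n_known]):
        seq = list(seqs[lnc.transcript_id])
        n_mut = max(1, len(seq) // 50)  # ~2% divergence
        for pos in rng.choice(len(seq), size=n_mut, replace=False):
            seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
        reference.append(SequenceRecord(id=f"ref_known{idx:02d}", sequence="".join(seq)))
        truth.known_ids.append(lnc.transcript_id)
    for d in range(3):
        reference.append(
            SequenceRecord(id=f"ref_decoy{d:02d}", sequence=_random_dna(rng, 500))
        )
    result.known_reference = reference

    # construction check: the classifier must recover every planted class
    for lnc in lncrnas:
        got = classify_position(lnc, genes)
        want = truth.planted_class[lnc.transcript_id]
        if got != want:
            raise RuntimeError(
                f"{lnc.transcript_id}: constructed as {want} but classified {got}"
            )
    return result


def generate_expression(
    truth: SyntheticTruth,
    n_samples: int = 10,
    r_target: float = 0.98,
    noise: float = 0.05,
    seed: int = 1,
    depth: float = 200.0,
) -> ExpressionMatrix:
    """Negative-binomial counts in which planted pairs share a latent signal.

    Each planted (and correlation-decoy) pair shares one log-normal latent per
    sample, making the pair's expected Pearson correlation exceed r_target;
    all other features draw independent latents (expected r ~ 0). noise is
    the negative-binomial overdispersion (variance = mu + noise * mu^2);
    noise = 0 gives deterministic rounded counts.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    if not 0.9 < r_target <= 1.0:
        raise ValueError("r_target must exceed the 0.9 prediction threshold")
    rng = np.random.default_rng(seed)
    features = list(truth.gene_ids) + list(truth.lnc_ids)

    shared: dict[str, int] = {}
    cluster = 0
    correlated = list(truth.planted_cis_pairs) + list(truth.planted_trans_pairs) + [
        (a, b) for a, b, kind in truth.decoy_pairs if kind == "correlation_only"
    ]
    for a, b in correlated:
        if a in shared:
            shared[b] = shared[a]
        elif b in shared:
            shared[a] = shared[b]
        else:
            shared[a] = shared[b] = cluster
            cluster += 1

    n_latents = cluster + sum(1 for f in features if f not in shared)
    latents = rng.normal(size=(n_latents, n_samples))
    next_free = cluster
    sigma = 1.0
    depth_factors = np.exp(rng.normal(0.0, 0.2, size=n_samples))

    rows = []
    for f in features:
        if f in shared:
            z = latents[shared[f]]
        else:
            z = latents[next_free]
            next_free += 1
        base = float(np.exp(rng.normal(np.log(depth), 0.5)))
        if f in truth.lnc_ids:
            base *= 0.2  # lncRNAs are expressed below mRNA levels
        mu = base * np.exp(sigma * z - sigma**2 / 2) * depth_factors
        if noise == 0:
            counts = np.round(mu)
        else:
            size = 1.0 / noise
            p = size / (size + mu)
            counts = rng.negative_binomial(size, p)
        rows.append(counts)
    df = pd.DataFrame(
        np.array(rows, dtype=float),
        index=features,
        columns=[f"cell{j:02d}" for j in range(n_samples)],
    )
    return ExpressionMatrix(values=df, unit="counts")


def generate_reads(
    transcripts: Mapping[str, str],
    expression: ExpressionMatrix | None,
    defect_rates: tuple[float, float, float] = (0.1, 0.1, 0.1),
    adapter_seq: str = read_qc.TRUSEQ_ADAPTER,
    seed: int = 1,
    n_reads: int = 1000,
    read_length: int = 100,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Single-end reads where each defective read violates exactly one QC rule.

    Adapter reads carry the adapter's first 8 bases at their 3' end; low-quality
    reads have just over 15% of bases below Q19; N reads just over 5% N. Clean
    reads are redrawn until they violate no rule.
    """
    if len(adapter_seq) < 6:
        raise ValueError("adapter sequence must be at least 6 nt")
    if any(r < 0 or r > 1 for r in defect_rates) or sum(defect_rates) > 1:
        raise ValueError("defect rates must be in [0, 1] and sum to at most 1")
    rng = np.random.default_rng(seed)
    ids = list(transcripts)
    usable = [t for t in ids if len(transcripts[t]) >= read_length]
    if not usable:
        raise ValueError(f"no transcript is >= {read_length} nt")
    if expression is not None:
        weights = np.array(
            [max(expression.values.loc[t].sum(), 0.0) if t in expression.values.index else 0.0
             for t in usable]
        )
        weights = weights / weights.sum() if weights.sum() > 0 else None
    else:
        weights = None

    thresholds = read_qc.QcThresholds(adapter_sequence=adapter_seq)
    n_adapter = int(round(defect_rates[0] * n_reads))
    n_quality = int(round(defect_rates[1] * n_reads))
    n_n = int(round(defect_rates[2] * n_reads))
    labels = (
        ["adapter"] * n_adapter
        + ["low_quality"] * n_quality
        + ["many_N"] * n_n
        + ["clean"] * (n_reads - n_adapter - n_quality - n_n)
    )
    rng.shuffle(labels)

    n_low = int(read_length * 0.15) + 1
    n_ns = int(read_length * 0.05) + 1

    def clean_body() -> str:
        for _ in range(100):
            t = usable[int(rng.choice(len(usable), p=weights))]
            start = int(rng.integers(0, len(transcripts[t]) - read_length + 1))
            seq = transcripts[t][start : start + read_length].replace("U", "T")
            probe = SequenceRecord(id="probe", sequence=seq)
            if read_qc.adapter_polluted_bases(probe, adapter_seq) <= thresholds.max_adapter_bases:
                return seq
        raise RuntimeError("could not draw an adapter-free read body")

    reads: list[SequenceRecord] = []
    truth = SyntheticTruth()
    for idx, label in enumerate(labels):
        rid = f"read{idx:05d}"
        seq = clean_body()
        quals = rng.integers(30, 41, size=read_length).tolist()
        if label == "adapter":
            seq = seq[: read_length - 8] + adapter_seq[:8]
        elif label == "low_quality":
            pos = rng.choice(read_length, size=n_low, replace=False)
            for p in pos:
                quals[p] = int(rng.integers(2, 16))
        elif label == "many_N":
            pos = rng.choice(read_length, size=n_ns, replace=False)
            chars = list(seq)
            for p in pos:
                chars[p] = "N"
            seq = "".join(chars)
        reads.append(SequenceRecord(id=rid, sequence=seq, qualities=quals))
        truth.planted_read_defects[rid] = label
    return reads, truth


def generate_qpcr(
    groups: Sequence[str],
    planted_fold: Mapping[str, float],
    n_reps: int = 3,
    seed: int = 1,
    noise_sd: float = 0.0,
    target_gene: str = "lnc304",
    control_group: str | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Ct table with the target shifted by -log2(fold) relative to the control.

    Reference genes ef1a and rpl13a are stable across groups; folds are
    expressed relative to the control group (whose planted fold must be 1).
    """
    control_group = control_group or groups[0]
    if abs(planted_fold.get(control_group, 1.0) - 1.0) > 1e-12:
        raise ValueError("the control group's planted fold must be 1")
    rng = np.random.default_rng(seed)
    rows = []
    baseline = {"ef1a": 20.0, "rpl13a": 22.0, target_gene: 25.0}
    for group in groups:
        fold = float(planted_fold.get(group, 1.0))
        for rep in range(1, n_reps + 1):
            for gene, base in baseline.items():
                ct = base + (0.0 if gene != target_gene else -np.log2(fold))
                if noise_sd > 0:
                    ct += float(rng.normal(0.0, noise_sd))
                rows.append(
                    {"group": group, "replicate": f"rep{rep}", "gene": gene, "ct": ct}
                )
    truth = SyntheticTruth(planted_fold_changes={g: float(planted_fold.get(g, 1.0)) for g in groups})
    return pd.DataFrame(rows), truth


def generate_phenotypes(
    group_specs: Mapping[str, tuple[int, float, float]],
    seed: int = 1,
    exact: bool = False,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Per-embryo mislocalized-PGC counts per group.

    group_specs maps group -> (n_embryos, affected_fraction,
    mean_count_among_affected). In exact mode the affected count and the mean
    among affected are hit exactly (up to integer rounding of the total);
    otherwise affectedness is Bernoulli and counts are 1 + Poisson(mean - 1).
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth = SyntheticTruth()
    for group, (n_embryos, fraction, mean_count) in group_specs.items():
        if not 0 <= fraction <= 1:
            raise ValueError("affected_fraction must be in [0, 1]")
        if n_embryos < 1:
            raise ValueError("need at least one embryo per group")
        if exact:
            n_aff = int(round(fraction * n_embryos))
            counts = np.zeros(n_embryos, dtype=int)
            if n_aff:
                total = int(round(mean_count * n_aff))
                base, extra = divmod(total, n_aff)
                counts[:n_aff] = base
                counts[:extra] += 1
        else:
            affected = rng.random(n_embryos) < fraction
            counts = np.where(
                affected, 1 + rng.poisson(max(mean_count - 1.0, 0.0), size=n_embryos), 0
            )
        for e, c in enumerate(counts):
            rows.append(
                {"group": group, "embryo": f"{group}_e{e:03d}", "mislocalized_count": int(c)}
            )
        truth.planted_phenotype_effects[group] = (float(fraction), float(mean_count))
    return pd.DataFrame(rows), truth
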