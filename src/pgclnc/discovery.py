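"""Known/novel lncRNA identification and positional classification.

A candidate transcript is *known* when it matches a reference lncRNA database
entry by gapped local alignment (k-mer seeded, k = 11) at >= 95% identity over
>= 90% of the candidate. A candidate is a *novel* lncRNA when its spliced
length is >= 200 nt and it survives a three-rule coding-potential filter —
longest ORF < 300 nt, ORF coverage < 0.35 of the transcript, and a hexamer
usage log-ratio < 0 — mirroring the practice of requiring a transcript to be
called non-coding by several independent predictors before accepting it.

Novel lncRNAs receive exactly one positional class relative to protein-coding
annotation, with precedence sense > intronic > antisense > intergenic
(same-strand evidence outranks opposite-strand evidence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from .formats import SequenceRecord, TranscriptModel

START_CODON = "ATG"
STOP_CODONS = ("TAA", "TAG", "TGA")

SEED_K = 11

ORF_MAX_NT = 300
ORF_MAX_COVERAGE = 0.35
HEXAMER_MAX_SCORE = 0.0
MIN_LNC_LENGTH = 200

POSITIONAL_CLASSES = ("sense", "intronic", "antisense", "intergenic")


@dataclass
class KnownMatch:
    reference_id: str
    identity: float
    query_coverage: float
    score: float


@dataclass
class CodingVerdict:
    longest_orf_nt: int
    orf_coverage: float
    hexamer_score: float
    orf_length_rule: bool
    orf_coverage_rule: bool
    hexamer_rule: bool

    @property
    def is_noncoding(self) -> bool:
        return self.orf_length_rule and self.orf_coverage_rule and self.hexamer_rule


@dataclass
class LncRNARecord:
    transcript: TranscriptModel
    status: str  # known | novel
    positional_class: str | None = None
    coding: CodingVerdict | None = None
    known_match: KnownMatch | None = None


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def _alignment_stats(alignment) -> tuple[float, int, int, int]:
    """(identity over alignment columns, query span, query start, query end)."""
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    qcoords = alignment.coordinates[0]
    return identity, int(qcoords[-1] - qcoords[0]), int(qcoords[0]), int(qcoords[-1])


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def match_known(
    candidates: Sequence[SequenceRecord],
    reference: Sequence[SequenceRecord],
    min_identity: float = 0.95,
    min_query_coverage: float = 0.90,
) -> tuple[list[tuple[SequenceRecord, KnownMatch]], list[SequenceRecord]]:
    """Partition candidates into (known with best match, unmatched)."""
    if not reference:
        raise ValueError("reference lncRNA set must be non-empty")
    aligner = _local_aligner()
    ref_kmers = [(ref, _kmer_set(ref.sequence.upper(), SEED_K)) for ref in reference]
    known: list[tuple[SequenceRecord, KnownMatch]] = []
    unmatched: list[SequenceRecord] = []
    for cand in candidates:
        cseq = cand.sequence.upper()
        ckmers = _kmer_set(cseq, SEED_K)
        best: KnownMatch | None = None
        for ref, kmers in ref_kmers:
            if not (ckmers & kmers):
                continue
            alignments = aligner.align(cseq, ref.sequence.upper())
            if not alignments:
                continue
            aln = alignments[0]
            identity, span, _, _ = _alignment_stats(aln)
            coverage = span / len(cseq)
            if identity >= min_identity and coverage >= min_query_coverage:
                match = KnownMatch(ref.id, identity, coverage, float(aln.score))
                if best is None or match.score > best.score:
                    best = match
        if best is not None:
            known.append((cand, best))
        else:
            unmatched.append(cand)
    return known, unmatched


def longest_orf(seq: str) -> tuple[int, int, int, int] | None:
    """Longest complete ATG..stop ORF over the three forward frames.

    Returns (length_nt including the stop codon, frame, start, end) with
    0-based half-open [start, end) on the input, or None when no complete ORF
    exists. Ties go to the earliest start.
    """
    seq = seq.upper().replace("U", "T")
    best: tuple[int, int, int, int] | None = None
    for frame in range(3):
        open_start: int | None = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if open_start is None:
                if codon == START_CODON:
                    open_start = pos
            elif codon in STOP_CODONS:
                length = pos + 3 - open_start
                if best is None or length > best[0]:
                    best = (length, frame, open_start, pos + 3)
                open_start = None
        # an ORF still open at the sequence end is incomplete: discarded
    return best


def hexamer_score(
    seq: str,
    coding_table: Mapping[str, float],
    noncoding_table: Mapping[str, float],
) -> float:
    """Mean log(coding_freq / noncoding_freq) over all sliding hexamers; 0 if < 6 nt."""
    seq = seq.upper().replace("U", "T")
    if len(seq) < 6:
        return 0.0
    total = 0.0
    n = 0
    for i in range(len(seq) - 5):
        hexamer = seq[i : i + 6]
        if "N" in hexamer:
            continue
        try:
            c = coding_table[hexamer]
            nc = noncoding_table[hexamer]
        except KeyError as exc:
            raise KeyError(f"hexamer table missing key {exc.args[0]!r}") from exc
        if c <= 0 or nc <= 0:
            raise ValueError("hexamer tables must be pseudocounted above zero")
        total += math.log(c / nc)
        n += 1
    return total / n if n else 0.0


# Fixed non-uniform codon usage for the pseudo-CDS hexamer background. The
# exact weights are arbitrary; what matters is a usage skew large enough that
# coding-like sequence scores positive and uniform-random sequence negative.
_CODON_WEIGHTS: dict[str, float] = {}
for _b1 in "ACGT":
    for _b2 in "ACGT":
        for _b3 in "ACGT":
            _codon = _b1 + _b2 + _b3
            if _codon in STOP_CODONS:
                continue
            _w = 1.0
            if _codon[2] in "GC":
                _w *= 3.0
            if _codon[0] in "GC":
                _w *= 2.0
            _CODON_WEIGHTS[_codon] = _w


def random_coding_sequence(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + body codons drawn from the fixed usage table + a stop codon."""
    codons = list(_CODON_WEIGHTS)
    weights = np.array([_CODON_WEIGHTS[c] for c in codons])
    weights = weights / weights.sum()
    body = rng.choice(len(codons), size=max(n_codons - 2, 1), p=weights)
    return START_CODON + "".join(codons[i] for i in body) + "TAA"


_DEFAULT_TABLES: tuple[dict[str, float], dict[str, float]] | None = None


def default_hexamer_tables() -> tuple[dict[str, float], dict[str, float]]:
    """(coding, noncoding) hexamer frequency tables.

    The coding table is estimated once from a long pseudo-CDS generated under
    the fixed codon-usage model (seeded, hence deterministic); the noncoding
    table is uniform. Both are pseudocounted so every hexamer has positive
    frequency.
    """
    global _DEFAULT_TABLES
    if _DEFAULT_TABLES is None:
        rng = np.random.default_rng(20230672)
        training = random_coding_sequence(40000, rng)
        counts = {"".join(h): 1.0 for h in _all_hexamers()}
        for i in range(len(training) - 5):
            counts[training[i : i + 6]] += 1.0
        total = sum(counts.values())
        coding = {h: c / total for h, c in counts.items()}
        uniform = 1.0 / 4096.0
        noncoding = {h: uniform for h in counts}
        _DEFAULT_TABLES = (coding, noncoding)
    return _DEFAULT_TABLES


def _all_hexamers():
    import itertools

    return itertools.product("ACGT", repeat=6)


def classify_coding_potential(
    seq: str,
    orf_max_nt: int = ORF_MAX_NT,
    orf_max_coverage: float = ORF_MAX_COVERAGE,
    hexamer_max: float = HEXAMER_MAX_SCORE,
    tables: tuple[Mapping[str, float], Mapping[str, float]] | None = None,
) -> CodingVerdict:
    """Three-rule coding filter; non-coding only when all three rules pass."""
    coding_table, noncoding_table = tables or default_hexamer_tables()
    orf = longest_orf(seq)
    orf_nt = orf[0] if orf else 0
    coverage = orf_nt / len(seq) if seq else 0.0
    score = hexamer_score(seq, coding_table, noncoding_table)
    return CodingVerdict(
        longest_orf_nt=orf_nt,
        orf_coverage=coverage,
        hexamer_score=score,
        orf_length_rule=orf_nt < orf_max_nt,
        orf_coverage_rule=coverage < orf_max_coverage,
        hexamer_rule=score < hexamer_max,
    )


def classify_position(
    lnc: TranscriptModel, annotation: Sequence[TranscriptModel]
) -> str:
    """Assign one positional class relative to protein-coding transcripts.

    Precedence: sense (>= 1 exonic base, same strand) > intronic (entire span
    inside one intron, same strand, no exonic overlap) > antisense (gene-body
    overlap on the opposite strand) > intergenic.
    """
    coding = [t for t in annotation if t.biotype == "protein_coding"]
    if not coding:
        raise ValueError("annotation contains no protein-coding transcripts")
    span = lnc.span

    for t in coding:
        if t.strand == lnc.strand and any(
            e.overlaps(le) for e in t.exons for le in lnc.exons
        ):
            return "sense"
    for t in coding:
        if t.strand != lnc.strand:
            continue
        for intron in t.introns():
            if intron.chrom == span.chrom and intron.start <= span.start and span.end <= intron.end:
                return "intronic"
    for t in coding:
        if t.strand != lnc.strand and t.span.overlaps(span):
            return "antisense"
    return "intergenic"


def summarize_categories(
    class_counts: Mapping[str, int], total_novel: int
) -> dict[str, dict[str, float]]:
    """Per-class count and percentage of total_novel, rounded half-up to 1 dp.

    Percentages are computed against the supplied total, not the category sum,
    so externally reported tallies remain checkable even when categories
    overlap.
    """
    if total_novel < 1:
        raise ValueError("total_novel must be >= 1")
    out: dict[str, dict[str, float]] = {}
    for cls, count in class_counts.items():
        if count < 0:
            raise ValueError(f"negative count for class {cls!r}")
        pct = Decimal(100 * count) / Decimal(total_novel)
        pct = float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
        out[cls] = {"count": count, "percent": pct, "total": total_novel}
    return out


def discover_lncrnas(
    candidates: Sequence[TranscriptModel],
    sequences: Mapping[str, str],
    reference: Sequence[SequenceRecord],
    annotation: Sequence[TranscriptModel],
    min_length: int = MIN_LNC_LENGTH,
    **filter_params,
) -> list[LncRNARecord]:
    """Full discovery: known matching, coding filter, positional classification.

    Candidates failing the novel criteria (length or any coding rule) and not
    matching the known reference are dropped.
    """
    seq_records = [
        SequenceRecord(id=t.transcript_id, sequence=sequences[t.transcript_id])
        for t in candidates
    ]
    by_id = {t.transcript_id: t for t in candidates}
    known, unmatched = match_known(seq_records, reference)
    records: list[LncRNARecord] = []
    for rec, match in known:
        t = by_id[rec.id]
        records.append(
            LncRNARecord(
                transcript=t,
                status="known",
                positional_class=classify_position(t, annotation),
                known_match=match,
            )
        )
    for rec in unmatched:
        t = by_id[rec.id]
        if t.spliced_length < min_length:
            continue
        verdict = classify_coding_potential(rec.sequence, **filter_params)
        if not verdict.is_noncoding:
            continue
        records.append(
            LncRNARecord(
                transcript=t,
                status="novel",
                positional_class=classify_position(t, annotation),
                coding=verdict,
            )
        )
    return records
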