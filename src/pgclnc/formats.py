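"""Shared genomic types and readers/writers for FASTA, FASTQ, GTF and TSV matrices.

Internal coordinates are 0-based half-open everywhere; GTF's 1-based inclusive
convention is converted at the I/O boundary. FASTQ qualities are Phred+33 only.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STRANDS = ("+", "-")


class ParseError(ValueError):
    """Raised when an input file violates its format."""


class ValidationError(ValueError):
    """Raised when parsed content violates a domain invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval on a chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 base, strand-blind."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Closest-boundary gap in bp; 0 when overlapping; None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


@dataclass
class SequenceRecord:
    """A named sequence, optionally with per-base Phred quality scores."""

    id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record id must be non-empty")
        if self.qualities is not None:
            if len(self.qualities) != len(self.sequence):
                raise ValidationError(
                    f"record {self.id}: {len(self.qualities)} qualities for "
                    f"{len(self.sequence)} bases"
                )
            if any(q < 0 or q > 60 for q in self.qualities):
                raise ValidationError(f"record {self.id}: quality outside [0, 60]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript anchored to one chromosome.

    Exons are non-overlapping, sorted by start, and share chrom and strand.
    """

    transcript_id: str
    gene_id: str
    biotype: str = "unknown"
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.biotype not in ("protein_coding", "lncRNA", "unknown"):
            raise ValidationError(f"unknown biotype {self.biotype!r}")
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1:
            raise ValidationError(
                f"transcript {self.transcript_id} spans chromosomes {sorted(chroms)}"
            )
        if len(strands) > 1:
            raise ValidationError(
                f"transcript {self.transcript_id} mixes strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"transcript {self.transcript_id} has overlapping exons"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        """Gene-body interval from first exon start to last exon end."""
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]


@dataclass
class ExpressionMatrix:
    """Non-negative feature x sample values tagged with their unit."""

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "FPKM"):
            raise ValidationError(f"unit must be counts or FPKM, got {self.unit!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate feature id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def row(self, feature_id: str):
        if feature_id not in self.values.index:
            raise KeyError(f"feature {feature_id!r} not in matrix")
        return self.values.loc[feature_id].to_numpy(dtype=float)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def parse_sequences(path: str | Path, format: str) -> list[SequenceRecord]:
    """Read FASTA or FASTQ (Phred+33) into SequenceRecord objects, order preserved."""
    if format == "fasta":
        with _open_text(path) as fh:
            return [
                SequenceRecord(id=rec.id, sequence=str(rec.seq).upper())
                for rec in SeqIO.parse(fh, "fasta")
            ]
    if format == "fastq":
        return _parse_fastq(path)
    raise ValueError(f"unsupported sequence format {format!r}")


def _parse_fastq(path: str | Path) -> list[SequenceRecord]:
    # Hand-parsed so errors can name the offending line.
    records: list[SequenceRecord] = []
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith("@"):
            raise ParseError(f"line {i + 1}: expected '@' header, got {lines[i][:20]!r}")
        if i + 3 >= len(lines):
            raise ParseError(f"line {i + 1}: truncated FASTQ record")
        header, seq, plus, qual = lines[i : i + 4]
        if not plus.startswith("+"):
            raise ParseError(f"line {i + 3}: expected '+' separator")
        if len(qual) != len(seq):
            raise ParseError(
                f"line {i + 4}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        quals = [ord(c) - 33 for c in qual]
        if any(q < 0 for q in quals):
            raise ParseError(f"line {i + 4}: quality character below Phred+33 range")
        records.append(
            SequenceRecord(id=header[1:].split()[0], sequence=seq.upper(), qualities=quals)
        )
        i += 4
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            if rec.qualities is None:
                raise ValidationError(f"record {rec.id} has no qualities")
            qual = "".join(chr(q + 33) for q in rec.qualities)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def parse_annotation(path: str | Path, dialect: str = "gtf") -> list[TranscriptModel]:
    """Read GTF exon features into TranscriptModel objects (0-based half-open)."""
    if dialect != "gtf":
        raise ValueError(f"unsupported annotation dialect {dialect!r}")
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"line {lineno}: expected 9 GTF fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            attr = dict(_GTF_ATTR.findall(attrs))
            if "transcript_id" not in attr:
                raise ParseError(f"line {lineno}: exon lacks transcript_id")
            tid = attr["transcript_id"]
            biotype = attr.get("gene_biotype", attr.get("transcript_biotype", "unknown"))
            if biotype not in ("protein_coding", "lncRNA"):
                biotype = "unknown"
            interval = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            exons.setdefault(tid, []).append(interval)
            meta.setdefault(tid, (attr.get("gene_id", tid), biotype))
    return [
        TranscriptModel(
            transcript_id=tid, gene_id=meta[tid][0], biotype=meta[tid][1], exons=ex
        )
        for tid, ex in exons.items()
    ]


def write_annotation(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcripts back to GTF (1-based inclusive) exon lines."""
    with _open_text(path, "wt") as fh:
        for t in transcripts:
            for e in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_biotype "{t.biotype}";'
                )
                fh.write(
                    f"{e.chrom}\tpgclnc\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t{attrs}\n"
                )


def read_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV matrix (header = sample ids, first column = feature ids)."""
    with _open_text(path) as fh:
        text = fh.read()
    header, *rows = [ln for ln in text.splitlines() if ln.strip()]
    unit = "counts"
    if header.startswith("#unit="):
        unit = header.split("=", 1)[1].strip()
        header, *rows = rows
    samples = header.split("\t")[1:]
    ncol = len(samples) + 1
    for lineno, row in enumerate(rows, start=2):
        if len(row.split("\t")) != ncol:
            raise ParseError(f"line {lineno}: expected {ncol} fields")
    df = pd.read_csv(io.StringIO(header + "\n" + "\n".join(rows)), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(values=df.astype(float), unit=unit)


def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(f"#unit={m.unit}\n")
        m.values.to_csv(fh, sep="\t", index_label="feature_id")


def reverse_complement(seq: str) -> str:
    return seq.translate(DNA_COMPLEMENT)[::-1]


def extract_transcript_sequences(
    genome: Mapping[str, str], transcripts: Sequence[TranscriptModel]
) -> dict[str, str]:
    """Spliced 5'->3' sequence per transcript from a chrom -> sequence mapping."""
    out: dict[str, str] = {}
    for t in transcripts:
        chrom_seq = genome[t.chrom]
        parts = [chrom_seq[e.start : e.end] for e in t.exons]
        seq = "".join(parts)
        if t.strand == "-":
            seq = reverse_complement(seq)
        out[t.transcript_id] = seq.upper()
    return out


def transcribe(seq: str) -> str:
    """DNA -> RNA alphabet (T to U); idempotent on RNA."""
    return str(Seq(seq).transcribe()) if "T" in seq or "t" in seq else seq.upper()
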