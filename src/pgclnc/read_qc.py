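"""Single-end read filtering.

Three rules, applied whole-read (no trimming): a read is rejected when it has
more than `max_adapter_bases` adapter-polluted bases, when more than
`max_low_quality_fraction` of its bases fall below the Phred `quality_floor`,
or when more than `max_n_fraction` of its bases are N. All boundaries are
strict, matching the "more than" phrasing of each rule. The rejection reason
records the first failing rule in the order adapter -> quality -> N.

Adapter pollution is overlap-based: the 3' end of the read is scanned against
the 5' end of the adapter (read-through geometry), accepting the longest
overlap of length >= 6 with >= 90% identity; full internal exact occurrences
of the adapter also count, with every matched base counted once.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats import SequenceRecord

# TruSeq single-index read-1 adapter prefix; the common read-through sequence.
TRUSEQ_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

MIN_OVERLAP = 6
MIN_OVERLAP_IDENTITY = 0.9


@dataclass
class QcThresholds:
    max_adapter_bases: int = 5
    quality_floor: int = 19
    max_low_quality_fraction: float = 0.15
    max_n_fraction: float = 0.05
    adapter_sequence: str = TRUSEQ_ADAPTER

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_low_quality_fraction <= 1.0:
            raise ValueError("max_low_quality_fraction must be in [0, 1]")
        if not 0.0 <= self.max_n_fraction <= 1.0:
            raise ValueError("max_n_fraction must be in [0, 1]")
        if not 0 <= self.quality_floor <= 60:
            raise ValueError("quality_floor must be in [0, 60]")
        if len(self.adapter_sequence) < MIN_OVERLAP:
            raise ValueError("adapter_sequence must be at least 6 nt")


@dataclass
class QcReport:
    n_input: int = 0
    n_kept: int = 0
    n_rejected_adapter: int = 0
    n_rejected_quality: int = 0
    n_rejected_n: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def adapter_polluted_bases(read: SequenceRecord, adapter: str) -> int:
    """Number of read bases attributable to adapter sequence.

    Counts the longest read-suffix / adapter-prefix overlap (length >= 6,
    identity >= 90%) plus any full internal exact occurrence of the adapter;
    each base is counted once even if covered by both.
    """
    seq = read.sequence.upper()
    adapter = adapter.upper()
    n = len(seq)
    covered: set[int] = set()

    best = 0
    for length in range(min(n, len(adapter)), MIN_OVERLAP - 1, -1):
        suffix = seq[n - length :]
        matches = sum(a == b for a, b in zip(suffix, adapter))
        if matches / length >= MIN_OVERLAP_IDENTITY:
            best = length
            break
    if best:
        covered.update(range(n - best, n))

    start = seq.find(adapter)
    while start != -1:
        covered.update(range(start, start + len(adapter)))
        start = seq.find(adapter, start + 1)
    return len(covered)


def _failing_rule(read: SequenceRecord, thresholds: QcThresholds) -> str | None:
    if read.qualities is None:
        raise ValueError(f"read {read.id} has no quality scores")
    n = len(read.sequence)
    if adapter_polluted_bases(read, thresholds.adapter_sequence) > thresholds.max_adapter_bases:
        return "adapter"
    n_low = sum(q < thresholds.quality_floor for q in read.qualities)
    if n_low / n > thresholds.max_low_quality_fraction:
        return "quality"
    n_n = read.sequence.upper().count("N")
    if n_n / n > thresholds.max_n_fraction:
        return "N"
    return None


def filter_reads(
    reads: list[SequenceRecord], thresholds: QcThresholds | None = None
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]], QcReport]:
    """Partition reads into kept and (rejected, reason) under the three rules."""
    thresholds = thresholds or QcThresholds()
    kept: list[SequenceRecord] = []
    rejected: list[tuple[SequenceRecord, str]] = []
    report = QcReport(n_input=len(reads))
    for read in reads:
        reason = _failing_rule(read, thresholds)
        if reason is None:
            kept.append(read)
        else:
            rejected.append((read, reason))
            if reason == "adapter":
                report.n_rejected_adapter += 1
            elif reason == "quality":
                report.n_rejected_quality += 1
            else:
                report.n_rejected_n += 1
    report.n_kept = len(kept)
    return kept, rejected, report
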