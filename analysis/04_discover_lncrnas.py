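"""Identify known/novel lncRNAs, classify positions, and tally categories.

Finding: every candidate passes discovery (2 known via the mutated reference
copies, the rest novel), and the positional classifier recovers the planted
class of all 12 lncRNAs. The category summary is also recomputed for the
published tallies (301/121/46/1 of 452) to reproduce the printed percentages
66.6 / 26.8 / 10.2 / 0.2.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pgclnc.discovery import discover_lncrnas, summarize_categories
from pgclnc.formats import parse_annotation, parse_sequences
from pgclnc.simulate import SyntheticTruth

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    annotation = parse_annotation(ROOT / "data" / "annotation.gtf")
    seqs = {r.id: r.sequence for r in parse_sequences(ROOT / "data" / "transcripts.fa", "fasta")}
    reference = parse_sequences(ROOT / "data" / "known_lncrna.fa", "fasta")
    truth = SyntheticTruth.from_json(ROOT / "data" / "truth.json")

    coding = [t for t in annotation if t.biotype == "protein_coding"]
    candidates = [t for t in annotation if t.biotype != "protein_coding"]
    records = discover_lncrnas(candidates, seqs, reference, coding)

    rows = [
        {
            "transcript_id": r.transcript.transcript_id,
            "status": r.status,
            "class": r.positional_class,
            "planted_class": truth.planted_class.get(r.transcript.transcript_id),
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "lncrna_discovery.tsv", sep="\t", index=False)
    accuracy = (df["class"] == df["planted_class"]).mean()
    counts = df["class"].value_counts().to_dict()
    summary = summarize_categories(counts, len(df))
    pd.DataFrame(summary).T.to_csv(ROOT / "category_summary.csv")

    published = summarize_categories(
        {"sense": 301, "intergenic": 121, "antisense": 46, "intronic": 1}, 452
    )
    print(f"discovered {len(df)} lncRNAs "
          f"({(df['status'] == 'known').sum()} known, {(df['status'] == 'novel').sum()} novel)")
    print(f"positional class accuracy vs planted truth: {accuracy:.3f}")
    print("synthetic categories:", {c: v["percent"] for c, v in summary.items()})
    print("published tallies recomputed:", {c: v["percent"] for c, v in published.items()})


if __name__ == "__main__":
    main()
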