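"""Cis/trans lncRNA-mRNA target prediction and the regulation network.

Cis targets are protein-coding genes whose body lies within a fixed window
(default 10 kb, closest-boundary gap, overlap = 0) of the lncRNA locus and
whose expression correlates with the lncRNA at r strictly greater than the
threshold (default 0.9). Trans targets require sequence complementarity (a
local alignment of the lncRNA against the reverse complement of the mRNA), a
sufficiently stable predicted RNA-RNA duplex over the complementary region,
and the same correlation gate.

The duplex minimum free energy is computed by dynamic programming under a
nearest-neighbor model: one duplex-initiation penalty, stack free energies
over consecutive intermolecular base pairs, and size-dependent bulge/interior
loop penalties, with no intramolecular pairing. An exhaustive enumerator over
all legal duplex structures is provided as an independent reference for small
inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import Align
from scipy import stats as scipy_stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, pearson, spearman
from .formats import GenomicInterval, reverse_complement

CANONICAL_PAIRS = {
    ("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G"),
}

RNA_ALPHABET = set("ACGUN")


@dataclass
class DuplexParams:
    """Nearest-neighbor energy set for intermolecular duplexes (kcal/mol)."""

    init: float
    stacks: dict[tuple[str, str], float]
    bulge: dict[int, float]
    interior: dict[int, float]
    loop_extrapolation: float
    asymmetry_per_unit: float
    asymmetry_max: float
    max_loop: int = 30

    @classmethod
    def load(cls, path: str | Path | None = None) -> "DuplexParams":
        if path is None:
            text = resources.files("pgclnc.data").joinpath("duplex_params.txt").read_text()
        else:
            text = Path(path).read_text()
        init = 0.0
        stacks: dict[tuple[str, str], float] = {}
        bulge: dict[int, float] = {}
        interior: dict[int, float] = {}
        extrap = 1.08
        asym = (0.5, 3.0)
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "init":
                init = float(fields[1])
            elif kind == "stack":
                p1, p2 = fields[1].split(",")
                stacks[(p1, p2)] = float(fields[2])
            elif kind == "bulge":
                bulge[int(fields[1])] = float(fields[2])
            elif kind == "interior":
                interior[int(fields[1])] = float(fields[2])
            elif kind == "loop_extrapolation":
                extrap = float(fields[1])
            elif kind == "asymmetry":
                asym = (float(fields[1]), float(fields[2]))
        return cls(
            init=init, stacks=stacks, bulge=bulge, interior=interior,
            loop_extrapolation=extrap, asymmetry_per_unit=asym[0], asymmetry_max=asym[1],
        )

    def stack_energy(self, pair1: tuple[str, str], pair2: tuple[str, str]) -> float:
        return self.stacks["".join(pair1), "".join(pair2)]

    def loop_energy(self, gap_a: int, gap_b: int) -> float | None:
        """Penalty for gap_a unpaired bases on A and gap_b on B between pairs.

        None when the loop exceeds max_loop (no legal connection).
        """
        if gap_a < 0 or gap_b < 0 or (gap_a == 0 and gap_b == 0):
            raise ValueError("loop requires at least one unpaired base")
        if gap_a + gap_b > self.max_loop:
            return None
        if gap_a == 0 or gap_b == 0:
            size = gap_a + gap_b
            table = self.bulge
            extra = 0.0
        else:
            size = gap_a + gap_b
            table = self.interior
            extra = min(
                self.asymmetry_per_unit * abs(gap_a - gap_b), self.asymmetry_max
            )
        max_tab = max(table)
        if size in table:
            return table[size] + extra
        return table[max_tab] + self.loop_extrapolation * math.log(size / max_tab) + extra


@dataclass
class DuplexStructure:
    """Intermolecular base pairs (i in A ascending, j in B descending) + energy."""

    pairs: list[tuple[int, int]]
    energy_kcal: float


_DEFAULT_PARAMS: DuplexParams | None = None


def default_duplex_params() -> DuplexParams:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = DuplexParams.load()
    return _DEFAULT_PARAMS


def _as_rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    if set(seq) - RNA_ALPHABET:
        bad = sorted(set(seq) - RNA_ALPHABET)
        raise ValueError(f"invalid RNA characters {bad}")
    return seq


def duplex_energy(
    pairs: Sequence[tuple[int, int]], seq_a: str, seq_b: str,
    params: DuplexParams | None = None,
) -> float | None:
    """Energy of a given duplex structure; None when it is not realizable.

    Validates antiparallel geometry (A indices strictly increasing, B indices
    strictly decreasing), pair legality, and the loop-size cap. Used by the
    exhaustive reference enumerator; independent of the DP recursion.
    """
    params = params or default_duplex_params()
    a, b = _as_rna(seq_a), _as_rna(seq_b)
    if not pairs:
        return None
    for i, j in pairs:
        if not (0 <= i < len(a) and 0 <= j < len(b)):
            return None
        if (a[i], b[j]) not in CANONICAL_PAIRS:
            return None
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if not (i1 < i2 and j1 > j2):
            return None
    energy = params.init
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        gap_a, gap_b = i2 - i1 - 1, j1 - j2 - 1
        if gap_a == 0 and gap_b == 0:
            energy += params.stack_energy((a[i1], b[j1]), (a[i2], b[j2]))
        else:
            loop = params.loop_energy(gap_a, gap_b)
            if loop is None:
                return None
            energy += loop
    return energy


def duplex_mfe(
    seq_a: str, seq_b: str, params: DuplexParams | None = None
) -> DuplexStructure | None:
    """Minimum-free-energy intermolecular duplex, or None when no pair is legal."""
    params = params or default_duplex_params()
    a, b = _as_rna(seq_a), _as_rna(seq_b)
    n, m = len(a), len(b)
    legal = [[(a[i], b[j]) in CANONICAL_PAIRS for j in range(m)] for i in range(n)]

    INF = float("inf")
    best = [[INF] * m for _ in range(n)]
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    max_loop = params.max_loop
    for i in range(n):
        for j in range(m - 1, -1, -1):
            if not legal[i][j]:
                continue
            e = params.init  # (i, j) opens the duplex
            for p in range(max(0, i - 1 - max_loop), i):
                row = best[p]
                for q in range(j + 1, min(m, j + 2 + max_loop)):
                    if row[q] == INF:
                        continue
                    gap_a, gap_b = i - p - 1, q - j - 1
                    if gap_a == 0 and gap_b == 0:
                        cand = row[q] + params.stack_energy((a[p], b[q]), (a[i], b[j]))
                    else:
                        if gap_a + gap_b > max_loop:
                            continue
                        loop = params.loop_energy(gap_a, gap_b)
                        if loop is None:
                            continue
                        cand = row[q] + loop
                    if cand < e:
                        e = cand
                        parent[(i, j)] = (p, q)
            best[i][j] = e

    mfe = INF
    end: tuple[int, int] | None = None
    for i in range(n):
        for j in range(m):
            if best[i][j] < mfe:
                mfe = best[i][j]
                end = (i, j)
    if end is None:
        return None
    pairs: list[tuple[int, int]] = []
    node: tuple[int, int] | None = end
    while node is not None:
        pairs.append(node)
        node = parent.get(node)
    pairs.reverse()
    return DuplexStructure(pairs=pairs, energy_kcal=mfe)


def duplex_mfe_exhaustive(
    seq_a: str, seq_b: str, params: DuplexParams | None = None
) -> DuplexStructure | None:
    """Reference MFE by exhaustive enumeration of every legal duplex structure.

    Exponential; intended for sequences of at most ~10 nt.
    """
    params = params or default_duplex_params()
    a, b = _as_rna(seq_a), _as_rna(seq_b)
    legal_pairs = [
        (i, j)
        for i in range(len(a))
        for j in range(len(b))
        if (a[i], b[j]) in CANONICAL_PAIRS
    ]
    best: DuplexStructure | None = None

    def extend(chain: list[tuple[int, int]]) -> None:
        nonlocal best
        if chain:
            e = duplex_energy(chain, a, b, params)
            if e is not None and (best is None or e < best.energy_kcal):
                best = DuplexStructure(pairs=list(chain), energy_kcal=e)
        last = chain[-1] if chain else None
        for i, j in legal_pairs:
            if last is None or (i > last[0] and j < last[1]):
                chain.append((i, j))
                extend(chain)
                chain.pop()

    extend([])
    return best


@dataclass
class ComplementarityHit:
    lnc_start: int
    lnc_end: int
    mrna_start: int
    mrna_end: int
    identity: float
    length: int
    score: float


@dataclass
class TargetPair:
    lnc_id: str
    gene_id: str
    mode: str  # cis | trans
    correlation: float
    distance_bp: int | None = None
    alignment: ComplementarityHit | None = None
    duplex_energy_kcal: float | None = None


def _hit_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def complementarity_hits(
    lnc_seq: str,
    mrna_seq: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    min_len: int = 20,
    min_identity: float = 0.8,
) -> list[ComplementarityHit]:
    """Local alignments of the lncRNA against the mRNA's reverse complement.

    A hit must score at least the score of a perfect min_len match scaled by
    min_identity. Coordinates are reported on both molecules in their native
    orientation. The best-scoring alignment is returned (empty list if none
    qualifies).
    """
    lnc = lnc_seq.upper().replace("U", "T")
    mrna = mrna_seq.upper().replace("U", "T")
    if len(lnc) < min_len or len(mrna) < min_len:
        raise ValueError(f"sequences must be at least {min_len} nt")
    threshold = match * min_len * min_identity
    aligner = _hit_aligner(match, mismatch, gap_open, gap_extend)
    rc = reverse_complement(mrna)
    alignments = aligner.align(lnc, rc)
    if not alignments:
        return []
    aln = alignments[0]
    if aln.score < threshold:
        return []
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    if identity < min_identity:
        return []
    qs, qe = int(aln.coordinates[0][0]), int(aln.coordinates[0][-1])
    ts, te = int(aln.coordinates[1][0]), int(aln.coordinates[1][-1])
    return [
        ComplementarityHit(
            lnc_start=qs,
            lnc_end=qe,
            mrna_start=len(mrna) - te,
            mrna_end=len(mrna) - ts,
            identity=identity,
            length=qe - qs,
            score=float(aln.score),
        )
    ]


def _correlate(expr: ExpressionMatrix, id_a: str, id_b: str, method: str) -> float:
    xa, xb = expr.row(id_a), expr.row(id_b)
    return pearson(xa, xb) if method == "pearson" else spearman(xa, xb)


def cis_targets(
    lnc_loci: Mapping[str, GenomicInterval],
    gene_loci: Mapping[str, GenomicInterval],
    expr: ExpressionMatrix,
    window_bp: int = 10_000,
    r_min: float = 0.9,
    method: str = "pearson",
) -> list[TargetPair]:
    """Genes with body within window_bp of the lncRNA locus and r > r_min (strict)."""
    pairs: list[TargetPair] = []
    for lnc_id, lnc_iv in lnc_loci.items():
        for gene_id, gene_iv in gene_loci.items():
            gap = lnc_iv.gap_to(gene_iv)
            if gap is None or gap > window_bp:
                continue
            r = _correlate(expr, lnc_id, gene_id, method)
            if r > r_min:
                pairs.append(
                    TargetPair(lnc_id, gene_id, "cis", correlation=r, distance_bp=gap)
                )
    return pairs


def trans_targets(
    lnc_seqs: Mapping[str, str],
    mrna_seqs: Mapping[str, str],
    expr: ExpressionMatrix,
    energy_max: float = -20.0,
    r_min: float = 0.9,
    method: str = "pearson",
    flank: int = 10,
    params: DuplexParams | None = None,
    **align_params,
) -> list[TargetPair]:
    """Pairs with a complementarity hit, duplex MFE <= energy_max, and r > r_min.

    The duplex is folded over the best hit's spans extended by `flank` nt on
    each side. The correlation gate is evaluated first (it is the cheapest).
    """
    params = params or default_duplex_params()
    pairs: list[TargetPair] = []
    for lnc_id, lnc_seq in lnc_seqs.items():
        for gene_id, mrna_seq in mrna_seqs.items():
            r = _correlate(expr, lnc_id, gene_id, method)
            if not r > r_min:
                continue
            hits = complementarity_hits(lnc_seq, mrna_seq, **align_params)
            if not hits:
                continue
            hit = hits[0]
            lnc_win = lnc_seq[max(0, hit.lnc_start - flank) : hit.lnc_end + flank]
            mrna_win = mrna_seq[max(0, hit.mrna_start - flank) : hit.mrna_end + flank]
            duplex = duplex_mfe(lnc_win, mrna_win, params)
            if duplex is None or duplex.energy_kcal > energy_max:
                continue
            pairs.append(
                TargetPair(
                    lnc_id, gene_id, "trans", correlation=r,
                    alignment=hit, duplex_energy_kcal=duplex.energy_kcal,
                )
            )
    return pairs


def build_network(pairs: Sequence[TargetPair]) -> nx.MultiGraph:
    """Deduplicated bipartite lncRNA-gene graph; edges keyed by mode."""
    lnc_ids = {p.lnc_id for p in pairs}
    gene_ids = {p.gene_id for p in pairs}
    clash = lnc_ids & gene_ids
    if clash:
        raise ValueError(f"id on both sides of the network: {sorted(clash)[0]!r}")
    net = nx.MultiGraph()
    for p in pairs:
        net.add_node(p.lnc_id, type="lncRNA")
        net.add_node(p.gene_id, type="gene")
        if not net.has_edge(p.lnc_id, p.gene_id, key=p.mode):
            net.add_edge(
                p.lnc_id, p.gene_id, key=p.mode, mode=p.mode,
                correlation=p.correlation,
                distance_bp=p.distance_bp if p.distance_bp is not None else -1,
                duplex_energy_kcal=(
                    p.duplex_energy_kcal if p.duplex_energy_kcal is not None else 0.0
                ),
            )
    return net


def subnetwork(net: nx.MultiGraph, gene_list: Sequence[str]) -> nx.MultiGraph:
    """Listed genes plus every lncRNA adjacent to at least one; no isolated nodes."""
    genes = {g for g in gene_list if g in net and net.nodes[g].get("type") == "gene"}
    lncs = {nbr for g in genes for nbr in net.neighbors(g)}
    sub = net.subgraph(genes | lncs).copy()
    sub.remove_nodes_from([n for n in list(sub) if sub.degree(n) == 0])
    return sub


def network_summary(net: nx.MultiGraph) -> dict[str, int]:
    n_lnc = sum(1 for _, d in net.nodes(data=True) if d.get("type") == "lncRNA")
    n_gene = sum(1 for _, d in net.nodes(data=True) if d.get("type") == "gene")
    return {"n_lncRNA": n_lnc, "n_genes": n_gene, "n_edges": net.number_of_edges()}


def write_pairs_tsv(pairs: Sequence[TargetPair], path) -> None:
    rows = []
    for p in pairs:
        rows.append(
            {
                "lnc_id": p.lnc_id,
                "gene_id": p.gene_id,
                "mode": p.mode,
                "correlation": p.correlation,
                "distance_bp": p.distance_bp if p.distance_bp is not None else "",
                "duplex_energy_kcal": (
                    p.duplex_energy_kcal if p.duplex_energy_kcal is not None else ""
                ),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "lnc_id", "gene_id", "mode", "correlation", "distance_bp",
            "duplex_energy_kcal",
        ],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def enrich_terms(
    study_set: set[str],
    background_set: set[str],
    term_map: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment per term with BH adjustment.

    Columns: term, k (study hits), n (study size), K (term size in
    background), N (background size), p, q.
    """
    if not study_set <= background_set:
        extra = sorted(study_set - background_set)[0]
        raise ValueError(f"study gene {extra!r} not in background")
    N = len(background_set)
    n = len(study_set)
    rows = []
    for term, genes in term_map.items():
        if not genes <= background_set:
            extra = sorted(genes - background_set)[0]
            raise ValueError(f"term {term!r} gene {extra!r} not in background")
        K = len(genes)
        k = len(study_set & genes)
        p = float(scipy_stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N, "p": p})
    df = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["q"] = pd.Series(dtype=float)
    return df
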