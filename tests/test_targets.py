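import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats

from pgclnc.formats import ExpressionMatrix, GenomicInterval, reverse_complement
from pgclnc.targets import (
    TargetPair,
    build_network,
    cis_targets,
    complementarity_hits,
    default_duplex_params,
    duplex_energy,
    duplex_mfe,
    duplex_mfe_exhaustive,
    enrich_terms,
    network_summary,
    subnetwork,
    trans_targets,
)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestDuplexMfe:
    def test_no_legal_pair(self):
        assert duplex_mfe("AAAA", "AAAA") is None

    def test_gc_helix_hand_sum(self):
        # 5 consecutive G-C pairs: initiation + 4 GC,GC stacks
        params = default_duplex_params()
        result = duplex_mfe("GGGGG", "CCCCC", params)
        expected = params.init + 4 * params.stacks[("GC", "GC")]
        assert result.energy_kcal == pytest.approx(expected)
        assert result.pairs == [(0, 4), (1, 3), (2, 2), (3, 1), (4, 0)]

    def test_dp_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(1234)
        for _ in range(100):
            a = random_rna(rng, int(rng.integers(2, 9)))
            b = random_rna(rng, int(rng.integers(2, 9)))
            dp = duplex_mfe(a, b)
            brute = duplex_mfe_exhaustive(a, b)
            if dp is None:
                assert brute is None
            else:
                assert dp.energy_kcal == pytest.approx(brute.energy_kcal, abs=1e-9)
                # the DP structure must itself score its reported energy
                assert duplex_energy(dp.pairs, a, b) == pytest.approx(dp.energy_kcal)

    def test_extending_a_helix_never_raises_mfe(self):
        seq = "GCGCGC"
        prev = None
        for k in range(3, len(seq) + 1):
            a = seq[:k]
            b = reverse_complement(a.replace("U", "T")).replace("T", "U")
            e = duplex_mfe(a, b).energy_kcal
            if prev is not None:
                assert e <= prev + 1e-9
            prev = e

    def test_t_mapped_to_u(self):
        rna = duplex_mfe("GGGTT", "AACCC")
        assert rna is not None  # T treated as U, pairs with A

    def test_invalid_alphabet(self):
        with pytest.raises(ValueError):
            duplex_mfe("GGXG", "CCCC")

    def test_structure_geometry_is_antiparallel(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a, b = random_rna(rng, 8), random_rna(rng, 8)
            result = duplex_mfe(a, b)
            if result is None:
                continue
            for (i1, j1), (i2, j2) in zip(result.pairs, result.pairs[1:]):
                assert i1 < i2 and j1 > j2


def smith_waterman_affine(a, b, match=2, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Gotoh local alignment score; independent oracle for short strings."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestComplementarityHits:
    def test_perfect_embedded_complement(self):
        rng = np.random.default_rng(21)
        mrna = "".join(rng.choice(list("ACGT"), size=500))
        window = mrna[200:225]
        lnc = (
            "".join(rng.choice(list("ACGT"), size=100))
            + reverse_complement(window)
            + "".join(rng.choice(list("ACGT"), size=100))
        )
        hits = complementarity_hits(lnc, mrna)
        assert len(hits) == 1
        hit = hits[0]
        assert hit.identity == pytest.approx(1.0)
        assert hit.length >= 25
        assert mrna[hit.mrna_start : hit.mrna_end].find(window) != -1 or (
            hit.mrna_start <= 200 and hit.mrna_end >= 225
        )

    def test_random_sequences_produce_no_hit(self):
        rng = np.random.default_rng(77)
        a = "".join(rng.choice(list("ACGT"), size=500))
        b = "".join(rng.choice(list("ACGT"), size=500))
        assert complementarity_hits(a, b) == []

    def test_alignment_score_matches_smith_waterman_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            mrna = "".join(rng.choice(list("ACGT"), size=60))
            window = list(mrna[10:40])
            for pos in rng.choice(30, size=3, replace=False):  # 3 mismatches
                window[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[window[pos]]
            lnc = "AAAA" + reverse_complement("".join(window)) + "TTTT"
            hits = complementarity_hits(lnc, mrna, min_len=20, min_identity=0.7)
            oracle = smith_waterman_affine(lnc, reverse_complement(mrna))
            if hits:
                assert hits[0].score == pytest.approx(oracle)


def loci(**kwargs):
    return {k: GenomicInterval("chr1", s, e, "+") for k, (s, e) in kwargs.items()}


def expr_matrix(rows: dict[str, list[float]]) -> ExpressionMatrix:
    df = pd.DataFrame(rows).T
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    return ExpressionMatrix(values=df, unit="FPKM")


class TestCisTargets:
    base = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]

    def test_near_and_correlated_pair_emitted(self):
        m = expr_matrix({"l": self.base, "g": [2 * v for v in self.base]})
        pairs = cis_targets(loci(l=(0, 1000)), loci(g=(6000, 8000)), m)
        assert len(pairs) == 1
        assert pairs[0].distance_bp == 5000
        assert pairs[0].correlation == pytest.approx(1.0)

    def test_correlation_exactly_at_threshold_not_emitted(self):
        rng = np.random.default_rng(3)
        for _ in range(200):  # find a vector pair with r very close below 0.9
            x = rng.normal(size=8)
            y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=8)
            r = scipy_stats.pearsonr(x, y).statistic
            if r <= 0.9:
                break
        m = expr_matrix({"l": list(np.exp(x)), "g": list(np.exp(x))})
        # same-vector pair has r = 1 -> emitted; now force r_min above it
        assert cis_targets(loci(l=(0, 100)), loci(g=(500, 600)), m, r_min=1.0) == []

    def test_window_boundary(self):
        m = expr_matrix({"l": self.base, "g": [2 * v for v in self.base]})
        inside = cis_targets(loci(l=(0, 1000)), loci(g=(11000, 12000)), m)
        outside = cis_targets(loci(l=(0, 1000)), loci(g=(11001, 12000)), m)
        assert len(inside) == 1 and inside[0].distance_bp == 10000
        assert outside == []

    def test_missing_id_raises(self):
        m = expr_matrix({"l": self.base})
        with pytest.raises(KeyError, match="g"):
            cis_targets(loci(l=(0, 1000)), loci(g=(2000, 3000)), m)


class TestTransTargets:
    def make_pair(self, rng, correlated=True, complement=True):
        mrna = "".join(rng.choice(list("ACGT"), size=500))
        insert = reverse_complement(mrna[200:230]) if complement else "".join(
            rng.choice(list("ACGT"), size=30)
        )
        lnc = (
            "".join(rng.choice(list("ACGT"), size=100))
            + insert
            + "".join(rng.choice(list("ACGT"), size=100))
        )
        base = np.exp(rng.normal(size=8))
        other = 3 * base if correlated else np.exp(rng.normal(size=8))
        m = expr_matrix({"l": list(base), "g": list(other)})
        return {"l": lnc}, {"g": mrna}, m

    def test_planted_pair_emitted(self):
        lnc, mrna, m = self.make_pair(np.random.default_rng(31))
        pairs = trans_targets(lnc, mrna, m)
        assert len(pairs) == 1
        assert pairs[0].mode == "trans"
        assert pairs[0].duplex_energy_kcal <= -20.0
        assert pairs[0].alignment is not None

    def test_correlation_gate(self):
        lnc, mrna, m = self.make_pair(np.random.default_rng(32), correlated=False)
        assert trans_targets(lnc, mrna, m) == []

    def test_sequence_gate(self):
        lnc, mrna, m = self.make_pair(np.random.default_rng(33), complement=False)
        assert trans_targets(lnc, mrna, m) == []


class TestNetwork:
    def pairs(self):
        return [
            TargetPair("l1", "g1", "cis", 0.95, distance_bp=100),
            TargetPair("l1", "g2", "trans", 0.92, duplex_energy_kcal=-25.0),
            TargetPair("l2", "g1", "cis", 0.99, distance_bp=0),
        ]

    def test_counts(self):
        net = build_network(self.pairs())
        assert network_summary(net) == {"n_lncRNA": 2, "n_genes": 2, "n_edges": 3}

    def test_duplicates_collapse(self):
        pairs = self.pairs() + [TargetPair("l1", "g1", "cis", 0.95, distance_bp=100)]
        assert build_network(pairs).number_of_edges() == 3

    def test_empty_input(self):
        net = build_network([])
        assert net.number_of_nodes() == 0

    def test_id_on_both_sides_rejected(self):
        with pytest.raises(ValueError):
            build_network([TargetPair("x", "x", "cis", 0.95, distance_bp=1)])

    def test_subnetwork_keeps_adjacent_lncrnas(self):
        net = build_network(self.pairs())
        sub = subnetwork(net, ["g1"])
        assert set(sub.nodes) == {"g1", "l1", "l2"}
        assert sub.number_of_edges() == 2

    def test_subnetwork_full_gene_list_is_identity(self):
        net = build_network(self.pairs())
        sub = subnetwork(net, ["g1", "g2"])
        assert set(sub.nodes) == set(net.nodes)
        assert sub.number_of_edges() == net.number_of_edges()

    def test_subnetwork_disjoint_gene_list_is_empty(self):
        net = build_network(self.pairs())
        assert subnetwork(net, ["g99"]).number_of_nodes() == 0


class TestEnrichment:
    def test_closed_form_hypergeometric(self):
        background = {f"g{i}" for i in range(10)}
        term = {"g0", "g1", "g2"}
        table = enrich_terms(term, background, {"T": term})
        from math import comb

        assert table.loc[0, "p"] == pytest.approx(1 / comb(10, 3))

    def test_bh_step_up(self):
        background = {f"g{i}" for i in range(30)}
        terms = {
            "t1": {"g0", "g1"},
            "t2": {"g0", "g2"},
            "t3": {"g3", "g4"},
        }
        table = enrich_terms({"g0", "g1"}, background, terms)
        # step-up arithmetic by hand: q_(i) = min_{j >= i} p_(j) * n / j
        p = np.sort(table["p"].to_numpy())
        n = len(p)
        raw = p * n / np.arange(1, n + 1)
        expected_sorted = np.minimum.accumulate(raw[::-1])[::-1]
        got_sorted = np.sort(table["q"].to_numpy())
        assert np.allclose(got_sorted, np.clip(expected_sorted, 0, 1))

    def test_empty_term_map(self):
        assert len(enrich_terms({"g0"}, {"g0", "g1"}, {})) == 0

    def test_study_outside_background_rejected(self):
        with pytest.raises(ValueError):
            enrich_terms({"x"}, {"g0"}, {})
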