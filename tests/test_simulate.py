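import numpy as np
import pytest
from scipy import stats as scipy_stats

from pgclnc import simulate
from pgclnc.discovery import classify_coding_potential
from pgclnc.expression import fpkm, pearson
from pgclnc.stats import ddct_fold_change, phenotype_summary


class TestGenomeAnnotation:
    def test_seed_determinism(self, tmp_path):
        a = simulate.generate_genome_annotation(n_genes=6, n_lnc_per_class=1, seed=4)
        b = simulate.generate_genome_annotation(n_genes=6, n_lnc_per_class=1, seed=4)
        pa = a.write(tmp_path / "a")
        pb = b.write(tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes()

    def test_all_classes_planted(self, synth):
        classes = set(synth.truth.planted_class.values())
        assert classes == {"sense", "intronic", "antisense", "intergenic"}
        per_class = {c: 0 for c in classes}
        for c in synth.truth.planted_class.values():
            per_class[c] += 1
        assert all(v == 3 for v in per_class.values())

    def test_zero_lnc_per_class(self):
        out = simulate.generate_genome_annotation(n_genes=6, n_lnc_per_class=0, seed=2)
        assert out.truth.planted_class == {}
        assert out.lncrnas == []

    def test_too_few_genes_raises_sizing_error(self):
        with pytest.raises(simulate.SizingError):
            simulate.generate_genome_annotation(n_genes=5, n_lnc_per_class=3, seed=1)

    def test_lncrnas_pass_coding_filter_and_mrnas_fail(self, synth):
        seqs = synth.transcript_sequences()
        for lnc in synth.lncrnas:
            assert classify_coding_potential(seqs[lnc.transcript_id]).is_noncoding
        for gene in synth.genes:
            assert not classify_coding_potential(seqs[gene.transcript_id]).is_noncoding

    def test_truth_roundtrips_through_json(self, synth, tmp_path):
        path = tmp_path / "truth.json"
        synth.truth.to_json(path)
        back = simulate.SyntheticTruth.from_json(path)
        assert back == synth.truth


class TestExpression:
    def test_noise_free_planted_pair_correlates_perfectly(self, synth, synth_counts):
        lengths = {t.transcript_id: t.spliced_length for t in synth.transcripts}
        m = fpkm(synth_counts, lengths)
        for lnc, gene in synth.truth.planted_cis_pairs + synth.truth.planted_trans_pairs:
            assert pearson(m.row(lnc), m.row(gene)) > 0.99

    def test_planted_pair_r_above_threshold_with_noise(self, synth):
        rs = []
        for rep in range(25):
            counts = simulate.generate_expression(
                synth.truth, n_samples=10, r_target=0.98, noise=0.05, seed=100 + rep
            )
            for lnc, gene in synth.truth.planted_cis_pairs:
                rs.append(pearson(counts.row(lnc), counts.row(gene)))
        assert np.median(rs) > 0.9

    def test_decoy_pairs_uncorrelated(self, synth):
        rs = []
        for rep in range(10):
            counts = simulate.generate_expression(
                synth.truth, n_samples=10, seed=200 + rep, noise=0.05
            )
            genes = synth.truth.gene_ids
            for i, lnc in enumerate(synth.truth.lnc_ids):
                gene = genes[(i * 5) % len(genes)]
                planted = set(
                    map(tuple, synth.truth.planted_cis_pairs + synth.truth.planted_trans_pairs)
                )
                correlated_decoys = {
                    (a, b) for a, b, k in synth.truth.decoy_pairs if k == "correlation_only"
                }
                if (lnc, gene) in planted | correlated_decoys:
                    continue
                rs.append(pearson(counts.row(lnc), counts.row(gene)))
        assert np.mean(np.abs(np.array(rs)) < 0.9) >= 0.95

    def test_r_target_must_exceed_pipeline_threshold(self, synth):
        with pytest.raises(ValueError):
            simulate.generate_expression(synth.truth, r_target=0.9)

    def test_determinism(self, synth):
        a = simulate.generate_expression(synth.truth, seed=3)
        b = simulate.generate_expression(synth.truth, seed=3)
        assert a.values.equals(b.values)


class TestReads:
    TRANSCRIPTS = {"t1": "ACCTGACCTTGGACCTGAACCGTACCTGACCTTGGACCTGAACCGTAGCA" * 10}

    def test_zero_defect_rates_all_kept(self):
        from pgclnc.read_qc import filter_reads

        reads, _ = simulate.generate_reads(
            self.TRANSCRIPTS, None, defect_rates=(0, 0, 0), seed=1, n_reads=50
        )
        kept, _, report = filter_reads(reads)
        assert report.n_kept == 50

    def test_defect_labels_partition_reads(self):
        reads, truth = simulate.generate_reads(
            self.TRANSCRIPTS, None, defect_rates=(0.1, 0.2, 0.3), seed=2, n_reads=100
        )
        labels = list(truth.planted_read_defects.values())
        assert len(labels) == 100
        assert labels.count("adapter") == 10
        assert labels.count("low_quality") == 20
        assert labels.count("many_N") == 30
        assert labels.count("clean") == 40

    def test_adapter_read_rejected_for_adapter_not_quality(self):
        from pgclnc.read_qc import filter_reads

        reads, truth = simulate.generate_reads(
            self.TRANSCRIPTS, None, defect_rates=(0.5, 0, 0), seed=3, n_reads=20
        )
        _, rejected, _ = filter_reads(reads)
        for read, reason in rejected:
            assert truth.planted_read_defects[read.id] == "adapter"
            assert reason == "adapter"

    def test_short_adapter_rejected(self):
        with pytest.raises(ValueError):
            simulate.generate_reads(self.TRANSCRIPTS, None, adapter_seq="ACGT")

    def test_rates_must_sum_to_at_most_one(self):
        with pytest.raises(ValueError):
            simulate.generate_reads(self.TRANSCRIPTS, None, defect_rates=(0.5, 0.4, 0.3))


class TestQpcr:
    def test_unit_fold_noise_free(self):
        ct, _ = simulate.generate_qpcr(["con", "trt"], {"con": 1.0, "trt": 1.0})
        folds = ddct_fold_change(ct, "lnc304", "con")
        assert folds["fold"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_planted_quarter_fold_recovered_exactly(self):
        ct, _ = simulate.generate_qpcr(["con", "kd"], {"con": 1.0, "kd": 0.25})
        folds = ddct_fold_change(ct, "lnc304", "con")
        assert folds.loc["kd", "fold"] == pytest.approx(0.25)

    def test_noisy_folds_converge_to_planted(self):
        recovered = []
        for rep in range(100):
            ct, _ = simulate.generate_qpcr(
                ["con", "kd"], {"con": 1.0, "kd": 0.5}, noise_sd=0.1, seed=rep
            )
            recovered.append(ddct_fold_change(ct, "lnc304", "con").loc["kd", "fold"])
        assert np.mean(recovered) == pytest.approx(0.5, rel=0.1)

    def test_control_fold_must_be_one(self):
        with pytest.raises(ValueError):
            simulate.generate_qpcr(["con", "t"], {"con": 2.0, "t": 1.0})


class TestPhenotypes:
    def test_zero_fraction_all_zero(self):
        table, _ = simulate.generate_phenotypes({"g": (20, 0.0, 4.0)}, seed=1)
        assert (table["mislocalized_count"] == 0).all()

    def test_exact_mode_recovers_spec(self):
        table, _ = simulate.generate_phenotypes({"g": (20, 0.5, 4.0)}, seed=1, exact=True)
        out = phenotype_summary(table)
        assert out.loc["g", "percent_mislocalized"] == pytest.approx(50.0)
        assert out.loc["g", "mean_mislocalized"] == pytest.approx(4.0)

    def test_seed_determinism(self):
        a, _ = simulate.generate_phenotypes({"g": (30, 0.3, 5.0)}, seed=9)
        b, _ = simulate.generate_phenotypes({"g": (30, 0.3, 5.0)}, seed=9)
        assert a.equals(b)

    def test_stochastic_mode_tracks_planted_effects(self):
        fracs, means = [], []
        for rep in range(50):
            table, _ = simulate.generate_phenotypes({"g": (50, 0.3, 5.0)}, seed=rep)
            out = phenotype_summary(table)
            fracs.append(out.loc["g", "percent_mislocalized"])
            means.append(out.loc["g", "mean_mislocalized"])
        assert np.mean(fracs) == pytest.approx(30.0, abs=3.0)
        assert np.mean(means) == pytest.approx(5.0, abs=0.5)
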