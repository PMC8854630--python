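"""Generator behaviour: planted truth, determinism, statistical calibration."""

import numpy as np
import pytest

import graftrace as gt
from graftrace import _seq


def config(**kw) -> gt.SimulationConfig:
    base = dict(seed=3, n_genes=10, gene_length_range=(400, 700),
                read_length=100, rna_depth=2000, dna_depth=10.0,
                n_conserved_genes=2, n_mobile_genes=2, n_de_genes=2)
    base.update(kw)
    return gt.SimulationConfig(**base)


class TestConfigValidation:
    def test_rejects_short_genes_relative_to_reads(self):
        with pytest.raises(ValueError, match="twice the read length"):
            config(gene_length_range=(150, 700))

    def test_rejects_oversubscribed_gene_classes(self):
        with pytest.raises(ValueError):
            config(n_conserved_genes=6, n_mobile_genes=6)

    def test_rejects_increasing_stress_schedule(self):
        with pytest.raises(ValueError, match="non-increasing"):
            config(stress_schedule={0: 0.5, 1: 0.8})

    def test_rejects_out_of_range_rates(self):
        with pytest.raises(ValueError):
            config(scion_snp_rate=1.5)

    def test_indels_not_supported(self):
        with pytest.raises(NotImplementedError):
            config(indel_rate=0.01)


class TestGenomes:
    def test_zero_snp_rate_gives_identical_published_and_true(self):
        g = gt.simulate_genomes(config(scion_snp_rate=0.0,
                                       n_unassembled_conserved=0))
        assert g.published_ref == g.true_scion
        assert g.scion_variants == []

    def test_zero_divergence_all_conserved_gives_identical_gene_space(self):
        cfg = config(rootstock_divergence=0.0, n_conserved_genes=10,
                     n_mobile_genes=0, n_unassembled_conserved=0)
        g = gt.simulate_genomes(cfg)
        scion = gt.gene_sequences(g.true_scion, g.scion_genes)
        root = gt.gene_sequences(g.rootstock, g.rootstock_genes)
        for i in range(cfg.n_genes):
            assert scion[f"CsaSynG{i:04d}"] == root[f"CmoSynG{i:04d}"]

    def test_variant_count_matches_binomial_oracle(self):
        # 3-sigma binomial bounds on the planted substitution count
        cfg = config(seed=7, n_genes=50, scion_snp_rate=0.01,
                     n_unassembled_conserved=0)
        g = gt.simulate_genomes(cfg)
        n = len(g.published_ref["chr1"])
        mu, sd = n * 0.01, (n * 0.01 * 0.99) ** 0.5
        assert mu - 3 * sd <= len(g.scion_variants) <= mu + 3 * sd

    def test_applying_variants_recovers_true_scion(self):
        g = gt.simulate_genomes(config())
        seq = list(g.published_ref["chr1"])
        for v in g.scion_variants:
            assert seq[v.pos] == v.ref
            seq[v.pos] = v.alt
        assert "".join(seq) == g.true_scion["chr1"]

    def test_conserved_rootstock_genes_match_scion_exactly(self):
        g = gt.simulate_genomes(config())
        scion = gt.gene_sequences(g.true_scion, g.scion_genes)
        root = gt.gene_sequences(g.rootstock, g.rootstock_genes)
        assert g.conserved_gene_ids
        for rid in g.conserved_gene_ids:
            sid = rid.replace("Cmo", "Csa")
            assert root[rid] == scion[sid]

    def test_determinism(self):
        a = gt.simulate_genomes(config())
        b = gt.simulate_genomes(config())
        assert a.true_scion == b.true_scion
        assert a.rootstock == b.rootstock
        assert a.scion_variants == b.scion_variants


class TestTranscriptome:
    def test_abundance_sums_to_one(self, small_transcripts):
        sums = small_transcripts.abundance.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_zero_mobile_multiplier_silences_rootstock_in_hetero(self):
        cfg = config(mobile_condition_profile={"WW": 0.0, "WS": 0.0})
        g = gt.simulate_genomes(cfg)
        t = gt.simulate_transcriptome(g, cfg)
        rs_ids = [gm.gene_id for gm in g.rootstock_genes]
        for key in t.samples:
            assert (t.weights.loc[rs_ids, key.label] == 0).all()

    def test_rootstock_absent_from_homograft_samples(self, small_transcripts,
                                                     small_genomes):
        rs_ids = [g.gene_id for g in small_genomes.rootstock_genes]
        for key in small_transcripts.samples:
            if key.graft == "homo":
                col = small_transcripts.weights.loc[rs_ids, key.label]
                assert (col == 0).all()

    def test_planted_fold_change_is_exact_on_weights(self):
        cfg = config(de_log2fc=1.5)
        g = gt.simulate_genomes(cfg)
        t = gt.simulate_transcriptome(g, cfg)
        ww = t.weights["hetero_WW_d11"]
        ws = t.weights["hetero_WS_d11"]
        for gene, lfc in t.de_log2fc.items():
            assert ws[gene] / ww[gene] == pytest.approx(2.0 ** lfc, rel=1e-12)

    def test_mobile_abundance_monotone_in_stress_exposure(self,
                                                          small_transcripts):
        ab = small_transcripts.abundance
        for gene in small_transcripts.mobile_truth:
            assert ab.loc[gene, "hetero_WS_d11"] >= ab.loc[gene,
                                                           "hetero_WS_d4"]

    def test_mobile_truth_subset_of_rootstock(self, small_transcripts,
                                              small_genomes):
        rs = {g.gene_id for g in small_genomes.rootstock_genes}
        assert small_transcripts.mobile_truth <= rs

    def test_unknown_sample_rejected(self, small_transcripts, small_genomes,
                                     small_config):
        with pytest.raises(KeyError):
            gt.simulate_reads(small_transcripts, small_genomes, small_config,
                              gt.SampleKey("hetero", "WS", 99))


class TestReads:
    def test_error_free_reads_are_transcript_substrings(self):
        cfg = config(sequencing_error_rate=0.0)
        g = gt.simulate_genomes(cfg)
        t = gt.simulate_transcriptome(g, cfg)
        batch = gt.simulate_reads(t, g, cfg, gt.SampleKey("hetero", "WS", 11),
                                  depth=200)
        for m1, m2, gene in zip(batch.mate1, batch.mate2, batch.truth_gene):
            seq = t.sequences[gene]
            assert m1 in seq
            assert _seq.revcomp(m2) in seq

    def test_single_gene_single_fragment(self):
        cfg = config(sequencing_error_rate=0.0)
        g = gt.simulate_genomes(cfg)
        t = gt.simulate_transcriptome(g, cfg)
        gene = t.weights.index[0]
        t.weights.loc[:, :] = 0.0
        t.weights.loc[gene, :] = 1.0
        batch = gt.simulate_reads(t, g, cfg, gt.SampleKey("homo", "WW", 0),
                                  depth=1)
        assert len(batch) == 1
        assert batch.truth_gene == [gene]
        assert batch.mate1[0] in t.sequences[gene]
        assert _seq.revcomp(batch.mate2[0]) in t.sequences[gene]

    def test_two_gene_split_matches_binomial_oracle(self):
        cfg = config(sequencing_error_rate=0.0)
        g = gt.simulate_genomes(cfg)
        t = gt.simulate_transcriptome(g, cfg)
        g1, g2 = t.weights.index[0], t.weights.index[1]
        t.weights.loc[:, :] = 0.0
        t.weights.loc[g1, :] = 0.5
        t.weights.loc[g2, :] = 0.5
        batch = gt.simulate_reads(t, g, cfg, gt.SampleKey("homo", "WW", 0),
                                  depth=10000)
        n1 = batch.truth_gene.count(g1)
        sd = (10000 * 0.25) ** 0.5
        assert abs(n1 - 5000) <= 3 * sd

    def test_zero_depth_returns_empty_batch(self, small_transcripts,
                                            small_genomes, small_config):
        batch = gt.simulate_reads(small_transcripts, small_genomes,
                                  small_config,
                                  gt.SampleKey("hetero", "WW", 0), depth=0)
        assert len(batch) == 0

    def test_same_seed_gives_byte_identical_fastq(self, tmp_path,
                                                  small_config,
                                                  small_genomes,
                                                  small_transcripts):
        from graftrace import io as gio
        key = gt.SampleKey("hetero", "WS", 11)
        paths = []
        for tag in ("a", "b"):
            batch = gt.simulate_reads(small_transcripts, small_genomes,
                                      small_config, key, depth=500)
            p1, p2 = gio.write_fastq_pair(batch, tmp_path / tag)
            paths.append((p1.read_bytes(), p2.read_bytes()))
        assert paths[0] == paths[1]


class TestDnaReads:
    def test_zero_depth_empty(self):
        cfg = config(dna_depth=0.0)
        g = gt.simulate_genomes(cfg)
        assert len(gt.simulate_dna_reads(g, cfg)) == 0

    def test_error_free_reads_substrings_of_true_scion(self):
        cfg = config(sequencing_error_rate=0.0)
        g = gt.simulate_genomes(cfg)
        batch = gt.simulate_dna_reads(g, cfg)
        for m1, contig in zip(batch.mate1[:100], batch.truth_gene[:100]):
            assert m1 in g.true_scion[contig]

    def test_total_bases_match_requested_coverage(self):
        cfg = config(dna_depth=20.0)
        g = gt.simulate_genomes(cfg)
        batch = gt.simulate_dna_reads(g, cfg)
        genome_bp = sum(len(s) for s in g.true_scion.values())
        total = 2 * cfg.read_length * len(batch)
        # fragment count is deterministic; allow one fragment of rounding
        assert abs(total - 20.0 * genome_bp) <= 2 * cfg.read_length


class TestRngStreams:
    def test_streams_are_independent_of_other_samples(self, small_config,
                                                      small_genomes,
                                                      small_transcripts):
        key = gt.SampleKey("hetero", "WS", 11)
        a = gt.simulate_reads(small_transcripts, small_genomes, small_config,
                              key, depth=300)
        # drawing another sample first must not shift this sample's reads
        gt.simulate_reads(small_transcripts, small_genomes, small_config,
                          gt.SampleKey("homo", "WW", 0), depth=300)
        b = gt.simulate_reads(small_transcripts, small_genomes, small_config,
                              key, depth=300)
        assert a.mate1 == b.mate1 and a.mate2 == b.mate2

    def test_distinct_tags_give_distinct_streams(self):
        r1 = gt.rng_stream(1, "a").integers(0, 1 << 30, 8)
        r2 = gt.rng_stream(1, "b").integers(0, 1 << 30, 8)
        assert not np.array_equal(r1, r2)
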